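"""Gate-level circuits and a dense statevector simulator.

Primitive gate set: rx, ry, rz, u3 (single-qubit), cx, cz (two-qubit)
plus the composite 15-parameter ``su4`` block used by the compiler,
which expands exactly into u3 layers and six CX gates.  Qubit q lives on
bit q of the basis index (little-endian), matching the Pauli module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

GateSpec = Tuple[str, Tuple[int, ...], Tuple[float, ...]]

_SQRT2 = np.sqrt(0.5)


def _rx(t):
    c, s = np.cos(t / 2), np.sin(t / 2)
    return np.array([[c, -1j * s], [-1j * s, c]])


def _ry(t):
    c, s = np.cos(t / 2), np.sin(t / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _rz(t):
    return np.diag([np.exp(-0.5j * t), np.exp(0.5j * t)])


def _u3(theta, phi, lam):
    return _rz(phi) @ _ry(theta) @ _rz(lam)


_CX = np.array(
    [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=complex
)
_CZ = np.diag([1, 1, 1, -1]).astype(complex)
_H = np.array([[_SQRT2, _SQRT2], [_SQRT2, -_SQRT2]], dtype=complex)
_X = np.array([[0, 1], [1, 0]], dtype=complex)

GATE_ARITY = {"rx": 1, "ry": 1, "rz": 1, "u3": 1, "h": 1, "x": 1,
              "cx": 2, "cz": 2, "su4": 2}
GATE_NPARAMS = {"rx": 1, "ry": 1, "rz": 1, "u3": 3, "h": 0, "x": 0,
                "cx": 0, "cz": 0, "su4": 15}


# Bell states diagonalize XX, YY and ZZ simultaneously; columns are
# Phi+, Phi-, Psi+, Psi- with signed eigenvalue rows (XX, YY, ZZ)
_BELL = np.array(
    [[1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, -1], [1, -1, 0, 0]], dtype=complex
) * _SQRT2
_BELL_SIGNS = np.array(
    [[1, -1, 1], [-1, 1, 1], [1, 1, -1], [-1, -1, -1]], dtype=float
)


def _interaction_core(cx_angle: float, cy: float, cz: float) -> np.ndarray:
    """exp(-i/2 (cx XX + cy YY + cz ZZ)); the three terms commute."""
    phases = np.exp(-0.5j * (_BELL_SIGNS @ np.array([cx_angle, cy, cz])))
    return (_BELL * phases) @ _BELL.conj().T


def gate_matrix(name: str, params: Sequence[float]) -> np.ndarray:
    """Unitary of a gate; 4x4 matrices index the first tuple qubit as the
    most significant gate-local bit."""
    if name == "rx":
        return _rx(params[0])
    if name == "ry":
        return _ry(params[0])
    if name == "rz":
        return _rz(params[0])
    if name == "u3":
        return _u3(*params)
    if name == "h":
        return _H
    if name == "x":
        return _X
    if name == "cx":
        return _CX
    if name == "cz":
        return _CZ
    if name == "su4":
        p = params
        pre = np.kron(_u3(*p[0:3]), _u3(*p[3:6]))
        core = _interaction_core(p[6], p[7], p[8])
        post = np.kron(_u3(*p[9:12]), _u3(*p[12:15]))
        return post @ core @ pre
    raise ValueError(f"unknown gate {name!r}")


@dataclass
class GateCircuit:
    """Ordered list of gates on a fixed register."""

    n_qubits: int
    gates: List[GateSpec] = field(default_factory=list)
    metadata: Dict = field(default_factory=dict)

    def add(self, name: str, qubits: Iterable[int], params: Iterable[float] = ()):
        qubits = tuple(int(q) for q in qubits)
        params = tuple(float(p) for p in params)
        if name not in GATE_ARITY:
            raise ValueError(f"unknown gate {name!r}")
        if len(qubits) != GATE_ARITY[name]:
            raise ValueError(f"gate {name} expects {GATE_ARITY[name]} qubits")
        if len(params) != GATE_NPARAMS[name]:
            raise ValueError(f"gate {name} expects {GATE_NPARAMS[name]} parameters")
        if len(set(qubits)) != len(qubits) or any(
            q < 0 or q >= self.n_qubits for q in qubits
        ):
            raise ValueError(f"invalid qubit tuple {qubits}")
        self.gates.append((name, qubits, params))
        return self

    # -- simulation ---------------------------------------------------
    def apply_to(self, psi: np.ndarray) -> np.ndarray:
        psi = np.asarray(psi, dtype=complex)
        for name, qubits, params in self.gates:
            psi = apply_gate(psi, self.n_qubits, name, qubits, params)
        return psi

    def statevector(self, initial: Optional[np.ndarray] = None) -> np.ndarray:
        if initial is None:
            initial = np.zeros(1 << self.n_qubits, dtype=complex)
            initial[0] = 1.0
        return self.apply_to(initial)

    # -- manipulation -------------------------------------------------
    def expand(self) -> "GateCircuit":
        """Rewrite composite su4 blocks into u3 + 6 CX primitives."""
        out = GateCircuit(self.n_qubits, metadata=dict(self.metadata))
        for name, qubits, params in self.gates:
            if name != "su4":
                out.gates.append((name, qubits, params))
                continue
            a, b = qubits
            p = params
            out.add("u3", (a,), p[0:3])
            out.add("u3", (b,), p[3:6])
            # Rxx(c) = (H ⊗ H) CX (I ⊗ Rz(c)) CX (H ⊗ H)
            out.add("h", (a,)).add("h", (b,))
            out.add("cx", (a, b)).add("rz", (b,), (p[6],)).add("cx", (a, b))
            out.add("h", (a,)).add("h", (b,))
            # Ryy(c) = (Rx(pi/2) ⊗ Rx(pi/2)) CX (I ⊗ Rz(c)) CX (Rx(-pi/2) ⊗ ..)
            out.add("rx", (a,), (np.pi / 2,)).add("rx", (b,), (np.pi / 2,))
            out.add("cx", (a, b)).add("rz", (b,), (p[7],)).add("cx", (a, b))
            out.add("rx", (a,), (-np.pi / 2,)).add("rx", (b,), (-np.pi / 2,))
            # Rzz(c) = CX (I ⊗ Rz(c)) CX
            out.add("cx", (a, b)).add("rz", (b,), (p[8],)).add("cx", (a, b))
            out.add("u3", (a,), p[9:12])
            out.add("u3", (b,), p[12:15])
        return out

    def inverse(self) -> "GateCircuit":
        inv = GateCircuit(self.n_qubits, metadata=dict(self.metadata))
        for name, qubits, params in reversed(self.gates):
            if name in ("rx", "ry", "rz"):
                inv.gates.append((name, qubits, (-params[0],)))
            elif name == "u3":
                t, p, l = params
                inv.gates.append((name, qubits, (-t, -l, -p)))
            elif name in ("cx", "cz", "h", "x"):
                inv.gates.append((name, qubits, params))
            elif name == "su4":
                raise ValueError("expand su4 blocks before inverting")
        return inv

    # -- serialization ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_qubits": self.n_qubits,
                "gates": [
                    {"name": n, "qubits": list(q), "params": list(p)}
                    for n, q, p in self.gates
                ],
                "metadata": self.metadata,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GateCircuit":
        doc = json.loads(text)
        circ = cls(int(doc["n_qubits"]), metadata=doc.get("metadata", {}))
        for g in doc["gates"]:
            circ.add(g["name"], g["qubits"], g.get("params", ()))
        return circ

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path) -> "GateCircuit":
        return cls.from_json(Path(path).read_text())

    def to_qasm(self) -> str:
        """OpenQASM 2-style text (gate set rx, ry, rz, u3, h, x, cx, cz)."""
        flat = self.expand()
        lines = [
            "OPENQASM 2.0;",
            'include "qelib1.inc";',
            f"qreg q[{self.n_qubits}];",
        ]
        for name, qubits, params in flat.gates:
            args = ",".join(f"{p:.17g}" for p in params)
            head = f"{name}({args})" if params else name
            lines.append(head + " " + ",".join(f"q[{q}]" for q in qubits) + ";")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_qasm(cls, text: str) -> "GateCircuit":
        circ = None
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip().rstrip(";")
            if (not line or line.startswith("OPENQASM")
                    or line.startswith("include") or line.startswith("//")):
                continue
            if line.startswith("qreg"):
                n = int(line[line.index("[") + 1: line.index("]")])
                circ = cls(n)
                continue
            if circ is None:
                raise ValueError(f"line {lineno}: gate before qreg declaration")
            head, _, tail = line.partition(" ")
            if "(" in head:
                name, argstr = head.split("(", 1)
                params = [float(a) for a in argstr.rstrip(")").split(",")]
            else:
                name, params = head, []
            qubits = [
                int(tok[tok.index("[") + 1: tok.index("]")])
                for tok in tail.split(",")
            ]
            circ.add(name, qubits, params)
        if circ is None:
            raise ValueError("no qreg declaration found")
        return circ

    def __len__(self) -> int:
        return len(self.gates)


def apply_gate(
    psi: np.ndarray, n_qubits: int, name: str,
    qubits: Tuple[int, ...], params: Sequence[float],
) -> np.ndarray:
    mat = gate_matrix(name, params)
    return apply_unitary(psi, n_qubits, mat, qubits)


def apply_unitary(
    psi: np.ndarray, n_qubits: int, mat: np.ndarray, qubits: Tuple[int, ...]
) -> np.ndarray:
    """Apply a 2^k x 2^k unitary on the given qubits (first qubit = most
    significant gate-local bit)."""
    arr = psi.reshape([2] * n_qubits)
    # axis for qubit q is n-1-q because bit q is the q-th least significant
    axes = [n_qubits - 1 - q for q in qubits]
    k = len(qubits)
    tensor = mat.reshape([2] * (2 * k))
    arr = np.tensordot(tensor, arr, axes=(list(range(k, 2 * k)), axes))
    arr = np.moveaxis(arr, list(range(k)), axes)
    return arr.reshape(-1)


def circuit_metrics(circuit: GateCircuit) -> Tuple[int, int]:
    """(two_qubit_count, two_qubit_depth) with single-qubit gates free.

    Composite su4 blocks count through their CX expansion.
    """
    flat = circuit.expand()
    level = [0] * circuit.n_qubits
    count = 0
    for name, qubits, _ in flat.gates:
        if len(qubits) != 2:
            continue
        count += 1
        lvl = max(level[q] for q in qubits) + 1
        for q in qubits:
            level[q] = lvl
    depth = max(level) if level else 0
    return count, depth
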