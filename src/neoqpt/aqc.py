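"""Adaptive approximate quantum compiling.

Builds a circuit of general two-qubit SU(4) blocks (over an initial
layer of free single-qubit rotations) that minimizes the infidelity
C = 1 - |<target|V(theta)|0>|^2 against a target statevector.  Blocks
are appended greedily: every candidate qubit pair gets a short trial
optimization of a fresh block, the best pair is kept, and all circuit
parameters are then re-optimized.

Internally the ansatz is flattened into elementary Pauli rotations
exp(-i theta/2 G) (u3 -> rz.ry.rz; the SU(4) core -> commuting XX, YY,
ZZ rotations), which gives an exact reverse-mode gradient of the cost
in two sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

from .circuits import GateCircuit, circuit_metrics
from .pauli import PauliSum


class AQCError(RuntimeError):
    pass


_BLOCK_NPARAMS = 15
_U3_NPARAMS = 3


@dataclass
class AQCResult:
    circuit: GateCircuit
    cost: float
    two_qubit_count: int
    two_qubit_depth: int
    block_history: List[Tuple[Tuple[int, int], float]]
    converged: bool
    preset: str
    seed: int

    @property
    def fidelity(self) -> float:
        return 1.0 - self.cost

    @property
    def n_blocks(self) -> int:
        return len(self.block_history)


def _pauli_on(n: int, spec: Sequence[Tuple[int, str]]) -> PauliSum:
    label = ["I"] * n
    for q, ch in spec:
        label[q] = ch
    return PauliSum.from_label("".join(label))


class _RotAnsatz:
    """u3 layer + su4 blocks flattened to elementary Pauli rotations.

    Parameters keep the circuit-order layout (3 per qubit for the u3
    layer, then 15 per block) so the structure converts losslessly to a
    GateCircuit; each parameter drives exactly one rotation gate.
    """

    def __init__(self, n_qubits: int):
        self.n_qubits = n_qubits
        self.pairs: List[Tuple[int, int]] = []
        # elementary gates as (generator PauliSum, parameter index)
        self.gates: List[Tuple[PauliSum, int]] = []
        for q in range(n_qubits):
            self._add_u3(q, 3 * q)

    def _add_u3(self, q: int, base: int) -> None:
        n = self.n_qubits
        # u3(theta, phi, lam) = Rz(phi) Ry(theta) Rz(lam), rightmost first
        self.gates.append((_pauli_on(n, [(q, "Z")]), base + 2))
        self.gates.append((_pauli_on(n, [(q, "Y")]), base + 0))
        self.gates.append((_pauli_on(n, [(q, "Z")]), base + 1))

    @property
    def n_params(self) -> int:
        return _U3_NPARAMS * self.n_qubits + _BLOCK_NPARAMS * len(self.pairs)

    def add_block(self, pair: Tuple[int, int]) -> None:
        a, b = pair
        n = self.n_qubits
        base = self.n_params
        self.pairs.append(tuple(pair))
        self._add_u3(a, base + 0)
        self._add_u3(b, base + 3)
        self.gates.append((_pauli_on(n, [(a, "X"), (b, "X")]), base + 6))
        self.gates.append((_pauli_on(n, [(a, "Y"), (b, "Y")]), base + 7))
        self.gates.append((_pauli_on(n, [(a, "Z"), (b, "Z")]), base + 8))
        self._add_u3(a, base + 9)
        self._add_u3(b, base + 12)

    # -- evaluation ---------------------------------------------------
    @staticmethod
    def _rotate(gen: PauliSum, theta: float, psi: np.ndarray) -> np.ndarray:
        return np.cos(theta / 2.0) * psi - 1j * np.sin(theta / 2.0) * gen.apply(psi)

    def prepare(self, theta: np.ndarray) -> np.ndarray:
        psi = np.zeros(1 << self.n_qubits, dtype=complex)
        psi[0] = 1.0
        for gen, k in self.gates:
            psi = self._rotate(gen, theta[k], psi)
        return psi

    def cost_and_grad(
        self, target: np.ndarray, theta: np.ndarray
    ) -> Tuple[float, np.ndarray]:
        """C = 1 - |<t|V|0>|^2 and its exact gradient (two sweeps)."""
        states = [None] * (len(self.gates) + 1)
        psi = np.zeros(1 << self.n_qubits, dtype=complex)
        psi[0] = 1.0
        states[0] = psi
        for i, (gen, k) in enumerate(self.gates):
            psi = self._rotate(gen, theta[k], psi)
            states[i + 1] = psi
        s = np.vdot(target, psi)
        grad = np.zeros(len(theta))
        phi = target.copy()
        for i in range(len(self.gates) - 1, -1, -1):
            gen, k = self.gates[i]
            # ds/dtheta_k = <phi_i| (-i/2 G) |psi_i>
            ds = np.vdot(phi, -0.5j * gen.apply(states[i + 1]))
            grad[k] += -2.0 * np.real(np.conj(s) * ds)
            phi = self._rotate(gen, -theta[k], phi)
        return float(1.0 - np.abs(s) ** 2), grad

    def cost(self, target: np.ndarray, theta: np.ndarray) -> float:
        psi = self.prepare(theta)
        return float(1.0 - np.abs(np.vdot(target, psi)) ** 2)

    def to_circuit(self, theta: np.ndarray, metadata=None) -> GateCircuit:
        circ = GateCircuit(self.n_qubits, metadata=metadata or {})
        for q in range(self.n_qubits):
            circ.add("u3", (q,), theta[3 * q: 3 * q + 3])
        off = _U3_NPARAMS * self.n_qubits
        for b, pair in enumerate(self.pairs):
            circ.add("su4", pair, theta[off + 15 * b: off + 15 * b + 15])
        return circ


class _TrialBlock:
    """One fresh su4 block (15 rotations) applied to a fixed prefix state."""

    def __init__(self, n_qubits: int, pair: Tuple[int, int], prefix: np.ndarray):
        self.prefix = prefix
        helper = _RotAnsatz.__new__(_RotAnsatz)
        helper.n_qubits = n_qubits
        helper.pairs = []
        helper.gates = []
        helper._add_u3(pair[0], 0)
        helper._add_u3(pair[1], 3)
        helper.gates.append((_pauli_on(n_qubits, [(pair[0], "X"), (pair[1], "X")]), 6))
        helper.gates.append((_pauli_on(n_qubits, [(pair[0], "Y"), (pair[1], "Y")]), 7))
        helper.gates.append((_pauli_on(n_qubits, [(pair[0], "Z"), (pair[1], "Z")]), 8))
        helper._add_u3(pair[0], 9)
        helper._add_u3(pair[1], 12)
        self.helper = helper

    def cost_and_grad(self, target: np.ndarray, theta: np.ndarray):
        h = self.helper
        states = [self.prefix]
        psi = self.prefix
        for gen, k in h.gates:
            psi = _RotAnsatz._rotate(gen, theta[k], psi)
            states.append(psi)
        s = np.vdot(target, psi)
        grad = np.zeros(15)
        phi = target.copy()
        for i in range(len(h.gates) - 1, -1, -1):
            gen, k = h.gates[i]
            ds = np.vdot(phi, -0.5j * gen.apply(states[i + 1]))
            grad[k] += -2.0 * np.real(np.conj(s) * ds)
            phi = _RotAnsatz._rotate(gen, -theta[k], phi)
        return float(1.0 - np.abs(s) ** 2), grad


def aqc_cost(target: np.ndarray, circuit: GateCircuit,
             parameters: Optional[Sequence[float]] = None) -> float:
    """C = 1 - |<target|V|0>|^2; `parameters` optionally overrides every
    parameterized gate's parameters in declaration order."""
    if circuit.n_qubits != int(np.log2(len(target))):
        raise AQCError("target dimension does not match the circuit register")
    if abs(np.linalg.norm(target) - 1.0) > 1e-8:
        raise AQCError("target statevector must be normalized")
    if parameters is not None:
        parameters = list(parameters)
        circ = GateCircuit(circuit.n_qubits, metadata=dict(circuit.metadata))
        pos = 0
        for name, qubits, params in circuit.gates:
            k = len(params)
            circ.add(name, qubits, parameters[pos: pos + k])
            pos += k
        if pos != len(parameters):
            raise AQCError("parameter vector length mismatch")
        circuit = circ
    psi = circuit.statevector()
    return float(np.clip(1.0 - np.abs(np.vdot(target, psi)) ** 2, 0.0, 1.0))


PRESETS = {
    "high": {"cost_tol": 1e-2, "max_blocks": 60},
    "low": {"cost_tol": 5e-2, "max_blocks": 8},
}


def _candidate_pairs(n_qubits: int, topology: str) -> List[Tuple[int, int]]:
    if topology == "all-to-all":
        return list(combinations(range(n_qubits), 2))
    if topology == "linear":
        return [(q, q + 1) for q in range(n_qubits - 1)]
    raise ValueError(f"unknown topology {topology!r}")


def _minimize(fun, x0, maxiter):
    return scipy.optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
    )


def run_adapt_aqc(
    target: np.ndarray,
    preset: str = "high",
    seed: int = 0,
    cost_tol: Optional[float] = None,
    max_blocks: Optional[int] = None,
    topology: str = "all-to-all",
    trial_maxiter: int = 40,
    full_maxiter: int = 300,
    n_restarts: int = 2,
    stagnation_patience: int = 3,
) -> AQCResult:
    """Greedy two-qubit-block compilation of the target state."""
    target = np.asarray(target, dtype=complex)
    n_qubits = int(np.log2(len(target)))
    if 1 << n_qubits != len(target):
        raise AQCError("target length is not a power of two")
    if n_qubits < 2:
        raise AQCError("need at least 2 qubits")
    if abs(np.linalg.norm(target) - 1.0) > 1e-8:
        raise AQCError("target statevector must be normalized")
    if preset in PRESETS:
        cfg = PRESETS[preset]
        cost_tol = cfg["cost_tol"] if cost_tol is None else cost_tol
        max_blocks = cfg["max_blocks"] if max_blocks is None else max_blocks
    elif preset != "custom":
        raise ValueError(f"unknown preset {preset!r}")
    if cost_tol is None or max_blocks is None:
        raise ValueError("custom preset requires cost_tol and max_blocks")

    rng = np.random.default_rng(seed)
    ansatz = _RotAnsatz(n_qubits)
    pairs = _candidate_pairs(n_qubits, topology)

    # optimize the free single-qubit layer first
    best = None
    for r in range(n_restarts):
        x0 = np.zeros(ansatz.n_params) if r == 0 else rng.uniform(
            -np.pi, np.pi, ansatz.n_params
        )
        res = _minimize(lambda x: ansatz.cost_and_grad(target, x), x0, full_maxiter)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    cost = ansatz.cost(target, theta)
    history: List[Tuple[Tuple[int, int], float]] = []
    converged = cost <= cost_tol
    stagnant = 0

    while not converged and len(ansatz.pairs) < max_blocks:
        prefix = ansatz.prepare(theta)
        best_pair, best_block, best_trial = None, None, np.inf
        for pair in pairs:
            trial = _TrialBlock(n_qubits, pair, prefix)
            for r in range(n_restarts):
                x0 = np.zeros(15) if r == 0 else rng.uniform(-np.pi, np.pi, 15)
                res = _minimize(lambda x: trial.cost_and_grad(target, x), x0,
                                trial_maxiter)
                if res.fun < best_trial:
                    best_pair, best_block, best_trial = pair, res.x, res.fun

        if best_trial >= cost - 1e-9:
            # no pair helps greedily: extend coverage with the least-used pair
            usage = {p: 0 for p in pairs}
            for p in ansatz.pairs:
                if p in usage:
                    usage[p] += 1
            best_pair = min(pairs, key=lambda p: (usage[p], p))
            best_block = np.zeros(15)

        ansatz.add_block(best_pair)
        theta_new = np.concatenate([theta, best_block])
        res = _minimize(lambda x: ansatz.cost_and_grad(target, x), theta_new,
                        full_maxiter)
        if res.fun <= cost:
            theta, new_cost = res.x, float(res.fun)
        else:
            theta, new_cost = theta_new, min(cost, best_trial)
        improvement = cost - new_cost
        history.append((best_pair, new_cost))
        cost = new_cost
        if cost <= cost_tol:
            converged = True
            break
        if improvement < 1e-12:
            # escape attempt: random re-initialization of the whole circuit
            rescued = False
            for _ in range(n_restarts + 2):
                x0 = rng.uniform(-np.pi, np.pi, ansatz.n_params)
                res = _minimize(lambda x: ansatz.cost_and_grad(target, x), x0,
                                2 * full_maxiter)
                if res.fun < cost - 1e-12:
                    theta, cost = res.x, float(res.fun)
                    history[-1] = (best_pair, cost)
                    rescued = True
                    break
            if not rescued:
                stagnant += 1
                if stagnant >= stagnation_patience:
                    break
            else:
                stagnant = 0
                if cost <= cost_tol:
                    converged = True
                    break
        else:
            stagnant = 0

    circuit = ansatz.to_circuit(theta, metadata={"preset": preset, "seed": seed})
    count, depth = circuit_metrics(circuit)
    final = aqc_cost(target, circuit)
    return AQCResult(circuit, final, count, depth, history, converged, preset, seed)


def compress_with_prefix(
    full_circuit: GateCircuit,
    split_point: int,
    preset: str = "high",
    seed: int = 0,
    **kwargs,
) -> GateCircuit:
    """Factor U = U1 U0 at a gate index and recompile the prefix state.

    Returns the circuit (compressed U0) followed by the untouched suffix
    U1; the end-state fidelity to U|0> equals the prefix compilation
    fidelity because the suffix is applied verbatim.
    """
    if split_point < 0 or split_point > len(full_circuit.gates):
        raise AQCError("split point out of range")
    if split_point == 0:
        return full_circuit
    prefix = GateCircuit(full_circuit.n_qubits, full_circuit.gates[:split_point])
    psi0 = prefix.statevector()
    result = run_adapt_aqc(psi0, preset=preset, seed=seed, **kwargs)
    out = GateCircuit(
        full_circuit.n_qubits,
        list(result.circuit.gates) + list(full_circuit.gates[split_point:]),
        metadata={
            "preset": preset,
            "seed": seed,
            "split_point": split_point,
            "prefix_cost": result.cost,
        },
    )
    return out
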