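"""Sparse Pauli-string algebra on statevectors.

A Pauli term on ``n`` qubits is stored as a pair of bit masks ``(x, z)``
with qubit ``q`` living on bit ``q`` of the basis-state index
(little-endian).  The operator encoded by ``(x, z)`` is

    i^{popcount(x & z)} * X^x * Z^z

which reproduces Y = i X Z on every qubit where both bits are set.  A
:class:`PauliSum` is a dictionary of such terms with complex weights.
String labels put qubit 0 in the leftmost character, e.g. ``"XZI"`` is
X on qubit 0, Z on qubit 1.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import scipy.sparse as sp

Key = Tuple[int, int]

_CHAR_TO_XZ = {"I": (0, 0), "X": (1, 0), "Y": (1, 1), "Z": (0, 1)}
_XZ_TO_CHAR = {v: k for k, v in _CHAR_TO_XZ.items()}


def _popcount(v: int) -> int:
    return int(v).bit_count()


def label_to_key(label: str) -> Key:
    x = z = 0
    for q, ch in enumerate(label):
        try:
            xq, zq = _CHAR_TO_XZ[ch]
        except KeyError:
            raise ValueError(f"invalid Pauli character {ch!r} in {label!r}")
        x |= xq << q
        z |= zq << q
    return x, z


def key_to_label(key: Key, n_qubits: int) -> str:
    x, z = key
    return "".join(_XZ_TO_CHAR[((x >> q) & 1, (z >> q) & 1)] for q in range(n_qubits))


def _term_product(k1: Key, c1: complex, k2: Key, c2: complex) -> Tuple[Key, complex]:
    """Product of two normal-form Pauli terms (left times right)."""
    x1, z1 = k1
    x2, z2 = k2
    x3, z3 = x1 ^ x2, z1 ^ z2
    # phase bookkeeping: i-exponent from Y normal forms plus XZ reordering sign
    ipow = (_popcount(x1 & z1) + _popcount(x2 & z2) - _popcount(x3 & z3)) % 4
    sign = -1.0 if _popcount(z1 & x2) & 1 else 1.0
    return (x3, z3), c1 * c2 * sign * (1j ** ipow)


class PauliSum:
    """Weighted sum of Pauli strings acting on a fixed qubit register."""

    __slots__ = ("n_qubits", "terms")

    def __init__(self, n_qubits: int, terms: Mapping[Key, complex] | None = None):
        self.n_qubits = int(n_qubits)
        self.terms: Dict[Key, complex] = dict(terms or {})

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls, n_qubits: int, coeff: complex = 1.0) -> "PauliSum":
        return cls(n_qubits, {(0, 0): coeff})

    @classmethod
    def zero(cls, n_qubits: int) -> "PauliSum":
        return cls(n_qubits, {})

    @classmethod
    def from_label(cls, label: str, coeff: complex = 1.0) -> "PauliSum":
        return cls(len(label), {label_to_key(label): coeff})

    @classmethod
    def from_label_dict(cls, n_qubits: int, d: Mapping[str, complex]) -> "PauliSum":
        out = cls(n_qubits)
        for label, c in d.items():
            if len(label) != n_qubits:
                raise ValueError("label length != n_qubits")
            out._add_term(label_to_key(label), c)
        return out

    # -- algebra ------------------------------------------------------
    def _add_term(self, key: Key, coeff: complex) -> None:
        c = self.terms.get(key, 0.0) + coeff
        if c == 0.0:
            self.terms.pop(key, None)
        else:
            self.terms[key] = c

    def __add__(self, other: "PauliSum") -> "PauliSum":
        out = PauliSum(self.n_qubits, self.terms)
        for k, c in other.terms.items():
            out._add_term(k, c)
        return out

    def __sub__(self, other: "PauliSum") -> "PauliSum":
        return self + (other * -1.0)

    def __mul__(self, other):
        if isinstance(other, PauliSum):
            out = PauliSum(self.n_qubits)
            for k1, c1 in self.terms.items():
                for k2, c2 in other.terms.items():
                    k3, c3 = _term_product(k1, c1, k2, c2)
                    out._add_term(k3, c3)
            return out
        out = PauliSum(self.n_qubits)
        for k, c in self.terms.items():
            out._add_term(k, c * other)
        return out

    __rmul__ = __mul__

    def dagger(self) -> "PauliSum":
        return PauliSum(self.n_qubits, {k: np.conj(c) for k, c in self.terms.items()})

    def prune(self, tol: float = 1e-12) -> "PauliSum":
        return PauliSum(
            self.n_qubits, {k: c for k, c in self.terms.items() if abs(c) > tol}
        )

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return all(abs(c.imag if isinstance(c, complex) else 0.0) <= tol
                   for c in self.terms.values())

    def is_antihermitian(self, tol: float = 1e-10) -> bool:
        return all(abs(complex(c).real) <= tol for c in self.terms.values())

    # -- representations ----------------------------------------------
    def label_dict(self) -> Dict[str, complex]:
        return {key_to_label(k, self.n_qubits): c for k, c in self.terms.items()}

    def apply(self, psi: np.ndarray) -> np.ndarray:
        """Apply the operator to a statevector of dimension 2**n_qubits."""
        dim = 1 << self.n_qubits
        if psi.shape[0] != dim:
            raise ValueError("statevector dimension mismatch")
        idx = np.arange(dim, dtype=np.uint64)
        out = np.zeros(dim, dtype=complex)
        for (x, z), c in self.terms.items():
            phase = c * (1j ** _popcount(x & z))
            signs = 1.0 - 2.0 * (np.bitwise_count(idx & np.uint64(z)) & 1).astype(float)
            out[idx ^ np.uint64(x)] += phase * signs * psi
        return out

    def expectation(self, psi: np.ndarray) -> complex:
        return complex(np.vdot(psi, self.apply(psi)))

    def to_sparse(self) -> sp.csr_matrix:
        dim = 1 << self.n_qubits
        idx = np.arange(dim, dtype=np.uint64)
        mats = []
        for (x, z), c in self.terms.items():
            phase = c * (1j ** _popcount(x & z))
            signs = 1.0 - 2.0 * (np.bitwise_count(idx & np.uint64(z)) & 1).astype(float)
            rows = (idx ^ np.uint64(x)).astype(np.int64)
            mats.append(
                sp.coo_matrix(
                    (phase * signs, (rows, idx.astype(np.int64))), shape=(dim, dim)
                )
            )
        if not mats:
            return sp.csr_matrix((dim, dim), dtype=complex)
        out = mats[0]
        for m in mats[1:]:
            out = out + m
        return out.tocsr()

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        items = ", ".join(
            f"{key_to_label(k, self.n_qubits)}: {c:+.4g}"
            for k, c in list(self.terms.items())[:6]
        )
        more = "" if len(self.terms) <= 6 else f", ... ({len(self.terms)} terms)"
        return f"PauliSum({self.n_qubits}, {{{items}{more}}})"


def pauli_string_sectors(op: PauliSum) -> Iterable[PauliSum]:
    """Split a sum into one single-string PauliSum per term."""
    for k, c in op.terms.items():
        yield PauliSum(op.n_qubits, {k: c})
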