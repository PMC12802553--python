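"""Coupled electron-proton second-quantized Hamiltonians.

Data model and algebra for Hamiltonians of the form

    H = E_core
      + sum_pq h1e[p,q] sum_s a†_ps a_qs
      + 1/2 sum_pqrs h2e[p,q,r,s] sum_st a†_ps a†_qt a_st a_rs   (physicist <pq|rs>)
      + sum_PQ v1p[P,Q] b†_P b_Q
      + sum_PQpq gep[P,Q,p,q] b†_P b_Q sum_s a†_ps a_qs

with lowercase indices over electronic *spatial* orbitals (expanded over
two spin channels) and uppercase indices over protonic orbitals carried
in a single spin channel (exactly one proton).  All tensors are real.

Qubit layout for the Jordan-Wigner mapping: electronic spin-up block,
then spin-down block, then the protonic block, each in ascending orbital
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fermion import FermionTerm, jordan_wigner
from .pauli import PauliSum

DEFAULT_SYMMETRY_TOL = 1e-8

#: index permutations of the 8-fold real-orbital symmetry group of the
#: physicist-notation two-electron tensor <pq|rs>
_H2E_PERMS = (
    (0, 1, 2, 3),
    (2, 1, 0, 3),
    (0, 3, 2, 1),
    (2, 3, 0, 1),
    (1, 0, 3, 2),
    (3, 0, 1, 2),
    (1, 2, 3, 0),
    (3, 2, 1, 0),
)


class ValidationError(ValueError):
    """Raised when a Hamiltonian or matrix violates a declared invariant."""


@dataclass(frozen=True)
class OrbitalSpace:
    """Orbital bookkeeping for one coupled electron-proton system."""

    n_electronic_spatial: int
    n_protonic: int
    n_electrons: int
    n_protons: int = 1
    electronic_labels: Tuple[str, ...] = ()
    protonic_labels: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_electronic_spatial < 1 or self.n_protonic < 1:
            raise ValidationError("orbital counts must be positive")
        if self.n_electrons > self.n_electronic_spin:
            raise ValidationError("n_electrons exceeds number of spin orbitals")
        if self.n_protons != 1:
            raise ValidationError("exactly one quantum proton is supported")
        if self.n_protons > self.n_protonic:
            raise ValidationError("n_protons exceeds protonic orbital count")
        e_labels = self.electronic_labels or tuple(
            f"e{i}" for i in range(self.n_electronic_spatial)
        )
        p_labels = self.protonic_labels or tuple(
            f"p{i}" for i in range(self.n_protonic)
        )
        if len(set(e_labels)) != self.n_electronic_spatial:
            raise ValidationError("electronic labels not unique")
        if len(set(p_labels)) != self.n_protonic:
            raise ValidationError("protonic labels not unique")
        object.__setattr__(self, "electronic_labels", e_labels)
        object.__setattr__(self, "protonic_labels", p_labels)

    @property
    def n_electronic_spin(self) -> int:
        return 2 * self.n_electronic_spatial

    @property
    def n_qubits(self) -> int:
        return self.n_electronic_spin + self.n_protonic

    # mode layout: up block, down block, protonic block
    def mode_up(self, p: int) -> int:
        return p

    def mode_down(self, p: int) -> int:
        return self.n_electronic_spatial + p

    def mode_protonic(self, P: int) -> int:
        return self.n_electronic_spin + P

    def electronic_spin_modes(self) -> List[int]:
        return list(range(self.n_electronic_spin))

    def protonic_modes(self) -> List[int]:
        return [self.mode_protonic(P) for P in range(self.n_protonic)]


def symmetrize_h2e(t: np.ndarray) -> np.ndarray:
    """Project onto the 8-fold permutational symmetry group."""
    acc = np.zeros_like(t)
    for perm in _H2E_PERMS:
        acc += np.transpose(t, perm)
    return acc / len(_H2E_PERMS)


def h2e_symmetry_residual(t: np.ndarray) -> float:
    return max(
        float(np.max(np.abs(t - np.transpose(t, perm)))) for perm in _H2E_PERMS[1:]
    )


@dataclass
class NEOHamiltonian:
    """Second-quantized coupled electron-proton Hamiltonian."""

    space: OrbitalSpace
    core_energy: float
    h1e: np.ndarray  # (n_sp, n_sp), spatial
    h2e: np.ndarray  # (n_sp,)*4, physicist <pq|rs>
    v1p: np.ndarray  # (n_P, n_P)
    gep: np.ndarray  # (n_P, n_P, n_sp, n_sp)

    def __post_init__(self):
        self.h1e = np.asarray(self.h1e, dtype=float)
        self.h2e = np.asarray(self.h2e, dtype=float)
        self.v1p = np.asarray(self.v1p, dtype=float)
        self.gep = np.asarray(self.gep, dtype=float)
        ne, np_ = self.space.n_electronic_spatial, self.space.n_protonic
        if self.h1e.shape != (ne, ne):
            raise ValidationError(f"h1e shape {self.h1e.shape} != {(ne, ne)}")
        if self.h2e.shape != (ne,) * 4:
            raise ValidationError(f"h2e shape {self.h2e.shape} != {(ne,) * 4}")
        if self.v1p.shape != (np_, np_):
            raise ValidationError(f"v1p shape {self.v1p.shape} != {(np_, np_)}")
        if self.gep.shape != (np_, np_, ne, ne):
            raise ValidationError(
                f"gep shape {self.gep.shape} != {(np_, np_, ne, ne)}"
            )

    def validate(self, tol: float = DEFAULT_SYMMETRY_TOL) -> None:
        for name, arr in (("h1e", self.h1e), ("h2e", self.h2e),
                          ("v1p", self.v1p), ("gep", self.gep)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")
        if not np.isfinite(self.core_energy):
            raise ValidationError("core_energy not finite")
        if np.max(np.abs(self.h1e - self.h1e.T)) > tol:
            raise ValidationError("h1e is not symmetric")
        if np.max(np.abs(self.v1p - self.v1p.T)) > tol:
            raise ValidationError("v1p is not symmetric")
        if h2e_symmetry_residual(self.h2e) > tol:
            raise ValidationError("h2e violates 8-fold permutational symmetry")
        if np.max(np.abs(self.gep - np.transpose(self.gep, (1, 0, 2, 3)))) > tol:
            raise ValidationError("gep not Hermitian in the protonic index pair")
        if np.max(np.abs(self.gep - np.transpose(self.gep, (0, 1, 3, 2)))) > tol:
            raise ValidationError("gep not Hermitian in the electronic index pair")

    # -- operator content ---------------------------------------------
    def fermion_terms(self, tol: float = 0.0) -> List[FermionTerm]:
        """Expand to a list of creation/annihilation strings over modes."""
        sp_ = self.space
        ne, np_ = sp_.n_electronic_spatial, sp_.n_protonic
        spin_modes = (sp_.mode_up, sp_.mode_down)
        terms: List[FermionTerm] = []

        for p in range(ne):
            for q in range(ne):
                c = self.h1e[p, q]
                if abs(c) <= tol:
                    continue
                for mode in spin_modes:
                    terms.append((c, ((mode(p), True), (mode(q), False))))

        for p in range(ne):
            for q in range(ne):
                for r in range(ne):
                    for s in range(ne):
                        c = 0.5 * self.h2e[p, q, r, s]
                        if abs(c) <= tol:
                            continue
                        for m1 in spin_modes:
                            for m2 in spin_modes:
                                terms.append(
                                    (
                                        c,
                                        (
                                            (m1(p), True),
                                            (m2(q), True),
                                            (m2(s), False),
                                            (m1(r), False),
                                        ),
                                    )
                                )

        for P in range(np_):
            for Q in range(np_):
                c = self.v1p[P, Q]
                if abs(c) <= tol:
                    continue
                terms.append(
                    (c, ((sp_.mode_protonic(P), True), (sp_.mode_protonic(Q), False)))
                )

        for P in range(np_):
            for Q in range(np_):
                for p in range(ne):
                    for q in range(ne):
                        c = self.gep[P, Q, p, q]
                        if abs(c) <= tol:
                            continue
                        for mode in spin_modes:
                            terms.append(
                                (
                                    c,
                                    (
                                        (sp_.mode_protonic(P), True),
                                        (sp_.mode_protonic(Q), False),
                                        (mode(p), True),
                                        (mode(q), False),
                                    ),
                                )
                            )
        return terms

    def copy(self) -> "NEOHamiltonian":
        return NEOHamiltonian(
            self.space,
            self.core_energy,
            self.h1e.copy(),
            self.h2e.copy(),
            self.v1p.copy(),
            self.gep.copy(),
        )


@dataclass(frozen=True)
class WeightTriple:
    """Convex weights over the Left/Middle/Right Hamiltonian triple."""

    alpha: float
    beta: float
    gamma: float
    label: Optional[str] = None

    def __post_init__(self):
        w = np.array([self.alpha, self.beta, self.gamma], dtype=float)
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValidationError("weights must have positive sum")
        w = w / total
        object.__setattr__(self, "alpha", float(w[0]))
        object.__setattr__(self, "beta", float(w[1]))
        object.__setattr__(self, "gamma", float(w[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


#: canonical seven-point trajectory labels, Left to Right
TRAJECTORY_LABELS = ("300", "210", "120", "030", "021", "012", "003")


def lmr_weights(label: str) -> WeightTriple:
    """Digit-weight label (e.g. '210') to normalized Left/Middle/Right weights."""
    if len(label) != 3 or not label.isdigit():
        raise ValidationError(f"label {label!r} is not a 3-digit string")
    digits = [int(ch) for ch in label]
    total = sum(digits)
    if total == 0:
        raise ValidationError(f"label {label!r} has zero digit sum")
    return WeightTriple(digits[0] / total, digits[1] / total, digits[2] / total,
                        label=label)


def interpolate_hamiltonians(
    hL: NEOHamiltonian, hM: NEOHamiltonian, hR: NEOHamiltonian, w: WeightTriple
) -> NEOHamiltonian:
    """Convex combination alpha*H_L + beta*H_M + gamma*H_R, tensor by tensor."""
    if not (hL.space == hM.space == hR.space):
        raise ValidationError("Hamiltonians do not share an orbital space")
    a, b, g = w.alpha, w.beta, w.gamma
    return NEOHamiltonian(
        hL.space,
        a * hL.core_energy + b * hM.core_energy + g * hR.core_energy,
        a * hL.h1e + b * hM.h1e + g * hR.h1e,
        a * hL.h2e + b * hM.h2e + g * hR.h2e,
        a * hL.v1p + b * hM.v1p + g * hR.v1p,
        a * hL.gep + b * hM.gep + g * hR.gep,
    )


def lowdin_orthogonalize(S: np.ndarray) -> np.ndarray:
    """Symmetric (Lowdin) orthogonalization X = S^(-1/2) for SPD overlap S."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("overlap matrix must be square")
    if np.max(np.abs(S - S.T)) > 1e-10:
        raise ValidationError("overlap matrix must be symmetric")
    evals, evecs = np.linalg.eigh(S)
    if np.min(evals) <= 0:
        raise ValidationError(
            f"overlap matrix is not positive definite (min eigenvalue {np.min(evals):.3e})"
        )
    return (evecs / np.sqrt(evals)) @ evecs.T


@dataclass
class OneParticleDensityMatrix:
    """One-particle reduced density matrix gamma[p,q] = <a†_p a_q>."""

    matrix: np.ndarray
    particle_type: str  # "electronic" | "protonic"
    trace_target: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.particle_type not in ("electronic", "protonic"):
            raise ValidationError(f"unknown particle type {self.particle_type!r}")

    def validate(self, tol: float = 1e-8) -> None:
        m = self.matrix
        if np.max(np.abs(m - m.T)) > tol:
            raise ValidationError("density matrix is not symmetric")
        evals = np.linalg.eigvalsh(m)
        if np.min(evals) < -tol:
            raise ValidationError("density matrix has negative occupation")
        if abs(np.trace(m) - self.trace_target) > max(tol, 1e-8):
            raise ValidationError(
                f"trace {np.trace(m):.6f} != target {self.trace_target:.6f}"
            )


def fno_select(
    dm: OneParticleDensityMatrix, n_keep: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural-orbital selection: keep the n_keep largest-occupation eigenvectors.

    Returns (rotation, kept_indices, occupations) with occupations sorted
    descending and rotation columns the corresponding orthonormal
    eigenvectors (all of them; the first n_keep are the kept ones).
    """
    if n_keep <= 0:
        raise ValidationError("n_keep must be at least 1")
    d = dm.matrix.shape[0]
    if n_keep > d:
        raise ValidationError("n_keep exceeds the orbital dimension")
    occ, vecs = np.linalg.eigh(dm.matrix)
    order = np.argsort(occ)[::-1]
    occ = occ[order]
    vecs = vecs[:, order]
    return vecs, np.arange(n_keep), occ


@dataclass
class QubitHamiltonian:
    """Hermitian Pauli-sum image of a NEOHamiltonian."""

    n_qubits: int
    terms: Dict[str, float]
    _pauli: Optional[PauliSum] = field(default=None, repr=False, compare=False)

    def pauli_sum(self) -> PauliSum:
        if self._pauli is None:
            self._pauli = PauliSum.from_label_dict(
                self.n_qubits, {k: complex(v) for k, v in self.terms.items()}
            )
        return self._pauli

    def apply(self, psi: np.ndarray) -> np.ndarray:
        return self.pauli_sum().apply(psi)

    def expectation(self, psi: np.ndarray) -> float:
        return float(np.real(self.pauli_sum().expectation(psi)))

    def to_sparse(self):
        return self.pauli_sum().to_sparse()

    def __len__(self) -> int:
        return len(self.terms)


SUPPORTED_ENCODINGS = ("jordan-wigner",)


def map_to_qubits(h: NEOHamiltonian, encoding: str = "jordan-wigner",
                  prune_tol: float = 1e-12) -> QubitHamiltonian:
    """Map the fermionic Hamiltonian to a qubit Pauli sum.

    The identity coefficient absorbs core_energy; coefficients are real
    by Hermiticity of the input (enforced within prune_tol).
    """
    if encoding not in SUPPORTED_ENCODINGS:
        raise ValueError(
            f"unsupported encoding {encoding!r}; supported: {SUPPORTED_ENCODINGS}"
        )
    n = h.space.n_qubits
    ps = jordan_wigner(h.fermion_terms(), n, constant=h.core_energy).prune(prune_tol)
    terms: Dict[str, float] = {}
    for label, c in ps.label_dict().items():
        c = complex(c)
        if abs(c.imag) > 1e-9:
            raise ValidationError(f"non-Hermitian Pauli coefficient for {label}")
        terms[label] = c.real
    return QubitHamiltonian(n, terms, _pauli=ps)
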