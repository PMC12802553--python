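"""Exact sector diagonalization (CASCI) and derived observables.

The solver works in the fixed particle-number sector spanned by products
of electronic determinants (n_electrons in 2*n_electronic_spatial spin
orbitals) and protonic determinants (one proton in n_protonic orbitals).
Determinants are ordered lexicographically with the electronic
configuration fastest; the sign convention comes from ascending
creation-operator order.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse.linalg as spla

from .fermion import (
    apply_term_to_det,
    build_sector_matrix,
    sector_determinants,
    sector_vector_to_statevector,
)
from .hamiltonian import NEOHamiltonian, OneParticleDensityMatrix, OrbitalSpace

DENSE_CUTOFF = 2000


class SolverError(RuntimeError):
    pass


@dataclass
class CASCIResult:
    """Ground state of one fixed-particle-number sector."""

    energy: float
    ci_vector: np.ndarray
    dets: List[int]  # determinant bitmasks (electronic bits low, protonic high)
    space: OrbitalSpace
    residual: float

    @property
    def basis_index(self) -> List[Tuple[int, int]]:
        """(electronic occupation mask, protonic occupation mask) per determinant."""
        ne = self.space.n_electronic_spin
        emask = (1 << ne) - 1
        return [(d & emask, d >> ne) for d in self.dets]

    def statevector(self) -> np.ndarray:
        """Embed the CI vector in the full 2**n_qubits register."""
        return sector_vector_to_statevector(
            self.ci_vector, self.dets, self.space.n_qubits
        )


def aufbau_reference(h: NEOHamiltonian) -> int:
    """Lowest-diagonal product determinant (bitmask over modes)."""
    space = h.space
    diag_spin = np.concatenate([np.diag(h.h1e), np.diag(h.h1e)])
    occ_e = np.argsort(diag_spin, kind="stable")[: space.n_electrons]
    occ_p = int(np.argmin(np.diag(h.v1p)))
    det = 0
    for m in occ_e:
        det |= 1 << int(m)
    det |= 1 << space.mode_protonic(occ_p)
    return det


def _sector(h: NEOHamiltonian, n_electrons: Optional[int],
            n_protons: Optional[int]) -> List[int]:
    space = h.space
    ne = space.n_electrons if n_electrons is None else n_electrons
    npr = space.n_protons if n_protons is None else n_protons
    if ne < 0 or ne > space.n_electronic_spin or npr < 1 or npr > space.n_protonic:
        raise SolverError("empty particle-number sector")
    return sector_determinants(space.n_electronic_spin, ne, space.n_protonic, npr)


def casci_solve(
    h: NEOHamiltonian,
    n_electrons: Optional[int] = None,
    n_protons: Optional[int] = None,
    residual_tol: float = 1e-8,
    max_iter: int = 500,
) -> CASCIResult:
    """Ground state of the Hamiltonian in the requested sector.

    Dense diagonalization below DENSE_CUTOFF determinants, deterministic
    shift-free Lanczos (ARPACK) above, started from the aufbau
    determinant so results are seed-free.
    """
    dets = _sector(h, n_electrons, n_protons)
    if not dets:
        raise SolverError("empty particle-number sector")
    terms = h.fermion_terms()
    mat = build_sector_matrix(terms, dets, constant=h.core_energy)
    dim = len(dets)
    if dim == 1:
        vec = np.ones(1)
        energy = float(mat[0, 0].real)
    elif dim <= DENSE_CUTOFF:
        dense = mat.toarray()
        evals, evecs = np.linalg.eigh(dense)
        energy = float(evals[0])
        vec = evecs[:, 0]
    else:
        ref = aufbau_reference(h)
        v0 = np.zeros(dim)
        try:
            v0[dets.index(ref)] = 1.0
        except ValueError:
            v0[0] = 1.0
        try:
            evals, evecs = spla.eigsh(
                mat, k=1, which="SA", v0=v0, maxiter=max_iter, tol=residual_tol
            )
        except spla.ArpackNoConvergence as exc:
            raise SolverError(f"iterative eigensolver did not converge: {exc}")
        energy = float(evals[0])
        vec = np.real(evecs[:, 0])
    vec = np.real_if_close(vec)
    norm = np.linalg.norm(vec)
    vec = vec / norm
    # fix global sign for reproducibility
    k = int(np.argmax(np.abs(vec)))
    if vec[k] < 0:
        vec = -vec
    res = float(np.linalg.norm(mat @ vec - energy * vec))
    if res > max(residual_tol, 1e-7):
        raise SolverError(f"eigenpair residual {res:.2e} above tolerance")
    return CASCIResult(energy, vec, dets, h.space, res)


def hf_product_energy(h: NEOHamiltonian, reference: Optional[int] = None) -> float:
    """Expectation value of H in a single product determinant.

    The default determinant fills the lowest diagonal one-body energies
    (aufbau) for both species.
    """
    det = aufbau_reference(h) if reference is None else reference
    energy = h.core_energy
    for coeff, ops in h.fermion_terms():
        hit = apply_term_to_det(ops, det)
        if hit is None:
            continue
        sign, new_det = hit
        if new_det == det:
            energy += sign * coeff
    return float(energy)


def barrier_height(e_middle: float, e_left: float) -> float:
    """Barrier = E_middle - E_left (same units as the inputs)."""
    return e_middle - e_left


def _one_rdm(vec: np.ndarray, dets: Sequence[int], modes: Sequence[int]) -> np.ndarray:
    index = {d: i for i, d in enumerate(dets)}
    n = len(modes)
    dm = np.zeros((n, n))
    for a, ma in enumerate(modes):
        for b, mb in enumerate(modes):
            ops = ((ma, True), (mb, False))
            acc = 0.0
            for j, det in enumerate(dets):
                if vec[j] == 0.0:
                    continue
                hit = apply_term_to_det(ops, det)
                if hit is None:
                    continue
                sign, new_det = hit
                i = index.get(new_det)
                if i is not None:
                    acc += vec[i] * sign * vec[j]
            dm[a, b] = acc
    return dm


def reduced_density_matrices(
    res: CASCIResult,
) -> Tuple[OneParticleDensityMatrix, OneParticleDensityMatrix]:
    """Electronic (spin-orbital) and protonic one-particle RDMs."""
    space = res.space
    dm_e = _one_rdm(res.ci_vector, res.dets, space.electronic_spin_modes())
    dm_p = _one_rdm(res.ci_vector, res.dets, space.protonic_modes())
    n_e = round(np.trace(dm_e))
    return (
        OneParticleDensityMatrix(dm_e, "electronic", float(n_e)),
        OneParticleDensityMatrix(dm_p, "protonic", float(space.n_protons)),
    )


def _amplitude_matrix(res: CASCIResult) -> np.ndarray:
    """CI amplitudes reshaped to (protonic config, electronic config)."""
    space = res.space
    n_e_conf = comb(space.n_electronic_spin, space.n_electrons)
    n_p_conf = len(res.dets) // n_e_conf
    return res.ci_vector.reshape(n_p_conf, n_e_conf)


def entanglement_entropy(res: CASCIResult, base: str = "e") -> float:
    """Von Neumann entropy of the proton after tracing out the electrons.

    base: "e" for natural log (default), "2" for log base 2.
    """
    c = _amplitude_matrix(res)
    rho_p = c @ c.conj().T
    evals = np.linalg.eigvalsh(rho_p)
    evals = evals[evals > 1e-15]
    s = float(-np.sum(evals * np.log(evals)))
    if base == "2":
        s /= np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return max(s, 0.0)


@dataclass
class ProtonDensityGrid:
    """Real-space proton density sampled on a quadrature grid."""

    points: np.ndarray  # (N, 3) Cartesian coordinates (Angstrom)
    values: np.ndarray  # (N,) probability density
    weights: np.ndarray  # (N,) quadrature weights
    position_expectation: np.ndarray  # (3,)

    @property
    def integral(self) -> float:
        return float(np.dot(self.weights, self.values))


def proton_density_and_position(
    dm: OneParticleDensityMatrix,
    orbital_values: np.ndarray,
    points: np.ndarray,
    weights: np.ndarray,
    position_integrals: np.ndarray,
    orthonormality_tol: float = 1e-3,
) -> ProtonDensityGrid:
    """Density rho(r) = sum_AB dm[A,B] phi_A(r) phi_B(r) and <r>.

    orbital_values has shape (n_orbitals, N); position_integrals has
    shape (3, n_orbitals, n_orbitals) with Hermitian components.
    """
    phi = np.asarray(orbital_values, dtype=float)
    n_orb = dm.matrix.shape[0]
    if phi.shape[0] != n_orb:
        raise ValueError(
            f"orbital grid rows {phi.shape[0]} != density-matrix dimension {n_orb}"
        )
    if phi.shape[1] != len(points) or len(weights) != len(points):
        raise ValueError("grid point/weight dimensions do not match")
    overlap = (phi * weights) @ phi.T
    if np.max(np.abs(overlap - np.eye(n_orb))) > orthonormality_tol:
        raise ValueError("orbital grid is not orthonormal under the quadrature")
    pos = np.asarray(position_integrals, dtype=float)
    for comp in pos:
        if np.max(np.abs(comp - comp.T)) > 1e-10:
            raise ValueError("position integrals must be Hermitian per component")
    values = np.einsum("ab,an,bn->n", dm.matrix, phi, phi)
    r_expect = np.array([float(np.sum(dm.matrix * comp)) for comp in pos])
    return ProtonDensityGrid(np.asarray(points), values, np.asarray(weights), r_expect)
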