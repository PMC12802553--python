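"""Seeded synthetic model builders.

Provides random valid Hamiltonians for property tests, a physically
structured Left/Middle/Right double-well proton-transfer triple with
closed-form limits, and Gaussian orbital grids for density evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .hamiltonian import (
    NEOHamiltonian,
    OrbitalSpace,
    symmetrize_h2e,
)


def make_random_neo(
    n_electronic_spatial: int,
    n_protonic: int,
    n_electrons: int,
    seed: int,
    scale: float = 0.01,
) -> NEOHamiltonian:
    """Random Hamiltonian with every invariant satisfied exactly.

    One-body parts are diagonally dominant with O(1) level spacings so a
    sensible aufbau reference exists; two-body and coupling tensors are
    scaled to put correlation energies in the few-mHa regime.
    """
    if n_electronic_spatial < 1 or n_protonic < 1 or n_electrons < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    ne, np_ = n_electronic_spatial, n_protonic
    space = OrbitalSpace(ne, np_, n_electrons)

    h1e = np.diag(np.sort(rng.uniform(-1.0, 1.0, ne)))
    h1e = h1e + _sym(rng.normal(0.0, 2.0 * scale, (ne, ne)))
    v1p = np.diag(np.sort(rng.uniform(-0.5, 0.5, np_)))
    v1p = v1p + _sym(rng.normal(0.0, 2.0 * scale, (np_, np_)))
    h2e = symmetrize_h2e(rng.normal(0.0, scale, (ne,) * 4))
    gep = rng.normal(0.0, scale, (np_, np_, ne, ne))
    gep = 0.5 * (gep + np.transpose(gep, (1, 0, 2, 3)))
    gep = 0.5 * (gep + np.transpose(gep, (0, 1, 3, 2)))
    core = float(rng.normal(0.0, 0.1))
    h = NEOHamiltonian(space, core, h1e, h2e, v1p, gep)
    h.validate()
    return h


def _sym(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


@dataclass(frozen=True)
class DoubleWellSpec:
    """Parameters of the synthetic Left/Middle/Right proton-transfer triple.

    The two lowest protonic orbitals are localized well sites with
    hopping ``t_p``; Left/Right tilt the wells by ``-+ delta`` while
    Middle is symmetric with its bottom raised by ``middle_raise``.  The
    proton site populations couple to an electronic orbital excitation
    with strength ``g0``.
    """

    n_protonic: int = 2
    n_electronic_spatial: int = 2
    n_electrons: int = 2
    t_p: float = 0.010  # Ha, proton tunneling
    delta: float = 0.004  # Ha, site asymmetry for Left/Right
    middle_raise: float = 0.008  # Ha, Middle well-bottom raise
    g0: float = 0.003  # Ha, electron-proton coupling strength
    electronic_gap: float = 0.100  # Ha
    ee_strength: float = 0.020  # Ha, density-density repulsion scale
    extra_protonic_offset: float = 0.400  # Ha, for n_protonic > 2
    seed: int = 0

    def __post_init__(self):
        if self.n_protonic < 2 or self.n_electronic_spatial < 2:
            raise ValueError("need at least 2 protonic and 2 electronic orbitals")
        if self.t_p <= 0:
            raise ValueError("t_p must be positive")
        for name in ("delta", "middle_raise", "g0", "electronic_gap"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def proton_ground_closed_form(self, which: str) -> float:
        """Protonic 2x2 ground energy at g0 = 0, relative to the well mean."""
        if which in ("L", "R", "left", "right"):
            return -float(np.hypot(self.delta, self.t_p))
        if which in ("M", "middle"):
            return self.middle_raise - self.t_p
        raise ValueError(f"unknown setup {which!r}")


def _double_well_common(spec: DoubleWellSpec):
    ne, np_ = spec.n_electronic_spatial, spec.n_protonic
    h1e = np.diag(spec.electronic_gap * np.arange(ne, dtype=float))
    # density-density repulsion only: 8-fold symmetric and invariant under
    # diagonal electronic sign flips, which keeps the L/R mirror exact
    rng = np.random.default_rng(spec.seed)
    u = _sym(rng.uniform(0.5, 1.0, (ne, ne))) * spec.ee_strength
    h2e = np.zeros((ne,) * 4)
    for p in range(ne):
        for q in range(ne):
            h2e[p, q, p, q] = u[p, q]
    return h1e, h2e


def _coupling(spec: DoubleWellSpec) -> np.ndarray:
    ne, np_ = spec.n_electronic_spatial, spec.n_protonic
    gep = np.zeros((np_, np_, ne, ne))
    # proton site imbalance (n_0 - n_1) times electronic 0<->1 excitation
    d_e = np.zeros((ne, ne))
    d_e[0, 1] = d_e[1, 0] = 1.0
    gep[0, 0] = spec.g0 * d_e
    gep[1, 1] = -spec.g0 * d_e
    return gep


def _v1p(spec: DoubleWellSpec, tilt: float, raise_: float) -> np.ndarray:
    np_ = spec.n_protonic
    v = np.zeros((np_, np_))
    v[0, 0] = raise_ - tilt
    v[1, 1] = raise_ + tilt
    v[0, 1] = v[1, 0] = -spec.t_p
    for P in range(2, np_):
        v[P, P] = spec.extra_protonic_offset * (P - 1)
    return v


def make_double_well_triple(
    spec: DoubleWellSpec,
) -> Tuple[NEOHamiltonian, NEOHamiltonian, NEOHamiltonian]:
    """Left, Middle and Right Hamiltonians of the double-well model.

    Left and Right are exact mirror images (the mirror is the proton
    site swap combined with an electronic orbital-1 sign flip); at
    g0 = 0 the proton decouples and its ground energy has the 2x2
    closed form returned by spec.proton_ground_closed_form.
    """
    space = OrbitalSpace(
        spec.n_electronic_spatial, spec.n_protonic, spec.n_electrons
    )
    h1e, h2e = _double_well_common(spec)
    gep = _coupling(spec)
    hL = NEOHamiltonian(space, 0.0, h1e, h2e, _v1p(spec, spec.delta, 0.0), gep)
    hM = NEOHamiltonian(
        space, 0.0, h1e, h2e, _v1p(spec, 0.0, spec.middle_raise), gep
    )
    hR = NEOHamiltonian(space, 0.0, h1e, h2e, _v1p(spec, -spec.delta, 0.0), gep)
    for h in (hL, hM, hR):
        h.validate()
    return hL, hM, hR


def electronic_only_hamiltonian(h: NEOHamiltonian) -> NEOHamiltonian:
    """Copy with the electron-proton coupling switched off."""
    out = h.copy()
    out.gep = np.zeros_like(out.gep)
    return out


# ------------------------------------------------------------------ grids

@dataclass
class GaussianOrbitalGrid:
    """Normalized 3D s-Gaussians evaluated on a uniform quadrature grid."""

    points: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N,)
    values: np.ndarray  # (n_orb, N), raw non-orthogonal orbitals
    overlap: np.ndarray  # (n_orb, n_orb), analytic
    position_integrals: np.ndarray  # (3, n_orb, n_orb), analytic <i|r|j>
    centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    exponents: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def orthonormalized(self) -> Tuple[np.ndarray, np.ndarray]:
        """Lowdin-orthonormal orbital values and transformed <r> integrals."""
        from .hamiltonian import lowdin_orthogonalize

        x = lowdin_orthogonalize(self.overlap)
        values = x.T @ self.values
        pos = np.einsum("pa,cpq,qb->cab", x, self.position_integrals, x)
        return values, pos


def uniform_grid(
    lo: Tuple[float, float, float],
    hi: Tuple[float, float, float],
    shape: Tuple[int, int, int],
) -> Tuple[np.ndarray, np.ndarray]:
    axes = [np.linspace(lo[i], hi[i], shape[i]) for i in range(3)]
    steps = [ax[1] - ax[0] if len(ax) > 1 else 1.0 for ax in axes]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    weights = np.full(points.shape[0], float(np.prod(steps)))
    return points, weights


def gaussian_orbital_grid(
    centers: np.ndarray,
    exponents: np.ndarray,
    points: np.ndarray,
    weights: np.ndarray,
) -> GaussianOrbitalGrid:
    """Evaluate normalized s-Gaussians and their analytic integrals.

    phi_i(r) = (2 a_i / pi)^(3/4) exp(-a_i |r - c_i|^2); the analytic
    overlap of two Gaussians follows the Gaussian product theorem and
    the position integrals place <i|r|j> at the weighted midpoint.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    exponents = np.atleast_1d(np.asarray(exponents, dtype=float))
    if np.any(exponents <= 0):
        raise ValueError("Gaussian exponents must be positive")
    n = len(exponents)
    if centers.shape != (n, 3):
        raise ValueError("centers must have shape (n_orbitals, 3)")
    norms = (2.0 * exponents / np.pi) ** 0.75
    diffs = points[None, :, :] - centers[:, None, :]
    r2 = np.einsum("onk,onk->on", diffs, diffs)
    values = norms[:, None] * np.exp(-exponents[:, None] * r2)

    overlap = np.zeros((n, n))
    pos = np.zeros((3, n, n))
    for i in range(n):
        for j in range(n):
            a, b = exponents[i], exponents[j]
            p = a + b
            d2 = float(np.sum((centers[i] - centers[j]) ** 2))
            s = (4.0 * a * b / p**2) ** 0.75 * np.exp(-a * b / p * d2)
            overlap[i, j] = s
            midpoint = (a * centers[i] + b * centers[j]) / p
            pos[:, i, j] = s * midpoint
    return GaussianOrbitalGrid(
        points=np.asarray(points),
        weights=np.asarray(weights),
        values=values,
        overlap=overlap,
        position_integrals=pos,
        centers=centers,
        exponents=exponents,
    )
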