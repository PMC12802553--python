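"""ADAPT-VQE over the coupled electron-proton excitation pool.

Pool construction (fermionic and qubit-string variants), commutator
gradient screening, iterative ansatz growth with full parameter
re-optimization, and statevector utilities.

Excitation generators tau = A - A† with all-distinct mode indices obey
tau^3 = -tau, so exp(theta*tau) = 1 + sin(theta)*tau + (1-cos(theta))*tau^2
is applied with two sparse matrix-vector products.  Qubit-pool operators
are single anti-Hermitian Pauli strings tau = iP with exp(theta*i*P) =
cos(theta) + i*sin(theta)*P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .fermion import det_to_statevector, jordan_wigner
from .hamiltonian import OrbitalSpace, QubitHamiltonian
from .pauli import PauliSum


class AdaptError(RuntimeError):
    pass


class StagnationWarning(UserWarning):
    pass


POOL_KINDS = ("e-single", "p-single", "ee-double", "pp-double", "ep-double",
              "pauli-string")


@dataclass
class PoolOperator:
    """Anti-Hermitian ansatz generator."""

    kind: str
    indices: Tuple[int, ...]
    generator: PauliSum  # anti-Hermitian qubit image
    _matrix: Optional[sp.csr_matrix] = field(default=None, repr=False)
    _is_single_string: bool = field(default=False, repr=False)

    def matrix(self) -> sp.csr_matrix:
        if self._matrix is None:
            self._matrix = self.generator.to_sparse()
        return self._matrix

    def apply(self, psi: np.ndarray) -> np.ndarray:
        return self.matrix() @ psi

    def evolve(self, psi: np.ndarray, theta: float) -> np.ndarray:
        """exp(theta * tau) |psi>."""
        if self._is_single_string:
            # tau = i*c*P with P^2 = 1: exp = cos(c*theta) + i sin(c*theta) P
            ((key, coeff),) = self.generator.terms.items()
            c = float(np.imag(coeff))
            p_psi = PauliSum(self.generator.n_qubits, {key: 1.0}).apply(psi)
            return np.cos(c * theta) * psi + 1j * np.sin(c * theta) * p_psi
        t1 = self.apply(psi)
        t2 = self.apply(t1)
        return psi + np.sin(theta) * t1 + (1.0 - np.cos(theta)) * t2


def _excitation_terms(creations: Sequence[int], annihilations: Sequence[int]):
    ops = tuple([(m, True) for m in creations] + [(m, False) for m in annihilations])
    dag = tuple(
        [(m, True) for m in reversed(annihilations)]
        + [(m, False) for m in reversed(creations)]
    )
    return [(1.0, ops), (-1.0, dag)]


def _spin(space: OrbitalSpace, mode: int) -> int:
    return 0 if mode < space.n_electronic_spatial else 1


def reference_modes(space: OrbitalSpace, reference: int) -> Tuple[List[int], List[int],
                                                                  List[int], List[int]]:
    """Occupied/virtual electronic spin modes and protonic modes of a determinant."""
    occ_e = [m for m in space.electronic_spin_modes() if reference >> m & 1]
    vir_e = [m for m in space.electronic_spin_modes() if not reference >> m & 1]
    occ_p = [m for m in space.protonic_modes() if reference >> m & 1]
    vir_p = [m for m in space.protonic_modes() if not reference >> m & 1]
    return occ_e, vir_e, occ_p, vir_p


def build_pool(
    space: OrbitalSpace,
    reference: int,
    variant: str = "fermionic",
    drop_z_chains: bool = False,
) -> List[PoolOperator]:
    """All spin- and number-conserving excitations out of the reference.

    variant="fermionic" enumerates the five generator families;
    variant="qubit" splits each Jordan-Wigner image into its individual
    Pauli strings (optionally with Z chains removed).
    """
    if variant not in ("fermionic", "qubit"):
        raise ValueError(f"unknown pool variant {variant!r}")
    occ_e, vir_e, occ_p, vir_p = reference_modes(space, reference)
    if not vir_e and not vir_p:
        raise AdaptError("empty virtual space: no excitations available")
    n = space.n_qubits
    ops: List[PoolOperator] = []

    def add(kind, idx, terms):
        gen = jordan_wigner(terms, n).prune()
        if len(gen):
            ops.append(PoolOperator(kind, idx, gen))

    for i in occ_e:
        for a in vir_e:
            if _spin(space, i) == _spin(space, a):
                add("e-single", (i, a), _excitation_terms([a], [i]))
    for idx_i, i in enumerate(occ_e):
        for j in occ_e[idx_i + 1:]:
            for idx_a, a in enumerate(vir_e):
                for b in vir_e[idx_a + 1:]:
                    if sorted((_spin(space, i), _spin(space, j))) == sorted(
                        (_spin(space, a), _spin(space, b))
                    ):
                        add("ee-double", (i, j, a, b),
                            _excitation_terms([a, b], [j, i]))
    for I in occ_p:
        for A in vir_p:
            add("p-single", (I, A), _excitation_terms([A], [I]))
    for idx_I, I in enumerate(occ_p):
        for J in occ_p[idx_I + 1:]:
            for idx_A, A in enumerate(vir_p):
                for B in vir_p[idx_A + 1:]:
                    add("pp-double", (I, J, A, B), _excitation_terms([A, B], [J, I]))
    for i in occ_e:
        for a in vir_e:
            if _spin(space, i) != _spin(space, a):
                continue
            for I in occ_p:
                for A in vir_p:
                    add("ep-double", (i, I, a, A), _excitation_terms([a, A], [I, i]))

    if variant == "fermionic":
        return ops

    seen = set()
    qubit_ops: List[PoolOperator] = []
    for op in ops:
        for key, coeff in op.generator.terms.items():
            x, z = key
            if drop_z_chains:
                z = z & x
            if (x, z) in seen:
                continue
            seen.add((x, z))
            gen = PauliSum(n, {(x, z): 1.0j})
            qubit_ops.append(
                PoolOperator("pauli-string", (x, z), gen, _is_single_string=True)
            )
    return qubit_ops


@dataclass
class AnsatzState:
    """Ordered generator sequence with parameters over a reference determinant."""

    space: OrbitalSpace
    reference: int
    generators: List[PoolOperator] = field(default_factory=list)
    parameters: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.parameters = np.asarray(self.parameters, dtype=float)
        if len(self.generators) != len(self.parameters):
            raise ValueError("generator/parameter length mismatch")

    def reference_state(self) -> np.ndarray:
        return det_to_statevector(self.reference, self.space.n_qubits)

    def forward_states(self, parameters: Optional[np.ndarray] = None) -> List[np.ndarray]:
        theta = self.parameters if parameters is None else parameters
        states = [self.reference_state()]
        for op, t in zip(self.generators, theta):
            states.append(op.evolve(states[-1], t))
        return states

    def statevector(self, parameters: Optional[np.ndarray] = None) -> np.ndarray:
        return self.forward_states(parameters)[-1]


def pool_gradient(op: PoolOperator, psi: np.ndarray, H: QubitHamiltonian) -> float:
    """<psi|[H, tau]|psi> = d/dtheta <psi(theta)|H|psi(theta)> at theta = 0."""
    h_psi = H.apply(psi)
    return float(2.0 * np.real(np.vdot(h_psi, op.apply(psi))))


def energy_and_gradient(
    ansatz: AnsatzState, H: QubitHamiltonian, parameters: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Analytic energy gradient via one forward and one backward sweep."""
    states = ansatz.forward_states(parameters)
    psi = states[-1]
    h_psi = H.apply(psi)
    energy = float(np.real(np.vdot(psi, h_psi)))
    n = len(ansatz.generators)
    grad = np.zeros(n)
    phi = h_psi
    for k in range(n - 1, -1, -1):
        op = ansatz.generators[k]
        grad[k] = 2.0 * np.real(np.vdot(phi, op.apply(states[k + 1])))
        phi = op.evolve(phi, -parameters[k])
    return energy, grad


@dataclass
class VQEResult:
    energy: float
    iterations: int
    gradient_norms: List[float]
    energies: List[float]
    ansatz: AnsatzState
    converged: bool
    preset: str
    message: str = ""

    def statevector(self) -> np.ndarray:
        return self.ansatz.statevector()


PRESETS = {
    "deep": {"energy_tol": 1e-3, "max_iterations": 500},
    "shallow": {"energy_tol": 1e-2, "max_iterations": 200},
}


def run_adapt_vqe(
    H: QubitHamiltonian,
    pool: Sequence[PoolOperator],
    space: OrbitalSpace,
    reference: int,
    preset: str = "deep",
    energy_tol: Optional[float] = None,
    reference_energy: Optional[float] = None,
    gradient_tol: float = 1e-6,
    max_iterations: Optional[int] = None,
    reoptimize_all: bool = True,
    optimizer_gtol: float = 1e-7,
) -> VQEResult:
    """Grow the ansatz one max-gradient operator at a time.

    Stops when |E - reference_energy| < energy_tol (when a reference is
    given), or when the largest pool gradient falls below gradient_tol.
    Ties on |gradient| break toward the lowest pool index.
    """
    if not pool:
        raise AdaptError("operator pool is empty")
    if preset in PRESETS:
        cfg = PRESETS[preset]
        energy_tol = cfg["energy_tol"] if energy_tol is None else energy_tol
        max_iterations = (
            cfg["max_iterations"] if max_iterations is None else max_iterations
        )
    elif preset == "custom":
        if energy_tol is None and reference_energy is not None:
            raise ValueError("custom preset requires energy_tol")
        max_iterations = 500 if max_iterations is None else max_iterations
    else:
        raise ValueError(f"unknown preset {preset!r}")

    ansatz = AnsatzState(space, reference)
    psi = ansatz.statevector()
    energy = H.expectation(psi)
    energies = [energy]
    grad_norms: List[float] = []

    def done(e):
        return reference_energy is not None and abs(e - reference_energy) < energy_tol

    if done(energy):
        return VQEResult(energy, 0, [], energies, ansatz, True, preset,
                         "reference tolerance met at the reference state")

    for it in range(1, max_iterations + 1):
        grads = np.array([pool_gradient(op, psi, H) for op in pool])
        k = int(np.argmax(np.abs(grads)))  # argmax takes first on ties
        gmax = abs(grads[k])
        grad_norms.append(float(np.linalg.norm(grads)))
        if gmax < gradient_tol:
            return VQEResult(
                energy, it - 1, grad_norms, energies, ansatz,
                reference_energy is None or done(energy), preset,
                f"pool gradient below {gradient_tol:g}",
            )

        ansatz.generators.append(pool[k])
        theta = np.append(ansatz.parameters, 0.0)

        if reoptimize_all:
            free = slice(None)
        else:
            free = slice(len(theta) - 1, len(theta))

        def objective(x):
            full = theta.copy()
            full[free] = x
            e, g = energy_and_gradient(ansatz, H, full)
            return e, g[free]

        res = scipy.optimize.minimize(
            objective, theta[free], jac=True, method="BFGS",
            options={"gtol": optimizer_gtol, "maxiter": 400},
        )
        if not np.all(np.isfinite(res.x)):
            raise AdaptError(f"optimizer failure at iteration {it}: {res.message}")
        theta[free] = res.x
        ansatz.parameters = theta
        psi = ansatz.statevector()
        new_energy = H.expectation(psi)
        if new_energy > energy + 1e-10:
            # re-optimization from the previous point should never go uphill
            raise AdaptError(
                f"energy increased at iteration {it}: {energy:.10f} -> {new_energy:.10f}"
            )
        if abs(new_energy - energy) < 1e-12 and gmax > gradient_tol and not done(
            new_energy
        ):
            warnings.warn(
                f"ADAPT stagnated at iteration {it} (gradient {gmax:.2e})",
                StagnationWarning,
            )
            energies.append(new_energy)
            return VQEResult(new_energy, it, grad_norms, energies, ansatz, False,
                             preset, "stagnation")
        energy = new_energy
        energies.append(energy)
        if done(energy):
            return VQEResult(energy, it, grad_norms, energies, ansatz, True, preset,
                             "reference tolerance met")

    return VQEResult(
        energy, max_iterations, grad_norms, energies, ansatz,
        reference_energy is None, preset, "iteration budget exhausted",
    )


def state_fidelity(a: np.ndarray, b: np.ndarray) -> float:
    """|<a|b>|^2 for normalized statevectors of equal dimension."""
    if a.shape != b.shape:
        raise ValueError("statevector dimensions differ")
    for v in (a, b):
        if abs(np.linalg.norm(v) - 1.0) > 1e-8:
            raise ValueError("statevectors must be normalized")
    return float(np.abs(np.vdot(a, b)) ** 2)
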