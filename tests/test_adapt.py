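"""ADAPT-VQE: pool construction, gradients, convergence, fidelity."""

import numpy as np
import pytest

from neoqpt.adapt import (
    AdaptError,
    build_pool,
    energy_and_gradient,
    AnsatzState,
    pool_gradient,
    run_adapt_vqe,
    state_fidelity,
)
from neoqpt.exact import aufbau_reference, casci_solve
from neoqpt.fermion import det_to_statevector, jordan_wigner
from neoqpt.hamiltonian import OrbitalSpace, map_to_qubits
from neoqpt.synthetic import make_random_neo
from neoqpt.pauli import PauliSum


@pytest.fixture(scope="module")
def small_setup():
    h = make_random_neo(2, 2, 2, seed=5)
    qh = map_to_qubits(h)
    ref = aufbau_reference(h)
    pool = build_pool(h.space, ref)
    return h, qh, ref, pool


class TestPool:
    def test_e_singles_count_matches_enumeration(self):
        # 2 occupied + 2 virtual electronic spin orbitals arranged so each
        # spin channel has 1 occupied and 1 virtual -> 2 same-spin singles
        space = OrbitalSpace(2, 2, 2)
        # modes 0 (up0) and 2 (down0) occupied + proton in orbital 0
        ref = (1 << 0) | (1 << 2) | (1 << space.mode_protonic(0))
        pool = build_pool(space, ref)
        singles = [op for op in pool if op.kind == "e-single"]
        # oracle: same-spin occupied -> virtual enumeration
        occ = [(0, 0), (2, 1)]  # (mode, spin)
        vir = [(1, 0), (3, 1)]
        expected = sum(1 for i, si in occ for a, sa in vir if si == sa)
        assert len(singles) == expected == 2

    def test_single_protonic_excitation(self):
        space = OrbitalSpace(2, 2, 2)
        ref = (1 << 0) | (1 << 2) | (1 << space.mode_protonic(0))
        pool = build_pool(space, ref)
        p_singles = [op for op in pool if op.kind == "p-single"]
        assert len(p_singles) == 1  # 1 occupied x 1 virtual protonic orbital

    def test_ep_double_structure(self):
        space = OrbitalSpace(2, 2, 2)
        ref = (1 << 0) | (1 << 2) | (1 << space.mode_protonic(0))
        pool = build_pool(space, ref)
        ep = [op for op in pool if op.kind == "ep-double"]
        assert len(ep) == 2  # 2 same-spin electronic singles x 1 protonic single

    def test_generators_antihermitian(self, small_setup):
        _, _, _, pool = small_setup
        for op in pool:
            assert op.generator.is_antihermitian(tol=1e-12)

    def test_qubit_pool_splits_strings(self):
        space = OrbitalSpace(2, 2, 2)
        ref = (1 << 0) | (1 << 2) | (1 << space.mode_protonic(0))
        fermionic = build_pool(space, ref, variant="fermionic")
        qubit = build_pool(space, ref, variant="qubit")
        # oracle: distinct Pauli keys across all JW images
        keys = set()
        for op in fermionic:
            keys.update(op.generator.terms.keys())
        assert len(qubit) == len(keys)
        for op in qubit:
            assert len(op.generator) == 1
            assert op.generator.is_antihermitian(tol=1e-12)

    def test_ep_double_string_count(self):
        # one ep-double: JW image term count equals its qubit-split size
        space = OrbitalSpace(2, 2, 2)
        from neoqpt.adapt import _excitation_terms

        gen = jordan_wigner(
            _excitation_terms([1, space.mode_protonic(1)],
                              [space.mode_protonic(0), 0]),
            space.n_qubits,
        ).prune()
        assert len(gen) == 8  # two fermionic doubles -> 8 distinct strings

    def test_empty_virtual_space(self):
        space = OrbitalSpace(1, 1, 2)
        ref = 0b111  # everything occupied
        with pytest.raises(AdaptError, match="virtual"):
            build_pool(space, ref)


class TestEvolution:
    def test_exponential_matches_expm(self, small_setup, rng):
        import scipy.linalg

        _, _, ref, pool = small_setup
        psi = rng.normal(size=64) + 1j * rng.normal(size=64)
        psi /= np.linalg.norm(psi)
        for op in pool[:4]:
            theta = 0.7
            expected = scipy.linalg.expm(theta * op.matrix().toarray()) @ psi
            np.testing.assert_allclose(op.evolve(psi, theta), expected, atol=1e-10)

    def test_qubit_op_evolution(self, rng):
        import scipy.linalg

        space = OrbitalSpace(2, 2, 2)
        ref = (1 << 0) | (1 << 2) | (1 << space.mode_protonic(0))
        pool = build_pool(space, ref, variant="qubit")
        psi = rng.normal(size=64) + 1j * rng.normal(size=64)
        psi /= np.linalg.norm(psi)
        op = pool[3]
        expected = scipy.linalg.expm(0.3 * op.generator.to_sparse().toarray()) @ psi
        np.testing.assert_allclose(op.evolve(psi, 0.3), expected, atol=1e-10)


class TestGradients:
    def test_stationary_at_noninteracting_reference(self):
        from neoqpt.hamiltonian import NEOHamiltonian

        space = OrbitalSpace(2, 2, 2)
        h = NEOHamiltonian(
            space, 0.0, np.diag([-1.0, 1.0]), np.zeros((2,) * 4),
            np.diag([-0.5, 0.5]), np.zeros((2, 2, 2, 2)),
        )
        qh = map_to_qubits(h)
        ref = aufbau_reference(h)
        psi = det_to_statevector(ref, space.n_qubits)
        for op in build_pool(space, ref):
            assert pool_gradient(op, psi, qh) == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_difference(self, small_setup, rng):
        _, qh, ref, pool = small_setup
        space = OrbitalSpace(2, 2, 2)
        for trial in range(20):
            op = pool[int(rng.integers(len(pool)))]
            # random normalized state in the full register
            psi = rng.normal(size=64) + 1j * rng.normal(size=64)
            psi /= np.linalg.norm(psi)
            g = pool_gradient(op, psi, qh)
            eps = 1e-5
            ep = np.real(np.vdot(op.evolve(psi, eps), qh.apply(op.evolve(psi, eps))))
            em = np.real(np.vdot(op.evolve(psi, -eps), qh.apply(op.evolve(psi, -eps))))
            assert g == pytest.approx((ep - em) / (2 * eps), abs=1e-6)

    def test_symmetry_protected_zero(self, small_setup):
        _, qh, ref, _ = small_setup
        space = OrbitalSpace(2, 2, 2)
        psi = det_to_statevector(ref, space.n_qubits)
        # a pure protonic-number string commutes with the Hamiltonian
        zop = PauliSum.from_label("IIIIZZ", 1.0j)
        from neoqpt.adapt import PoolOperator

        op = PoolOperator("pauli-string", (0,), zop, _is_single_string=True)
        assert pool_gradient(op, psi, qh) == pytest.approx(0.0, abs=1e-12)

    def test_ansatz_gradient_matches_fd(self, small_setup, rng):
        _, qh, ref, pool = small_setup
        space = OrbitalSpace(2, 2, 2)
        ansatz = AnsatzState(space, ref, list(pool[:3]),
                             rng.normal(0, 0.2, 3))
        theta = ansatz.parameters.copy()
        e0, grad = energy_and_gradient(ansatz, qh, theta)
        for k in range(3):
            eps = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            ep, _ = energy_and_gradient(ansatz, qh, tp)
            em, _ = energy_and_gradient(ansatz, qh, tm)
            assert grad[k] == pytest.approx((ep - em) / (2 * eps), abs=1e-7)


class TestRunAdapt:
    def test_non_interacting_zero_iterations(self):
        from neoqpt.hamiltonian import NEOHamiltonian

        space = OrbitalSpace(2, 2, 2)
        h = NEOHamiltonian(
            space, 0.0, np.diag([-1.0, 1.0]), np.zeros((2,) * 4),
            np.diag([-0.5, 0.5]), np.zeros((2, 2, 2, 2)),
        )
        qh = map_to_qubits(h)
        ref = aufbau_reference(h)
        res = run_adapt_vqe(qh, build_pool(space, ref), space, ref,
                            preset="custom", energy_tol=1e-9,
                            reference_energy=casci_solve(h).energy)
        assert res.iterations == 0
        assert res.converged

    def test_double_well_converges_to_casci(self, double_well_triple):
        hL, hM, hR = double_well_triple
        casci = casci_solve(hM)
        qh = map_to_qubits(hM)
        ref = aufbau_reference(hL)
        pool = build_pool(hM.space, ref)
        res = run_adapt_vqe(qh, pool, hM.space, ref, preset="custom",
                            energy_tol=1e-8, reference_energy=casci.energy,
                            gradient_tol=1e-9, optimizer_gtol=1e-11)
        assert res.converged
        assert res.energy == pytest.approx(casci.energy, abs=1e-8)

    def test_energies_monotone(self, small_setup):
        h, qh, ref, pool = small_setup
        res = run_adapt_vqe(qh, pool, h.space, ref, preset="custom",
                            energy_tol=1e-6,
                            reference_energy=casci_solve(h).energy)
        diffs = np.diff(res.energies)
        assert np.all(diffs <= 1e-10)

    def test_particle_number_conserved(self, small_setup):
        h, qh, ref, pool = small_setup
        space = h.space
        res = run_adapt_vqe(qh, pool, space, ref, preset="custom",
                            energy_tol=1e-6,
                            reference_energy=casci_solve(h).energy)
        from neoqpt.fermion import jordan_wigner, number_operator_terms

        n_e = jordan_wigner(
            number_operator_terms(space.electronic_spin_modes()), space.n_qubits
        )
        n_p = jordan_wigner(
            number_operator_terms(space.protonic_modes()), space.n_qubits
        )
        for k in range(len(res.ansatz.generators) + 1):
            partial = AnsatzState(space, ref, res.ansatz.generators[:k],
                                  res.ansatz.parameters[:k])
            psi = partial.statevector()
            assert np.real(n_e.expectation(psi)) == pytest.approx(2.0, abs=1e-10)
            assert np.real(n_p.expectation(psi)) == pytest.approx(1.0, abs=1e-10)

    def test_empty_pool_rejected(self, small_setup):
        h, qh, ref, _ = small_setup
        with pytest.raises(AdaptError, match="empty"):
            run_adapt_vqe(qh, [], h.space, ref)

    def test_shallow_preset_tolerance(self, double_well_triple):
        hL, _, _ = double_well_triple
        casci = casci_solve(hL)
        qh = map_to_qubits(hL)
        ref = aufbau_reference(hL)
        res = run_adapt_vqe(qh, build_pool(hL.space, ref), hL.space, ref,
                            preset="shallow", reference_energy=casci.energy)
        assert res.converged
        assert abs(res.energy - casci.energy) < 1e-2


class TestFidelity:
    def test_identical(self, rng):
        v = rng.normal(size=8) + 1j * rng.normal(size=8)
        v /= np.linalg.norm(v)
        assert state_fidelity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        a = np.zeros(4, dtype=complex)
        b = np.zeros(4, dtype=complex)
        a[0] = 1.0
        b[3] = 1.0
        assert state_fidelity(a, b) == 0.0

    def test_symmetric(self, rng):
        a = rng.normal(size=8) + 1j * rng.normal(size=8)
        b = rng.normal(size=8) + 1j * rng.normal(size=8)
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        assert state_fidelity(a, b) == pytest.approx(state_fidelity(b, a))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            state_fidelity(np.ones(2) / np.sqrt(2), np.ones(4) / 2)

    def test_hf_vs_casci_below_one(self, double_well_triple):
        hL, _, _ = double_well_triple
        casci = casci_solve(hL)
        psi_hf = det_to_statevector(aufbau_reference(hL), hL.space.n_qubits)
        f = state_fidelity(psi_hf, casci.statevector())
        assert 0.5 < f < 1.0
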