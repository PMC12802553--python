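"""Hamiltonian data model: interpolation, weights, Lowdin, FNO, mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoqpt.exact import casci_solve
from neoqpt.fermion import restrict_dense, sector_determinants
from neoqpt.hamiltonian import (
    NEOHamiltonian,
    OneParticleDensityMatrix,
    OrbitalSpace,
    ValidationError,
    WeightTriple,
    fno_select,
    h2e_symmetry_residual,
    interpolate_hamiltonians,
    lmr_weights,
    lowdin_orthogonalize,
    map_to_qubits,
    symmetrize_h2e,
)
from neoqpt.synthetic import make_random_neo


class TestOrbitalSpace:
    def test_counts(self):
        sp = OrbitalSpace(3, 2, 4)
        assert sp.n_electronic_spin == 6
        assert sp.n_qubits == 8

    def test_too_many_electrons(self):
        with pytest.raises(ValidationError):
            OrbitalSpace(1, 2, 3)

    def test_single_proton_only(self):
        with pytest.raises(ValidationError):
            OrbitalSpace(2, 2, 2, n_protons=2)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            OrbitalSpace(2, 2, 2, electronic_labels=("a", "a"))

    def test_mode_layout(self):
        sp = OrbitalSpace(2, 3, 2)
        assert sp.mode_up(1) == 1
        assert sp.mode_down(0) == 2
        assert sp.mode_protonic(2) == 6


class TestInterpolation:
    def test_endpoint_left(self, double_well_triple):
        hL, hM, hR = double_well_triple
        out = interpolate_hamiltonians(hL, hM, hR, WeightTriple(1, 0, 0))
        np.testing.assert_array_equal(out.h1e, hL.h1e)
        np.testing.assert_array_equal(out.v1p, hL.v1p)
        np.testing.assert_array_equal(out.gep, hL.gep)
        assert out.core_energy == hL.core_energy

    def test_endpoint_middle(self, double_well_triple):
        hL, hM, hR = double_well_triple
        out = interpolate_hamiltonians(hL, hM, hR, WeightTriple(0, 1, 0))
        np.testing.assert_array_equal(out.v1p, hM.v1p)

    def test_equal_weights_elementwise_mean(self):
        triple = [make_random_neo(2, 2, 2, seed=s) for s in (1, 2, 3)]
        out = interpolate_hamiltonians(*triple, WeightTriple(1, 1, 1))
        for attr in ("h1e", "h2e", "v1p", "gep"):
            mean = sum(getattr(h, attr) for h in triple) / 3.0
            np.testing.assert_allclose(getattr(out, attr), mean, atol=1e-15)

    def test_result_valid(self, double_well_triple):
        out = interpolate_hamiltonians(*double_well_triple,
                                       WeightTriple(0.2, 0.5, 0.3))
        out.validate()

    @given(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1))
    @settings(max_examples=20, deadline=None)
    def test_linearity_property(self, a, b, g):
        triple = [make_random_neo(2, 2, 2, seed=s) for s in (4, 5, 6)]
        w = WeightTriple(a, b, g)
        out = interpolate_hamiltonians(*triple, w)
        expected = (
            w.alpha * triple[0].h1e + w.beta * triple[1].h1e + w.gamma * triple[2].h1e
        )
        np.testing.assert_allclose(out.h1e, expected, atol=1e-14)


class TestLMRWeights:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("300", (1.0, 0.0, 0.0)),
            ("210", (2 / 3, 1 / 3, 0.0)),
            ("030", (0.0, 1.0, 0.0)),
            ("003", (0.0, 0.0, 1.0)),
            ("021", (0.0, 2 / 3, 1 / 3)),
        ],
    )
    def test_canonical_labels(self, label, expected):
        w = lmr_weights(label)
        assert (w.alpha, w.beta, w.gamma) == pytest.approx(expected)

    def test_zero_digit_sum_rejected(self):
        with pytest.raises(ValidationError):
            lmr_weights("000")

    def test_non_digit_rejected(self):
        with pytest.raises(ValidationError):
            lmr_weights("3a0")

    def test_weights_normalized(self):
        w = lmr_weights("123")
        assert w.alpha + w.beta + w.gamma == pytest.approx(1.0)


class TestLowdin:
    def test_identity(self):
        np.testing.assert_allclose(lowdin_orthogonalize(np.eye(3)), np.eye(3))

    def test_2x2_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        X = lowdin_orthogonalize(S)
        np.testing.assert_allclose(X.T @ S @ X, np.eye(2), atol=1e-12)
        # closed form via eigendecomposition of S = V diag(1.5, 0.5) V^T
        v = np.sqrt(0.5)
        V = np.array([[v, v], [v, -v]])
        X_ref = V @ np.diag([1.5**-0.5, 0.5**-0.5]) @ V.T
        np.testing.assert_allclose(X, X_ref, atol=1e-12)

    def test_random_spd_6x6(self, rng):
        a = rng.normal(size=(6, 6))
        S = a @ a.T + 6 * np.eye(6)
        X = lowdin_orthogonalize(S)
        assert np.max(np.abs(X.T @ S @ X - np.eye(6))) < 1e-10

    def test_not_positive_definite(self):
        with pytest.raises(ValidationError, match="positive definite"):
            lowdin_orthogonalize(np.diag([1.0, -0.1]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            lowdin_orthogonalize(np.array([[1.0, 0.2], [0.0, 1.0]]))


class TestFNO:
    def test_diagonal_case(self):
        dm = OneParticleDensityMatrix(np.diag([1.9, 0.05, 0.001]), "electronic", 1.951)
        rot, kept, occ = fno_select(dm, 2)
        np.testing.assert_allclose(occ[:2], [1.9, 0.05])
        assert list(kept) == [0, 1]

    def test_idempotent_pure_state(self):
        v = np.array([0.6, 0.8, 0.0])
        dm = OneParticleDensityMatrix(np.outer(v, v), "protonic", 1.0)
        _, _, occ = fno_select(dm, 1)
        assert np.all((np.abs(occ) < 1e-10) | (np.abs(occ - 1) < 1e-10))

    def test_full_reconstruction(self, rng):
        a = rng.normal(size=(5, 5))
        m = a @ a.T
        dm = OneParticleDensityMatrix(m, "electronic", float(np.trace(m)))
        rot, kept, occ = fno_select(dm, 5)
        np.testing.assert_allclose(rot @ np.diag(occ) @ rot.T, m, atol=1e-12)
        np.testing.assert_allclose(rot.T @ rot, np.eye(5), atol=1e-12)
        assert np.all(np.diff(occ) <= 1e-12)

    def test_occupation_trace_conservation(self, rng):
        a = rng.normal(size=(4, 4))
        m = a @ a.T
        dm = OneParticleDensityMatrix(m, "electronic", float(np.trace(m)))
        _, _, occ = fno_select(dm, 2)
        assert np.sum(occ) == pytest.approx(np.trace(m), abs=1e-10)
        # truncation error in trace equals sum of dropped occupations
        assert np.trace(m) - np.sum(occ[:2]) == pytest.approx(np.sum(occ[2:]))

    def test_empty_keep_rejected(self):
        dm = OneParticleDensityMatrix(np.eye(2), "protonic", 2.0)
        with pytest.raises(ValidationError):
            fno_select(dm, 0)


class TestSymmetrization:
    def test_projection_is_idempotent(self, rng):
        t = rng.normal(size=(3, 3, 3, 3))
        s = symmetrize_h2e(t)
        assert h2e_symmetry_residual(s) < 1e-12
        np.testing.assert_allclose(symmetrize_h2e(s), s, atol=1e-14)


class TestMapToQubits:
    def test_unsupported_encoding(self, random_ham):
        with pytest.raises(ValueError, match="unsupported encoding"):
            map_to_qubits(random_ham, encoding="bravyi-kitaev")

    def test_number_operator_image(self):
        # a single-mode number operator maps to (I - Z)/2; probe it through
        # a protonic-only Hamiltonian with v1p = [[1]]-like structure
        space = OrbitalSpace(1, 1, 1)
        h = NEOHamiltonian(
            space, 0.0, np.zeros((1, 1)), np.zeros((1, 1, 1, 1)),
            np.ones((1, 1)), np.zeros((1, 1, 1, 1)),
        )
        qh = map_to_qubits(h)
        assert qh.terms == pytest.approx({"III": 0.5, "IIZ": -0.5})

    def test_separable_limit(self):
        space = OrbitalSpace(2, 1, 2)
        h1e = np.diag([-1.0, 0.5])
        h = NEOHamiltonian(
            space, 0.25, h1e, np.zeros((2, 2, 2, 2)),
            np.array([[-0.3]]), np.zeros((1, 1, 2, 2)),
        )
        qh = map_to_qubits(h)
        dets = sector_determinants(4, 2, 1, 1)
        sub = restrict_dense(qh.to_sparse(), dets)
        e0 = np.linalg.eigvalsh(sub)[0]
        # two electrons in the lowest spatial orbital (both spins) + proton
        assert e0 == pytest.approx(0.25 - 2.0 - 0.3, abs=1e-12)

    def test_identity_absorbs_core(self, random_ham):
        qh = map_to_qubits(random_ham)
        shifted = random_ham.copy()
        shifted.core_energy += 1.5
        qh2 = map_to_qubits(shifted)
        n = random_ham.space.n_qubits
        ident = "I" * n
        assert qh2.terms[ident] - qh.terms[ident] == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sector_spectrum_matches_casci(self, seed):
        h = make_random_neo(2, 2, 2, seed=seed)
        qh = map_to_qubits(h)
        dets = sector_determinants(4, 2, 2, 1)
        sub = restrict_dense(qh.to_sparse(), dets)
        e0 = np.linalg.eigvalsh(sub)[0]
        assert e0 == pytest.approx(casci_solve(h).energy, abs=1e-9)

    def test_coefficients_real(self, random_ham):
        qh = map_to_qubits(random_ham)
        assert all(isinstance(v, float) for v in qh.terms.values())


class TestValidation:
    def test_asymmetric_h1e_rejected(self, random_ham):
        bad = random_ham.copy()
        bad.h1e[0, 1] += 1e-3
        with pytest.raises(ValidationError, match="h1e"):
            bad.validate()

    def test_gep_pair_hermiticity(self, random_ham):
        bad = random_ham.copy()
        bad.gep[0, 1, 0, 0] += 1e-3
        with pytest.raises(ValidationError, match="gep"):
            bad.validate()

    def test_nonfinite_rejected(self, random_ham):
        bad = random_ham.copy()
        bad.v1p[0, 0] = np.nan
        with pytest.raises(ValidationError):
            bad.validate()
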