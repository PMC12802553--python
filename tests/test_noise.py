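"""Noise model construction, folding, noisy expectations, ZNE fits."""

import numpy as np
import pytest

from neoqpt.circuits import GateCircuit
from neoqpt.hamiltonian import QubitHamiltonian
from neoqpt.noise import (
    NoiseModelError,
    build_noise_model,
    device_table,
    fold_circuit,
    noiseless_device_table,
    noisy_expectation,
    zne_extrapolate,
)


class TestNoiseModel:
    def test_build_from_table(self, tmp_path):
        df = device_table(3)
        path = tmp_path / "device.csv"
        df.to_csv(path, index=False)
        model = build_noise_model(path)
        assert set(model.qubits) == {0, 1, 2}
        assert model.qubits[0].err_2q == pytest.approx(1.471e-3)

    def test_default_two_qubit_error_is_eplg_scale(self):
        # representative 2-qubit error chosen at the reported EPLG scale
        model = build_noise_model(device_table(2))
        assert model.qubits[0].err_2q == pytest.approx(0.001471)

    def test_t2_bound_violated(self):
        df = device_table(1, T1_us=50.0, T2_us=150.0)
        with pytest.raises(NoiseModelError, match="T2"):
            build_noise_model(df)

    def test_missing_column(self):
        df = device_table(1).drop(columns=["p01"])
        with pytest.raises(NoiseModelError, match="p01"):
            build_noise_model(df)

    def test_missing_qubit(self):
        model = build_noise_model(device_table(1))
        with pytest.raises(NoiseModelError, match="qubit 1"):
            model.require(1)

    def test_probability_out_of_range(self):
        df = device_table(1, err_1q=1.5)
        with pytest.raises(NoiseModelError):
            build_noise_model(df)


class TestNoisyExpectation:
    def test_noiseless_matches_statevector(self):
        model = build_noise_model(noiseless_device_table(2))
        c = GateCircuit(2).add("h", (0,)).add("cx", (0, 1))
        H = QubitHamiltonian(2, {"ZZ": 1.0, "XX": 0.5})
        mean, sem = noisy_expectation(c, H, model, shots=10, seed=0)
        psi = c.statevector()
        exact = float(np.real(np.vdot(psi, H.to_sparse() @ psi)))
        assert mean == pytest.approx(exact, abs=1e-12)
        assert sem == 0.0

    def test_diagonal_h_basis_state_zero_variance(self):
        model = build_noise_model(noiseless_device_table(1))
        c = GateCircuit(1).add("x", (0,))
        H = QubitHamiltonian(1, {"Z": 1.0})
        mean, sem = noisy_expectation(c, H, model, shots=5, seed=0)
        assert mean == pytest.approx(-1.0, abs=1e-12)
        assert sem == 0.0

    def test_t1_decay_closed_form(self):
        t1, dur_ns = 100.0, 50000.0  # 50 us pulse: strong decay
        df = device_table(1, T1_us=t1, T2_us=2 * t1, err_1q=0.0, err_2q=0.0,
                          dur_1q_ns=dur_ns, p01=0.0, p10=0.0)
        model = build_noise_model(df)
        c = GateCircuit(1).add("x", (0,))
        H = QubitHamiltonian(1, {"Z": 1.0})
        mean, sem = noisy_expectation(c, H, model, shots=40000, seed=7)
        p1 = (1.0 - mean) / 2.0
        expected = np.exp(-dur_ns * 1e-3 / t1)
        assert abs(p1 - expected) < 3.0 * max(sem / 2.0, 1e-4)

    def test_depolarizing_channel_mean(self):
        p = 0.2
        df = device_table(1, T1_us=np.inf, T2_us=np.inf, err_1q=p, err_2q=0.0,
                          p01=0.0, p10=0.0)
        model = build_noise_model(df)
        c = GateCircuit(1).add("rz", (0,), (0.0,))  # identity, but noisy
        H = QubitHamiltonian(1, {"Z": 1.0})
        mean, sem = noisy_expectation(c, H, model, shots=60000, seed=3)
        # X or Y (2 of 3 equally likely Paulis) flip <Z>: 1 - 4p/3
        assert mean == pytest.approx(1.0 - 4.0 * p / 3.0, abs=4 * sem)

    def test_variance_scaling_with_shots(self):
        df = device_table(1, T1_us=np.inf, T2_us=np.inf, err_1q=0.3, err_2q=0.0,
                          p01=0.0, p10=0.0)
        model = build_noise_model(df)
        c = GateCircuit(1).add("h", (0,)).add("rz", (0,), (0.7,)).add("h", (0,))
        H = QubitHamiltonian(1, {"Z": 1.0})
        _, sem_1k = noisy_expectation(c, H, model, shots=1000, seed=5)
        _, sem_4k = noisy_expectation(c, H, model, shots=4000, seed=5)
        assert sem_4k == pytest.approx(0.5 * sem_1k, rel=0.25)

    def test_seed_reproducible(self):
        model = build_noise_model(device_table(2))
        c = GateCircuit(2).add("h", (0,)).add("cx", (0, 1))
        H = QubitHamiltonian(2, {"ZZ": 1.0})
        a = noisy_expectation(c, H, model, shots=50, seed=11)
        b = noisy_expectation(c, H, model, shots=50, seed=11)
        assert a == b

    def test_qubit_count_mismatch(self):
        model = build_noise_model(device_table(2))
        c = GateCircuit(2)
        H = QubitHamiltonian(3, {"ZZZ": 1.0})
        with pytest.raises(NoiseModelError):
            noisy_expectation(c, H, model, shots=1)


class TestFolding:
    @pytest.fixture
    def circuit(self):
        c = GateCircuit(3)
        for i in range(5):
            c.add("cx", (i % 3, (i + 1) % 3))
            c.add("ry", (i % 3,), (0.1 * (i + 1),))
        return c

    def test_lambda_one_unchanged(self, circuit):
        folded = fold_circuit(circuit, 1.0, seed=0)
        assert folded.gates == circuit.gates

    def test_lambda_three_triples_count(self, circuit):
        folded = fold_circuit(circuit, 3.0, seed=0)
        n2 = sum(1 for _, q, _ in folded.gates if len(q) == 2)
        assert n2 == 15

    def test_unitary_preserved(self, circuit):
        for lam in (2.0, 2.5, 3.0, 4.0):
            folded = fold_circuit(circuit, lam, seed=42)
            d = np.linalg.norm(circuit.statevector() - folded.statevector())
            assert d < 1e-10

    def test_counts_near_target(self, circuit):
        for lam in (1.5, 2.0, 3.5):
            folded = fold_circuit(circuit, lam, seed=1)
            n2 = sum(1 for _, q, _ in folded.gates if len(q) == 2)
            assert abs(n2 - lam * 5) <= 1.0

    def test_lambda_below_one_rejected(self, circuit):
        with pytest.raises(ValueError):
            fold_circuit(circuit, 0.5)


class TestZNE:
    LAMS = (1.0, 2.0, 3.0, 4.0)

    def test_exact_linear_recovery_both_methods(self):
        eL = [[-2.0 + 0.3 * l] for l in self.LAMS]
        eM = [[-1.0 + 0.5 * l] for l in self.LAMS]
        for method in ("fit_first", "difference_first"):
            est = zne_extrapolate(self.LAMS, eL, eM, method=method, model="linear")
            assert est.intercept == pytest.approx(1.0, abs=1e-12)
            assert est.intercept_stderr == pytest.approx(0.0, abs=1e-10)

    def test_exact_quadratic_recovery(self):
        eL = [[1.0 + 0.2 * l - 0.05 * l * l] for l in self.LAMS]
        eM = [[3.0 - 0.1 * l + 0.02 * l * l] for l in self.LAMS]
        est = zne_extrapolate(self.LAMS, eL, eM, method="fit_first",
                              model="quadratic")
        assert est.intercept == pytest.approx(2.0, abs=1e-10)

    def test_exponential_decay_taylor_bound(self):
        # on a {1,2,3} grid the linear-extrapolation bias is (5/3) p^2 E0
        lams = (1.0, 2.0, 3.0)
        e0, p = -2.0, 0.01
        eL = [[e0 * (1 - p) ** l] for l in lams]
        eM = [[0.0] for _ in lams]
        est = zne_extrapolate(lams, eL, eM, method="difference_first",
                              model="linear")
        assert abs(est.intercept - (-e0)) <= 2.0 * p * p * abs(e0)

    def test_correlated_noise_difference_first_tighter(self):
        rng = np.random.default_rng(0)
        common = [rng.normal(0, 0.05, 60) for _ in self.LAMS]
        eL = [(-2.0 + 0.3 * l) + c + rng.normal(0, 0.01, 60)
              for l, c in zip(self.LAMS, common)]
        eM = [(-1.0 + 0.5 * l) + c + rng.normal(0, 0.01, 60)
              for l, c in zip(self.LAMS, common)]
        f = zne_extrapolate(self.LAMS, eL, eM, method="fit_first", model="linear")
        d = zne_extrapolate(self.LAMS, eL, eM, method="difference_first",
                            model="linear")
        assert d.intercept_stderr <= f.intercept_stderr

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(1)
        eL = [(-2.0 + 0.3 * l) + rng.normal(0, 0.02, 30) for l in self.LAMS]
        eM = [(-1.0 + 0.5 * l) + rng.normal(0, 0.02, 30) for l in self.LAMS]
        a = zne_extrapolate(self.LAMS, eL, eM, bootstrap=200, seed=9)
        b = zne_extrapolate(self.LAMS, eL, eM, bootstrap=200, seed=9)
        assert a.bootstrap_stderr == b.bootstrap_stderr
        assert a.bootstrap_stderr > 0

    def test_single_lambda_rejected(self):
        with pytest.raises(ValueError):
            zne_extrapolate((1.0,), [[1.0]], [[2.0]])

    def test_default_models_per_method(self):
        eL = [[-2.0 + 0.3 * l] for l in self.LAMS]
        eM = [[-1.0 + 0.5 * l] for l in self.LAMS]
        assert zne_extrapolate(self.LAMS, eL, eM, method="fit_first").model == "quadratic"
        assert zne_extrapolate(self.LAMS, eL, eM,
                               method="difference_first").model == "linear"
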