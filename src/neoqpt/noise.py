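"""Device-style noise emulation, gate folding and zero-noise extrapolation.

The noisy backend samples one Kraus realization per shot on a
statevector (quantum-trajectory method): after each gate, a depolarizing
error drawn from the gate error rate, then thermal relaxation over the
gate duration from the per-qubit T1/T2 times; at measurement, an
asymmetric readout bit-flip channel.  Expectation values are evaluated
exactly on each trajectory and averaged over shots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .circuits import GateCircuit, apply_unitary, gate_matrix
from .hamiltonian import QubitHamiltonian

DEVICE_COLUMNS = ["qubit", "T1_us", "T2_us", "err_1q", "err_2q",
                  "dur_1q_ns", "dur_2q_ns", "p01", "p10"]

_X = np.array([[0, 1], [1, 0]], dtype=complex)
_Y = np.array([[0, -1j], [1j, 0]])
_Z = np.diag([1.0, -1.0]).astype(complex)
_PAULIS_1Q = (_X, _Y, _Z)


class NoiseModelError(ValueError):
    pass


@dataclass
class QubitParams:
    T1_us: float
    T2_us: float
    err_1q: float
    err_2q: float
    dur_1q_ns: float
    dur_2q_ns: float
    p01: float  # P(read 1 | prepared 0)
    p10: float  # P(read 0 | prepared 1)


@dataclass
class NoiseModel:
    """Per-qubit channel parameters derived from a device table."""

    qubits: Dict[int, QubitParams] = field(default_factory=dict)

    def validate(self) -> None:
        for q, p in self.qubits.items():
            for name in ("err_1q", "err_2q", "p01", "p10"):
                v = getattr(p, name)
                if not 0.0 <= v <= 1.0:
                    raise NoiseModelError(f"qubit {q}: {name}={v} outside [0, 1]")
            if p.T2_us > 2.0 * p.T1_us + 1e-12:
                raise NoiseModelError(f"qubit {q}: T2 > 2*T1")
            if p.dur_1q_ns <= 0 or p.dur_2q_ns <= 0:
                raise NoiseModelError(f"qubit {q}: gate durations must be positive")

    def is_noiseless(self) -> bool:
        return all(
            p.err_1q == 0 and p.err_2q == 0 and p.p01 == 0 and p.p10 == 0
            and np.isinf(p.T1_us) and np.isinf(p.T2_us)
            for p in self.qubits.values()
        )

    def require(self, q: int) -> QubitParams:
        try:
            return self.qubits[q]
        except KeyError:
            raise NoiseModelError(f"no characterization data for qubit {q}")


def build_noise_model(device_table: Union[str, Path, pd.DataFrame]) -> NoiseModel:
    """Noise model from a delimited device characterization table."""
    if isinstance(device_table, pd.DataFrame):
        df = device_table
    else:
        df = pd.read_csv(device_table, sep=None, engine="python")
    missing = [c for c in DEVICE_COLUMNS if c not in df.columns]
    if missing:
        raise NoiseModelError(f"device table missing columns {missing}")
    model = NoiseModel()
    for _, row in df.iterrows():
        model.qubits[int(row["qubit"])] = QubitParams(
            float(row["T1_us"]), float(row["T2_us"]),
            float(row["err_1q"]), float(row["err_2q"]),
            float(row["dur_1q_ns"]), float(row["dur_2q_ns"]),
            float(row["p01"]), float(row["p10"]),
        )
    model.validate()
    return model


def noiseless_device_table(n_qubits: int) -> pd.DataFrame:
    return device_table(n_qubits, T1_us=np.inf, T2_us=np.inf, err_1q=0.0,
                        err_2q=0.0, p01=0.0, p10=0.0)


def device_table(
    n_qubits: int,
    T1_us: float = 200.0,
    T2_us: float = 150.0,
    err_1q: float = 2.5e-4,
    err_2q: float = 1.471e-3,
    dur_1q_ns: float = 32.0,
    dur_2q_ns: float = 68.0,
    p01: float = 1e-2,
    p10: float = 1e-2,
) -> pd.DataFrame:
    """Uniform device table; the default two-qubit error rate matches the
    per-layered-gate error scale of a representative heavy-hex device."""
    return pd.DataFrame(
        {
            "qubit": np.arange(n_qubits),
            "T1_us": T1_us, "T2_us": T2_us,
            "err_1q": err_1q, "err_2q": err_2q,
            "dur_1q_ns": dur_1q_ns, "dur_2q_ns": dur_2q_ns,
            "p01": p01, "p10": p10,
        }
    )


# ----------------------------------------------------------- trajectories

def _relaxation(psi, n_qubits, q, t_ns, params, rng):
    """Amplitude damping + dephasing sampled as a trajectory."""
    if np.isinf(params.T1_us) and np.isinf(params.T2_us):
        return psi
    t_us = t_ns * 1e-3
    gamma = 1.0 - np.exp(-t_us / params.T1_us) if np.isfinite(params.T1_us) else 0.0
    # K0 = diag(1, sqrt(1-gamma)), K1 = sqrt(gamma)|0><1|
    k0 = np.diag([1.0, np.sqrt(1.0 - gamma)]).astype(complex)
    branch = apply_unitary(psi, n_qubits, k0, (q,))
    p0 = float(np.vdot(branch, branch).real)
    if rng.random() < p0:
        psi = branch / np.sqrt(p0)
    else:
        k1 = np.zeros((2, 2), dtype=complex)
        k1[0, 1] = np.sqrt(gamma)
        branch = apply_unitary(psi, n_qubits, k1, (q,))
        psi = branch / np.linalg.norm(branch)
    if np.isfinite(params.T2_us):
        decay2 = np.exp(-t_us / params.T2_us)
        ratio = decay2 / np.sqrt(1.0 - gamma) if gamma < 1.0 else 0.0
        p_z = max(0.0, 0.5 * (1.0 - min(1.0, ratio)))
        if rng.random() < p_z:
            psi = apply_unitary(psi, n_qubits, _Z, (q,))
    return psi


def _depolarize_1q(psi, n_qubits, q, p, rng):
    if p > 0 and rng.random() < p:
        k = rng.integers(3)
        psi = apply_unitary(psi, n_qubits, _PAULIS_1Q[k], (q,))
    return psi


def _depolarize_2q(psi, n_qubits, qubits, p, rng):
    if p > 0 and rng.random() < p:
        k = rng.integers(15) + 1  # skip II
        for q, idx in zip(qubits, (k >> 2, k & 3)):
            if idx:
                psi = apply_unitary(psi, n_qubits, _PAULIS_1Q[idx - 1], (q,))
    return psi


def _readout_channel(psi, n_qubits, q, params, rng):
    p01, p10 = params.p01, params.p10
    if p01 == 0.0 and p10 == 0.0:
        return psi
    k0 = np.diag([np.sqrt(1.0 - p01), np.sqrt(1.0 - p10)]).astype(complex)
    branch = apply_unitary(psi, n_qubits, k0, (q,))
    p_keep = float(np.vdot(branch, branch).real)
    if rng.random() < p_keep:
        return branch / np.sqrt(p_keep)
    # flip branch: |0> -> |1> with sqrt(p01), |1> -> |0> with sqrt(p10)
    kf = np.array([[0.0, np.sqrt(p10)], [np.sqrt(p01), 0.0]], dtype=complex)
    branch = apply_unitary(psi, n_qubits, kf, (q,))
    return branch / np.linalg.norm(branch)


def sample_trajectory(
    circuit: GateCircuit, noise: NoiseModel, rng: np.random.Generator,
    with_readout: bool = True,
) -> np.ndarray:
    """One Kraus-sampled statevector realization of the noisy circuit."""
    flat = circuit.expand()
    n = flat.n_qubits
    psi = np.zeros(1 << n, dtype=complex)
    psi[0] = 1.0
    for name, qubits, params in flat.gates:
        psi = apply_unitary(psi, n, gate_matrix(name, params), qubits)
        if len(qubits) == 1:
            qp = noise.require(qubits[0])
            psi = _depolarize_1q(psi, n, qubits[0], qp.err_1q, rng)
            psi = _relaxation(psi, n, qubits[0], qp.dur_1q_ns, qp, rng)
        else:
            qp0 = noise.require(qubits[0])
            psi = _depolarize_2q(psi, n, qubits, qp0.err_2q, rng)
            for q in qubits:
                qp = noise.require(q)
                psi = _relaxation(psi, n, q, qp.dur_2q_ns, qp, rng)
    if with_readout:
        for q in range(n):
            psi = _readout_channel(psi, n, q, noise.require(q), rng)
    return psi


def noisy_expectation(
    circuit: GateCircuit,
    H: QubitHamiltonian,
    noise: NoiseModel,
    shots: int = 1000,
    seed: int = 0,
    with_readout: bool = True,
) -> Tuple[float, float]:
    """Shot-mean and standard error of <H> under the noisy channel."""
    if circuit.n_qubits != H.n_qubits:
        raise NoiseModelError("circuit and Hamiltonian qubit counts differ")
    if shots < 1:
        raise ValueError("shots must be at least 1")
    rng = np.random.default_rng(seed)
    hmat = H.to_sparse()
    if noise.is_noiseless():
        psi = circuit.statevector()
        e = float(np.real(np.vdot(psi, hmat @ psi)))
        return e, 0.0
    samples = np.empty(shots)
    for s in range(shots):
        psi = sample_trajectory(circuit, noise, rng, with_readout=with_readout)
        samples[s] = float(np.real(np.vdot(psi, hmat @ psi)))
    mean = float(np.mean(samples))
    sem = float(np.std(samples, ddof=1) / np.sqrt(shots)) if shots > 1 else 0.0
    return mean, sem


# ---------------------------------------------------------------- folding

def fold_circuit(circuit: GateCircuit, lam: float, seed: int = 0) -> GateCircuit:
    """Local gate folding G -> G G† G on randomly selected two-qubit gates
    until the two-qubit count is the nearest integer to lam times the
    original count.  The noiseless unitary is unchanged."""
    if lam < 1.0:
        raise ValueError("noise amplification factor must be >= 1")
    flat = circuit.expand()
    two_q = [i for i, (_, qubits, _) in enumerate(flat.gates) if len(qubits) == 2]
    m = len(two_q)
    if m == 0 or lam == 1.0:
        return flat
    target = int(round(lam * m))
    n_folds = max(0, (target - m) // 2)
    base, extra = divmod(n_folds, m)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(m, size=extra, replace=False) if extra else np.array([], int)
    folds = np.full(m, base, dtype=int)
    folds[chosen] += 1

    out = GateCircuit(flat.n_qubits, metadata=dict(flat.metadata))
    out.metadata["folded_lambda"] = lam
    k = 0
    for i, (name, qubits, params) in enumerate(flat.gates):
        out.gates.append((name, qubits, params))
        if len(qubits) == 2:
            g = GateCircuit(flat.n_qubits, [(name, qubits, params)])
            ginv = g.inverse().gates[0]
            for _ in range(folds[k]):
                out.gates.append(ginv)
                out.gates.append((name, qubits, params))
            k += 1
    return out


# ------------------------------------------------------------------- ZNE

@dataclass
class ZNEEstimate:
    lambdas: np.ndarray
    method: str  # fit_first | difference_first
    model: str  # linear | quadratic
    intercept: float
    intercept_stderr: float
    per_lambda_means: Dict[str, np.ndarray]
    fit_coefficients: Dict[str, np.ndarray]
    bootstrap_stderr: Optional[float] = None
    n_bootstrap: int = 0


def _ols_intercept(lams: np.ndarray, y: np.ndarray, degree: int):
    """OLS polynomial fit; returns (coeffs ascending, intercept, stderr)."""
    if len(lams) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct lambda values for degree {degree}"
        )
    X = np.vander(lams, degree + 1, increasing=True)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(lams) - (degree + 1)
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, float(beta[0]), float(np.sqrt(max(cov[0, 0], 0.0)))


def zne_extrapolate(
    lambdas: Sequence[float],
    energies_left: Sequence[Sequence[float]],
    energies_middle: Sequence[Sequence[float]],
    method: str = "difference_first",
    model: Optional[str] = None,
    bootstrap: Optional[int] = None,
    seed: int = 0,
) -> ZNEEstimate:
    """Extrapolate the Middle-minus-Left barrier to the zero-noise limit.

    energies_* hold one array of per-circuit energies for each lambda.
    fit_first fits each configuration separately (quadratic default) and
    differences the intercepts; difference_first fits the per-lambda
    mean differences (linear default).  The optional bootstrap resamples
    circuits within each lambda nonparametrically.
    """
    lams = np.asarray(lambdas, dtype=float)
    if len(lams) < 2 or np.any(np.diff(lams) <= 0) or lams[0] < 1.0:
        raise ValueError("lambdas must be strictly increasing and start at >= 1")
    if method not in ("fit_first", "difference_first"):
        raise ValueError(f"unknown method {method!r}")
    if model is None:
        model = "quadratic" if method == "fit_first" else "linear"
    if model not in ("linear", "quadratic"):
        raise ValueError(f"unknown model {model!r}")
    degree = 1 if model == "linear" else 2
    eL = [np.asarray(a, dtype=float) for a in energies_left]
    eM = [np.asarray(a, dtype=float) for a in energies_middle]
    if len(eL) != len(lams) or len(eM) != len(lams):
        raise ValueError("per-lambda sample lists must match the lambda grid")
    mean_L = np.array([a.mean() for a in eL])
    mean_M = np.array([a.mean() for a in eM])

    def estimate(eL_means, eM_means):
        if method == "fit_first":
            cL, iL, sL = _ols_intercept(lams, eL_means, degree)
            cM, iM, sM = _ols_intercept(lams, eM_means, degree)
            return (
                iM - iL,
                float(np.hypot(sL, sM)),
                {"left": cL, "middle": cM},
            )
        cD, iD, sD = _ols_intercept(lams, eM_means - eL_means, degree)
        return iD, sD, {"difference": cD}

    intercept, stderr, coeffs = estimate(mean_L, mean_M)

    boot_stderr = None
    n_boot = 0
    if bootstrap:
        rng = np.random.default_rng(seed)
        draws = np.empty(bootstrap)
        for b in range(bootstrap):
            mL = np.array([a[rng.integers(0, len(a), len(a))].mean() for a in eL])
            mM = np.array([a[rng.integers(0, len(a), len(a))].mean() for a in eM])
            draws[b] = estimate(mL, mM)[0]
        boot_stderr = float(np.std(draws, ddof=1))
        n_boot = bootstrap

    return ZNEEstimate(
        lambdas=lams,
        method=method,
        model=model,
        intercept=float(intercept),
        intercept_stderr=float(stderr),
        per_lambda_means={"left": mean_L, "middle": mean_M},
        fit_coefficients=coeffs,
        bootstrap_stderr=boot_stderr,
        n_bootstrap=n_boot,
    )


def zne_energy_sweep(
    circuit: GateCircuit,
    H: QubitHamiltonian,
    noise: NoiseModel,
    lambdas: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
    n_circuits: int = 100,
    shots: int = 1000,
    seed: int = 0,
) -> List[np.ndarray]:
    """Per-lambda arrays of per-circuit mean energies (randomized folding)."""
    rng = np.random.default_rng(seed)
    out = []
    for lam in lambdas:
        vals = np.empty(n_circuits)
        for c in range(n_circuits):
            folded = fold_circuit(circuit, lam, seed=int(rng.integers(2**31)))
            vals[c], _ = noisy_expectation(
                folded, H, noise, shots=shots, seed=int(rng.integers(2**31))
            )
        out.append(vals)
    return out
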