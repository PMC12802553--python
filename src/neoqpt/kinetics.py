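"""Transition-state-theory rate constants from effective quantum barriers.

k(T) = (k_B T / h) * exp(-dE / (k_B T)) with the Eyring-style prefactor;
ratio-based quantities (suppression, sensitivity) are independent of the
prefactor convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import K_B_HA_PER_K, K_B_J_PER_K, H_J_S

PREFACTOR_CONVENTION = "eyring-kBT/h"


def _check_temperature(T: float) -> None:
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")


def tst_rate(barrier_ha: float, T: float) -> float:
    """Rate constant in 1/s for a barrier in Hartree at temperature T (K)."""
    _check_temperature(T)
    prefactor = K_B_J_PER_K * T / H_J_S
    return float(prefactor * np.exp(-barrier_ha / (K_B_HA_PER_K * T)))


def rate_suppression(barrier_approx_ha: float, barrier_ref_ha: float,
                     T: float) -> float:
    """Fractional rate underestimate 1 - k(approx)/k(ref); prefactors cancel."""
    _check_temperature(T)
    delta = barrier_approx_ha - barrier_ref_ha
    return float(1.0 - np.exp(-delta / (K_B_HA_PER_K * T)))


def barrier_tolerance(T: float, max_rate_error: float) -> float:
    """Barrier error (mHa) keeping |dk/k| below max_rate_error, from the
    linearized sensitivity dk/k ~= -dE/(k_B T)."""
    _check_temperature(T)
    if not 0.0 < max_rate_error < 1.0:
        raise ValueError("max_rate_error must lie strictly between 0 and 1")
    return float(max_rate_error * K_B_HA_PER_K * T * 1.0e3)


@dataclass
class RateCurve:
    """TST rates over a temperature grid for one barrier."""

    temperatures: np.ndarray  # K
    rates: np.ndarray  # 1/s
    barrier_ha: float
    prefactor_convention: str = PREFACTOR_CONVENTION


def rate_curve(barrier_ha: float, temperatures) -> RateCurve:
    temps = np.asarray(temperatures, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive")
    rates = np.array([tst_rate(barrier_ha, t) for t in temps])
    return RateCurve(temps, rates, barrier_ha)
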