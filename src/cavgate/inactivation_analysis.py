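"""Inactivation metrics from 3 s depolarizing sweeps.

Two measurements per sweep: the degree of inactivation (% decay of the inward
current from its peak to the end of the pulse) and the time constant of a
single-exponential fit to the decay phase.  The exponential is fitted with a
constant pedestal, since a degree of inactivation below 100% implies a
non-inactivating current component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidInputError, UnreliableMeasurementError
from .iv_analysis import detect_peak_current
from .synthetic_recordings import DEFAULT_BLANK_MS, Sweep

__all__ = ["InactivationResult", "percent_inactivation", "fit_inactivation_tau"]

#: Window (ms) at the pulse end averaged to estimate the residual current.
END_WINDOW_MS = 50.0


@dataclass(frozen=True)
class InactivationResult:
    test_voltage: float
    degree_pct: float  # in [0, 100]
    tau_ms: float
    pedestal_fraction: float  # residual current / peak current, in [0, 1]
    fit_window: tuple[float, float]  # (t_start, t_end) ms
    converged: bool


def _noise_floor(sweep: Sweep) -> float:
    """Noise SD estimate from the median absolute successive difference."""
    diffs = np.diff(sweep.current)
    if len(diffs) == 0:
        return 0.0
    return float(np.median(np.abs(diffs)) / (0.6745 * np.sqrt(2.0)))


def percent_inactivation(
    sweep: Sweep, blank_ms: float = DEFAULT_BLANK_MS
) -> float:
    """Degree of inactivation, ``100 * (1 - I_end / I_peak)``, clipped to [0, 100].

    ``I_end`` is the mean current over the final 50 ms of the pulse; ``I_peak``
    is the most negative sample after the blanking window.  A peak within
    3x the estimated noise SD raises :class:`UnreliableMeasurementError`.
    """
    peak = detect_peak_current(sweep, blank_ms)
    floor = 3.0 * _noise_floor(sweep)
    if abs(peak) <= floor:
        raise UnreliableMeasurementError(
            f"peak {peak:.2f} pA is within the noise floor ({floor:.2f} pA)"
        )
    end_mask = sweep.time >= sweep.time[-1] - END_WINDOW_MS
    i_end = float(np.mean(sweep.current[end_mask]))
    return float(np.clip(100.0 * (1.0 - i_end / peak), 0.0, 100.0))


def fit_inactivation_tau(
    sweep: Sweep, blank_ms: float = DEFAULT_BLANK_MS
) -> InactivationResult:
    """Single-exponential-plus-pedestal fit of the decay phase.

    Fits ``I(t) = A exp(-(t - t_peak)/tau) + C`` from the time of the peak
    inward current to the end of the pulse.  The decay phase must exist
    (degree of inactivation > 5%).
    """
    degree = percent_inactivation(sweep, blank_ms)
    if degree <= 5.0:
        raise InvalidInputError(
            f"no decay phase to fit (degree of inactivation {degree:.1f}% <= 5%)"
        )
    peak = detect_peak_current(sweep, blank_ms)
    mask = sweep.time >= blank_ms
    i_peak_idx = int(np.argmin(np.where(mask, sweep.current, np.inf)))
    t_peak = float(sweep.time[i_peak_idx])
    t = sweep.time[i_peak_idx:] - t_peak
    y = sweep.current[i_peak_idx:]

    i_end = float(np.mean(y[t >= t[-1] - END_WINDOW_MS]))
    tau0 = _tau_initial_guess(t, y, peak, i_end)

    def residuals(x: np.ndarray) -> np.ndarray:
        a, c, tau = x
        return a * np.exp(-t / tau) + c - y

    sol = least_squares(
        residuals,
        x0=np.array([peak - i_end, i_end, tau0]),
        bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        max_nfev=2000,
    )
    a, c, tau = (float(x) for x in sol.x)
    pedestal = float(np.clip(c / peak, 0.0, 1.0)) if peak != 0 else 0.0
    return InactivationResult(
        test_voltage=sweep.test_voltage,
        degree_pct=degree,
        tau_ms=tau,
        pedestal_fraction=pedestal,
        fit_window=(t_peak, float(sweep.time[-1])),
        converged=bool(sol.success) and tau > 0,
    )


def _tau_initial_guess(t: np.ndarray, y: np.ndarray, peak: float, i_end: float) -> float:
    """Time for the decay to cover (1 - 1/e) of its span, as a tau estimate."""
    target = i_end + (peak - i_end) / np.e
    above = np.nonzero(y >= target)[0]  # inward currents: decay moves up toward 0
    if len(above) == 0 or above[0] == 0:
        return max(float(t[-1]) / 5.0, 1.0)
    return max(float(t[above[0]]), 1.0)
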