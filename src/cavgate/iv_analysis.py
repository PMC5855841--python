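"""From sweeps to I-V curves to Boltzmann-ohmic fits.

Peak inward currents from 20 ms step sweeps are normalized by membrane
capacitance to current densities (pA/pF), assembled into an I-V curve and
fitted by nonlinear least squares with the Boltzmann-ohmic model

    I(V) = G_max (V - V_rev) / (1 + exp(-(V - V_half) / k)).

V_half, k and V_rev are invariant under scaling of the curve, so fits of raw
and peak-normalized curves agree; G_max alone carries the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateCurveError,
    IncompleteRecordingError,
    InvalidInputError,
)
from .synthetic_recordings import DEFAULT_BLANK_MS, CellRecording, Sweep

__all__ = [
    "IVCurve",
    "BoltzmannFitResult",
    "detect_peak_current",
    "current_density",
    "build_iv_curve",
    "normalize_iv",
    "fit_boltzmann_iv",
    "v_half_shift",
]


@dataclass(frozen=True)
class IVCurve:
    """Peak current density vs test voltage for one cell."""

    voltages: np.ndarray  # mV, strictly increasing
    densities: np.ndarray  # pA/pF (or dimensionless if normalized)
    normalized: bool = False
    cell_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if v.shape != d.shape or v.ndim != 1:
            raise InvalidInputError("voltages and densities must be equal-length 1-D")
        if np.any(np.diff(v) <= 0):
            raise InvalidInputError("voltages must be strictly increasing")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "densities", d)

    @property
    def peak_voltage(self) -> float:
        """Test voltage of the most negative (maximal inward) density."""
        return float(self.voltages[int(np.argmin(self.densities))])


@dataclass(frozen=True)
class BoltzmannFitResult:
    """Least-squares estimate of the Boltzmann-ohmic parameters."""

    g_max: float
    v_rev: float
    v_half: float
    k: float
    rss: float
    converged: bool
    n_iter: int = 0


def detect_peak_current(sweep: Sweep, blank_ms: float = DEFAULT_BLANK_MS) -> float:
    """Most negative sample after the blanking window (inward convention).

    The sign is preserved: an all-outward trace returns its (positive)
    minimum.  Ties break to the earliest sample.
    """
    if len(sweep.current) == 0:
        raise InvalidInputError("empty sweep")
    if sweep.time[-1] <= blank_ms:
        raise InvalidInputError(
            f"sweep duration {sweep.time[-1]} ms does not exceed blanking "
            f"window {blank_ms} ms"
        )
    mask = sweep.time >= blank_ms
    return float(np.min(sweep.current[mask]))


def current_density(peak_pA: float, capacitance_pF: float) -> float:
    """Peak current normalized by membrane capacitance, pA/pF."""
    if not capacitance_pF > 0:
        raise InvalidInputError(f"capacitance must be > 0, got {capacitance_pF}")
    return peak_pA / capacitance_pF


def build_iv_curve(
    recording: CellRecording, blank_ms: float = DEFAULT_BLANK_MS
) -> IVCurve:
    """Unnormalized density-voltage curve from a cell's 20 ms sweeps."""
    sweeps = recording.sweeps_for("iv_20ms")
    if not sweeps:
        raise IncompleteRecordingError(
            f"recording {recording.cell_id} has no iv_20ms sweeps"
        )
    sweeps = sorted(sweeps, key=lambda s: s.test_voltage)
    voltages = np.array([s.test_voltage for s in sweeps])
    densities = np.array(
        [
            current_density(detect_peak_current(s, blank_ms), recording.capacitance)
            for s in sweeps
        ]
    )
    return IVCurve(voltages=voltages, densities=densities, cell_id=recording.cell_id)


def normalize_iv(curve: IVCurve) -> IVCurve:
    """Divide densities by max |density| (the inward peak maps to -1).

    Idempotent; raises :class:`DegenerateCurveError` on an all-zero curve.
    """
    scale = float(np.max(np.abs(curve.densities)))
    if scale == 0:
        raise DegenerateCurveError("cannot normalize an all-zero I-V curve")
    return replace(curve, densities=curve.densities / scale, normalized=True)


def _boltzmann_ohmic(v: np.ndarray, g: float, v_rev: float, v_half: float, k: float) -> np.ndarray:
    return g * (v - v_rev) / (1.0 + np.exp(-(v - v_half) / k))


# Parameter bounds for the fit (order: g_max, v_rev, v_half, k).  g_max > 0:
# the ohmic term (V - V_rev) makes the current inward below V_rev.
_LOWER = np.array([0.0, 20.0, -40.0, 0.5])
_UPPER = np.array([np.inf, 90.0, 30.0, 20.0])


def _initial_guess(v: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Heuristic start: v_rev from the zero crossing beyond the peak, v_half
    from the half-peak voltage on the rising limb, k = 5 mV."""
    i_peak = int(np.argmin(d))
    peak = d[i_peak]
    v_rev = 60.0
    for j in range(i_peak, len(v) - 1):
        if d[j] <= 0 <= d[j + 1]:
            frac = -d[j] / (d[j + 1] - d[j]) if d[j + 1] != d[j] else 0.0
            v_rev = v[j] + frac * (v[j + 1] - v[j])
            break
    v_half = v[i_peak] - 5.0
    for j in range(i_peak):
        if d[j] <= peak / 2 and j > 0:
            v_half = float(v[j])
            break
    k = 5.0
    g = abs(peak) / max(abs(v[i_peak] - v_rev), 1e-6)
    x0 = np.array([g, v_rev, v_half, k])
    return np.clip(x0, _LOWER + 1e-9, np.where(np.isfinite(_UPPER), _UPPER - 1e-9, x0))


def fit_boltzmann_iv(curve: IVCurve) -> BoltzmannFitResult:
    """Unweighted least-squares fit of the Boltzmann-ohmic model to a curve.

    Requires at least 6 points spanning both sides of the inward peak.
    Non-convergence is reported via ``converged=False``, never silently.
    """
    v = curve.voltages
    d = curve.densities
    if len(v) < 6:
        raise InvalidInputError("need at least 6 I-V points to fit 4 parameters")
    i_peak = int(np.argmin(d))
    if i_peak == 0 or i_peak == len(v) - 1:
        raise DegenerateCurveError(
            "I-V curve peak lies at the edge of the voltage range"
        )
    if float(np.max(np.abs(d))) == 0:
        raise DegenerateCurveError("all-zero I-V curve")

    def residuals(x: np.ndarray) -> np.ndarray:
        g, v_rev, v_half, k = x
        return _boltzmann_ohmic(v, g, v_rev, v_half, k) - d

    sol = least_squares(
        residuals,
        _initial_guess(v, d),
        bounds=(_LOWER, _UPPER),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    g, v_rev, v_half, k = (float(x) for x in sol.x)
    # a solution pinned at a box bound is not a credible parameter estimate
    at_bound = bool(
        np.any(sol.x[1:] <= _LOWER[1:] + 1e-6) or np.any(sol.x[1:] >= _UPPER[1:] - 1e-6)
    )
    return BoltzmannFitResult(
        g_max=g,
        v_rev=v_rev,
        v_half=v_half,
        k=k,
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success) and not at_bound,
        n_iter=int(sol.nfev),
    )


def v_half_shift(
    group_a: list[BoltzmannFitResult], group_b: list[BoltzmannFitResult]
) -> dict:
    """Difference of group-mean V_half, ``mean(b) - mean(a)``.

    Non-converged fits are excluded and counted; an all-non-converged group
    raises :class:`InvalidInputError`.
    """
    summaries = {}
    means = {}
    for label, group in (("a", group_a), ("b", group_b)):
        if not group:
            raise InvalidInputError(f"group {label} is empty")
        ok = [f.v_half for f in group if f.converged]
        if not ok:
            raise InvalidInputError(f"group {label} has no converged fits")
        arr = np.asarray(ok)
        summaries[label] = {
            "n": len(ok),
            "n_excluded": len(group) - len(ok),
            "mean_v_half": float(arr.mean()),
            "sd_v_half": float(arr.std(ddof=1)) if len(ok) > 1 else 0.0,
        }
        means[label] = float(arr.mean())
    return {
        "shift_mV": means["b"] - means["a"],
        "groups": summaries,
    }
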