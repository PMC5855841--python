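"""Boltzmann-ohmic gating model for CaV2.1 and per-condition parameter presets.

The steady-state current density through a population of high-voltage-activated
Ca2+ channels is modelled as an ohmic driving force gated by a Boltzmann
activation term:

    I(V) = G_max (V - V_rev) / (1 + exp(-(V - V_half) / k))

with G_max the maximal conductance per unit capacitance (nS/pF), V_rev the
extrapolated reversal potential (mV), V_half the half-activation voltage (mV)
and k the activation slope factor (mV).  Inactivation over seconds-long pulses
is described per test voltage by a degree of inactivation (% decay of the
current from its peak to the end of a 3 s pulse) and a single-exponential time
constant.

Condition presets encode the experimental groups of a tunicamycin
hypoglycosylation / N283Q glycosylation-site mutagenesis study in HEK293 cells:
mean peak current densities, activation V_half shifts and inactivation changes
per condition, plus between-cell variability used by the synthetic recording
generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "InactSpec",
    "GatingParams",
    "Variability",
    "ConditionPreset",
    "steady_state_activation",
    "iv_current",
    "peak_current_voltage",
    "solve_v_half_for_peak",
    "make_presets",
    "dump_presets",
    "load_presets",
    "PRESET_NAMES",
]

#: Default activation slope factor (mV), a typical CaV2.1 value.
DEFAULT_K_ACT = 4.5
#: Default extrapolated reversal potential (mV) in 2.5 mM external Ca2+.
DEFAULT_V_REV = 60.0
#: Default activation time constant (ms); fast relative to a 20 ms pulse.
DEFAULT_TAU_ACT = 1.0

PRESET_NAMES = (
    "vehicle",
    "tun02",
    "tun06",
    "tun20",
    "no_a2d1",
    "wt_exp2",
    "n283q",
    "n283q_vehicle",
    "n283q_tun06",
)


@dataclass(frozen=True)
class InactSpec:
    """Inactivation at one test voltage: % decay at 3 s and exponential tau."""

    degree_pct: float
    tau_ms: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.degree_pct <= 100.0:
            raise ConfigurationError(
                f"degree_pct must be in [0, 100], got {self.degree_pct}"
            )
        if not self.tau_ms > 0:
            raise ConfigurationError(f"tau_inact must be > 0, got {self.tau_ms}")


@dataclass(frozen=True)
class GatingParams:
    """Biophysical state of one condition.

    Parameters
    ----------
    g_max_density
        Maximal conductance per capacitance, nS/pF (> 0).
    v_rev
        Reversal potential, mV.
    v_half_act
        Half-maximal activation voltage, mV.
    k_act
        Boltzmann slope factor, mV (> 0).
    tau_act
        Activation time constant, ms (> 0).
    inact
        Mapping test voltage (mV) -> :class:`InactSpec`.
    """

    g_max_density: float
    v_rev: float
    v_half_act: float
    k_act: float
    tau_act: float = DEFAULT_TAU_ACT
    inact: Mapping[float, InactSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.g_max_density > 0:
            raise ConfigurationError(
                f"g_max_density must be > 0, got {self.g_max_density}"
            )
        if not self.k_act > 0:
            raise ConfigurationError(f"k_act must be > 0, got {self.k_act}")
        if not self.tau_act > 0:
            raise ConfigurationError(f"tau_act must be > 0, got {self.tau_act}")

    def inact_at(self, v: float) -> InactSpec:
        """Inactivation parameters at voltage ``v``.

        Linear interpolation between specified test voltages, constant
        extrapolation beyond them.  Inactivation is a smooth function of
        voltage; the experiment only pins it at the 3 s test potentials.
        """
        if not self.inact:
            return InactSpec(degree_pct=0.0, tau_ms=1e9)
        volts = sorted(self.inact)
        if v <= volts[0]:
            return self.inact[volts[0]]
        if v >= volts[-1]:
            return self.inact[volts[-1]]
        vs = np.asarray(volts, dtype=float)
        deg = np.interp(v, vs, [self.inact[x].degree_pct for x in volts])
        tau = np.interp(v, vs, [self.inact[x].tau_ms for x in volts])
        return InactSpec(degree_pct=float(deg), tau_ms=float(tau))


@dataclass(frozen=True)
class Variability:
    """Between-cell variability of a condition group (all entries >= 0)."""

    peak_density_cv: float
    v_half_sd_mV: float
    degree_sd_pct: float
    tau_cv: float

    def __post_init__(self) -> None:
        for name in ("peak_density_cv", "v_half_sd_mV", "degree_sd_pct", "tau_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ConditionPreset:
    """One experimental condition: group size, mean effect and variability."""

    name: str
    n_cells: int
    mean_peak_density: float  # pA/pF, negative = inward
    gating: GatingParams
    variability: Variability
    noise_sd_pA: float

    def __post_init__(self) -> None:
        if not self.mean_peak_density < 0:
            raise ConfigurationError(
                f"mean_peak_density must be negative (inward), got "
                f"{self.mean_peak_density}"
            )
        if self.n_cells < 1:
            raise ConfigurationError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.noise_sd_pA < 0:
            raise ConfigurationError("noise_sd_pA must be >= 0")


def steady_state_activation(v: float, p: GatingParams) -> float:
    """Boltzmann open fraction ``1 / (1 + exp(-(v - V_half)/k))`` in (0, 1)."""
    if not np.all(np.isfinite(v)):
        raise InvalidInputError(f"voltage must be finite, got {v}")
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - p.v_half_act) / p.k_act))


def iv_current(v: float, p: GatingParams) -> float:
    """Steady-state current density (pA/pF) at voltage ``v`` (mV).

    Zero exactly at ``v_rev``; negative (inward) below it.
    """
    return p.g_max_density * (np.asarray(v, dtype=float) - p.v_rev) * steady_state_activation(v, p)


def peak_current_voltage(p: GatingParams) -> float:
    """Voltage of maximal inward current.

    At the optimum the derivative of ``(V - V_rev) * m(V)`` vanishes, which
    rearranges to ``(V_rev - V*) (1 - m(V*)) = k``.  The left side decreases
    monotonically in V* on (-inf, v_rev), so the root is unique and bracketed.
    """
    def grad(v: float) -> float:
        m = 1.0 / (1.0 + math.exp(-(v - p.v_half_act) / p.k_act))
        return (p.v_rev - v) * (1.0 - m) - p.k_act

    lo = p.v_half_act - 30.0 * p.k_act
    hi = p.v_rev - 1e-9
    while grad(lo) < 0:  # pragma: no cover - defensive bracket widening
        lo -= 50.0
    return float(brentq(grad, lo, hi, xtol=1e-10))


def solve_v_half_for_peak(
    v_peak: float, k_act: float = DEFAULT_K_ACT, v_rev: float = DEFAULT_V_REV
) -> float:
    """V_half such that the inward-current maximum falls at ``v_peak``.

    Inverts the stationarity relation ``(v_rev - v*)(1 - m(v*)) = k``:
    ``m(v*) = 1 - k/(v_rev - v*)`` and ``V_half = v* - k ln(m/(1-m))``.
    """
    if not v_rev - v_peak > k_act:
        raise InvalidInputError(
            "v_peak too close to v_rev: need v_rev - v_peak > k_act"
        )
    m_star = 1.0 - k_act / (v_rev - v_peak)
    return v_peak - k_act * math.log(m_star / (1.0 - m_star))


def _g_for_peak_density(mean_peak_density: float, gating: GatingParams) -> float:
    """Scale g_max so the steady-state I-V minimum equals ``mean_peak_density``."""
    unit = replace(gating, g_max_density=1.0)
    v_star = peak_current_voltage(unit)
    per_unit = float(iv_current(v_star, unit))  # negative, pA/pF per nS/pF
    return mean_peak_density / per_unit


# Printed group means: (n_cells, mean peak density pA/pF, SEM pA/pF).
_GROUP_MEANS = {
    "vehicle": (27, -149.8, 14.9),
    "tun02": (13, -107.03, 25.1),
    "tun06": (16, -26.7, 7.9),
    "tun20": (6, -1.9, 1.8),
    "no_a2d1": (7, -7.8, 2.9),
    "wt_exp2": (13, -69.4, 12.9),
    "n283q": (19, -19.5, 3.2),
    "n283q_vehicle": (10, -23.3, 5.6),
    "n283q_tun06": (8, -11.6, 3.6),
}

# Activation V_half shift (mV) relative to the untreated control of each series.
_V_HALF_SHIFTS = {
    "tun02": -3.5,
    "tun06": -5.0,
    "n283q_tun06": -4.5,
}

# Control degrees of inactivation (%) at the 3 s test potentials.  Only
# condition differences are reported experimentally; the control levels are
# model assumptions (see docs).
_CONTROL_DEGREE = {20.0: 80.0, 0.0: 75.0}
_CONTROL_TAU = {20.0: 300.0, 0.0: 400.0}
# Degree reduction (percentage points) and tau multiplier per condition.
_INACT_EFFECTS = {
    "tun06": ({20.0: 14.0, 0.0: 16.0}, 1.5),
    "n283q": ({20.0: 22.0, 0.0: 35.0}, 2.0),
    "n283q_vehicle": ({20.0: 22.0, 0.0: 35.0}, 2.0),
    "n283q_tun06": ({20.0: 22.0, 0.0: 35.0}, 2.0),
}

DEFAULT_NOISE_SD_PA = 5.0
_DEFAULT_V_HALF_SD = 2.0
_DEFAULT_DEGREE_SD = 5.0
_DEFAULT_TAU_CV = 0.3


def _build_preset(name: str) -> ConditionPreset:
    n, mean_density, sem = _GROUP_MEANS[name]
    v_half = solve_v_half_for_peak(15.0) + _V_HALF_SHIFTS.get(name, 0.0)

    degree_drop, tau_mult = _INACT_EFFECTS.get(name, ({}, 1.0))
    inact = {
        v: InactSpec(
            degree_pct=_CONTROL_DEGREE[v] - degree_drop.get(v, 0.0),
            tau_ms=_CONTROL_TAU[v] * tau_mult,
        )
        for v in (0.0, 20.0)
    }
    gating = GatingParams(
        g_max_density=1.0,
        v_rev=DEFAULT_V_REV,
        v_half_act=v_half,
        k_act=DEFAULT_K_ACT,
        tau_act=DEFAULT_TAU_ACT,
        inact=inact,
    )
    gating = replace(gating, g_max_density=_g_for_peak_density(mean_density, gating))

    sd = sem * math.sqrt(n)  # between-cell SD reconstructed from printed SEM
    variability = Variability(
        peak_density_cv=sd / abs(mean_density),
        v_half_sd_mV=_DEFAULT_V_HALF_SD,
        degree_sd_pct=_DEFAULT_DEGREE_SD,
        tau_cv=_DEFAULT_TAU_CV,
    )
    return ConditionPreset(
        name=name,
        n_cells=n,
        mean_peak_density=mean_density,
        gating=gating,
        variability=variability,
        noise_sd_pA=DEFAULT_NOISE_SD_PA,
    )


def make_presets(config: Mapping[str, Mapping[str, object]] | None = None) -> dict[str, ConditionPreset]:
    """Build the nine condition presets, optionally overriding fields.

    ``config`` maps preset name -> {field: value}, where field is a flat
    attribute path as used by :func:`dump_presets` (e.g. ``"noise_sd_pA"``,
    ``"gating.v_half_act"``).  Overrides that violate type invariants raise
    :class:`ConfigurationError`.
    """
    presets = {name: _build_preset(name) for name in PRESET_NAMES}
    if config:
        for name, fields in config.items():
            if name not in presets:
                raise ConfigurationError(f"unknown preset {name!r}")
            flat = _flatten_preset(presets[name])
            for key, value in fields.items():
                if key not in flat and not key.startswith("gating.inact."):
                    raise ConfigurationError(f"unknown preset field {name}.{key}")
                flat[key] = value
            presets[name] = _unflatten_preset(name, flat)
    return presets


# -- flat key=value serialization -------------------------------------------
#
# One line per scalar field: "<preset>.<path> = <repr>".  Float reprs
# round-trip bit-identically through Python's float().

_SCALAR_FIELDS = ("n_cells", "mean_peak_density", "noise_sd_pA")
_GATING_FIELDS = ("g_max_density", "v_rev", "v_half_act", "k_act", "tau_act")
_VAR_FIELDS = ("peak_density_cv", "v_half_sd_mV", "degree_sd_pct", "tau_cv")


def _flatten_preset(p: ConditionPreset) -> dict[str, object]:
    flat: dict[str, object] = {f: getattr(p, f) for f in _SCALAR_FIELDS}
    for f in _GATING_FIELDS:
        flat[f"gating.{f}"] = getattr(p.gating, f)
    for v in sorted(p.gating.inact):
        spec = p.gating.inact[v]
        flat[f"gating.inact.{v!r}.degree_pct"] = spec.degree_pct
        flat[f"gating.inact.{v!r}.tau_inact_ms"] = spec.tau_ms
    for f in _VAR_FIELDS:
        flat[f"variability.{f}"] = getattr(p.variability, f)
    return flat


def _unflatten_preset(name: str, flat: Mapping[str, object]) -> ConditionPreset:
    inact: dict[float, dict[str, float]] = {}
    gating_kw: dict[str, float] = {}
    var_kw: dict[str, float] = {}
    top: dict[str, object] = {}
    for key, value in flat.items():
        if key.startswith("gating.inact."):
            _, _, rest = key.partition("gating.inact.")
            vtxt, _, fname = rest.rpartition(".")
            inact.setdefault(float(vtxt), {})[fname] = float(value)
        elif key.startswith("gating."):
            gating_kw[key.split(".", 1)[1]] = float(value)
        elif key.startswith("variability."):
            var_kw[key.split(".", 1)[1]] = float(value)
        else:
            top[key] = value
    try:
        gating = GatingParams(
            **gating_kw,
            inact={
                v: InactSpec(d["degree_pct"], d["tau_inact_ms"])
                for v, d in inact.items()
            },
        )
        return ConditionPreset(
            name=name,
            n_cells=int(top["n_cells"]),
            mean_peak_density=float(top["mean_peak_density"]),
            gating=gating,
            variability=Variability(**var_kw),
            noise_sd_pA=float(top["noise_sd_pA"]),
        )
    except TypeError as exc:
        raise ConfigurationError(f"bad preset fields for {name}: {exc}") from exc


def dump_presets(presets: Mapping[str, ConditionPreset]) -> str:
    """Serialize presets to a flat ``key = value`` text config."""
    lines = ["# cavgate condition presets (units in key names; mV, ms, pA, pF)"]
    for name in presets:
        lines.append("")
        for key, value in _flatten_preset(presets[name]).items():
            lines.append(f"{name}.{key} = {value!r}")
    return "\n".join(lines) + "\n"


def load_presets(text: str) -> dict[str, ConditionPreset]:
    """Parse the output of :func:`dump_presets` (exact round-trip)."""
    per_preset: dict[str, dict[str, object]] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        name, _, path = key.strip().partition(".")
        per_preset.setdefault(name, {})[path] = value.strip()
    return {
        name: _unflatten_preset(name, flat) for name, flat in per_preset.items()
    }
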