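"""Seeded generator of synthetic whole-cell voltage-clamp recordings.

Emulates the two stimulation protocols of a CaV2.1 patch-clamp study in
HEK293-like cells: a 20 ms step I-V protocol from a -80 mV holding potential
and 3 s inactivation pulses to +20 and 0 mV.  Cells are sampled from a
:class:`~cavgate.gating_model.ConditionPreset` (between-cell variability in
peak density, V_half, inactivation degree and tau, plus membrane capacitance),
and each sweep is the deterministic kinetic model

    I(t) = I_ss(V) * (1 - exp(-t / tau_act)) * h(t),
    h(t) = r + (1 - r) * exp(-t / tau_inact),

with the pedestal ``r`` chosen so that ``h(3 s) = 1 - degree/100``, plus
additive white Gaussian recording noise.  Leak and capacitive transients are
not simulated; the first millisecond of every sweep is flagged as a blanking
window so downstream analysis stays robust to importers that do contain them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ProtocolError
from .gating_model import ConditionPreset, GatingParams, InactSpec, iv_current

__all__ = [
    "Protocol",
    "Sweep",
    "CellRecording",
    "IV_20MS",
    "INACT_3S",
    "DEFAULT_BLANK_MS",
    "sample_cell",
    "simulate_sweep",
    "generate_condition_group",
]

#: Initial blanking window (ms) excluded from peak detection.
DEFAULT_BLANK_MS = 1.0

#: Mean membrane capacitance (pF) of a HEK293 cell and its lognormal CV.
CAPACITANCE_MEAN_PF = 12.0
CAPACITANCE_CV = 0.3

#: Sample rate (kHz) at which a preset's ``noise_sd_pA`` is defined.  White
#: recording noise has a fixed spectral density, so traces acquired at a
#: lower rate (anti-alias filtered before decimation, as on a real rig) carry
#: proportionally less per-sample noise: SD scales with sqrt(rate / 20 kHz).
NOISE_REFERENCE_RATE_KHZ = 20.0


def noise_sd_for(protocol: "Protocol", noise_sd_pA: float) -> float:
    """Per-sample noise SD (pA) for a protocol's acquisition bandwidth."""
    return noise_sd_pA * math.sqrt(protocol.sample_rate / NOISE_REFERENCE_RATE_KHZ)


@dataclass(frozen=True)
class Protocol:
    """A voltage-step protocol: holding level, test voltages, timing."""

    name: str
    holding: float  # mV
    test_voltages: tuple[float, ...]
    duration: float  # ms
    sample_rate: float  # kHz

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ProtocolError("duration must be > 0")
        if not self.sample_rate > 0:
            raise ProtocolError("sample_rate must be > 0")
        if not self.test_voltages:
            raise ProtocolError("test_voltages must be non-empty")
        if self.name == "iv_20ms" and not all(
            b > a for a, b in zip(self.test_voltages, self.test_voltages[1:])
        ):
            raise ProtocolError("iv_20ms test voltages must be strictly increasing")

    def time_ms(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate)) + 1
        return np.arange(n) / self.sample_rate


#: 20 ms I-V protocol, -50..+60 mV in 5 mV steps (covers the current maxima
#: at +10/+15 mV and the reversal potential), sampled at 20 kHz.
IV_20MS = Protocol(
    name="iv_20ms",
    holding=-80.0,
    test_voltages=tuple(float(v) for v in range(-50, 65, 5)),
    duration=20.0,
    sample_rate=20.0,
)

#: 3 s inactivation pulses to +20 and 0 mV, sampled at 1 kHz.
INACT_3S = Protocol(
    name="inact_3s",
    holding=-80.0,
    test_voltages=(0.0, 20.0),
    duration=3000.0,
    sample_rate=1.0,
)


@dataclass(frozen=True)
class Sweep:
    """One current trace at one test voltage."""

    test_voltage: float
    time: np.ndarray  # ms, strictly increasing from 0
    current: np.ndarray  # pA
    protocol_name: str

    def __post_init__(self) -> None:
        if len(self.time) != len(self.current):
            raise ProtocolError("time and current arrays must have equal length")
        if len(self.time) == 0 or self.time[0] != 0 or np.any(np.diff(self.time) <= 0):
            raise ProtocolError("time must increase strictly from 0")


@dataclass(frozen=True)
class CellRecording:
    """All sweeps recorded from one simulated cell."""

    cell_id: str
    condition: str
    capacitance: float  # pF
    seed: int
    sweeps: tuple[Sweep, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.capacitance > 0:
            raise ProtocolError("capacitance must be > 0")

    def sweeps_for(self, protocol_name: str) -> list[Sweep]:
        return [s for s in self.sweeps if s.protocol_name == protocol_name]


#: Duration (ms) of the inactivation pulse at which the degree of
#: inactivation is defined (the 3 s test pulse).
DEGREE_REFERENCE_MS = 3000.0


def _pedestal(spec: InactSpec) -> float:
    """Pedestal r of h(t) = r + (1-r) exp(-t/tau) such that h at the 3 s
    reference time equals 1 - degree/100 (degrees are defined at pulse end,
    not at t = infinity, so slow cells still reach their nominal degree)."""
    e = math.exp(-DEGREE_REFERENCE_MS / spec.tau_ms)
    r = (1.0 - spec.degree_pct / 100.0 - e) / (1.0 - e)
    return min(max(r, 0.0), 1.0)


def _peak_gate_factor(gating: GatingParams, v: float, protocol: Protocol) -> float:
    """Maximum over the sweep of the kinetic gate m_kin(t) * h(t) at voltage v."""
    t = protocol.time_ms()[1:]  # t=0 carries no current
    spec = gating.inact_at(v)
    r = _pedestal(spec)
    m_kin = 1.0 - np.exp(-t / gating.tau_act)
    h = r + (1.0 - r) * np.exp(-t / spec.tau_ms)
    return float(np.max(m_kin * h))


def _calibrated_gating(
    preset: ConditionPreset, target_density: float, rng: np.random.Generator
) -> GatingParams:
    """Per-cell gating parameters with g_max set so the analyzed noiseless
    peak density over the I-V protocol equals ``target_density``."""
    var = preset.variability
    v_half = preset.gating.v_half_act + rng.normal(0.0, var.v_half_sd_mV)
    inact = {}
    for v, spec in preset.gating.inact.items():
        degree = float(
            np.clip(spec.degree_pct + rng.normal(0.0, var.degree_sd_pct), 0.0, 100.0)
        )
        tau = spec.tau_ms * _lognormal_factor(rng, var.tau_cv)
        inact[v] = InactSpec(degree_pct=degree, tau_ms=tau)
    gating = replace(preset.gating, g_max_density=1.0, v_half_act=v_half, inact=inact)

    # Noiseless peak density over the I-V protocol at unit conductance.
    densities = [
        float(iv_current(v, gating)) * _peak_gate_factor(gating, v, IV_20MS)
        for v in IV_20MS.test_voltages
    ]
    per_unit = min(densities)  # most negative
    return replace(gating, g_max_density=target_density / per_unit)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def sample_cell(
    preset: ConditionPreset, seed: int
) -> tuple[GatingParams, float]:
    """Draw one cell's gating parameters and capacitance from a preset.

    Deterministic given ``(preset, seed)``.  The peak-density target is
    lognormal on the inward magnitude (mean equal to the preset mean, CV from
    the preset variability, so conductance stays positive and densities
    negative); V_half and inactivation degree are normal; tau and capacitance
    are lognormal.  The cell's maximal conductance is calibrated so that the
    noiseless simulated I-V peak density equals the sampled target.
    """
    rng = np.random.default_rng(seed)
    magnitude = abs(preset.mean_peak_density) * _lognormal_factor(
        rng, preset.variability.peak_density_cv
    )
    gating = _calibrated_gating(preset, -magnitude, rng)
    capacitance = CAPACITANCE_MEAN_PF * _lognormal_factor(rng, CAPACITANCE_CV)
    return gating, capacitance


def simulate_sweep(
    cell: tuple[GatingParams, float],
    protocol: Protocol,
    test_voltage: float,
    noise_seed: int | None = None,
    noise_sd_pA: float = 0.0,
) -> Sweep:
    """Simulate one sweep for ``cell = (gating, capacitance_pF)``.

    Raises :class:`ProtocolError` if ``test_voltage`` is not in the protocol.
    """
    gating, capacitance = cell
    if test_voltage not in protocol.test_voltages:
        raise ProtocolError(
            f"{test_voltage} mV is not a test voltage of protocol {protocol.name}"
        )
    t = protocol.time_ms()
    spec = gating.inact_at(test_voltage)
    r = _pedestal(spec)
    m_kin = 1.0 - np.exp(-t / gating.tau_act)
    h = r + (1.0 - r) * np.exp(-t / spec.tau_ms)
    i_ss_pA = float(iv_current(test_voltage, gating)) * capacitance
    current = i_ss_pA * m_kin * h
    if noise_sd_pA > 0:
        rng = np.random.default_rng(noise_seed)
        current = current + rng.normal(0.0, noise_sd_pA, size=current.shape)
    return Sweep(
        test_voltage=test_voltage,
        time=t,
        current=current,
        protocol_name=protocol.name,
    )


def generate_condition_group(
    preset: ConditionPreset,
    n_cells: int | None = None,
    master_seed: int = 0,
    protocols: Iterable[Protocol] = (IV_20MS, INACT_3S),
    noise: bool = True,
) -> tuple[list[CellRecording], dict]:
    """Simulate a full condition group and a reproducibility manifest.

    Per-cell seeds are spawned deterministically from ``master_seed`` via
    :class:`numpy.random.SeedSequence`, so two runs with the same master seed
    produce byte-identical sweep tables.
    """
    if n_cells is None:
        n_cells = preset.n_cells
    if n_cells < 1:
        raise ProtocolError("n_cells must be >= 1")
    protocols = tuple(protocols)
    master = np.random.SeedSequence(master_seed)
    cell_seqs = master.spawn(n_cells)
    noise_sd = preset.noise_sd_pA if noise else 0.0

    recordings: list[CellRecording] = []
    manifest_cells = []
    for i, seq in enumerate(cell_seqs):
        cell_seed, noise_root = (int(s) for s in seq.generate_state(2) >> 1)
        cell = sample_cell(preset, cell_seed)
        sweeps: list[Sweep] = []
        k = 0
        for protocol in protocols:
            for v in protocol.test_voltages:
                sweeps.append(
                    simulate_sweep(
                        cell, protocol, v,
                        noise_seed=noise_root + k,
                        noise_sd_pA=noise_sd_for(protocol, noise_sd),
                    )
                )
                k += 1
        rec = CellRecording(
            cell_id=f"{preset.name}_{i:03d}",
            condition=preset.name,
            capacitance=cell[1],
            seed=cell_seed,
            sweeps=tuple(sweeps),
        )
        recordings.append(rec)
        manifest_cells.append(
            {"cell_id": rec.cell_id, "seed": cell_seed, "noise_root": noise_root,
             "capacitance_pF": rec.capacitance}
        )
    manifest = {
        "preset": preset.name,
        "master_seed": master_seed,
        "noise_sd_pA": noise_sd,
        "n_cells": n_cells,
        "protocols": [
            {
                "name": p.name,
                "holding_mV": p.holding,
                "test_voltages_mV": list(p.test_voltages),
                "duration_ms": p.duration,
                "sample_rate_kHz": p.sample_rate,
            }
            for p in protocols
        ],
        "cells": manifest_cells,
    }
    return recordings, manifest
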