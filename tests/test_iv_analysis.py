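"""I-V analysis: peak detection, density, normalization, Boltzmann fitting."""

from dataclasses import replace

import numpy as np
import pytest

from cavgate.errors import (
    DegenerateCurveError,
    IncompleteRecordingError,
    InvalidInputError,
)
from cavgate.gating_model import GatingParams, iv_current
from cavgate.iv_analysis import (
    IVCurve,
    build_iv_curve,
    current_density,
    detect_peak_current,
    fit_boltzmann_iv,
    normalize_iv,
    v_half_shift,
    BoltzmannFitResult,
)
from cavgate.synthetic_recordings import (
    IV_20MS,
    CellRecording,
    Sweep,
    generate_condition_group,
    sample_cell,
    simulate_sweep,
)


def _flat_sweep(value, n=100, rate=10.0):
    t = np.arange(n) / rate
    return Sweep(
        test_voltage=0.0, time=t, current=np.full(n, float(value)),
        protocol_name="iv_20ms",
    )


class TestDetectPeakCurrent:
    def test_constant_trace(self):
        assert detect_peak_current(_flat_sweep(-100.0)) == -100.0

    def test_outward_trace_returns_positive_minimum(self):
        t = np.arange(50) / 10.0
        sweep = Sweep(0.0, t, 10.0 + np.arange(50.0), "iv_20ms")
        assert detect_peak_current(sweep) == pytest.approx(10.0 + 10)  # after 1 ms

    def test_blanking_window_excluded(self):
        t = np.arange(50) / 10.0
        current = np.zeros(50)
        current[3] = -500.0  # 0.3 ms: capacitive-transient territory
        current[30] = -100.0
        sweep = Sweep(0.0, t, current, "iv_20ms")
        assert detect_peak_current(sweep, blank_ms=1.0) == -100.0

    def test_matches_forward_model_plateau(self, vehicle):
        cell = sample_cell(vehicle, 8)
        sweep = simulate_sweep(cell, IV_20MS, 15.0)
        assert detect_peak_current(sweep) == pytest.approx(
            float(np.min(sweep.current)), rel=1e-12
        )

    def test_empty_sweep_rejected(self):
        with pytest.raises((InvalidInputError, Exception)):
            detect_peak_current(
                Sweep(0.0, np.array([0.0]), np.array([0.0]), "iv_20ms")
            )


class TestCurrentDensity:
    @pytest.mark.parametrize(
        "peak,cap,expected",
        [(-1498.0, 10.0, -149.8), (0.0, 12.0, 0.0), (-234.0, 12.0, -19.5)],
    )
    def test_arithmetic(self, peak, cap, expected):
        assert current_density(peak, cap) == pytest.approx(expected)

    def test_nonpositive_capacitance_rejected(self):
        with pytest.raises(InvalidInputError):
            current_density(-100.0, 0.0)


class TestBuildIVCurve:
    def test_one_point_per_test_voltage(self, vehicle):
        recs, _ = generate_condition_group(vehicle, n_cells=1, master_seed=0)
        curve = build_iv_curve(recs[0])
        assert len(curve.voltages) == len(IV_20MS.test_voltages) == 23
        assert np.all(np.diff(curve.voltages) > 0)

    def test_noise_free_vehicle_peaks_at_plus15(self, vehicle):
        recs, _ = generate_condition_group(
            vehicle, n_cells=3, master_seed=1, noise=False
        )
        for rec in recs:
            assert build_iv_curve(rec).peak_voltage == 15.0

    def test_noise_free_tun06_peaks_at_plus10(self, presets):
        recs, _ = generate_condition_group(
            presets["tun06"], n_cells=3, master_seed=1, noise=False
        )
        for rec in recs:
            assert build_iv_curve(rec).peak_voltage == 10.0

    def test_missing_sweeps_rejected(self):
        rec = CellRecording(cell_id="x", condition="vehicle", capacitance=10.0, seed=0)
        with pytest.raises(IncompleteRecordingError):
            build_iv_curve(rec)


class TestNormalizeIV:
    def test_peak_maps_to_minus_one_and_zero_stays(self):
        curve = IVCurve(np.array([-10.0, 0.0, 10.0]), np.array([0.0, -149.8, -50.0]))
        norm = normalize_iv(curve)
        assert norm.normalized
        assert norm.densities[1] == -1.0
        assert norm.densities[0] == 0.0

    def test_idempotent(self):
        curve = IVCurve(np.array([0.0, 10.0, 20.0]), np.array([-3.0, -6.0, 2.0]))
        once = normalize_iv(curve)
        twice = normalize_iv(once)
        assert np.array_equal(once.densities, twice.densities)

    def test_all_zero_rejected(self):
        curve = IVCurve(np.array([0.0, 10.0]), np.zeros(2))
        with pytest.raises(DegenerateCurveError):
            normalize_iv(curve)


def _model_curve(g_max=3.7, v_rev=60.0, v_half=5.11, k=4.5):
    gating = GatingParams(
        g_max_density=g_max, v_rev=v_rev, v_half_act=v_half, k_act=k
    )
    v = np.arange(-50.0, 65.0, 5.0)
    return IVCurve(v, np.asarray(iv_current(v, gating))), gating


def _grid_oracle_rss(curve, v_half_grid, k_grid):
    """Brute force: for each (v_half, k) on the lattice solve g, v_rev by
    linear least squares of I = a*(V m) - b*m with a=g, b=g*v_rev."""
    v, d = curve.voltages, curve.densities
    best = np.inf
    for v_half in v_half_grid:
        for k in k_grid:
            m = 1.0 / (1.0 + np.exp(-(v - v_half) / k))
            design = np.column_stack([v * m, -m])
            coef, *_ = np.linalg.lstsq(design, d, rcond=None)
            rss = float(np.sum((design @ coef - d) ** 2))
            best = min(best, rss)
    return best


class TestFitBoltzmann:
    @pytest.mark.parametrize(
        "truth",
        [
            dict(g_max=3.7, v_rev=60.0, v_half=5.11, k=4.5),
            dict(g_max=0.8, v_rev=55.0, v_half=0.11, k=4.5),
            dict(g_max=2.0, v_rev=65.0, v_half=-5.0, k=6.0),
        ],
    )
    def test_exact_recovery_on_noiseless_curves(self, truth):
        curve, _ = _model_curve(**truth)
        fit = fit_boltzmann_iv(curve)
        assert fit.converged
        assert fit.v_half == pytest.approx(truth["v_half"], abs=1e-4)
        assert fit.k == pytest.approx(truth["k"], abs=1e-4)
        assert fit.v_rev == pytest.approx(truth["v_rev"], abs=1e-4)
        assert fit.g_max == pytest.approx(truth["g_max"], rel=1e-4)

    def test_scale_invariance(self):
        curve, _ = _model_curve()
        rng = np.random.default_rng(0)
        noisy = replace(curve, densities=curve.densities + rng.normal(0, 0.5, 23))
        fit1 = fit_boltzmann_iv(noisy)
        fit2 = fit_boltzmann_iv(replace(noisy, densities=noisy.densities * 7.5))
        assert fit2.v_half == pytest.approx(fit1.v_half, abs=1e-6)
        assert fit2.k == pytest.approx(fit1.k, abs=1e-6)
        assert fit2.v_rev == pytest.approx(fit1.v_rev, abs=1e-6)
        assert fit2.g_max == pytest.approx(7.5 * fit1.g_max, rel=1e-6)

    def test_normalized_and_raw_fits_agree(self):
        curve, _ = _model_curve()
        rng = np.random.default_rng(3)
        noisy = replace(curve, densities=curve.densities + rng.normal(0, 1.0, 23))
        raw = fit_boltzmann_iv(noisy)
        norm = fit_boltzmann_iv(normalize_iv(noisy))
        assert norm.v_half == pytest.approx(raw.v_half, abs=1e-6)
        assert norm.k == pytest.approx(raw.k, abs=1e-6)

    def test_optimizer_beats_grid_oracle(self):
        """Optimizer RSS <= brute-force lattice RSS + 1% on 5 noisy curves."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            curve, _ = _model_curve()
            noisy = replace(
                curve, densities=curve.densities + rng.normal(0, 2.0, 23)
            )
            fit = fit_boltzmann_iv(noisy)
            oracle = _grid_oracle_rss(
                noisy,
                np.arange(3.0, 7.0, 0.05),
                np.arange(3.5, 5.5, 0.05),
            )
            assert fit.rss <= oracle * 1.01 + 1e-12

    def test_too_few_points_rejected(self):
        curve = IVCurve(np.arange(5.0), -np.arange(5.0) - 1)
        with pytest.raises(InvalidInputError):
            fit_boltzmann_iv(curve)

    def test_vhalf_recovery_bias_small(self, vehicle):
        """Bias of group-mean V_half over 200 simulated cells < 0.3 mV."""
        recs, _ = generate_condition_group(vehicle, n_cells=200, master_seed=9)
        fits = [fit_boltzmann_iv(build_iv_curve(r)) for r in recs]
        mean_vhalf = np.mean([f.v_half for f in fits if f.converged])
        assert abs(mean_vhalf - vehicle.gating.v_half_act) < 0.3


class TestVHalfShift:
    def _fits(self, values):
        return [
            BoltzmannFitResult(1.0, 60.0, v, 4.5, 0.0, True) for v in values
        ]

    def test_identical_groups_zero_shift(self):
        fits = self._fits([5.0, 6.0, 4.0])
        assert v_half_shift(fits, fits)["shift_mV"] == 0.0

    def test_direction_and_exclusions(self):
        a = self._fits([5.0, 5.0])
        b = self._fits([0.0, 0.0]) + [
            BoltzmannFitResult(1.0, 60.0, 99.0, 4.5, 0.0, False)
        ]
        out = v_half_shift(a, b)
        assert out["shift_mV"] == pytest.approx(-5.0)
        assert out["groups"]["b"]["n_excluded"] == 1

    def test_all_nonconverged_rejected(self):
        bad = [BoltzmannFitResult(1.0, 60.0, 0.0, 4.5, 0.0, False)]
        with pytest.raises(InvalidInputError):
            v_half_shift(bad, self._fits([1.0]))
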