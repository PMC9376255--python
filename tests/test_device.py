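import math

import numpy as np
import pytest

from counterpulse.device import (
    BENCH_P_ACT,
    BENCH_P_AORTA,
    DEFAULT_GAIN_COEFFS,
    BenchGrid,
    DeviceError,
    DeviceParams,
    calibrate_correction,
    device_flow_contribution,
    fit_gain_surface,
    gain,
    normalize_time,
    relaxation_constants,
    source_pressure,
    synth_bench_data,
    timing_lookup,
)


class TestNormalizeTime:
    @pytest.mark.parametrize("t,dt_act,hr,expected", [
        (0.65, 0.65, 60.0, 0.0),
        (5.70, 0.65, 60.0, 0.05),
        (0.30, 0.65, 60.0, 0.65),  # wrap before the first actuation
    ])
    def test_printed_formula(self, t, dt_act, hr, expected):
        assert normalize_time(t, dt_act, hr) == pytest.approx(expected)

    def test_range(self):
        for t in np.linspace(-3, 7, 101):
            tn = normalize_time(float(t), 0.42, 75.0)
            assert 0 <= tn < 60.0 / 75.0


class TestGainSurface:
    def test_zero_and_constant(self):
        assert gain(100, 10, (0, 0, 0, 0, 0)) == 0.0
        assert gain(123, 7, (0, 0, 0, 0.5, 0)) == 0.5

    def test_hand_value(self):
        assert gain(100, 10, (0, -0.001, 0.05, 0.5, 0)) == pytest.approx(0.9)

    def test_fit_round_trip(self):
        grid = synth_bench_data(seed=3, noise_sd=0.0)
        coeffs, rmse = fit_gain_surface(grid)
        assert np.allclose(coeffs, DEFAULT_GAIN_COEFFS, atol=1e-8)
        assert rmse < 1e-10

    def test_fit_idempotent(self):
        grid = synth_bench_data(seed=0, noise_sd=0.02)
        c1, _ = fit_gain_surface(grid)
        refit_grid = BenchGrid(
            p_aorta=grid.p_aorta, p_act=grid.p_act,
            g_exp=np.array([gain(a, c, c1) for a, c in zip(grid.p_aorta, grid.p_act)]),
            t_on=grid.t_on, t_off=grid.t_off)
        c2, rmse = fit_gain_surface(refit_grid)
        assert np.allclose(c1, c2, atol=1e-10)
        assert rmse < 1e-12

    def test_constant_grid_recovers_offset(self):
        grid = synth_bench_data(seed=0)
        grid = BenchGrid(grid.p_aorta, grid.p_act,
                         np.full(len(grid), 0.4), grid.t_on, grid.t_off)
        coeffs, _ = fit_gain_surface(grid)
        assert coeffs[3] == pytest.approx(0.4, abs=1e-8)
        assert np.allclose([coeffs[0], coeffs[1], coeffs[2], coeffs[4]], 0, atol=1e-8)

    def test_degenerate_designs_rejected(self):
        small = BenchGrid(np.array([50., 60., 70., 80.]), np.array([6., 6., 6., 6.]),
                          np.full(4, 0.3), np.full(4, 0.3), np.full(4, 0.5))
        with pytest.raises(DeviceError):
            fit_gain_surface(small)
        one_pa = BenchGrid(np.full(7, 100.0), np.array(BENCH_P_ACT),
                           np.linspace(0.2, 0.5, 7), np.full(7, 0.3), np.full(7, 0.5))
        with pytest.raises(DeviceError):
            fit_gain_surface(one_pa)


class TestSourcePressure:
    def test_zero_gain_silences_source(self):
        dev = DeviceParams(gain_coeffs=(0, 0, 0, 0, 0))
        for tn in np.linspace(0, 1, 50):
            assert source_pressure(float(tn), 100.0, dev) == 0.0

    def test_continuity_hand_example(self):
        # g = 0.3, p_aorta = 100, k1 = 13.04, t_on = 0.3, k2 = 34.66, t_off = 0.5
        dev = DeviceParams(gain_coeffs=(0, 0, 0, 0.3, 0), t_on=0.3, t_off=0.5)
        p_on = source_pressure(0.3, 100.0, dev)
        assert p_on == pytest.approx(30 * (1 - math.exp(-3.912)), rel=1e-4)
        assert p_on == pytest.approx(29.40, abs=0.01)
        c, d = relaxation_constants(p_on, dev.k2, 0.3, 0.5)
        assert c == pytest.approx(29.43, abs=0.01)
        assert d == pytest.approx(-0.0288, abs=0.001)

    def test_continuity_for_random_parameter_sets(self):
        """p_sr is continuous at t_on and zero at t_off to 1e-9 mmHg for 100
        random admissible parameter sets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            t_on = rng.uniform(0.1, 0.5)
            dev = DeviceParams(
                p_act=rng.uniform(6, 12),
                t_on=t_on, t_off=t_on + rng.uniform(0.05, 0.5),
                k1=rng.uniform(5, 30), k2=rng.uniform(10, 60),
                gain_coeffs=(0, 0, rng.uniform(0.01, 0.05), rng.uniform(0, 0.4), 0))
            pa = rng.uniform(50, 150)
            left = source_pressure(dev.t_on, pa, dev)  # contraction branch
            c, d = relaxation_constants(left, dev.k2, dev.t_on, dev.t_off)
            assert abs(left - (c + d)) < 1e-9  # relaxation limit at t_on
            assert abs(source_pressure(dev.t_off, pa, dev)) < 1e-9
            assert source_pressure(dev.t_off + 1e-9, pa, dev) == 0.0

    def test_invalid_windows_rejected(self):
        with pytest.raises(DeviceError):
            DeviceParams(t_on=0.5, t_off=0.3)


class TestDeviceCoupling:
    def test_equilibrium_passes_no_flow(self):
        dev = DeviceParams()
        x_eq = dev.C_sr * (100.0 - dev.correction * 20.0)
        q, dxdt = device_flow_contribution(100.0, 20.0, x_eq, dev)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert dxdt == pytest.approx(0.0, abs=1e-12)

    def test_ramp_injection_rate(self):
        """Ramping the scaled source at +100 mmHg/s with C_sr = 0.05 mL/mmHg
        injects +5 mL/s once the fast coupling transient has passed."""
        dev = DeviceParams(correction=1.0, C_sr=0.05, R_sr=0.01)
        p_node, dt = 90.0, 1e-5
        x = dev.C_sr * p_node  # rest state at p_sr = 0
        q = 0.0
        for k in range(30000):
            p_sr = 100.0 * k * dt
            q, dxdt = device_flow_contribution(p_node, p_sr, x, dev)
            x += dt * dxdt
        assert q == pytest.approx(5.0, rel=0.01)


class TestTimingLookup:
    def test_exact_grid_point(self, bench_grid):
        i = 10
        t_on, t_off = timing_lookup(bench_grid.p_act[i], bench_grid.p_aorta[i], bench_grid)
        assert t_on == pytest.approx(bench_grid.t_on[i])
        assert t_off == pytest.approx(bench_grid.t_off[i])

    def test_interpolation_between_neighbors(self, bench_grid):
        lo, _ = timing_lookup(8.0, 100.0, bench_grid)
        hi, _ = timing_lookup(9.0, 100.0, bench_grid)
        mid, _ = timing_lookup(8.5, 100.0, bench_grid)
        assert min(lo, hi) <= mid <= max(lo, hi)

    def test_clamped_outside_grid(self, bench_grid):
        inside = timing_lookup(12.0, 150.0, bench_grid)
        assert timing_lookup(20.0, 300.0, bench_grid) == inside

    def test_empty_grid_rejected(self):
        empty = BenchGrid(*[np.array([])] * 5)
        with pytest.raises(DeviceError):
            timing_lookup(8.0, 100.0, empty)


class TestSyntheticBench:
    def test_deterministic_for_seed(self):
        a = synth_bench_data(seed=7, noise_sd=0.05)
        b = synth_bench_data(seed=7, noise_sd=0.05)
        assert np.array_equal(a.g_exp, b.g_exp)

    def test_protocol_grid(self, bench_grid):
        assert len(bench_grid) == len(BENCH_P_AORTA) * len(BENCH_P_ACT)
        assert set(np.unique(bench_grid.p_aorta)) == set(BENCH_P_AORTA)
        assert set(np.unique(bench_grid.p_act)) == set(BENCH_P_ACT)

    def test_monotonicity_invariants(self, bench_grid):
        df = bench_grid.to_frame()
        for pa, sub in df.groupby("p_aorta_mmHg"):
            g = sub.sort_values("p_act_psi")["g_exp"].to_numpy()
            assert np.all(np.diff(g) > 0)  # increasing in p_act
        for pc, sub in df.groupby("p_act_psi"):
            g = sub.sort_values("p_aorta_mmHg")["g_exp"].to_numpy()
            assert np.all(np.diff(g) < 0)  # decreasing in p_aorta

    def test_gains_in_unit_interval(self, bench_grid):
        assert np.all(bench_grid.g_exp > 0)
        assert np.all(bench_grid.g_exp < 1)

    def test_csv_round_trip(self, bench_grid, tmp_path):
        path = tmp_path / "bench.csv"
        bench_grid.to_csv(path)
        back = BenchGrid.from_csv(path)
        assert np.allclose(back.g_exp, bench_grid.g_exp)


class TestCorrectionFactor:
    def test_linear_scaling(self):
        model = lambda lam: 2.5 * lam  # capacitive coupling is linear in lambda
        assert calibrate_correction(2.5, model) == pytest.approx(1.0, rel=0.01)
        assert calibrate_correction(5.0, model) == pytest.approx(2.0, rel=0.01)

    def test_zero_target(self):
        assert calibrate_correction(0.0, lambda lam: 2.5 * lam) == 0.0

    def test_unbracketed_root_rejected(self):
        with pytest.raises(DeviceError):
            calibrate_correction(1e9, lambda lam: 2.5 * lam, lam_bracket=(0, 10))
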