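import numpy as np
import pytest

from counterpulse.chambers import ChamberParams
from counterpulse.network import build_network
from counterpulse.simulator import (
    CardiovascularModel,
    NotPeriodicError,
    SimulationError,
    SystemState,
    Trajectory,
    detect_periodicity,
    literature_initial_state,
)


def _total_volume(model, traj):
    vol = traj.column("V_LA") + traj.column("V_LV") + traj.column("x_dev")
    pcs = np.stack([traj.column(f"p_cap_{n}") for n in model.terminal_order])
    return vol + model._Cc @ pcs


class TestAssembly:
    def test_equilibrium_has_zero_derivatives(self):
        """With both valves shut, zero transvalvular flow, equal chamber and
        capacitor pressures, and no activation, every derivative vanishes."""
        net = build_network()
        # flat chambers: activation window placed away from t = 0
        lv = ChamberParams(E_act_max=1.0, V0=10.0, A_pas=0.5, B_pas=0.02,
                           t_onset=0.5, t_sys=0.1, label="LV")
        la = ChamberParams(E_act_max=1.0, V0=10.0, A_pas=0.5, B_pas=0.02,
                           t_onset=0.5, t_sys=0.1, label="LA")
        model = CardiovascularModel(net, lv=lv, la=la)
        v_star = 10.0 + np.log(1 + 40.0 / 0.5) / 0.02  # passive pressure = 40
        state = SystemState(V_LA=v_star, V_LV=v_star, s_MV=0.0, s_AV=0.0,
                            terminal_pressures={n: 40.0 for n in model.terminal_order})
        dy, aux = model.derivative(state, t=0.0)
        assert np.allclose(dy, 0.0, atol=1e-9)
        assert aux["Q_ven"] == pytest.approx(0.0, abs=1e-9)

    def test_arch_junction_flow_balance(self, calibrated):
        """Kirchhoff at the arch: flow through the trunk equals the sum of the
        downstream branch and terminal flows at every evaluation."""
        model, _, state = calibrated
        _, aux = model.derivative(state, t=0.25)
        downstream = sum(aux[f"q_{n}"] for n in model.terminal_order
                         if n != "coronaries")
        assert aux["Q_AV"] + aux["q_device"] - aux["q_coronaries"] == \
            pytest.approx(downstream, abs=1e-8)


class TestIntegration:
    def test_volume_conservation_over_ten_cycles(self, calibrated, baseline_traj):
        model, _, _ = calibrated
        tot = _total_volume(model, baseline_traj)
        assert (tot.max() - tot.min()) / tot.mean() < 1e-3

    def test_prefix_determinism(self, calibrated):
        model, _, state = calibrated
        t1 = model.integrate(state, n_cycles=1)
        t3 = model.integrate(state, n_cycles=3)
        n = t1.data.shape[0]
        assert np.array_equal(t1.data, t3.data[:n])

    def test_step_refinement(self, calibrated):
        from counterpulse.metrics import summarize

        model, _, state = calibrated
        a = summarize(model.integrate(state, dt=1e-4, n_cycles=2))
        b = summarize(model.integrate(state, dt=5e-5, n_cycles=2))
        for attr in ("co", "peak_systolic", "edv"):
            assert abs(getattr(a, attr) - getattr(b, attr)) / getattr(a, attr) < 5e-3

    def test_divergence_reported_with_time(self, calibrated):
        model, _, state = calibrated
        bad = model.with_device(None)
        bad = CardiovascularModel(bad.network, lv=bad.lv, la=bad.la,
                                  mv=bad.mv, av=bad.av, hr=60.0, R_ven=1e-9)
        for term in bad.network.terminals.values():
            term.C = 1e-9
        bad._build_linear_maps()
        with pytest.raises(SimulationError, match="t ="):
            bad.integrate(state, dt=1e-2, n_cycles=1)

    def test_invalid_arguments(self, calibrated):
        model, _, state = calibrated
        with pytest.raises(ValueError):
            model.integrate(state, dt=-1.0)
        with pytest.raises(ValueError):
            model.integrate(state, n_cycles=0)


class TestOffDeviceEquivalence:
    def test_zero_actuation_is_bitwise_baseline(self, calibrated):
        from counterpulse.device import DeviceParams

        model, _, state = calibrated
        off = model.with_device(DeviceParams(p_act=0.0))
        a = model.integrate(state, n_cycles=2)
        b = off.integrate(state, n_cycles=2)
        assert np.array_equal(a.data, b.data)

    def test_zero_gain_surface_is_bitwise_baseline(self, calibrated):
        from counterpulse.device import DeviceParams

        model, _, state = calibrated
        off = model.with_device(DeviceParams(p_act=12.0, gain_coeffs=(0, 0, 0, 0, 0)))
        a = model.integrate(state, n_cycles=1)
        b = off.integrate(state, n_cycles=1)
        assert np.array_equal(a.data, b.data)


class TestInitialConditions:
    def test_fixed_point_returned_unchanged(self, calibrated):
        model, _, state = calibrated
        refined = model.estimate_initial_conditions(guess=state, tol=1e-4, max_iter=20)
        a = state.to_vector(model.terminal_order)
        b = refined.to_vector(model.terminal_order)
        assert np.allclose(a, b, rtol=5e-3, atol=1e-3)

    def test_literature_guess_converges_within_five_cycles(self, calibrated):
        model, _, _ = calibrated
        spc = int(round(model.T / 1e-4))
        guess = literature_initial_state()
        state = guess
        for k in range(1, 6):
            traj = model.integrate(state, n_cycles=1, rec_stride=spc)
            end = traj.end_state()
            a = state.to_vector(model.terminal_order)
            b = end.to_vector(model.terminal_order)
            scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1.0)
            mismatch = float(np.mean(((b - a) / scale) ** 2))
            end.t = 0.0
            state = end
            if mismatch < 1e-4:
                break
        assert k <= 5 and mismatch < 1e-4

    def test_nonconvergence_warns(self, calibrated):
        model, _, _ = calibrated
        far = SystemState(V_LA=400.0, V_LV=400.0,
                          terminal_pressures={n: 200.0 for n in model.terminal_order})
        with pytest.warns(UserWarning, match="did not converge"):
            model.estimate_initial_conditions(guess=far, tol=1e-14, max_iter=2)


class TestPeriodicityDetector:
    def test_calibrated_model_is_periodic_early(self, baseline_traj):
        assert detect_periodicity(baseline_traj) <= 5

    def test_exactly_repeating_trajectory(self, baseline_traj):
        spc = baseline_traj.samples_per_cycle
        one = baseline_traj.data[:spc]
        data = np.vstack([one, one, baseline_traj.data[2 * spc:2 * spc + 1]])
        repeated = Trajectory(data[:2 * spc + 1], baseline_traj.dt, baseline_traj.T,
                              baseline_traj.rec_stride, baseline_traj.terminal_order)
        assert detect_periodicity(repeated) == 1

    def test_drifting_trajectory_raises(self, baseline_traj):
        drift = baseline_traj.data[:2 * baseline_traj.samples_per_cycle + 1].copy()
        drift[:, 1] = np.linspace(50, 150, drift.shape[0])  # monotone V_LA ramp
        traj = Trajectory(drift, baseline_traj.dt, baseline_traj.T,
                          baseline_traj.rec_stride, baseline_traj.terminal_order)
        with pytest.raises(NotPeriodicError):
            detect_periodicity(traj)

    def test_requires_two_cycles(self, calibrated):
        model, _, state = calibrated
        short = model.integrate(state, n_cycles=1)
        with pytest.raises(ValueError):
            detect_periodicity(short)


def test_trajectory_io_round_trip(calibrated, tmp_path):
    model, _, state = calibrated
    traj = model.integrate(state, n_cycles=1, rec_stride=100)
    csv, meta = tmp_path / "t.csv", tmp_path / "t.json"
    traj.to_csv(csv, meta_path=meta)
    import json

    import pandas as pd

    df = pd.read_csv(csv)
    assert list(df.columns) == traj.columns
    assert json.loads(meta.read_text())["cycle_s"] == pytest.approx(model.T)
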