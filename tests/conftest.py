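import numpy as np
import pytest

from counterpulse.calibration import PatientTargets, calibrate
from counterpulse.device import (
    BENCH_PEAK_DISPLACEMENT_ML,
    DeviceParams,
    calibrate_correction,
    synth_bench_data,
    timing_lookup,
)


@pytest.fixture(scope="session")
def calibrated():
    """Model calibrated to the study patient's target table (deterministic)."""
    model, report, state = calibrate(PatientTargets.default_patient(), seed=0)
    return model, report, state


@pytest.fixture(scope="session")
def baseline_traj(calibrated):
    model, _, state = calibrated
    return model.integrate(state, dt=1e-4, n_cycles=10)


@pytest.fixture(scope="session")
def bench_grid():
    return synth_bench_data(seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def device_factory(calibrated, bench_grid):
    """Experiment-ready device blocks with the bench-calibrated correction."""
    model, _, state = calibrated
    t_on, t_off = timing_lookup(12.0, 100.0, bench_grid)

    def displacement(lam):
        dev = DeviceParams(p_act=12.0, dt_act=0.65, t_on=t_on, t_off=t_off,
                           correction=lam)
        m = model.with_device(dev)
        st = m.estimate_initial_conditions(guess=state, max_iter=8)
        traj = m.integrate(st, n_cycles=1)
        x = traj.column("x_dev")
        return float(x.max() - x.min())

    lam = calibrate_correction(BENCH_PEAK_DISPLACEMENT_ML, displacement)

    def make(p_act=12.0, delay_ms=650.0):
        on, off = timing_lookup(p_act, 100.0, bench_grid)
        return DeviceParams(p_act=p_act, dt_act=delay_ms / 1000.0,
                            t_on=on, t_off=off, correction=lam)

    make.correction = lam
    return make
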