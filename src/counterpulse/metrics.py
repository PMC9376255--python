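"""Hemodynamic metrics, waveform comparison and actuation sweep experiments.

Definitions used throughout:

* cardiac output — mean aortic-root flow over the cycle, converted to L/min;
* end-diastole — the LV activation onset (R-wave, the cycle origin), so EDV
  and EDP are the LV volume and pressure at the cycle boundary;
* end-systolic volume — the cycle minimum of LV volume;
* stroke work — the area of the LV pressure-volume loop, -∮P dV over the
  time-ordered cycle (positive for an ejecting loop), reported in mmHg·mL
  and joules;
* arterial elastance EA — end-systolic pressure divided by cardiac output,
  where ESP is the LV pressure at aortic-valve closure (opening state first
  below 0.05 after ejection); units mmHg/(mL/s) when CO is taken per second;
* branch measurements — flow and pressure at the junction between the last
  vessel sub-resistor of a branch and its terminal's proximal resistor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .network import OUTLET_NAMES

__all__ = [
    "HemodynamicSummary",
    "SweepResult",
    "summarize",
    "waveform_rmse",
    "delay_sweep",
    "pressure_sweep",
    "report",
    "diastolic_peak_count",
    "MMHG_ML_TO_J",
]

#: 1 mmHg·mL in joules
MMHG_ML_TO_J = 1.33322e-4

UPPER_BODY = ("right_subclavian", "right_carotid", "left_carotid",
              "left_subclavian", "coronaries")


@dataclass
class HemodynamicSummary:
    co: float  # L/min
    peak_systolic: float  # mmHg
    diastolic: float  # mmHg
    peak_flow: float  # mL/s
    edv: float  # mL
    esv: float  # mL
    edp: float  # mmHg
    stroke_work: float  # mmHg·mL
    stroke_work_J: float  # J
    ea: float  # mmHg per (mL/s)
    mean_lap: float  # mmHg
    coronary_flow: float  # L/min
    branch_splits: dict = field(default_factory=dict)  # % per branch

    def as_dict(self):
        d = {k: v for k, v in self.__dict__.items() if k != "branch_splits"}
        d.update({f"split_{k}_pct": v for k, v in self.branch_splits.items()})
        return d

    @property
    def upper_split(self):
        """Upper-body flow fraction (all branches except the descending aorta), %."""
        return sum(self.branch_splits[b] for b in UPPER_BODY)


def summarize(traj, cycle=-1):
    """Hemodynamic summary of one complete cycle of a trajectory."""
    n_cyc = traj.n_cycles
    if n_cyc < 1:
        raise ValueError("trajectory contains no complete cycle")
    if cycle < 0:
        cycle = n_cyc + cycle
    rows = traj.cycle(cycle)
    cols = traj.columns

    def c(name):
        return rows[:, cols.index(name)]

    t = c("time_s")
    q_av = c("Q_AV")
    p_root = c("p_root")
    v_lv = c("V_LV")
    p_lv = c("P_LV")

    # means over the cycle by trapezoid (endpoints are both boundaries)
    span = t[-1] - t[0]
    mean = lambda x: float(np.trapezoid(x, t) / span)

    co_mls = mean(q_av)
    edv = float(v_lv[0])
    edp = float(p_lv[0])
    esv = float(v_lv.min())
    sw = -float(np.trapezoid(p_lv, v_lv))

    # ESP: LV pressure when the aortic valve state first falls below 0.05
    # after its ejection maximum
    s_av = c("s_AV")
    i_peak = int(np.argmax(s_av))
    after = np.nonzero(s_av[i_peak:] < 0.05)[0]
    i_esp = i_peak + int(after[0]) if after.size else int(np.argmin(s_av[i_peak:]) + i_peak)
    esp = float(p_lv[i_esp])

    branch_means = {name: mean(c(f"q_{name}")) for name in traj.terminal_order}
    total = sum(branch_means.values())
    splits = {name: 100.0 * v / total for name, v in branch_means.items()}

    return HemodynamicSummary(
        co=co_mls * 0.06,
        peak_systolic=float(p_root.max()),
        diastolic=float(p_root.min()),
        peak_flow=float(q_av.max()),
        edv=edv, esv=esv, edp=edp,
        stroke_work=sw, stroke_work_J=sw * MMHG_ML_TO_J,
        ea=esp / co_mls if co_mls else np.nan,
        mean_lap=mean(c("P_LA")),
        coronary_flow=branch_means["coronaries"] * 0.06,
        branch_splits=splits,
    )


def waveform_rmse(model_time, model_flow, ref_time, ref_flow):
    """Root-mean-square error (mL/s) between two flow waveforms over one cycle.

    The reference is resampled to the model timing by linear interpolation;
    the time supports must overlap.
    """
    model_time = np.asarray(model_time, float)
    ref_time = np.asarray(ref_time, float)
    if model_time[0] > ref_time[-1] or model_time[-1] < ref_time[0]:
        raise ValueError("non-overlapping time supports")
    ref = np.interp(model_time, ref_time, ref_flow)
    return float(np.sqrt(np.mean((np.asarray(model_flow, float) - ref) ** 2)))


def diastolic_peak_count(traj, branch=None, cycle=-1, prominence=2.0):
    """Number of local pressure maxima within a cycle for one branch.

    Counterpulsation timed in diastole adds a second peak to every branch's
    pressure waveform; baseline shows a single (systolic) peak.  ``branch``
    of ``None`` uses the aortic root.
    """
    rows = traj.cycle(traj.n_cycles + cycle if cycle < 0 else cycle)
    name = "p_root" if branch is None else f"p_{branch}"
    p = rows[:, traj.columns.index(name)]
    peaks, _ = find_peaks(p, prominence=prominence)
    return int(len(peaks))


@dataclass
class SweepResult:
    axis_name: str  # "delay_ms" or "p_act_psi"
    axis_values: list
    summaries: list  # one HemodynamicSummary per axis point
    baseline: HemodynamicSummary
    failures: dict = field(default_factory=dict)  # axis value -> error message

    def frame(self):
        rows = [{self.axis_name: "baseline", **self.baseline.as_dict()}]
        for v, s in zip(self.axis_values, self.summaries):
            if s is None:
                rows.append({self.axis_name: v})
            else:
                rows.append({self.axis_name: v, **s.as_dict()})
        return pd.DataFrame(rows)

    def metric(self, name):
        return np.array([getattr(s, name) if s is not None else np.nan
                         for s in self.summaries])


def _run_point(model, device, settle_cycles, measure_cycles, dt, state0):
    m = model.with_device(device)
    state = m.estimate_initial_conditions(guess=state0, dt=dt, max_iter=settle_cycles)
    traj = m.integrate(state, dt=dt, n_cycles=measure_cycles)
    return traj


def delay_sweep(model, delays_ms=tuple(range(50, 1000, 50)), p_act=12.0,
                device=None, dt=1e-4, settle_cycles=8, measure_cycles=2, state0=None):
    """Sweep the actuation delay at a fixed actuation pressure.

    Returns one periodic-steady-state summary per delay plus the actuator-off
    baseline.  Points whose integration diverges are flagged and skipped.
    """
    from .device import DeviceParams

    base_dev = device or DeviceParams(p_act=p_act)
    if state0 is None:
        state0 = model.with_device(None).estimate_initial_conditions(dt=dt)
    base_traj = _run_point(model, None, settle_cycles, measure_cycles, dt, state0)
    baseline = summarize(base_traj)
    summaries, failures = [], {}
    for d_ms in delays_ms:
        from dataclasses import replace
        dev = replace(base_dev, p_act=p_act, dt_act=d_ms / 1000.0)
        try:
            traj = _run_point(model, dev, settle_cycles, measure_cycles, dt, state0)
            summaries.append(summarize(traj))
        except Exception as exc:  # divergence at one point must not kill the sweep
            summaries.append(None)
            failures[d_ms] = str(exc)
    return SweepResult("delay_ms", list(delays_ms), summaries, baseline, failures)


def pressure_sweep(model, p_acts=(6.0, 8.0, 10.0, 12.0), delay_ms=650.0,
                   device=None, dt=1e-4, settle_cycles=8, measure_cycles=2, state0=None):
    """Sweep the actuation pressure at a fixed (diastolic) delay."""
    from .device import DeviceParams
    from dataclasses import replace

    base_dev = device or DeviceParams()
    if state0 is None:
        state0 = model.with_device(None).estimate_initial_conditions(dt=dt)
    base_traj = _run_point(model, None, settle_cycles, measure_cycles, dt, state0)
    baseline = summarize(base_traj)
    summaries, failures = [], {}
    for p in p_acts:
        dev = replace(base_dev, p_act=p, dt_act=delay_ms / 1000.0)
        try:
            traj = _run_point(model, dev, settle_cycles, measure_cycles, dt, state0)
            summaries.append(summarize(traj))
        except Exception as exc:
            summaries.append(None)
            failures[p] = str(exc)
    return SweepResult("p_act_psi", list(p_acts), summaries, baseline, failures)


def report(sweep: SweepResult, out_dir, plots=False):
    """Write sweep tables (and optional plots) to a directory.

    Produces ``sweep.csv`` (one row per point, baseline first) and
    ``splits.csv`` (branch flow-split percentages per point).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = sweep.frame()
    frame.to_csv(out / "sweep.csv", index=False)

    rows = []
    labels = ["baseline"] + list(sweep.axis_values)
    for label, s in zip(labels, [sweep.baseline] + sweep.summaries):
        if s is None:
            continue
        rows.append({sweep.axis_name: label, "co_L_min": s.co, **{
            f"{b}_pct": s.branch_splits[b] for b in OUTLET_NAMES}})
    pd.DataFrame(rows).to_csv(out / "splits.csv", index=False)

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        metrics = ["peak_systolic", "co", "stroke_work", "ea", "coronary_flow", "mean_lap"]
        fig, axes = plt.subplots(2, 3, figsize=(12, 6))
        for ax, mname in zip(axes.ravel(), metrics):
            ax.plot(sweep.axis_values, sweep.metric(mname), "o-")
            ax.axhline(getattr(sweep.baseline, mname), color="k", ls="--", lw=0.8)
            ax.set_xlabel(sweep.axis_name)
            ax.set_title(mname)
        fig.tight_layout()
        fig.savefig(out / "sweep.png", dpi=120)
        plt.close(fig)
    return frame
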