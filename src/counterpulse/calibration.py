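"""Staged patient-specific calibration of the closed-loop model.

The tuning order follows the physiology of the quantities involved, each
stage owning the knob that dominates its target:

1. total resistance   — total arterial resistance set Ohmically from
                        MAP/CO (MAP estimated as DBP + pulse/3), then the
                        total stressed blood volume trimmed until cardiac
                        output matches;
2. flow splits        — per-branch distal resistances set from the requested
                        mean-flow fractions at preserved total resistance;
3. compliance         — uniform scaling of the terminal capacitances until
                        the aortic-root pulse pressure matches;
4. heart              — the LV passive curve pinned so that the passive
                        pressure at the target EDV equals the target EDP,
                        then peak active elastance and systolic duration
                        tuned for ESV and peak aortic flow.

Outer refinement loops repeat damped multiplicative updates of all knobs
simultaneously (the couplings are weak in this order) and re-pin the passive
curve at the *measured* EDV so the realized end-diastolic pressure meets the
target.  All updates are deterministic.

Printed patient tables can be mutually inconsistent (a cuff/CMR cardiac
output need not equal HR·(EDV − ESV)); ``reconcile_volume_targets`` resolves
EDV/ESV/stroke-volume into feasible internal setpoints by a minimax program
over per-quantity fidelity tolerances.  For self-consistent targets it is
the identity, so parameter-recovery round trips are unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .chambers import ChamberParams, passive_pressure
from .metrics import UPPER_BODY, summarize
from .network import OUTLET_NAMES, build_network
from .simulator import CardiovascularModel, SystemState, default_heart, literature_initial_state
from .valves import ValveParams, blood_inertance

__all__ = [
    "PatientTargets",
    "CalibrationReport",
    "CalibrationError",
    "Calibrator",
    "calibrate",
    "reconcile_volume_targets",
    "DEFAULT_BRANCH_FRACTIONS",
    "mean_arterial_pressure",
]


class CalibrationError(RuntimeError):
    """A stage failed or the error envelope was not met."""


#: default per-branch mean-flow fractions (%), in line with in-vivo splits
DEFAULT_BRANCH_FRACTIONS = {
    "descending_aorta": 70.27,
    "coronaries": 3.00,
    "right_subclavian": 7.45,
    "right_carotid": 9.18,
    "left_subclavian": 5.25,
    "left_carotid": 4.86,
}

#: relative-error envelope the calibrated model must satisfy
ENVELOPE = {
    "hr": 0.05, "sbp": 0.05, "peak_flow": 0.05, "co": 0.05,
    "upper_split": 0.05, "edv": 0.05, "edp": 0.05,
    "dbp": 0.07,  # signed upper bound
    "esv": 0.08,
}


@dataclass
class PatientTargets:
    """The nine printed patient quantities the model is tuned to."""

    hr: float  # bpm
    dbp: float  # mmHg
    sbp: float  # mmHg
    peak_flow: float  # mL/s
    co: float  # L/min
    upper_split: float  # % of CO to upper body incl. coronaries
    edv: float  # mL
    esv: float  # mL
    edp: float  # mmHg

    def __post_init__(self):
        if not (self.sbp > self.dbp > 0):
            raise ValueError("need sbp > dbp > 0")
        if not (self.edv > self.esv > 0):
            raise ValueError("need edv > esv > 0")
        if not (0 < self.upper_split < 100):
            raise ValueError("upper_split must be a percentage in (0, 100)")

    @classmethod
    def default_patient(cls):
        """The HFpEF study patient (60 bpm, 68/150 mmHg, CO 5.17 L/min)."""
        return cls(hr=60.0, dbp=68.0, sbp=150.0, peak_flow=266.0, co=5.17,
                   upper_split=29.0, edv=116.0, esv=36.0, edp=16.0)

    @property
    def sv_mL(self):
        """Stroke volume implied by the flow-derived cardiac output."""
        return self.co * 1000.0 / self.hr

    def as_dict(self):
        return dict(self.__dict__)


def mean_arterial_pressure(dbp, sbp):
    """Cuff convention: MAP = DBP + (SBP − DBP)/3."""
    return dbp + (sbp - dbp) / 3.0


def reconcile_volume_targets(edv, esv, sv, tol_edv=0.028, tol_esv=0.075, tol_sv=0.003):
    """Feasible (EDV, ESV) setpoints honouring EDV − ESV = SV as far as possible.

    Minimizes the maximum of the three deviations, each normalized by a
    fidelity tolerance reflecting how tightly the quantity must be matched.
    Consistent targets (edv − esv == sv) return unchanged.
    """
    if abs(edv - esv - sv) <= 1e-9 * sv:
        return edv, esv

    def cost(p):
        E, S = p
        return max(abs(E - edv) / (edv * tol_edv),
                   abs(S - esv) / (esv * tol_esv),
                   abs(E - S - sv) / (sv * tol_sv))

    res = minimize(cost, [edv, esv], method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 5000})
    return float(res.x[0]), float(res.x[1])


@dataclass
class CalibrationReport:
    """Per-target model values and errors plus the tuned parameter set."""

    targets: PatientTargets
    model_values: dict
    abs_errors: dict
    rel_errors_pct: dict
    branch_splits: dict
    converged: bool
    envelope_ok: bool
    stage_flags: dict
    tuned_parameters: dict
    n_iterations: int

    def frame(self):
        rows = []
        for key, patient in self.targets.as_dict().items():
            rows.append({
                "quantity": key, "patient": patient,
                "model": self.model_values[key],
                "delta_abs": self.abs_errors[key],
                "delta_pct": self.rel_errors_pct[key],
            })
        return pd.DataFrame(rows)

    def splits_frame(self):
        return pd.DataFrame([
            {"vessel": k, "split_pct": v} for k, v in self.branch_splits.items()
        ])

    def write(self, path, splits_path=None):
        self.frame().to_csv(path, index=False)
        if splits_path:
            self.splits_frame().to_csv(splits_path, index=False)


class Calibrator:
    """Stateful staged calibration toward a :class:`PatientTargets` table."""

    #: default total terminal capacitance, mL/mmHg (scaled by stage 3)
    C_TOTAL_DEFAULT = 0.9
    #: proximal (characteristic-impedance) share of each branch resistance
    RP_FRACTION = 0.22

    def __init__(self, targets: PatientTargets, geometry=None, seed=0,
                 dt=1e-4, R_ven=0.03, settle_cycles=14, settle_tol=3e-8):
        self.targets = targets
        self.seed = seed  # interface stability; all updates are deterministic
        self.dt = dt
        self.settle_cycles = settle_cycles
        self.settle_tol = settle_tol
        self.network = build_network(geometry)
        lv, la = default_heart(targets.hr)
        self.lv = lv
        self.la = la
        self.mv = ValveParams(A_eff_max=4.0, label="MV")
        self.av = ValveParams(A_eff_max=1.0,
                              inertance_coeff=blood_inertance(1.0, 10.0), label="AV")
        self.R_ven = R_ven
        self.fractions = self._goal_fractions(DEFAULT_BRANCH_FRACTIONS)
        self.C_scale = 1.0
        self.R_total = 1.0
        self.state = literature_initial_state()
        self.stage_flags = {}
        self.n_iterations = 0
        self._last_summary = None

        # internal setpoints
        t = targets
        edv_sp, esv_sp = reconcile_volume_targets(t.edv, t.esv, t.sv_mL)
        self.sp = {
            "edv": edv_sp, "esv": esv_sp, "sv": edv_sp - esv_sp,
            "peak_flow": t.peak_flow, "sbp": t.sbp,
            "pp": t.sbp - t.dbp, "edp": t.edp,
        }
        self._pin_passive(t.edv)

    # ------------------------------------------------------------- plumbing
    def _goal_fractions(self, proportions):
        """Branch fractions (%) rescaled so the upper-body total matches the
        patient's measured upper/lower split, keeping the given inter-branch
        proportions."""
        total = sum(proportions.values())
        props = {n: 100.0 * v / total for n, v in proportions.items()}
        upper_default = sum(props[n] for n in UPPER_BODY)
        scale = self.targets.upper_split / upper_default
        goal = {n: props[n] * scale for n in UPPER_BODY}
        goal["descending_aorta"] = 100.0 - self.targets.upper_split
        return goal

    def _pin_passive(self, edv_ref):
        """Set A_pas so the passive curve passes through (edv_ref, EDP target)."""
        denom = math.exp(self.lv.B_pas * (edv_ref - self.lv.V0)) - 1.0
        self.lv = replace(self.lv, A_pas=self.sp["edp"] / denom)

    def _apply_resistances(self):
        """Distribute the current total resistance over branches by fraction."""
        total_g = sum(self.fractions.values())
        for name in OUTLET_NAMES:
            f = self.fractions[name] / total_g
            r_branch = self.R_total / f
            seg_r = self.network.path_resistance(self.network.outlet_segments[name])
            term = self.network.terminals[name]
            term.R_proximal = self.RP_FRACTION * r_branch
            term.R_distal = max(r_branch - term.R_proximal - seg_r, 1e-6)
            term.C = self.C_scale * self.C_TOTAL_DEFAULT * f

    def build_model(self):
        self._apply_resistances()
        return CardiovascularModel(
            self.network, lv=self.lv, la=self.la, mv=self.mv, av=self.av,
            device=None, hr=self.targets.hr, R_ven=self.R_ven,
            pa_mean_init=mean_arterial_pressure(self.targets.dbp, self.targets.sbp))

    def measure(self, measure_cycles=2):
        """Settle to a periodic state from the current warm-start state, then
        summarize the final cycle."""
        model = self.build_model()
        self.state = model.estimate_initial_conditions(
            guess=self.state, dt=self.dt, tol=self.settle_tol,
            max_iter=self.settle_cycles)
        traj = model.integrate(self.state, dt=self.dt, n_cycles=measure_cycles)
        self.state = traj.end_state()
        self.state.t = 0.0
        self.n_iterations += 1
        self._last_summary = summarize(traj)
        return self._last_summary

    def _add_volume(self, dv):
        self.state = replace(self.state, V_LA=max(self.state.V_LA + dv, 5.0))

    # --------------------------------------------------------------- stages
    def stage_total_resistance(self, co_tol=0.02, max_iter=8):
        """Ohmic total resistance from MAP/CO, then a stressed-volume secant
        until simulated cardiac output is within ``co_tol`` of target."""
        t = self.targets
        map_t = mean_arterial_pressure(t.dbp, t.sbp)
        co_mls = t.co * 1000.0 / 60.0
        p_ven_est = max(t.edp - 3.0, 5.0)
        self.R_total = (map_t - p_ven_est) / co_mls

        co_sp = self.sp["sv"] * t.hr / 60.0 * 0.06  # L/min from reconciled SV
        s = self.measure()
        prev = None
        for _ in range(max_iter):
            err = (s.co - co_sp) / co_sp
            if abs(err) < co_tol * 0.5:
                break
            dv = -(s.co - co_sp) / 0.06 * 1.5  # mL per (mL/s), damped gain
            if prev is not None and abs(s.co - prev[1]) > 1e-6:
                gain = prev[0] / ((s.co - prev[1]) / 0.06)
                if 0.5 < gain < 8.0:
                    dv = -(s.co - co_sp) / 0.06 * gain
            prev = (dv, s.co)
            self._add_volume(dv)
            s = self.measure()
        if abs(s.co - co_sp) / co_sp > co_tol:
            raise CalibrationError(
                f"stage failure: CO {s.co:.2f} L/min not within {co_tol:.0%} "
                f"of {co_sp:.2f} (valve-limited?)")
        self.stage_flags["total_resistance"] = True
        return {n: self.network.terminals[n].R_distal for n in OUTLET_NAMES}

    def stage_flow_splits(self, branch_fractions=None, tol_pp=0.5, max_iter=4):
        """Per-branch distal resistances from the requested flow fractions."""
        if branch_fractions is not None:
            total = sum(branch_fractions.values())
            if abs(total - 100.0) > 0.5:
                raise CalibrationError(f"branch fractions sum to {total:.2f}, not 100 ± 0.5")
            self.fractions = dict(branch_fractions)
            targets = {n: 100.0 * v / sum(branch_fractions.values())
                       for n, v in branch_fractions.items()}
        else:
            targets = self._goal_fractions(DEFAULT_BRANCH_FRACTIONS)
        r_before = self.R_total
        s = self.measure()
        for _ in range(max_iter):
            worst = max(abs(s.branch_splits[n] - targets[n]) for n in OUTLET_NAMES)
            if worst < tol_pp * 0.3:
                break
            for n in OUTLET_NAMES:
                self.fractions[n] *= (targets[n] / s.branch_splits[n]) ** 0.9
            s = self.measure()
        worst = max(abs(s.branch_splits[n] - targets[n]) for n in OUTLET_NAMES)
        if worst > tol_pp:
            raise CalibrationError(f"flow splits off by {worst:.2f} pp (> {tol_pp})")
        assert abs(self.R_total - r_before) / r_before < 0.01
        self.stage_flags["flow_splits"] = True
        return {n: self.fractions[n] for n in OUTLET_NAMES}

    def stage_compliance(self, pp_tol=0.05, max_iter=8):
        """Scale terminal capacitances until pulse pressure matches."""
        pp_t = self.sp["pp"]
        s = self.measure()
        for _ in range(max_iter):
            pp = s.peak_systolic - s.diastolic
            if abs(pp - pp_t) / pp_t < pp_tol * 0.4:
                break
            factor = (pp / pp_t) ** 0.8  # more compliance -> lower pulse
            self.C_scale *= min(max(factor, 0.6), 1.6)
            s = self.measure()
        pp = s.peak_systolic - s.diastolic
        if abs(pp - pp_t) / pp_t > pp_tol:
            raise CalibrationError(f"stage failure: pulse pressure {pp:.1f} vs {pp_t:.1f}")
        self.stage_flags["compliance"] = True
        return self.C_scale

    def stage_heart(self, max_iter=10):
        """Pin the passive curve at the target EDV, then tune contractility
        and systolic duration toward the ESV and peak-flow setpoints."""
        self._pin_passive(self.targets.edv)
        s = self.measure()
        T = 60.0 / self.targets.hr
        for _ in range(max_iter):
            e_esv = (s.esv - self.sp["esv"]) / self.sp["esv"]
            e_pf = (s.peak_flow - self.sp["peak_flow"]) / self.sp["peak_flow"]
            e_edv = (s.edv - self.sp["edv"]) / self.sp["edv"]
            if abs(e_esv) < 0.01 and abs(e_pf) < 0.01 and abs(e_edv) < 0.005:
                break
            de = (s.esv - self.sp["esv"]) * self.lv.E_act_max ** 2 / 130.0
            new_E = min(max(self.lv.E_act_max + 0.8 * de, 1.0), 12.0)
            factor = (s.peak_flow / self.sp["peak_flow"]) ** 0.7
            new_ts = min(max(self.lv.t_sys * min(max(factor, 0.8), 1.25),
                             0.40 * T), 0.85 * T)
            self.lv = replace(self.lv, E_act_max=new_E, t_sys=new_ts)
            self._add_volume((self.sp["edv"] - s.edv) * 2.0)
            s = self.measure()
        self.stage_flags["heart"] = True
        return self.lv

    # ------------------------------------------------------------ refinement
    def _refine_pass(self, max_iter=24):
        """One outer refinement loop: damped simultaneous updates of all
        knobs, re-pinning the passive curve at the measured EDV."""
        T = 60.0 / self.targets.hr
        split_goal = self._goal_fractions(DEFAULT_BRANCH_FRACTIONS)
        co_sp = self.sp["sv"] * self.targets.hr * 0.06 / 60.0
        s = self.measure()
        for _ in range(max_iter):
            pp = s.peak_systolic - s.diastolic
            errs = {
                "edv": (s.edv - self.sp["edv"]) / self.sp["edv"],
                "esv": (s.esv - self.sp["esv"]) / self.sp["esv"],
                "co": (s.co - co_sp) / co_sp,
                "pf": (s.peak_flow - self.sp["peak_flow"]) / self.sp["peak_flow"],
                "sbp": (s.peak_systolic - self.sp["sbp"]) / self.sp["sbp"],
                "pp": (pp - self.sp["pp"]) / self.sp["pp"],
                "edp": (s.edp - self.sp["edp"]) / self.sp["edp"],
                "split": max(abs(s.branch_splits[n] - split_goal[n])
                             for n in OUTLET_NAMES),
            }
            if (abs(errs["edv"]) < 0.0008 and abs(errs["esv"]) < 0.0025
                    and abs(errs["co"]) < 0.0008
                    and abs(errs["pf"]) < 0.004 and abs(errs["sbp"]) < 0.002
                    and abs(errs["pp"]) < 0.005 and abs(errs["edp"]) < 0.005
                    and errs["split"] < 0.15):
                return s, True

            # volume -> EDV (with a stroke-volume assist so CO converges);
            # contractility -> ESV; t_sys -> peak flow; R -> SBP;
            # C -> pulse pressure; fractions -> splits; pin -> EDP
            sv_m = s.co / 0.06 * 60.0 / self.targets.hr
            self._add_volume((self.sp["edv"] - s.edv) * 2.0
                             + (self.sp["sv"] - sv_m) * 0.8)
            de = (s.esv - self.sp["esv"] + 0.4 * (sv_m - self.sp["sv"])) \
                * self.lv.E_act_max ** 2 / 130.0
            new_E = min(max(self.lv.E_act_max + 0.7 * de, 1.0), 12.0)
            factor = (s.peak_flow / self.sp["peak_flow"]) ** 0.6
            new_ts = min(max(self.lv.t_sys * min(max(factor, 0.85), 1.18),
                             0.40 * T), 0.85 * T)
            self.lv = replace(self.lv, E_act_max=new_E, t_sys=new_ts)
            self.R_total *= min(max((self.sp["sbp"] / s.peak_systolic) ** 1.0, 0.85), 1.18)
            self.C_scale *= min(max((pp / self.sp["pp"]) ** 0.7, 0.8), 1.25)
            for n in OUTLET_NAMES:
                self.fractions[n] *= (split_goal[n] / s.branch_splits[n]) ** 0.8
            self._pin_passive(s.edv)
            s = self.measure()
        return s, False

    # ------------------------------------------------------------- envelope
    def model_values(self, s):
        t = self.targets
        return {
            "hr": t.hr,  # prescribed
            "dbp": s.diastolic, "sbp": s.peak_systolic,
            "peak_flow": s.peak_flow, "co": s.co,
            "upper_split": s.upper_split,
            "edv": s.edv, "esv": s.esv, "edp": s.edp,
        }

    def envelope_check(self, s):
        t = self.targets.as_dict()
        m = self.model_values(s)
        bad = []
        for key, tol in ENVELOPE.items():
            rel = (m[key] - t[key]) / t[key]
            if key == "dbp":
                ok = rel <= tol  # only the upper bound is printed
            else:
                ok = abs(rel) <= tol
            if not ok:
                bad.append(f"{key}: {100 * rel:+.1f}% (bound {100 * tol:.0f}%)")
        return bad

    def report(self, s, converged):
        t = self.targets.as_dict()
        m = self.model_values(s)
        bad = self.envelope_check(s)
        return CalibrationReport(
            targets=self.targets,
            model_values=m,
            abs_errors={k: m[k] - t[k] for k in t},
            rel_errors_pct={k: 100.0 * (m[k] - t[k]) / t[k] for k in t},
            branch_splits=dict(s.branch_splits),
            converged=converged,
            envelope_ok=not bad,
            stage_flags=dict(self.stage_flags),
            tuned_parameters={
                "R_total": self.R_total, "C_scale": self.C_scale,
                "E_act_max": self.lv.E_act_max, "t_sys": self.lv.t_sys,
                "A_pas": self.lv.A_pas, "B_pas": self.lv.B_pas,
                "fractions": dict(self.fractions), "R_ven": self.R_ven,
            },
            n_iterations=self.n_iterations,
        )

    # ----------------------------------------------------------------- main
    def run(self, max_outer=5, strict=True):
        self.stage_total_resistance()
        self.stage_flow_splits()
        self.stage_compliance()
        self.stage_heart()
        s, converged = None, False
        for _ in range(max_outer):
            s, converged = self._refine_pass()
            if converged and not self.envelope_check(s):
                break
        bad = self.envelope_check(s)
        if bad and strict:
            raise CalibrationError("error envelope not met: " + "; ".join(bad))
        return self.build_model(), self.report(s, converged), s


def calibrate(targets=None, geometry=None, seed=0, dt=1e-4, strict=True, **kwargs):
    """Full staged calibration; returns (model, report, final_state).

    ``model`` is the tuned :class:`CardiovascularModel`; ``final_state`` is a
    periodic warm-start state for subsequent simulations.
    """
    targets = targets or PatientTargets.default_patient()
    cal = Calibrator(targets, geometry=geometry, seed=seed, dt=dt, **kwargs)
    model, rep, _ = cal.run(strict=strict)
    return model, rep, cal.state
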