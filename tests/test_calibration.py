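import math

import numpy as np
import pytest

from counterpulse.calibration import (
    DEFAULT_BRANCH_FRACTIONS,
    CalibrationError,
    Calibrator,
    PatientTargets,
    calibrate,
    mean_arterial_pressure,
    reconcile_volume_targets,
)
from counterpulse.chambers import passive_pressure


class TestTargets:
    def test_default_patient_table(self):
        t = PatientTargets.default_patient()
        assert (t.hr, t.dbp, t.sbp) == (60.0, 68.0, 150.0)
        assert (t.edv, t.esv, t.edp) == (116.0, 36.0, 16.0)

    def test_map_estimator(self):
        assert mean_arterial_pressure(68.0, 150.0) == pytest.approx(95.33, abs=0.01)

    def test_inconsistent_volumes_rejected(self):
        with pytest.raises(ValueError):
            PatientTargets(hr=60, dbp=68, sbp=150, peak_flow=266, co=5.17,
                           upper_split=29, edv=36, esv=116, edp=16)

    def test_pressure_ordering_rejected(self):
        with pytest.raises(ValueError):
            PatientTargets(hr=60, dbp=150, sbp=68, peak_flow=266, co=5.17,
                           upper_split=29, edv=116, esv=36, edp=16)


class TestReconcileVolumeTargets:
    def test_consistent_targets_unchanged(self):
        edv, esv = reconcile_volume_targets(120.0, 34.0, 86.0)
        assert (edv, esv) == (120.0, 34.0)

    def test_inconsistent_targets_land_inside_tolerances(self):
        t = PatientTargets.default_patient()
        edv, esv = reconcile_volume_targets(t.edv, t.esv, t.sv_mL)
        assert abs(edv - t.edv) / t.edv <= 0.03
        assert abs(esv - t.esv) / t.esv <= 0.08
        assert abs((edv - esv) - t.sv_mL) / t.sv_mL <= 0.0045


@pytest.fixture(scope="module")
def staged():
    """The four stages run in order, with the summary measured after each."""
    cal = Calibrator(PatientTargets.default_patient())
    out = {}
    out["R"] = cal.stage_total_resistance()
    out["after_R"] = cal.measure()
    out["fracs"] = cal.stage_flow_splits()
    out["after_splits"] = cal.measure()
    out["C"] = cal.stage_compliance()
    out["after_C"] = cal.measure()
    out["lv"] = cal.stage_heart()
    out["after_heart"] = cal.measure()
    return cal, out


class TestStages:
    def test_total_resistance_is_ohmic(self, staged):
        cal, _ = staged
        t = cal.targets
        map_t = mean_arterial_pressure(t.dbp, t.sbp)
        # doubling target CO at fixed MAP halves the total resistance
        doubled = PatientTargets(**{**t.as_dict(), "co": 2 * t.co})
        cal2 = Calibrator(doubled)
        cal2.R_total = (map_t - max(t.edp - 3, 5)) / (doubled.co * 1000 / 60)
        assert cal2.R_total == pytest.approx(cal.R_total * 0.5, rel=0.02)

    def test_co_within_stage_tolerance(self, staged):
        cal, out = staged
        co_sp = cal.sp["sv"] * cal.targets.hr * 0.06 / 60.0
        assert abs(out["after_R"].co - co_sp) / co_sp < 0.02

    def test_flow_splits_within_half_point(self, staged):
        cal, out = staged
        s = out["after_splits"]
        goal = cal._goal_fractions(DEFAULT_BRANCH_FRACTIONS)
        for name, f in goal.items():
            assert abs(s.branch_splits[name] - f) < 0.5

    def test_pulse_pressure_within_five_percent(self, staged):
        cal, out = staged
        s = out["after_C"]
        pp = s.peak_systolic - s.diastolic
        assert abs(pp - cal.sp["pp"]) / cal.sp["pp"] < 0.05

    def test_passive_curve_pinned_at_target_edv(self, staged):
        # A_pas * (exp(B_pas * (116 - V0)) - 1) = 16 mmHg after the heart stage
        lv = staged[1]["lv"]
        pinned = lv.A_pas * (math.exp(lv.B_pas * (116.0 - lv.V0)) - 1.0)
        assert pinned == pytest.approx(16.0, rel=1e-9)

    def test_bad_fraction_sum_rejected(self):
        cal = Calibrator(PatientTargets.default_patient())
        with pytest.raises(CalibrationError, match="sum"):
            cal.stage_flow_splits(branch_fractions={
                "descending_aorta": 60, "coronaries": 3, "right_subclavian": 7,
                "right_carotid": 9, "left_subclavian": 6, "left_carotid": 5})


class TestCalibratedModel:
    def test_report_covers_every_target(self, calibrated):
        _, report, _ = calibrated
        assert set(report.model_values) == set(PatientTargets.default_patient().as_dict())
        assert report.envelope_ok

    def test_contractility_monotonically_lowers_esv(self, calibrated):
        from dataclasses import replace

        from counterpulse.metrics import summarize
        from counterpulse.simulator import CardiovascularModel

        model, _, state = calibrated
        esvs = []
        for scale in (0.9, 1.0, 1.1):
            m = CardiovascularModel(
                model.network, lv=replace(model.lv, E_act_max=scale * model.lv.E_act_max),
                la=model.la, mv=model.mv, av=model.av, hr=model.hr, R_ven=model.R_ven,
                pa_mean_init=model.pa_mean_init)
            st = m.estimate_initial_conditions(guess=state, max_iter=8)
            esvs.append(summarize(m.integrate(st, n_cycles=1)).esv)
        assert esvs[0] > esvs[1] > esvs[2]

    def test_determinism(self, calibrated):
        _, report, _ = calibrated
        _, report2, _ = calibrate(PatientTargets.default_patient(), seed=0)
        assert report.rel_errors_pct == report2.rel_errors_pct
        assert report.tuned_parameters["E_act_max"] == report2.tuned_parameters["E_act_max"]

    def test_report_writer(self, calibrated, tmp_path):
        _, report, _ = calibrated
        report.write(tmp_path / "r.csv", tmp_path / "s.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "r.csv")
        assert set(df["quantity"]) == set(report.model_values)
        splits = pd.read_csv(tmp_path / "s.csv")
        assert splits["split_pct"].sum() == pytest.approx(100.0, abs=0.1)
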