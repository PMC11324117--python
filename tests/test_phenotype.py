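"""Phenotype readouts: milestones, phases, classification, localization."""

import numpy as np
import pytest

from startbycc.phenotype import (
    PhenotypeReport,
    active_form_breakdown,
    detect_milestones,
    localization_fractions,
    phase_durations,
)
from startbycc.simulate import SimulationConfig, Trajectory


def _synthetic_traj(times, columns):
    """Small hand-built trajectory over the real species layout."""
    from startbycc import build_model

    model = build_model()
    states = np.zeros((len(times), len(model.names)))
    for name, values in columns.items():
        states[:, model.index(name)] = values
    return Trajectory(times=np.asarray(times, float), states=states,
                      names=model.names, events=[],
                      config=SimulationConfig(t_end=float(times[-1])))


class TestDetectMilestones:
    def test_linear_interpolation_of_crossing(self):
        # ORI ramps 0.5 -> 1.5 between t=12 and t=13: crossing at exactly 12.5
        times = np.arange(0.0, 20.0)
        ori = np.zeros_like(times)
        ori[:12] = 0.5
        ori[12] = 0.5
        ori[13:] = 1.5
        traj = _synthetic_traj(times, {"ORI": ori})
        ms = detect_milestones(traj)
        assert ms["ORI"] == [pytest.approx(12.5)]

    def test_constant_zero_has_no_milestones(self):
        times = np.arange(0.0, 10.0)
        traj = _synthetic_traj(times, {})
        ms = detect_milestones(traj)
        assert ms["BUD"] == [] and ms["ORI"] == [] and ms["SPN"] == []

    def test_wildtype_bud_and_ori_nearly_simultaneous(self, wt_traj):
        ms = detect_milestones(wt_traj)
        divs = wt_traj.division_times()
        t0, t1 = divs[-2], divs[-1]
        bud = [t for t in ms["BUD"] if t0 <= t < t1][0]
        ori = [t for t in ms["ORI"] if t0 <= t < t1][0]
        assert abs(bud - ori) < 10.0


class TestPhaseDurations:
    def test_degenerate_arithmetic(self):
        ms = {"ORI": [40.0], "BUD": [45.0], "SPN": [80.0]}
        rows = phase_durations(ms, [0.0, 100.0])
        assert rows[0]["g1_length"] == pytest.approx(40.0)
        assert rows[0]["budded_period"] == pytest.approx(55.0)
        assert rows[0]["cycle_time"] == pytest.approx(100.0)

    def test_missing_milestones_give_none(self):
        rows = phase_durations({"ORI": [], "BUD": []}, [0.0, 100.0])
        assert rows[0]["g1_length"] is None
        assert rows[0]["budded_period"] is None

    def test_wildtype_g1_near_fifty_minutes(self, wt_steady):
        assert wt_steady.g1_length == pytest.approx(50.0, abs=4.0)


class TestClassification:
    def test_wildtype_viable(self, wt_report):
        assert wt_report.viable
        assert wt_report.arrest_stage == "none"
        assert wt_report.size_rel_wt == pytest.approx(1.0)

    def test_inviable_report_requires_arrest_stage(self):
        with pytest.raises(ValueError):
            PhenotypeReport(genotype="x", viable=False, arrest_stage="none",
                            size_rel_wt=None, cycle_time=None,
                            g1_length=None, budded_period=None)

    def test_double_activator_deletion_arrests_in_g1(self, screen_reports):
        rep = screen_reports["bck2Δ cln3Δ"]
        assert not rep.viable
        assert rep.arrest_stage == "G1"

    def test_whi5_rescue_of_double_deletion(self, screen_reports):
        rep = screen_reports["bck2Δ cln3Δ whi5Δ"]
        assert rep.viable
        assert rep.size_rel_wt > 1.1


class TestActiveForms:
    def test_wildtype_dominant_form_is_swi6_phosphorylated_sbf(
            self, wt_traj, wt_model):
        bd = active_form_breakdown(wt_traj, wt_model)
        assert bd.dominant()[0] in ("SBFa2", "MBFa")
        # among SBF classes specifically, SBFa2 dominates
        sbf_only = {k: v.max() for k, v in bd.series.items()
                    if k.startswith("SBFa")}
        assert max(sbf_only, key=sbf_only.get) == "SBFa2"

    def test_total_sbf_is_weighted_sum(self, wt_traj, wt_model):
        bd = active_form_breakdown(wt_traj, wt_model)
        p = wt_model.parameters
        manual = (p["wa1"] * wt_traj["SBFB"]
                  + p["wa2"] * (wt_traj["SBFB6P"] + wt_traj["SBFB6PQ"])
                  + p["wa3"] * (wt_traj["WSB6P"] + wt_traj["WSB6PQ"])
                  + p["wa4"] * wt_traj["WSB5P"]
                  + p["wa5"] * wt_traj["SWI4B"]
                  + p["wab"] * wt_traj["WSBB"])
        np.testing.assert_allclose(bd.total_sbf(), manual, rtol=1e-12)

    def test_swi4_deletion_has_no_sbf_forms(self):
        from startbycc import build_model
        from startbycc.simulate import simulate

        model = build_model(mutant="swi4Δ")
        traj = simulate(model, SimulationConfig(t_end=150.0))
        bd = active_form_breakdown(traj, model)
        for k in ("SBFa1", "SBFa2", "SBFa3", "SBFa4", "SBFa5"):
            assert float(np.abs(bd.series[k]).max(initial=0.0)) == 0.0


class TestLocalization:
    def test_whi5_nuclear_in_early_g1_cytoplasmic_after_start(
            self, wt_traj, wt_model):
        divs = wt_traj.division_times()
        t0, t1 = divs[-2], divs[-1]
        sel = (wt_traj.times >= t0) & (wt_traj.times <= t1)
        f = localization_fractions(wt_traj, wt_model, "Whi5")[sel]
        ts = wt_traj.times[sel] - t0
        early = f[(ts > 5) & (ts < 20)]
        late = f[(ts > 60) & (ts < 85)]
        assert float(early.max()) < 0.1
        assert float(late.max()) > 0.4

    def test_swi4_mostly_nuclear(self, wt_traj, wt_model):
        f = localization_fractions(wt_traj, wt_model, "Swi4")
        assert float(f.max()) < 0.1

    def test_deleted_monomer_reported_absent(self):
        from startbycc import build_model
        from startbycc.simulate import simulate

        model = build_model(mutant="whi5Δ")
        traj = simulate(model, SimulationConfig(t_end=50.0))
        with pytest.raises(ValueError, match="absent"):
            localization_fractions(traj, model, "Whi5")
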