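"""Alcohol timeline, treatments, end-to-end scenarios and direction reports."""

import numpy as np
import pytest

import neuromobile as nm
from neuromobile.transmitters import TRANSMITTERS

GABA = TRANSMITTERS.index("GABA")
GLU = TRANSMITTERS.index("Glu")
NA = TRANSMITTERS.index("NA")


class TestAlcoholTimeline:
    def test_default_timeline_has_the_four_phase_modifier_pattern(self):
        schedule = nm.build_alcohol_timeline(alpha=1.3, gamma=1.3)
        names = [p.name for p in schedule.phases]
        assert names == ["baseline", "acute", "adaptation", "withdrawal"]
        base, acute, adapt, wd = schedule.phases
        assert base.modifiers.is_unit()
        # acute: production-side only
        assert acute.modifiers.production[GABA] == pytest.approx(1.3)
        assert acute.modifiers.production[GLU] == pytest.approx(1 / 1.3)
        assert np.all(acute.modifiers.degradation == 1)
        # adaptation: acute production plus compensatory degradation
        assert np.array_equal(adapt.modifiers.production, acute.modifiers.production)
        assert adapt.modifiers.degradation[GABA] == pytest.approx(1.3)
        assert adapt.modifiers.degradation[GLU] == pytest.approx(1 / 1.3)
        # withdrawal: compensation only
        assert np.all(wd.modifiers.production == 1)
        assert np.array_equal(wd.modifiers.degradation, adapt.modifiers.degradation)

    @pytest.mark.parametrize("bad", [{"alpha": 0.9}, {"alpha": 1.0}, {"gamma": 0.5}])
    def test_directionality_is_enforced(self, bad):
        with pytest.raises(ValueError, match="exceed 1"):
            nm.build_alcohol_timeline(**bad)

    def test_phases_are_contiguous_and_ordered(self):
        schedule = nm.build_alcohol_timeline()
        for prev, nxt in zip(schedule.phases, schedule.phases[1:]):
            assert prev.end == nxt.start

    def test_custom_phase_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            nm.build_alcohol_timeline(phase_times={"acute": 500.0})


class TestTreatments:
    def test_diazepam_raises_gaba_production_after_start(self):
        schedule = nm.apply_treatment(nm.build_alcohol_timeline(), preset="diazepam")
        treat = schedule.phase_named("treatment")
        assert treat.start == 275.0
        assert treat.modifiers.production[GABA] == pytest.approx(1.2)
        # compensation carried over unchanged
        assert treat.modifiers.degradation[GABA] == pytest.approx(1.3)

    def test_clonidine_suppresses_noradrenaline_release(self):
        schedule = nm.apply_treatment(nm.build_alcohol_timeline(), preset="clonidine")
        assert schedule.phase_named("treatment").modifiers.production[NA] < 1.0

    def test_unit_fold_leaves_schedule_unchanged(self):
        base = nm.build_alcohol_timeline()
        assert nm.apply_treatment(base, preset="diazepam", fold=1.0) is base

    def test_start_outside_withdrawal_is_rejected(self):
        with pytest.raises(ValueError, match="withdrawal"):
            nm.apply_treatment(nm.build_alcohol_timeline(), preset="diazepam", start=120.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            nm.apply_treatment(nm.build_alcohol_timeline(), preset="aspirin")


class TestRunScenario:
    def test_unit_schedule_keeps_mobile_level_and_profile_at_baseline(self, model, tree):
        result = nm.run_scenario(model, tree, nm.ModifierSchedule.unit(0, 50))
        rel = np.abs(result.trajectory.values / model.baseline.values - 1)
        assert np.max(rel) < 1e-3
        assert np.max(result.mobile.imbalance) < 1e-6

    def test_acute_end_has_high_gaba_low_glu(self, alcohol_result):
        profile = alcohol_result.phase_end_profile("acute")
        base = alcohol_result.model.baseline
        assert profile["GABA"] > base["GABA"]
        assert profile["Glu"] < base["Glu"]

    def test_withdrawal_end_reverses_glu_and_gaba(self, alcohol_result):
        profile = alcohol_result.phase_end_profile("withdrawal")
        base = alcohol_result.model.baseline
        assert profile["Glu"] > base["Glu"]
        assert profile["GABA"] < base["GABA"]

    def test_adaptation_partially_compensates_the_glu_gaba_rod(self, alcohol_result):
        acute = alcohol_result.phase_end_angle("Glu_GABA", "acute")
        adapt = alcohol_result.phase_end_angle("Glu_GABA", "adaptation")
        assert 0 < abs(adapt) < abs(acute)

    def test_identical_inputs_give_bit_identical_results(self, model, tree):
        schedule = nm.build_alcohol_timeline()
        r1 = nm.run_scenario(model, tree, schedule, grid_dt=0.5)
        r2 = nm.run_scenario(model, tree, schedule, grid_dt=0.5)
        assert np.array_equal(r1.trajectory.values, r2.trajectory.values)
        assert np.array_equal(r1.mobile.angles, r2.mobile.angles)

    def test_da_and_na_responses_overlap(self, alcohol_result):
        """DA and NA start equal and follow near-identical dynamics."""
        traj = alcohol_result.trajectory
        da = traj.values[:, TRANSMITTERS.index("DA")]
        na = traj.values[:, TRANSMITTERS.index("NA")]
        assert np.max(np.abs(da / na - 1)) < 0.01


class TestDirectionReport:
    def test_withdrawal_labels_match_the_clinical_picture(self, alcohol_result):
        report = nm.direction_of_change_report(alcohol_result, at="withdrawal")
        assert report == {
            "Glu": "elevated",
            "GABA": "reduced",
            "DA": "elevated",
            "NA": "elevated",
            "ACh": "unchanged",
            "HT": "unchanged",
        }

    def test_unit_schedule_reports_everything_unchanged(self, model, tree):
        result = nm.run_scenario(model, tree, nm.ModifierSchedule.unit(0, 20))
        report = nm.direction_of_change_report(result, at="baseline")
        assert set(report.values()) == {"unchanged"}

    def test_huge_band_swallows_every_change(self, alcohol_result):
        report = nm.direction_of_change_report(alcohol_result, epsilon=1e9)
        assert set(report.values()) == {"unchanged"}

    def test_epsilon_must_be_positive(self, alcohol_result):
        with pytest.raises(ValueError):
            nm.direction_of_change_report(alcohol_result, epsilon=0.0)


class TestMobileReversals:
    def test_top_rod_swings_from_inhibitory_side_to_monoamine_side(self, alcohol_result):
        tree = alcohol_result.tree
        acute = alcohol_result.phase_end_angle("TOP", "acute")
        wd = alcohol_result.phase_end_angle("TOP", "withdrawal")
        assert "GABA" in nm.descending_side(tree, "TOP", acute)
        assert "DA" in nm.descending_side(tree, "TOP", wd)

    def test_ht_da_rod_tilts_toward_dopamine_during_withdrawal(self, alcohol_result):
        theta = alcohol_result.phase_end_angle("HT_DA", "withdrawal")
        assert nm.descending_side(alcohol_result.tree, "HT_DA", theta) == ("DA",)

    def test_diazepam_lowers_the_imbalance_index(self, alcohol_result, diazepam_result):
        t = alcohol_result.mobile.times
        mask = t > 275.0
        treated = diazepam_result.mobile.imbalance[mask]
        untreated = alcohol_result.mobile.imbalance[mask]
        assert np.all(treated < untreated)
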