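import numpy as np
import pytest

from metrano.longitudinal import LesionMatchSet
from metrano.quantify import LesionRecord
from metrano.rano import (
    TargetSet,
    assess_response_1d,
    assess_response_volumetric,
    assess_study_pair,
    select_target_lesions,
)


def _rec(lid, diameter, volume=None):
    volume = volume if volume is not None else diameter**3
    return LesionRecord(lid, 0, volume, diameter, (0.0, 0.0, 0.0), (0, 1))


def _targets(diameters):
    return select_target_lesions([_rec(i + 1, d) for i, d in enumerate(diameters)])


# Independent table-driven oracle: ordered (condition, category) rows,
# written directly from the rule definitions, evaluated top-down.
def _oracle_1d(s_b, s_f, new):
    rules = [
        (lambda: new, "PD"),
        (lambda: s_f == 0, "CR"),
        (lambda: (s_f - s_b) / s_b <= -0.30, "PR"),
        (lambda: (s_f - s_b) / s_b >= 0.20, "PD"),
        (lambda: True, "SD"),
    ]
    return next(cat for cond, cat in rules if cond())


def _oracle_vol(v_b, v_f, new):
    rules = [
        (lambda: new, "PD"),
        (lambda: v_f == 0, "CR"),
        (lambda: v_f / v_b <= 0.343, "PR"),
        (lambda: v_f / v_b >= 1.728, "PD"),
        (lambda: True, "SD"),
    ]
    return next(cat for cond, cat in rules if cond())


class TestSelectTargetLesions:
    def test_threshold_then_five_largest(self):
        ts = _targets([12, 11, 9, 8, 6, 5, 4])
        assert [r.longest_axial_diameter_mm for r in ts.records] == [12, 11, 9, 8, 6]
        assert ts.sum_longest_diameters_mm == 46

    def test_fewer_than_five(self):
        ts = _targets([6, 5])
        assert len(ts) == 2
        assert ts.sum_longest_diameters_mm == 11

    def test_all_below_threshold_gives_empty_set(self):
        ts = _targets([4, 3, 2])
        assert len(ts) == 0
        assert ts.sum_longest_diameters_mm == 0

    def test_ties_broken_by_volume_then_id(self):
        recs = [_rec(3, 8, volume=100), _rec(1, 8, volume=300), _rec(2, 8, volume=300)]
        ts = select_target_lesions(recs, max_n=2)
        assert ts.ids == [1, 2]

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="sorted"):
            TargetSet([_rec(1, 6), _rec(2, 9)])
        with pytest.raises(ValueError, match="threshold"):
            TargetSet([_rec(1, 4)])


class TestOneDimensionalRules:
    def test_pr_boundary_inclusive(self):
        a = assess_response_1d(_targets([20, 20]), 28.0, new_lesion=False)
        assert a.category == "PR"
        assert a.percent_change == pytest.approx(-30.0)

    def test_pd_boundary_inclusive(self):
        assert assess_response_1d(_targets([20, 20]), 48.0, new_lesion=False).category == "PD"

    def test_new_lesion_overrides_shrinkage(self):
        # any new lesion, regardless of its size, means progression
        assert assess_response_1d(_targets([20, 20]), 39.0, new_lesion=True).category == "PD"

    def test_disappearance_is_cr(self):
        assert assess_response_1d(_targets([10, 8]), 0.0, new_lesion=False).category == "CR"

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assess_response_1d(_targets([4]), 0.0, new_lesion=False)


class TestVolumetricRules:
    def test_pr_boundary_is_cube_of_thirty_percent(self):
        assert assess_response_volumetric(1000.0, 343.0, False).category == "PR"

    def test_pd_boundary_is_cube_of_twenty_percent(self):
        assert assess_response_volumetric(1000.0, 1728.0, False).category == "PD"

    def test_disappearance_is_cr(self):
        assert assess_response_volumetric(1000.0, 0.0, False).category == "CR"

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            assess_response_volumetric(0.0, 10.0, False)


class TestRuleEngineAgainstOracle:
    def test_exhaustive_1d_grid_including_boundaries(self):
        s_b_values = [10.0, 23.0, 40.0]
        for s_b in s_b_values:
            ratios = np.concatenate([np.linspace(0.0, 2.5, 101), [0.70, 1.20, 0.699999, 0.700001, 1.199999, 1.200001]])
            for r in ratios:
                s_f = r * s_b
                for new in (False, True):
                    got = assess_response_1d(_targets([s_b]), s_f, new).category
                    assert got == _oracle_1d(s_b, s_f, new), (s_b, s_f, new)

    def test_exhaustive_volumetric_grid_including_boundaries(self):
        for v_b in [500.0, 1000.0, 3333.0]:
            ratios = np.concatenate([np.linspace(0.0, 3.0, 101), [0.343, 1.728, 0.3429, 0.3431, 1.7279, 1.7281]])
            for r in ratios:
                v_f = r * v_b
                for new in (False, True):
                    got = assess_response_volumetric(v_b, v_f, new).category
                    assert got == _oracle_vol(v_b, v_f, new), (v_b, v_f, new)

    def test_1d_and_volumetric_agree_for_isotropic_change(self):
        # a single sphere scaled by k: thresholds are consistent by construction
        for k in np.linspace(0.05, 2.2, 87):
            d_b, d_f = 10.0, 10.0 * k
            cat_1d = assess_response_1d(_targets([d_b]), d_f, False).category
            cat_vol = assess_response_volumetric(d_b**3, d_f**3, False).category
            assert cat_1d == cat_vol, k

    def test_category_monotone_in_followup_sum(self):
        order = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}
        cats = [assess_response_1d(_targets([30.0]), s_f, False).category for s_f in np.linspace(0, 60, 121)]
        assert all(order[a] <= order[b] for a, b in zip(cats, cats[1:]))


class TestAssessStudyPair:
    def test_halved_radii_give_pr_on_both_bases(self):
        base = [_rec(1, 10.0, 523.6), _rec(2, 8.0, 268.1)]
        follow = [_rec(1, 5.0, 65.4), _rec(2, 4.0, 33.5)]
        matches = LesionMatchSet([(1, 1, 0.1), (2, 2, 0.1)])
        one_d, vol = assess_study_pair(base, follow, matches)
        assert (one_d.category, vol.category) == ("PR", "PR")

    def test_new_lesion_gives_pd_on_both_bases(self):
        base = [_rec(1, 10.0)]
        follow = [_rec(1, 10.0), _rec(9, 3.0)]
        matches = LesionMatchSet([(1, 1, 0.1)], new=[9])
        one_d, vol = assess_study_pair(base, follow, matches)
        assert (one_d.category, vol.category) == ("PD", "PD")

    def test_identical_followup_is_sd(self):
        base = [_rec(1, 10.0)]
        matches = LesionMatchSet([(1, 1, 0.0)])
        one_d, vol = assess_study_pair(base, base, matches)
        assert (one_d.category, vol.category) == ("SD", "SD")

    def test_disappeared_target_contributes_zero(self):
        base = [_rec(1, 10.0), _rec(2, 10.0)]
        follow = [_rec(1, 10.0)]
        matches = LesionMatchSet([(1, 1, 0.0)], disappeared=[2])
        one_d, _ = assess_study_pair(base, follow, matches)
        assert one_d.followup_sum == 10.0
        assert one_d.category == "PR"  # 20 -> 10 is a 50% drop

    def test_phantom_truth_scenarios(self, measurable_config):
        from metrano.phantom import FollowupChanges, generate_followup, generate_phantom
        from metrano.pipeline import truth_assessment
        from metrano.transform import SimilarityTransform

        _, _, truth = generate_phantom(measurable_config, seed=31)
        ident = SimilarityTransform(center_mm=truth.brain.center_mm)
        ids = [l.id for l in truth.lesions]
        for changes, expected in [
            (FollowupChanges(factors={i: 0.5 for i in ids}), "PR"),
            (FollowupChanges(), "SD"),
            (FollowupChanges(factors={i: 1.35 for i in ids}), "PD"),
            (FollowupChanges(removed=tuple(ids)), "CR"),
        ]:
            _, _, ftruth = generate_followup(truth, ident, changes, seed=1)
            one_d, vol = truth_assessment(truth, ftruth)
            assert one_d.category == expected
            assert vol.category == expected
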