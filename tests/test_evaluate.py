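import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from metrano.evaluate import (
    ConfusionTable4,
    dice_coefficient,
    kappa_agreement_category,
    match_detections_to_truth,
    per_lesion_dice,
    proportion_ci,
    sensitivity_by_size,
    weighted_kappa,
)
from metrano.reference import RESPONSE_AGREEMENT_1D, RESPONSE_AGREEMENT_VOLUMETRIC


def _brute_force_weighted_kappa(counts, weights):
    counts = np.asarray(counts, float)
    k = counts.shape[0]
    n = counts.sum()
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            if weights == "linear":
                w = 1 - abs(i - j) / (k - 1)
            else:
                w = 1 - ((i - j) / (k - 1)) ** 2
            po += w * counts[i, j] / n
            pe += w * counts[i, :].sum() * counts[:, j].sum() / n**2
    return (po - pe) / (1 - pe)


class TestMatchDetectionsToTruth:
    def _maps(self):
        t = np.zeros((20, 20, 20), np.int32)
        t[1:4, 1:4, 1:4] = 1
        t[8:11, 8:11, 8:11] = 2
        t[15:18, 15:18, 15:18] = 3
        p = np.zeros_like(t)
        p[2:5, 2:5, 2:5] = 1  # overlaps truth 1
        p[9:10, 9:10, 9:10] = 2  # overlaps truth 2
        p[15:17, 1:3, 1:3] = 3  # stray
        return p, t

    def test_hit_and_fp_counting(self):
        p, t = self._maps()
        ev = match_detections_to_truth(p, t)
        assert ev.n_detected == 2 and ev.n_truth == 3
        assert ev.fp_count == 1
        assert ev.sensitivity() == pytest.approx(2 / 3)

    def test_empty_prediction(self):
        _, t = self._maps()
        ev = match_detections_to_truth(np.zeros_like(t), t)
        assert ev.n_detected == 0 and ev.fp_count == 0

    def test_perfect_prediction(self):
        _, t = self._maps()
        ev = match_detections_to_truth(t, t)
        assert ev.n_detected == 3 and ev.fp_count == 0
        assert all(d == 1.0 for d in ev.dice_by_id.values())

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            match_detections_to_truth(np.zeros((4, 4, 4)), np.zeros((5, 5, 5)))


class TestSensitivityBySize:
    def test_binning_and_aggregate(self):
        ev = match_detections_to_truth(
            np.zeros((4, 4, 4), np.int32), np.zeros((4, 4, 4), np.int32)
        )
        ev.hits = {1: False, 2: True, 3: True}
        ev.diameters_mm = {1: 4.0, 2: 6.0, 3: 12.0}
        table = sensitivity_by_size([ev], bin_edges_mm=(0, 5, 10, np.inf))
        assert list(table["sensitivity"][:3]) == [0.0, 1.0, 1.0]
        agg = table.iloc[-1]
        assert agg["n"] == 2 and agg["detected"] == 2

    def test_empty_bin_reports_nan(self):
        ev = match_detections_to_truth(np.zeros((2, 2, 2), np.int32), np.zeros((2, 2, 2), np.int32))
        ev.hits, ev.diameters_mm = {1: True}, {1: 7.0}
        table = sensitivity_by_size([ev], bin_edges_mm=(0, 5, 10, np.inf))
        assert np.isnan(table["sensitivity"][0])

    def test_unordered_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sensitivity_by_size([], bin_edges_mm=(5, 0, 10))

    def test_sensitivity_plus_miss_fraction_is_one(self):
        r = np.random.default_rng(1)
        ev = match_detections_to_truth(np.zeros((2, 2, 2), np.int32), np.zeros((2, 2, 2), np.int32))
        ev.hits = {i: bool(r.integers(2)) for i in range(1, 30)}
        ev.diameters_mm = {i: float(r.uniform(1, 25)) for i in range(1, 30)}
        table = sensitivity_by_size([ev])
        for _, row in table.iterrows():
            if row["n"]:
                assert row["sensitivity"] + (row["n"] - row["detected"]) / row["n"] == pytest.approx(1.0)


class TestDiceCoefficient:
    def test_identical_masks(self, rng):
        m = rng.random((8, 8, 8)) > 0.5
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:, :, :1] = True  # 100 voxels
        b[:, :, 0:1][:5] = True  # 50 overlapping
        b[:, :, 9:10][:5] = True  # 50 elsewhere
        assert dice_coefficient(b, a) == pytest.approx(0.5)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            dice_coefficient(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool))

    def test_matches_set_arithmetic_on_random_masks(self, rng):
        for _ in range(20):
            a = rng.random((6, 6, 6)) > 0.5
            b = rng.random((6, 6, 6)) > 0.3
            expected = 2 * np.sum(a & b) / (a.sum() + b.sum())
            assert dice_coefficient(a, b) == pytest.approx(expected)


class TestWeightedKappa:
    def test_reference_one_dimensional_table(self):
        k = weighted_kappa(RESPONSE_AGREEMENT_1D)
        assert round(k, 2) == 0.52
        assert kappa_agreement_category(k) == "moderate"

    def test_reference_volumetric_table(self):
        k = weighted_kappa(RESPONSE_AGREEMENT_VOLUMETRIC)
        assert round(k, 2) == 0.68
        assert kappa_agreement_category(k) == "substantial"

    def test_observed_and_chance_agreement_components(self):
        # intermediate quantities for the one-dimensional table, by brute force
        counts = np.asarray(RESPONSE_AGREEMENT_1D, float)
        n = counts.sum()
        i, j = np.indices(counts.shape)
        w = 1 - np.abs(i - j) / 3
        assert (w * counts).sum() / n == pytest.approx(0.800, abs=5e-4)
        assert (w * np.outer(counts.sum(1), counts.sum(0))).sum() / n**2 == pytest.approx(0.580, abs=5e-4)

    def test_diagonal_table_is_perfect_agreement(self):
        assert weighted_kappa(np.diag([3, 5, 2, 7])) == pytest.approx(1.0)

    def test_matches_brute_force_and_sklearn_on_random_tables(self, rng):
        labels = [0, 1, 2, 3]
        for _ in range(40):
            counts = rng.integers(0, 9, size=(4, 4))
            if counts.sum() == 0:
                continue
            for weights, sk_w in (("linear", "linear"), ("quadratic", "quadratic")):
                ours = weighted_kappa(counts, weights)
                brute = _brute_force_weighted_kappa(counts, weights)
                assert ours == pytest.approx(brute, abs=1e-12)
                a, b = [], []
                for i in range(4):
                    for j in range(4):
                        a += [i] * counts[i, j]
                        b += [j] * counts[i, j]
                try:
                    sk = cohen_kappa_score(a, b, labels=labels, weights=sk_w)
                except Exception:
                    continue
                if np.isfinite(sk):
                    assert ours == pytest.approx(sk, abs=1e-9)

    def test_identity_weights_equal_unweighted_kappa(self, rng):
        counts = rng.integers(1, 9, size=(4, 4))
        a, b = [], []
        for i in range(4):
            for j in range(4):
                a += [i] * counts[i, j]
                b += [j] * counts[i, j]
        assert weighted_kappa(counts, "identity") == pytest.approx(
            cohen_kappa_score(a, b, labels=[0, 1, 2, 3]), abs=1e-9
        )

    def test_invariant_to_count_scaling(self, rng):
        counts = rng.integers(0, 9, size=(4, 4)) + np.eye(4, dtype=int)
        assert weighted_kappa(counts) == pytest.approx(weighted_kappa(counts * 7), abs=1e-12)

    def test_empty_and_degenerate_tables_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_kappa(np.zeros((4, 4)))
        bad = np.zeros((4, 4))
        bad[2, 2] = 5  # all mass in one cell: chance agreement is 1
        with pytest.raises(ValueError, match="degenerate"):
            weighted_kappa(bad)

    def test_table_from_categories(self):
        t = ConfusionTable4.from_categories(["CR", "PD", "PD"], ["CR", "PD", "SD"])
        assert t.counts[0, 0] == 1 and t.counts[3, 3] == 1 and t.counts[3, 2] == 1
        assert t.total == 3


class TestProportionCI:
    def test_eighteen_of_nineteen_exact(self):
        lo, hi = proportion_ci(18, 19)
        assert round(lo, 1) == 74.0
        assert round(hi, 1) == 99.9

    def test_zero_successes_lower_bound(self):
        lo, _ = proportion_ci(0, 10)
        assert lo == 0.0

    def test_all_successes_upper_bound(self):
        _, hi = proportion_ci(10, 10)
        assert hi == 100.0

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 200))
            x = int(rng.integers(0, n + 1))
            for method in ("clopper-pearson", "wilson"):
                lo, hi = proportion_ci(x, n, method=method)
                assert lo - 1e-9 <= 100 * x / n <= hi + 1e-9

    def test_widens_with_fewer_trials(self):
        lo1, hi1 = proportion_ci(80, 100)
        lo2, hi2 = proportion_ci(8, 10)
        assert hi2 - lo2 > hi1 - lo1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 0)
        with pytest.raises(ValueError):
            proportion_ci(7, 5)


class TestPerLesionDice:
    def test_mean_and_sd_over_matched_lesions(self):
        ev1 = match_detections_to_truth(np.zeros((2, 2, 2), np.int32), np.zeros((2, 2, 2), np.int32))
        ev1.hits = {1: True, 2: True}
        ev1.diameters_mm = {1: 8.0, 2: 6.0}
        ev1.dice_by_id = {1: 0.8, 2: 0.6}
        mean, sd, n = per_lesion_dice([ev1])
        assert mean == pytest.approx(0.7)
        assert n == 2
        assert sd == pytest.approx(np.std([0.8, 0.6], ddof=1))
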