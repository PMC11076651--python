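"""Metric suite, inverse reconstruction, statistics, regions, aggregation."""

import numpy as np
import pytest

from microsel import (ConfusionMatrix, aggregate_report, compute_metrics,
                      confusion, descriptive_stats, mcc_kappa_analysis,
                      reconstruct_confusion)
from microsel.metrics import classify_region, round_half_away
from microsel.published import PUBLISHED_ROWS, accuracies, published_row


def random_cms(n, rng, n_pos=77, n_neg=59):
    tps = rng.integers(0, n_pos + 1, size=n)
    fps = rng.integers(0, n_neg + 1, size=n)
    return [ConfusionMatrix(int(tp), int(fp), int(n_pos - tp), int(n_neg - fp))
            for tp, fp in zip(tps, fps)]


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        y = np.array([1, 1, 0, 0, 1])
        cm = confusion(y, y)
        assert (cm.fp, cm.fn) == (0, 0) and (cm.tp, cm.tn) == (3, 2)
        cm = confusion(y, 1 - y)
        assert (cm.tp, cm.tn) == (0, 0) and (cm.fp, cm.fn) == (2, 3)

    def test_swapping_positive_label_transposes(self):
        rng = np.random.default_rng(0)
        y, p = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        a = confusion(y, p, positive_label=1)
        b = confusion(y, p, positive_label=0)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tn, b.fn, b.fp, b.tp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestComputeMetrics:
    def test_headline_row_values(self):
        """The reconstructed benchmark matrix (72, 2, 5, 57) must
        reproduce its published row after 2-dp rounding."""
        row = compute_metrics(ConfusionMatrix(72, 2, 5, 57)).to_published_row()
        want = published_row("eho", "DCT", "SVM (RBF)")
        for key in ("accuracy", "precision", "f1", "mcc", "fm", "error_rate",
                    "jaccard", "kappa"):
            assert row[key] == pytest.approx(want[key], abs=1e-9), key

    def test_perfect_classifier(self):
        ms = compute_metrics(ConfusionMatrix(77, 0, 0, 59))
        assert ms.accuracy == 1.0 and ms.error_rate == 0.0
        assert ms.mcc == 1.0 and ms.kappa == 1.0

    def test_constant_predictor_is_chance(self):
        ms = compute_metrics(ConfusionMatrix(50, 50, 0, 0))
        assert ms.kappa == 0.0
        assert ms.mcc == 0.0
        assert "mcc" in ms.degenerate

    def test_identities_on_random_matrices(self, rng):
        """accuracy + error = 1, Jaccard = F1/(2-F1), FM >= F1,
        kappa <= accuracy, MCC in [-1, 1] over 10,000 random tallies."""
        for cm in random_cms(10_000, rng):
            ms = compute_metrics(cm)
            assert ms.accuracy + ms.error_rate == pytest.approx(1.0, abs=1e-12)
            if ms.f1 > 0:
                assert ms.jaccard == pytest.approx(ms.f1 / (2 - ms.f1), abs=1e-9)
            assert ms.fm >= ms.f1 - 1e-12
            assert ms.kappa <= ms.accuracy + 1e-12
            assert -1.0 - 1e-12 <= ms.mcc <= 1.0 + 1e-12

    def test_agrees_with_brute_force_tally(self, rng):
        """Independent per-sample tallying on random label vectors."""
        for _ in range(50):
            y = rng.integers(0, 2, 40)
            p = rng.integers(0, 2, 40)
            cm = confusion(y, p)
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
            tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
            ms = compute_metrics(cm)
            n = 40
            assert ms.accuracy == pytest.approx((tp + tn) / n, abs=1e-12)
            if tp + fp and tp + fn and tn + fp and tn + fn:
                want_mcc = (tp * tn - fp * fn) / np.sqrt(
                    float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
                assert ms.mcc == pytest.approx(want_mcc, abs=1e-12)

    def test_mcc_kappa_invariant_under_class_swap(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        a = compute_metrics(confusion(y, p, positive_label=1))
        b = compute_metrics(confusion(1 - y, 1 - p, positive_label=1))
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert a.kappa == pytest.approx(b.kappa, abs=1e-12)


class TestReconstruction:
    def test_headline_rows_unique(self):
        got = reconstruct_confusion(94.85, 97.30, 95.36, 77, 59)
        assert [(c.tp, c.fp, c.fn, c.tn) for c in got] == [(72, 2, 5, 57)]
        got = reconstruct_confusion(94.12, 98.59, 94.60, 77, 59, ulp_slack=1)
        assert [(c.tp, c.fp, c.fn, c.tn) for c in got] == [(70, 1, 7, 58)]

    def test_perfect_row(self):
        got = reconstruct_confusion(100.0, 100.0, 100.0, 77, 59)
        assert [(c.tp, c.fp, c.fn, c.tn) for c in got] == [(77, 0, 0, 59)]

    def test_impossible_triple_empty(self):
        assert reconstruct_confusion(94.12, 98.59, 94.60, 77, 59) == []

    def test_round_trip_containment_all_matrices(self):
        """Every integer matrix with class totals 77/59 is recovered from
        its own rounded (accuracy, precision, F1)."""
        for tp in range(0, 78):
            for fp in range(0, 60):
                cm = ConfusionMatrix(tp, fp, 77 - tp, 59 - fp)
                ms = compute_metrics(cm)
                got = reconstruct_confusion(
                    round_half_away(100 * ms.accuracy),
                    round_half_away(100 * ms.precision),
                    round_half_away(100 * ms.f1), 77, 59)
                assert (tp, fp, 77 - tp, 59 - fp) in [
                    (c.tp, c.fp, c.fn, c.tn) for c in got]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(101.0, 50.0, 50.0, 77, 59)
        with pytest.raises(ValueError):
            reconstruct_confusion(50.0, 50.0, 50.0, 0, 59)


class TestDescriptiveStats:
    def test_identical_groups_t_zero_p_one(self, rng):
        A = rng.normal(size=(30, 10))
        prof = descriptive_stats(A, A.copy())
        assert prof.ttest_t == pytest.approx(0.0, abs=1e-12)
        assert prof.ttest_p == pytest.approx(1.0, abs=1e-12)
        assert prof.pcc == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_data_zero_skew(self):
        A = np.array([[c, -c] for c in (1.0, 2.0, 3.0, 4.0)]).reshape(-1, 1)
        prof = descriptive_stats(np.hstack([A, -A]), np.hstack([A, A]))
        assert prof.group_a.skewness == pytest.approx(0.0, abs=1e-9)

    def test_large_normal_sample_excess_kurtosis_near_zero(self, rng):
        A = rng.normal(size=(100_000, 1))
        prof = descriptive_stats(A, A)
        assert abs(prof.group_a.kurtosis) < 0.1

    def test_pearson_kurtosis_switch(self, rng):
        A = rng.normal(size=(5000, 3))
        fisher = descriptive_stats(A, A, excess_kurtosis=True)
        pearson = descriptive_stats(A, A, excess_kurtosis=False)
        assert pearson.group_a.kurtosis == pytest.approx(
            fisher.group_a.kurtosis + 3.0, abs=1e-9)

    def test_constant_columns_excluded_and_counted(self, rng):
        A = np.hstack([rng.normal(size=(20, 2)), np.ones((20, 1))])
        prof = descriptive_stats(A, A)
        assert prof.group_a.n_constant_excluded == 1

    def test_cca_in_unit_interval(self, rng):
        prof = descriptive_stats(rng.normal(size=(25, 8)), rng.normal(size=(30, 8)))
        assert 0.0 <= prof.cca <= 1.0

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            descriptive_stats(np.empty((0, 3)), rng.normal(size=(5, 3)))


class TestMccKappaAnalysis:
    def test_region_boundaries(self):
        assert classify_region(0.25) == "R1"
        assert classify_region(0.45) == "R2"
        assert classify_region(0.65) == "R3"
        assert classify_region(0.55) == "unclassified"
        assert classify_region(-0.2) == "unclassified"

    def test_identity_rows_slope_one(self):
        rows = [(v, v) for v in np.linspace(0.1, 0.9, 9)]
        _, slope = mcc_kappa_analysis(rows)
        assert slope == pytest.approx(1.0, abs=1e-12)

    def test_scaled_rows_recover_scale(self):
        rows = [(v, 0.9 * v) for v in np.linspace(0.05, 0.95, 10)]
        _, slope = mcc_kappa_analysis(rows)
        assert slope == pytest.approx(0.9, abs=1e-9)

    def test_published_rows_slope_near_unity(self):
        from microsel.published import mcc_kappa_pairs
        labels, slope = mcc_kappa_analysis(mcc_kappa_pairs())
        assert slope == pytest.approx(0.999, abs=0.005)
        assert sum(1 for l in labels if l.region == "R3") > 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            mcc_kappa_analysis([(0.5, 0.5)])


class TestAggregateReport:
    @staticmethod
    def _published_results(selection):
        cols = ("accuracy", "precision", "f1", "mcc", "fm", "error_rate",
                "jaccard", "csi", "gmean", "kappa")
        return [(selection, ext, clf, dict(zip(cols, vals)))
                for ext, clf, *vals in PUBLISHED_ROWS[selection]]

    def test_published_table_averages(self):
        """Cross-table averages of the printed accuracies."""
        report = aggregate_report(self._published_results("eho")
                                  + self._published_results("none"))
        assert report["overall_average_accuracy"]["eho"] == 79.19
        assert report["overall_average_accuracy"]["none"] == 69.02

    def test_single_row_average_is_the_row(self):
        rows = self._published_results("firefly")[:1]
        report = aggregate_report(rows)
        assert report["overall_average_accuracy"]["firefly"] == rows[0][3]["accuracy"]

    def test_best_configuration_ties_broken_by_mcc(self):
        cols = ("accuracy", "precision", "f1", "mcc", "fm", "error_rate",
                "jaccard", "csi", "gmean", "kappa")
        base = dict(zip(cols, [90.0, 90.0, 90.0, 0.5, 0.9, 10.0, 80.0, 80.0,
                               90.0, 0.5]))
        better = {**base, "mcc": 0.8}
        report = aggregate_report([("none", "DCT", "A", base),
                                   ("none", "PCA", "B", better)])
        assert report["best_configuration"]["extraction"] == "PCA"

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])


class TestPublishedTables:
    def test_row_counts_and_internal_consistency(self):
        for rows in PUBLISHED_ROWS.values():
            assert len(rows) == 40
            for ext, clf, acc, prec, f1, mcc, fm, err, jac, csi, gm, kap in rows:
                assert acc + err == pytest.approx(100.0, abs=0.02)
                f = f1 / 100
                assert jac == pytest.approx(100 * f / (2 - f), abs=0.02)

    def test_accuracy_means(self):
        from microsel.metrics import mean_2dp
        assert mean_2dp(accuracies("none")) == 69.02  # exact mean 69.025
        assert mean_2dp(accuracies("harmony_search")) == 73.16
        assert mean_2dp(accuracies("firefly")) == 75.07
        assert mean_2dp(accuracies("eho")) == 79.19
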