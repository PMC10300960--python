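"""Thresholding, confusion counts, ROC construction, AUC and the metric
battery, each checked against brute-force or rank-statistic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamdetect.detection import (
    ConfusionCounts,
    LabelSeries,
    ThresholdConfig,
    auc,
    confusion,
    detect,
    label_by_energy,
    metrics,
    pct,
    rates,
    read_labels,
    roc_curve,
    roc_optimal_threshold,
    threshold_value,
)


def _mann_whitney_auc(values, labels):
    """Rank-statistic oracle: (concordant pairs + half ties) / (P*N)."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def _optimal_by_midpoint_search(values, labels, polarity="high_is_positive"):
    """Exhaustive oracle: try midpoints between sorted distinct values plus
    cutoffs beyond both extremes; return the best (distance, -tpr, fpr)."""
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[distinct[0] - 1], mids, distinct, [distinct[-1] + 1]])
    best = None
    for c in candidates:
        pred = values > c if polarity == "high_is_positive" else values < c
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        tpr = tp / labels.sum()
        fpr = fp / (labels.size - labels.sum())
        key = (np.hypot(fpr, 1 - tpr), -tpr, fpr)
        if best is None or key < best:
            best = key
    return best


class TestLabelByEnergy:
    def test_strict_greater_boundary(self):
        out = label_by_energy(np.array([1.0, 4.0, 3.09]), threshold=3.09)
        np.testing.assert_array_equal(out.labels, [0, 1, 0])

    def test_all_below_gives_zeros(self):
        out = label_by_energy(np.array([0.1, 0.2]), threshold=1.0)
        np.testing.assert_array_equal(out.labels, 0)

    def test_noise_free_recording_recovers_generator_truth(self):
        from pamdetect.audio import segment
        from conftest import small_synth_config
        from pamdetect.synth import generate

        lab = generate(small_synth_config(seed=5, noise_sd=0.0))
        segs = segment(lab.recording, 200.0)
        energies = np.array([np.sum(s.samples**2) for s in segs])
        out = label_by_energy(energies, threshold=0.0)
        np.testing.assert_array_equal(out.labels, lab.labels)


class TestThresholdValue:
    def test_median(self):
        cfg = ThresholdConfig(method="median")
        assert threshold_value(np.array([1.0, 2.0, 3.0]), cfg) == 2.0

    def test_median_plus_mad(self):
        cfg = ThresholdConfig(method="median_plus_M_dev", M=2.0)
        v = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        med = 3.0
        mad = np.median(np.abs(v - med))
        assert threshold_value(v, cfg) == med + 2.0 * mad

    def test_separable_optimal_reaches_corner(self):
        values = np.array([5.0, 6.0, 7.0, 1.0, 2.0])
        truth = LabelSeries(labels=np.array([1, 1, 1, 0, 0]))
        cut = roc_optimal_threshold(values, truth)
        pred = detect(values, cut)
        c = confusion(pred, truth)
        assert rates(c) == (1.0, 0.0)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            threshold_value(np.array([]), ThresholdConfig())

    @pytest.mark.parametrize("seed", range(20))
    def test_optimal_matches_exhaustive_midpoint_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        values = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        truth = LabelSeries(labels=labels)
        cut = roc_optimal_threshold(values, truth)
        pred = detect(values, cut)
        tpr, fpr = rates(confusion(pred, truth))
        got = (np.hypot(fpr, 1 - tpr), -tpr, fpr)
        assert got == pytest.approx(_optimal_by_midpoint_search(values, labels))


class TestDetect:
    def test_high_polarity(self):
        out = detect(np.array([5.0, 1.0]), cutoff=3.0, polarity="high_is_positive")
        np.testing.assert_array_equal(out.labels, [1, 0])

    def test_low_polarity(self):
        out = detect(np.array([5.0, 1.0]), cutoff=3.0, polarity="low_is_positive")
        np.testing.assert_array_equal(out.labels, [0, 1])

    def test_cutoff_above_max_detects_nothing(self):
        out = detect(np.array([5.0, 1.0]), cutoff=10.0)
        np.testing.assert_array_equal(out.labels, 0)


class TestConfusion:
    def test_perfect_agreement(self):
        p = LabelSeries(labels=np.array([1, 0, 1]))
        c = confusion(p, p)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_total_disagreement(self):
        t = LabelSeries(labels=np.array([1, 0, 1]))
        p = LabelSeries(labels=1 - t.labels)
        c = confusion(p, t)
        assert c.tp == 0 and c.tn == 0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(11)
        p = LabelSeries(labels=rng.integers(0, 2, 100))
        t = LabelSeries(labels=rng.integers(0, 2, 100))
        c = confusion(p, t)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for a, b in zip(p.labels, t.labels):
            tally[{(1, 1): "tp", (1, 0): "fp", (0, 0): "tn", (0, 1): "fn"}[(a, b)]] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == tuple(tally.values())
        assert c.tp + c.fn == t.labels.sum()
        assert c.fp + c.tn == (1 - t.labels).sum()

    def test_zone_breakdown(self):
        t = LabelSeries(labels=np.array([1, 1, 0, 0]),
                        zones=np.array(["A", "B", "A", None], dtype=object))
        p = LabelSeries(labels=np.array([1, 1, 1, 1]))
        c = confusion(p, t)
        assert c.per_zone == {"A": (1, 1), "B": (1, 0)}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(LabelSeries(labels=np.array([1])), LabelSeries(labels=np.array([1, 0])))


class TestRates:
    def test_reported_true_positive_rate(self):
        # 148 detections out of 175 positives
        c = ConfusionCounts(tp=148, fp=0, tn=0, fn=27)
        tpr, _ = rates(c)
        assert pct(tpr) == 84.57

    def test_reported_false_positive_rate(self):
        # 124 false alarms against 325 negatives
        c = ConfusionCounts(tp=0, fp=124, tn=201, fn=0)
        _, fpr = rates(c)
        assert pct(fpr) == 38.15

    def test_empty_positive_class_rate_is_zero(self):
        c = ConfusionCounts(tp=0, fp=1, tn=1, fn=0)
        tpr, _ = rates(c)
        assert tpr == 0.0


class TestROC:
    def test_separable_curve_passes_through_corner(self):
        values = np.array([4.0, 5.0, 6.0, 1.0, 2.0])
        truth = LabelSeries(labels=np.array([1, 1, 1, 0, 0]))
        roc = roc_curve(values, truth)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(roc.fpr, roc.tpr))
        assert auc(roc) == 1.0

    def test_constant_features_give_chance_auc(self):
        values = np.full(10, 2.0)
        truth = LabelSeries(labels=np.array([1, 0] * 5))
        roc = roc_curve(values, truth)
        assert auc(roc) == pytest.approx(0.5)

    def test_anti_separated_auc_is_zero(self):
        values = np.array([1.0, 2.0, 8.0, 9.0])
        truth = LabelSeries(labels=np.array([1, 1, 0, 0]))
        assert auc(roc_curve(values, truth)) == 0.0

    def test_monotone_sweep(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=60)
        truth = LabelSeries(labels=rng.integers(0, 2, 60))
        roc = roc_curve(values, truth)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_points_match_per_cutoff_confusion(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=40)
        truth = LabelSeries(labels=rng.integers(0, 2, 40))
        roc = roc_curve(values, truth)
        for cut, tpr, fpr in zip(roc.thresholds, roc.tpr, roc.fpr):
            c = confusion(detect(values, cut), truth)
            assert rates(c) == (tpr, fpr)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([1.0, 2.0]), LabelSeries(labels=np.array([1, 1])))

    def test_polarity_reversal_complements_auc(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=50)  # continuous: no ties
        truth = LabelSeries(labels=rng.integers(0, 2, 50))
        hi = auc(roc_curve(values, truth, polarity="high_is_positive"))
        lo = auc(roc_curve(values, truth, polarity="low_is_positive"))
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_auc_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        values = np.round(rng.normal(size=80), 1)
        labels = rng.integers(0, 2, 80)
        truth = LabelSeries(labels=labels)
        ours = auc(roc_curve(values, truth))
        ref = sklearn_metrics.roc_auc_score(labels, values)
        assert ours == pytest.approx(ref, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_auc_equals_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        values = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        truth = LabelSeries(labels=labels)
        assert auc(roc_curve(values, truth)) == pytest.approx(
            _mann_whitney_auc(values, labels), abs=1e-12
        )


class TestMetrics:
    def test_reported_metric_battery(self):
        c = ConfusionCounts(tp=148, fp=69, tn=256, fn=27)
        m = metrics(c)
        assert pct(m.precision) == 68.20
        assert pct(m.recall) == 84.57
        assert pct(m.f1) == 75.51

    def test_perfect_detector(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(8)
        tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, 4))
        m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        assert m.precision == pytest.approx(tp / (tp + fp))
        assert m.recall == pytest.approx(tp / (tp + fn))
        assert m.f1 == pytest.approx(2 * m.precision * m.recall / (m.precision + m.recall))

    def test_degenerate_counts_give_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0


class TestLabelIO:
    def test_roundtrip(self, tmp_path):
        from pamdetect.synth import write_labels
        import pandas as pd

        df = pd.DataFrame({"segment": range(5), "label": [0, 1, 1, 0, 0]})
        write_labels(df, tmp_path / "l.csv")
        back = read_labels(tmp_path / "l.csv")
        np.testing.assert_array_equal(back.labels, [0, 1, 1, 0, 0])

    def test_empty_series(self, tmp_path):
        from pamdetect.synth import write_labels
        import pandas as pd

        write_labels(pd.DataFrame({"segment": [], "label": []}), tmp_path / "e.csv")
        back = read_labels(tmp_path / "e.csv")
        assert back.labels.size == 0

    def test_missing_label_column_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="label"):
            read_labels(tmp_path / "bad.csv")
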