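"""Confusion metrics, AUC, DeLong test and the printed-table reconstruction."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_curve

from slicefuse.stats import (
    ConfusionMatrix,
    auc_mann_whitney,
    confusion_from_scores,
    delong_paired_test,
    metrics_from_confusion,
    pool_confusions,
    reconstruct_confusion_from_printed,
    roc_result,
)


class TestConfusionFromScores:
    def test_direct_count(self):
        cm = confusion_from_scores([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_all_above_threshold(self):
        cm = confusion_from_scores([1, 0, 1], [0.9, 0.8, 0.7])
        assert cm.fn == 0 and cm.tn == 0

    def test_zero_threshold_everything_positive(self):
        cm = confusion_from_scores([1, 0], [0.0, 0.0], threshold=0.0)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 0, 1, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_scores([1, 0], [0.5])


class TestPooling:
    def test_elementwise_sum(self):
        pooled = pool_confusions(
            [ConfusionMatrix(1, 2, 3, 4), ConfusionMatrix(4, 3, 2, 1)]
        )
        assert (pooled.tp, pooled.fn, pooled.fp, pooled.tn) == (5, 5, 5, 5)

    def test_single_fold_identity(self):
        cm = ConfusionMatrix(7, 1, 2, 3)
        assert pool_confusions([cm]) == cm

    def test_pooling_commutes_with_metrics(self):
        # metrics on the pooled matrix == metrics on the unpartitioned predictions
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        parts = np.array_split(np.arange(200), 5)
        pooled = pool_confusions(
            [confusion_from_scores(labels[p], scores[p]) for p in parts]
        )
        assert pooled == confusion_from_scores(labels, scores)


class TestMetrics:
    def test_pooled_clinical_scale_matrix(self):
        # integer matrix uniquely reconstructed from a printed 2-dp row
        rep = metrics_from_confusion(ConfusionMatrix(tp=1868, fn=91, fp=132, tn=691))
        assert round(rep.accuracy.value, 2) == 91.98
        assert round(rep.precision.value, 2) == 93.40
        assert round(rep.recall.value, 2) == 95.35

    def test_perfect_classifier(self):
        rep = metrics_from_confusion(ConfusionMatrix(10, 0, 0, 10))
        assert (rep.accuracy.value, rep.precision.value, rep.recall.value) == (100, 100, 100)

    def test_symmetric_case(self):
        rep = metrics_from_confusion(ConfusionMatrix(5, 5, 5, 5))
        assert (rep.accuracy.value, rep.precision.value, rep.recall.value) == (50, 50, 50)

    def test_ci_contains_point_estimate(self):
        rep = metrics_from_confusion(ConfusionMatrix(80, 20, 10, 90))
        for m in (rep.accuracy, rep.precision, rep.recall):
            assert m.ci_low <= m.value <= m.ci_high
            assert 0 <= m.ci_low and m.ci_high <= 100

    def test_zero_denominator_flagged_undefined(self):
        rep = metrics_from_confusion(ConfusionMatrix(0, 0, 0, 10))
        assert not rep.precision.defined and not rep.recall.defined
        assert rep.accuracy.value == 100


class TestAuc:
    def test_pair_counting_example(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        assert auc_mann_whitney(labels, scores) == pytest.approx(8 / 9)

    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert auc_mann_whitney([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 1], [0.2, 0.3])

    def test_equals_trapezoidal_roc_area(self):
        # dual route: rank statistic vs geometric area, 100 random instances
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            fpr, tpr, _ = roc_curve(labels, scores)
            assert auc_mann_whitney(labels, scores) == pytest.approx(
                np.trapezoid(tpr, fpr), abs=1e-12
            )

    def test_roc_result_curve_monotone(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        res = roc_result(labels, rng.random(60))
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert 0 <= res.auc <= 1


class TestDeLong:
    def _paired_case(self, seed=7, n=40):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        latent = rng.normal(size=n)
        scores_a = latent + np.where(labels == 1, 1.0, 0.0) + 0.5 * rng.normal(size=n)
        scores_b = latent + np.where(labels == 1, 0.6, 0.0) + 0.5 * rng.normal(size=n)
        return labels, scores_a, scores_b

    def test_identical_classifiers(self):
        labels, s, _ = self._paired_case()
        out = delong_paired_test(labels, s, s)
        assert out.delta == 0 and out.p_value == 1.0

    def test_relabeling_invariance(self):
        labels, sa, sb = self._paired_case()
        perm = np.random.default_rng(0).permutation(len(labels))
        a = delong_paired_test(labels, sa, sb)
        b = delong_paired_test(labels[perm], sa[perm], sb[perm])
        assert a.delta == pytest.approx(b.delta)
        assert a.p_value == pytest.approx(b.p_value)

    def test_agrees_with_bootstrap_oracle(self):
        # independent oracle: stratified case-resampling bootstrap of the
        # paired AUC difference, normal-theory p from the bootstrap SD
        labels, sa, sb = self._paired_case(seed=7, n=40)
        result = delong_paired_test(labels, sa, sb)

        rng = np.random.default_rng(123)
        pos, neg = np.where(labels == 1)[0], np.where(labels == 0)[0]
        n_boot, deltas = 200_000, []
        for start in range(0, n_boot, 20_000):
            b = min(20_000, n_boot - start)
            pi = rng.integers(0, len(pos), size=(b, len(pos)))
            ni = rng.integers(0, len(neg), size=(b, len(neg)))
            pa, na = sa[pos][pi], sa[neg][ni]
            pb, nb = sb[pos][pi], sb[neg][ni]
            auc_a = (
                (pa[:, :, None] > na[:, None, :]).mean(axis=(1, 2))
                + 0.5 * (pa[:, :, None] == na[:, None, :]).mean(axis=(1, 2))
            )
            auc_b = (
                (pb[:, :, None] > nb[:, None, :]).mean(axis=(1, 2))
                + 0.5 * (pb[:, :, None] == nb[:, None, :]).mean(axis=(1, 2))
            )
            deltas.append(auc_a - auc_b)
        sd = np.concatenate(deltas).std(ddof=1)
        p_boot = 2 * norm.sf(abs(result.delta) / sd)
        assert result.p_value == pytest.approx(p_boot, abs=0.02)

    def test_variance_matches_resimulation(self):
        # DeLong variance of a single AUC vs the empirical variance of AUC
        # over 2,000 resimulations of a fixed score-generating model
        rng = np.random.default_rng(5)
        m = n = 100

        def simulate():
            labels = np.array([1] * m + [0] * n)
            scores = np.concatenate([rng.normal(1.0, 1.0, m), rng.normal(0.0, 1.0, n)])
            return labels, scores

        aucs, delong_vars = [], []
        for i in range(2000):
            labels, scores = simulate()
            aucs.append(auc_mann_whitney(labels, scores))
            if i < 100:
                delong_vars.append(roc_result(labels, scores).delong_variance)
        empirical = np.var(aucs, ddof=1)
        assert np.mean(delong_vars) == pytest.approx(empirical, rel=0.15)

    def test_degenerate_flagged(self):
        labels = np.array([1, 1, 0, 0])
        out = delong_paired_test(labels, [0.9, 0.8, 0.2, 0.1], [0.1, 0.2, 0.8, 0.9])
        assert out.degenerate


class TestReconstruction:
    # printed 2-dp (recall, precision) pairs with class totals 1,959/823 and
    # the unique integer matrix each pair pins down
    ROWS = [
        (93.11, 91.11, (1824, 135, 178, 645), 88.75),
        (93.77, 92.78, (1837, 122, 143, 680), 90.47),
        (92.09, 93.13, (1804, 155, 133, 690), 89.65),
        (94.38, 92.91, (1849, 110, 141, 682), 90.98),
        (95.25, 92.56, (1866, 93, 150, 673), 91.27),
        (95.35, 93.40, (1868, 91, 132, 691), 91.98),
    ]

    @pytest.mark.parametrize("recall,precision,expected,accuracy", ROWS)
    def test_unique_matrix_and_accuracy(self, recall, precision, expected, accuracy):
        out = reconstruct_confusion_from_printed(1959, 823, recall, precision)
        assert len(out) == 1
        cm = out[0]
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == expected
        assert round(100 * (cm.tp + cm.tn) / cm.n, 2) == accuracy

    def test_perfect_row(self):
        out = reconstruct_confusion_from_printed(10, 10, 100.00, 100.00)
        assert out == [ConfusionMatrix(10, 0, 0, 10)]

    def test_inconsistent_row_is_empty(self):
        # recall 99.99% is unreachable with 10 positives
        assert reconstruct_confusion_from_printed(10, 10, 99.99, 50.00) == []
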