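"""Metrics: accuracy, confusion percentage conventions, one-vs-rest
metrics against brute-force oracles, and ICC(2,1) agreement."""

import numpy as np
import pytest

from vhsnet.errors import DomainError
from vhsnet.evaluation import (ConfusionMatrix, confusion, icc_agreement,
                               metrics_report, one_vs_rest_metrics,
                               overall_accuracy, percentages, plot_confusion)


class TestOverallAccuracy:
    @pytest.mark.parametrize("yt, yp, expected", [
        ([0, 1, 2, 1], [0, 1, 2, 1], 1.0),
        ([0, 0, 1], [1, 1, 2], 0.0),
        ([0, 1, 2, 1], [0, 1, 1, 1], 0.75),
    ])
    def test_hand_counts(self, yt, yp, expected):
        assert overall_accuracy(yt, yp) == expected

    def test_errors(self):
        with pytest.raises(DomainError):
            overall_accuracy([0, 1], [0])
        with pytest.raises(DomainError):
            overall_accuracy([], [])
        with pytest.raises(DomainError):
            overall_accuracy([0, 3], [0, 1])


class TestConfusion:
    def test_percentage_conventions_from_printed_counts(self):
        """Row of (30, 3, 0) small-heart counts in a 200-sample set gives a
        90.9% row-correct, 15.0% cell-of-total and 9.1% row-error."""
        counts = np.array([[30, 3, 0], [4, 71, 10], [0, 12, 70]])
        cm = ConfusionMatrix(counts=counts)
        assert cm.n == 200
        pct = percentages(cm)
        assert pct["row_correct_pct"][0] == 90.9
        assert pct["cell_pct"][0, 0] == 15.0
        assert pct["row_pct"][0, 1] == 9.1
        assert pct["cell_pct"][0, 1] == 1.5

    def test_row_percentages_sum_to_100(self, rng):
        yt = rng.integers(0, 3, 500)
        yp = rng.integers(0, 3, 500)
        pct = percentages(confusion(yt, yp))
        np.testing.assert_allclose(pct["row_pct"].sum(axis=1), 100.0, atol=0.15)

    def test_identity_predictions_diagonal(self):
        y = [0, 0, 1, 2, 2, 2]
        cm = confusion(y, y)
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)
        assert list(percentages(cm)["row_correct_pct"]) == [100.0, 100.0, 100.0]

    def test_single_sample(self):
        cm = confusion([1], [2])
        assert percentages(cm)["cell_pct"][1, 2] == 100.0

    def test_trace_equals_accuracy(self, rng):
        yt = rng.integers(0, 3, 321)
        yp = rng.integers(0, 3, 321)
        cm = confusion(yt, yp)
        assert np.trace(cm.counts) / cm.n == overall_accuracy(yt, yp)

    def test_plot_written(self, tmp_path):
        cm = confusion([0, 1, 2, 1], [0, 1, 1, 1])
        plot_confusion(cm, tmp_path / "cm.png")
        assert (tmp_path / "cm.png").stat().st_size > 0


def auc_pairwise_oracle(pos_mask, scores):
    """O(n^2) rank statistic: P(score_pos > score_neg), ties counted 1/2."""
    pos = scores[pos_mask]
    neg = scores[~pos_mask]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestOneVsRest:
    def _probs(self, rng, n):
        p = rng.dirichlet(np.ones(3), size=n)
        return p

    def test_perfect_separation_auc_one(self):
        yt = np.array([0, 0, 1, 1, 2, 2])
        probs = np.where(np.eye(3)[yt] > 0, 0.8, 0.1)
        m = one_vs_rest_metrics(yt, probs)
        for cls in ("small", "normal", "large"):
            assert m[cls]["auc"] == 1.0
            assert m[cls]["sensitivity"] == 1.0

    def test_auc_matches_pairwise_oracle(self, rng):
        for n in (20, 87, 200):
            yt = rng.integers(0, 3, n)
            probs = self._probs(rng, n)
            m = one_vs_rest_metrics(yt, probs)
            for k, cls in enumerate(("small", "normal", "large")):
                expected = auc_pairwise_oracle(yt == k, probs[:, k])
                assert m[cls]["auc"] == pytest.approx(expected, abs=1e-12)

    def test_uninformative_scores_auc_half(self, rng):
        yt = rng.integers(0, 3, 60)
        probs = np.full((60, 3), 1 / 3)
        m = one_vs_rest_metrics(yt, probs)
        for cls in ("small", "normal", "large"):
            assert m[cls]["auc"] == pytest.approx(0.5)

    def test_hand_tallied_contingency(self):
        # class 0: TP=2, FP=1, FN=0, TN=3
        yt = np.array([0, 0, 1, 1, 2, 2])
        probs = np.array([[.8, .1, .1], [.7, .2, .1], [.6, .3, .1],
                          [.1, .8, .1], [.1, .1, .8], [.2, .2, .6]])
        m = one_vs_rest_metrics(yt, probs)["small"]
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(3 / 4)
        assert m["sensitivity"] == 1.0

    def test_absent_class_auc_missing(self):
        yt = np.array([1, 1, 2, 2])
        probs = np.full((4, 3), 1 / 3)
        m = one_vs_rest_metrics(yt, probs)
        assert m["small"]["auc"] is None


def icc21_mean_squares_oracle(x):
    """Hand ANOVA decomposition for an n x k table (independent route)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_ratings_give_one(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        assert icc_agreement(a, a) == pytest.approx(1.0)

    def test_mirrored_ratings_negative(self):
        a = np.array([1.0, -2.0, 3.0, -4.0])
        assert icc_agreement(a, -a) < 0

    def test_small_table_matches_hand_anova(self):
        x = np.array([[9.1, 9.3], [7.8, 8.1], [10.6, 10.2], [8.4, 8.4]])
        expected = icc21_mean_squares_oracle(x)
        assert icc_agreement(x[:, 0], x[:, 1]) == pytest.approx(expected, abs=1e-9)

    def test_symmetric(self, rng):
        a = rng.normal(size=50)
        b = a + rng.normal(scale=0.1, size=50)
        assert icc_agreement(a, b) == pytest.approx(icc_agreement(b, a), abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        a = rng.normal(10, 2, size=40)
        b = a + rng.normal(0, 0.5, size=40) + 0.3
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(40), 2),
            "raters": np.tile([0, 1], 40),
            "ratings": np.stack([a, b], axis=1).ravel()})
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]   # naming differs by version
        icc2 = float(row["ICC"].iloc[0])
        assert icc_agreement(a, b) == pytest.approx(icc2, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(DomainError):
            icc_agreement([1.0], [1.0])


def test_metrics_report_bundle(rng):
    yt = rng.integers(0, 3, 120)
    probs = rng.dirichlet(np.ones(3), size=120)
    yp = probs.argmax(axis=1)
    rep = metrics_report(yt, yp, probs, icc_pair=(yt.astype(float), yt.astype(float) + 0.01))
    d = rep.to_dict()
    assert d["overall_accuracy"] == overall_accuracy(yt, yp)
    assert np.isclose(np.sum(d["confusion_counts"]), 120)
    assert rep.icc > 0.99
    assert "ICC(2,1)" in rep.to_text()
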