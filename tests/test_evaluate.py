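import numpy as np
import pytest
from scipy import stats

from somaclass.evaluate import (
    ConfusionCounts,
    SampleSummary,
    binary_metrics,
    bias_report,
    confusion_from_calls,
    exact_auc,
    explain_tpr,
    fp_tn_contingency,
    ols,
    roc_pr_by_quantiles,
    tmb_concordance,
)


class TestBinaryMetrics:
    def test_published_confusion_row_reproduced(self):
        # attentive-model overall row of the first blind test set
        m = binary_metrics(ConfusionCounts(tp=28184, fp=5397, fn=2086, tn=25962))
        assert round(m.tpr, 3) == 0.931
        assert round(m.tnr, 3) == 0.828
        assert round(m.ppv, 3) == 0.839
        assert round(m.npv, 3) == 0.926
        assert round(m.mcc, 3) == 0.762
        assert round(m.balanced_accuracy, 3) == 0.879

    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionCounts(10, 0, 0, 10))
        assert m.tpr == m.tnr == m.ppv == m.npv == 1.0
        assert m.mcc == 1.0

    def test_mcc_degenerate_reported_zero_with_flag(self):
        m = binary_metrics(ConfusionCounts(0, 0, 10, 10))
        assert m.tpr == 0.0
        assert m.mcc == 0.0
        assert m.mcc_degenerate

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_absent_rates_when_empty_denominator(self):
        m = binary_metrics(ConfusionCounts(0, 0, 0, 10))
        assert m.tpr is None
        assert m.balanced_accuracy is None

    def test_confusion_from_calls(self):
        calls = np.array([1, 1, 0, 0, 1])
        labels = np.array([1, 0, 1, 0, 1])
        c = confusion_from_calls(calls, labels)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)
        assert c.n_somatic == 3 and c.n_germline == 2


class TestAuc:
    def test_perfect(self):
        labels = np.array([0, 0, 1, 1])
        sweep = roc_pr_by_quantiles(labels.astype(float), labels)
        assert sweep.auc == pytest.approx(1.0, abs=1e-9)

    def test_random_posteriors_near_half(self):
        rng = np.random.default_rng(123)
        n = 10_000
        labels = rng.integers(0, 2, n)
        post = rng.random(n)  # independent of labels
        assert abs(exact_auc(post, labels) - 0.5) < 0.02
        assert abs(roc_pr_by_quantiles(post, labels).auc - 0.5) < 0.02

    def test_quantile_grid_matches_exact_rank_auc(self):
        rng = np.random.default_rng(7)
        n = 5000
        labels = rng.integers(0, 2, n)
        post = np.clip(labels * 0.3 + rng.normal(0.4, 0.2, n), 0, 1)
        exact = exact_auc(post, labels)
        grid = roc_pr_by_quantiles(post, labels, n_quantiles=500).auc
        assert abs(grid - exact) < 1e-3

    def test_exact_auc_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, 500)
        post = rng.random(500)
        assert exact_auc(post, labels) == pytest.approx(
            roc_auc_score(labels, post), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 2000)
        post = rng.random(2000)
        a1 = roc_pr_by_quantiles(post, labels).auc
        a2 = roc_pr_by_quantiles(post**3, labels).auc
        assert abs(a1 - a2) < 1e-3

    def test_fpr_monotone(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 300)
        sweep = roc_pr_by_quantiles(rng.random(300), labels)
        assert np.all(np.diff(sweep.fpr) >= 0)
        assert sweep.fpr[0] == 0.0 and sweep.fpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_by_quantiles(np.array([0.1, 0.9]), np.array([1, 1]))


class TestRegression:
    def test_identity(self):
        x = np.arange(10.0)
        r = ols(x, x)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-9)

    def test_affine(self):
        x = np.arange(10.0)
        r = ols(x, 2 * x + 1)
        assert (r.r_squared, r.slope, r.intercept) == (
            pytest.approx(1.0), pytest.approx(2.0), pytest.approx(1.0)
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ols(np.ones(5), np.arange(5.0))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ols(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def _summaries(true_tmbs, naive=None, corrected=None, groups=None, mvtsm=None, tpr=None):
    out = []
    for i, t in enumerate(true_tmbs):
        out.append(
            SampleSummary(
                sample_id=f"P{i}",
                true_tmb=t,
                naive_tmb=naive[i] if naive is not None else t,
                corrected_tmb={"m": corrected[i]} if corrected is not None else {},
                group=groups[i] if groups is not None else None,
                mvtsm=mvtsm[i] if mvtsm is not None else None,
                tpr=tpr[i] if tpr is not None else None,
            )
        )
    return out


class TestTmbConcordance:
    def test_exact_agreement(self):
        s = _summaries(np.linspace(1, 10, 8))
        r = tmb_concordance(s, "naive")
        assert r.slope == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_affine_method_on_truth_axis(self):
        true = np.linspace(1, 10, 8)
        s = _summaries(true, naive=2 * true + 1)
        r = tmb_concordance(s, "naive", x_axis="truth")
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)

    def test_inflation_shallows_default_orientation(self):
        # heavy independent leakage on the estimate axis compresses the slope
        rng = np.random.default_rng(0)
        true = rng.uniform(1, 4, 60)
        naive = true + rng.uniform(5, 40, 60)
        r = tmb_concordance(_summaries(true, naive=naive), "naive")
        assert r.slope < 0.5
        assert r.r_squared < 0.5

    def test_unknown_method(self):
        with pytest.raises(KeyError):
            tmb_concordance(_summaries([1, 2, 3]), "nope")


class TestBiasReport:
    def test_null_case_not_significant(self):
        rng = np.random.default_rng(1)
        tmbs = rng.uniform(1, 5, 30)
        groups = ["A"] * 15 + ["B"] * 15
        rep = bias_report(_summaries(tmbs, groups=groups), methods=["truth"])
        assert rep["truth"]["p_value"] > 0.05

    def test_constructed_shift_significant(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(5, 15, 55)
        b = a[:12] + 20.0
        tmbs = np.concatenate([a, b])
        groups = ["white"] * 55 + ["black"] * 12
        rep = bias_report(_summaries(tmbs, groups=groups), methods=["truth"])
        assert rep["truth"]["p_value"] < 0.001
        meds = rep["truth"]["groups"]
        assert meds["black"]["median_tmb"] > meds["white"]["median_tmb"]

    def test_small_group_excluded(self):
        tmbs = [1.0] * 8
        groups = ["A"] * 4 + ["B"] * 2 + ["C"] * 2
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError):
                bias_report(_summaries(tmbs, groups=groups))

    def test_rank_sum_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(5, 1, 10), rng.normal(7, 1, 12)
        tmbs = np.concatenate([a, b])
        groups = ["A"] * 10 + ["B"] * 12
        rep = bias_report(_summaries(tmbs, groups=groups), methods=["truth"])
        assert rep["truth"]["p_value"] == pytest.approx(stats.ranksums(a, b).pvalue)


class TestExplainTpr:
    def test_exact_inverse_relationship(self):
        mv = np.linspace(0.1, 0.45, 10)
        s = _summaries(np.ones(10), mvtsm=mv, tpr=1 - mv)
        r = explain_tpr(s)
        assert r.slope == pytest.approx(-1.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_mvtsm_rejected(self):
        s = _summaries(np.ones(5), mvtsm=np.full(5, 0.3), tpr=np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            explain_tpr(s)

    def test_requires_three_complete(self):
        s = _summaries(np.ones(2), mvtsm=[0.1, 0.2], tpr=[0.9, 0.8])
        with pytest.raises(ValueError):
            explain_tpr(s)


class TestFpTnContingency:
    def test_published_proportions(self):
        # FP: 993/5397 nonzero (18%); TN: 3612/25962 nonzero (14%)
        calls = np.concatenate([np.ones(5397), np.zeros(25962)]).astype(int)
        labels = np.zeros(5397 + 25962, dtype=int)
        feature = np.concatenate(
            [np.ones(993), np.zeros(5397 - 993), np.ones(3612), np.zeros(25962 - 3612)]
        )
        res = fp_tn_contingency(calls, labels, feature)
        assert res["table"] == [[993, 4404], [3612, 22350]]
        assert round(100 * res["fp_nonzero_proportion"]) == 18
        assert round(100 * res["tn_nonzero_proportion"]) == 14
        assert res["fisher_p"] < 1e-5

    def test_all_zero_feature(self):
        calls = np.array([1, 1, 0, 0])
        labels = np.zeros(4, dtype=int)
        res = fp_tn_contingency(calls, labels, np.zeros(4))
        assert res["fp_nonzero_proportion"] == 0.0
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_symmetric_table_p_one(self):
        calls = np.array([1] * 10 + [0] * 10)
        labels = np.zeros(20, dtype=int)
        feature = np.array([1] * 5 + [0] * 5 + [1] * 5 + [0] * 5)
        res = fp_tn_contingency(calls, labels, feature)
        assert res["table"] == [[5, 5], [5, 5]]
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_empty_stratum_absent_p(self):
        calls = np.ones(4, dtype=int)
        labels = np.zeros(4, dtype=int)
        res = fp_tn_contingency(calls, labels, np.ones(4))
        assert res["fisher_p"] is None
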