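"""Benchmark metrics, ROC/PR sweeps, TMB concordance, and bias analyses.

Conventions: somatic is the positive class. TP = somatic called somatic,
FP = germline called somatic, FN = somatic called germline, TN = germline
called germline. AUC is computed with the exact rank statistic; the
quantile-grid sweep exists for curve construction and matches the exact
value to grid tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RegressionResult",
    "SampleSummary",
    "CurveSweep",
    "binary_metrics",
    "confusion_from_calls",
    "exact_auc",
    "roc_pr_by_quantiles",
    "ols",
    "tmb_concordance",
    "bias_report",
    "explain_tpr",
    "fp_tn_contingency",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_somatic(self) -> int:
        return self.tp + self.fn

    @property
    def n_germline(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    tpr: float | None
    tnr: float | None
    ppv: float | None
    npv: float | None
    mcc: float
    balanced_accuracy: float | None
    auc: float | None = None
    call_rate: float = 100.0
    stratum: str = "overall"
    mcc_degenerate: bool = False


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample quantities feeding the concordance / bias / TPR analyses."""

    sample_id: str
    true_tmb: float
    naive_tmb: float
    corrected_tmb: Mapping[str, float] = field(default_factory=dict)
    mvtsm: float | None = None
    group: str | None = None
    tpr: float | None = None

    @property
    def purity_proxy(self) -> float | None:
        return None if self.mvtsm is None else 2.0 * self.mvtsm


def _safe_ratio(num: int, denom: int) -> float | None:
    return num / denom if denom > 0 else None


def binary_metrics(counts: ConfusionCounts, stratum: str = "overall") -> MetricsReport:
    """Derived rates from a confusion matrix.

    MCC with a zero denominator is reported as 0 with a degeneracy flag.
    Rates with empty denominators are reported as absent (None).
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    tpr = _safe_ratio(tp, tp + fn)
    tnr = _safe_ratio(tn, tn + fp)
    ppv = _safe_ratio(tp, tp + fp)
    npv = _safe_ratio(tn, tn + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    balanced = None if tpr is None or tnr is None else (tpr + tnr) / 2
    return MetricsReport(
        tpr=tpr, tnr=tnr, ppv=ppv, npv=npv, mcc=mcc,
        balanced_accuracy=balanced, stratum=stratum, mcc_degenerate=degenerate,
    )


def confusion_from_calls(calls: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if calls.shape != labels.shape:
        raise ValueError("calls/labels shape mismatch")
    return ConfusionCounts(
        tp=int(np.sum((calls == 1) & (labels == 1))),
        fp=int(np.sum((calls == 1) & (labels == 0))),
        fn=int(np.sum((calls == 0) & (labels == 1))),
        tn=int(np.sum((calls == 0) & (labels == 0))),
    )


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------

def exact_auc(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Exact ROC AUC via the Mann-Whitney rank statistic (tie-aware)."""
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(p)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class CurveSweep:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float
    average_precision: float


def roc_pr_by_quantiles(
    posteriors: np.ndarray, labels: np.ndarray, n_quantiles: int = 500
) -> CurveSweep:
    """ROC and PR curves thresholded at the posterior quantile grid.

    The sweep always includes the degenerate endpoints (0,0) and (1,1) of
    ROC space; AUC is trapezoidal over the full sweep.
    """
    p = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("curve construction requires both classes")

    grid = np.unique(np.quantile(p, np.linspace(0.0, 1.0, n_quantiles)))
    # descending thresholds -> monotone non-decreasing FPR/TPR
    thresholds = grid[::-1]
    tprs, fprs, precs, recs = [0.0], [0.0], [1.0], [0.0]
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    y_sorted = y[order]
    cum_pos = np.cumsum(y_sorted[::-1])[::-1]  # positives with p >= p_sorted[i]
    cum_all = np.arange(len(p), 0, -1)
    for t in thresholds:
        i = np.searchsorted(p_sorted, t, side="left")
        n_called = int(cum_all[i]) if i < len(p) else 0
        tp = int(cum_pos[i]) if i < len(p) else 0
        fp = n_called - tp
        tprs.append(tp / n_pos)
        fprs.append(fp / n_neg)
        precs.append(tp / n_called if n_called else 1.0)
        recs.append(tp / n_pos)
    tprs.append(1.0)
    fprs.append(1.0)
    precs.append(n_pos / len(p))
    recs.append(1.0)

    fpr = np.asarray(fprs)
    tpr = np.asarray(tprs)
    auc = float(np.trapezoid(tpr, fpr))
    rec = np.asarray(recs)
    prec = np.asarray(precs)
    # step-wise average precision over the sweep
    ap = float(np.sum(np.diff(rec) * prec[1:]))
    return CurveSweep(
        thresholds=np.concatenate(([np.inf], thresholds, [-np.inf])),
        fpr=fpr, tpr=tpr, precision=prec, recall=rec, auc=auc, average_precision=ap,
    )


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple ordinary least squares of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"regression requires n >= 3, got {len(x)}")
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return RegressionResult(
        r_squared=r2, slope=float(slope), intercept=float(intercept), n=len(x)
    )


def _method_tmb(s: SampleSummary, method: str) -> float:
    if method == "naive":
        return s.naive_tmb
    if method == "truth":
        return s.true_tmb
    if method in s.corrected_tmb:
        return s.corrected_tmb[method]
    raise KeyError(f"sample {s.sample_id} has no TMB for method {method!r}")


def tmb_concordance(
    samples: Sequence[SampleSummary], method: str, x_axis: str = "method"
) -> RegressionResult:
    """Concordance regression between matched-normal (truth) and method TMB.

    ``x_axis="method"`` regresses truth TMB on the method estimate, matching
    the published concordance plots (a leakage-inflated estimator then shows
    a shallow slope). ``x_axis="truth"`` regresses the estimate on truth.
    """
    est = np.array([_method_tmb(s, method) for s in samples])
    true = np.array([s.true_tmb for s in samples])
    if x_axis == "method":
        return ols(est, true)
    if x_axis == "truth":
        return ols(true, est)
    raise ValueError(f"x_axis must be 'method' or 'truth', got {x_axis!r}")


# ---------------------------------------------------------------------------
# Bias and performance-explanation analyses
# ---------------------------------------------------------------------------

MIN_GROUP_SIZE = 3


def bias_report(
    samples: Sequence[SampleSummary], methods: Sequence[str] = ("truth", "naive")
) -> dict[str, dict]:
    """Per-method group TMB medians and two-sided Wilcoxon rank-sum p-values.

    Groups with fewer than 3 samples are excluded with a warning; at least
    two eligible groups are required.
    """
    groups: dict[str, list[SampleSummary]] = {}
    for s in samples:
        if s.group is not None:
            groups.setdefault(s.group, []).append(s)
    eligible = {}
    for g, members in sorted(groups.items()):
        if len(members) < MIN_GROUP_SIZE:
            warnings.warn(
                f"group {g!r} has {len(members)} < {MIN_GROUP_SIZE} samples; excluded",
                stacklevel=2,
            )
        else:
            eligible[g] = members
    if len(eligible) < 2:
        raise ValueError("bias report requires >= 2 groups with >= 3 samples each")
    if len(eligible) > 2:
        raise ValueError("bias report compares exactly 2 groups")
    (ga, mem_a), (gb, mem_b) = eligible.items()

    report: dict[str, dict] = {}
    for method in methods:
        a = np.array([_method_tmb(s, method) for s in mem_a])
        b = np.array([_method_tmb(s, method) for s in mem_b])
        stat = stats.ranksums(a, b)
        report[method] = {
            "groups": {ga: {"n": len(a), "median_tmb": float(np.median(a))},
                       gb: {"n": len(b), "median_tmb": float(np.median(b))}},
            "p_value": float(stat.pvalue),
        }
    return report


def explain_tpr(samples: Sequence[SampleSummary]) -> RegressionResult:
    """OLS of per-patient TPR on MVTSM (median VAF of true somatic mutations)."""
    pairs = [(s.mvtsm, s.tpr) for s in samples if s.mvtsm is not None and s.tpr is not None]
    if len(pairs) < 3:
        raise ValueError(f"explain_tpr requires n >= 3 complete samples, got {len(pairs)}")
    x, y = zip(*pairs)
    return ols(np.array(x), np.array(y))


def fp_tn_contingency(
    calls: np.ndarray, labels: np.ndarray, feature: np.ndarray
) -> dict:
    """2x2 table of {FP, TN} x {feature nonzero, feature zero} with Fisher p.

    Also reports the per-stratum nonzero proportions and feature means. The
    p-value is absent when either stratum is empty.
    """
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    feature = np.asarray(feature, dtype=float)
    fp_mask = (calls == 1) & (labels == 0)
    tn_mask = (calls == 0) & (labels == 0)
    fp_nz = int(np.sum(feature[fp_mask] > 0))
    tn_nz = int(np.sum(feature[tn_mask] > 0))
    n_fp = int(fp_mask.sum())
    n_tn = int(tn_mask.sum())
    table = [[fp_nz, n_fp - fp_nz], [tn_nz, n_tn - tn_nz]]
    p = None
    if n_fp > 0 and n_tn > 0:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {
        "table": table,
        "fp_nonzero_proportion": fp_nz / n_fp if n_fp else 0.0,
        "tn_nonzero_proportion": tn_nz / n_tn if n_tn else 0.0,
        "fp_feature_mean": float(feature[fp_mask].mean()) if n_fp else None,
        "tn_feature_mean": float(feature[tn_mask].mean()) if n_tn else None,
        "fisher_p": p,
    }
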