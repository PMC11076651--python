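"""Confusion-matrix metric suite, inverse reconstruction and reporting.

Ten metrics are derived from binary TP/FP/FN/TN tallies (accuracy,
precision, recall/specificity-based Gmean, F1, Fowlkes–Mallows, error
rate, Jaccard, CSI, MCC, Cohen's kappa).  An exhaustive inverse maps a
published (accuracy, precision, F1) triple back to every integer
confusion matrix consistent with it, which makes printed metric rows
arithmetically verifiable.  Descriptive statistics and the MCC/kappa
region-and-slope analysis complete the layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats


def mean_2dp(values) -> float:
    """Mean of 2-dp values, rounded half-to-even at 2 dp.

    Summation runs in integer hundredths, so boundary cases (a mean
    ending in exactly .xx5) round the way published averages do instead
    of drifting on accumulated binary error.
    """
    hundredths = [round(float(v) * 100) for v in values]
    return round(sum(hundredths) / len(hundredths)) / 100.0


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed metric tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# Confusion matrix and metric suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_label: object = 1

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred, positive_label=1) -> ConfusionMatrix:
    """Tally binary outcomes with respect to the positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        positive_label=positive_label,
    )


#: columns reported on the percent scale in published tables
PERCENT_METRICS = ("accuracy", "precision", "recall", "specificity", "f1",
                   "error_rate", "jaccard", "csi", "gmean")


@dataclass
class MetricSet:
    """Ten-metric suite, all values on the fraction scale ([0,1] or [-1,1]).

    ``degenerate`` lists metrics whose denominator was zero (reported
    as 0).  ``to_published_row`` applies the percent convention.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    fm: float
    error_rate: float
    jaccard: float
    csi: float
    gmean: float
    kappa: float
    degenerate: list = field(default_factory=list)

    def to_published_row(self, decimals: int = 2) -> dict:
        out = {}
        for name in ("accuracy", "precision", "f1", "mcc", "fm", "error_rate",
                     "jaccard", "csi", "gmean", "kappa"):
            value = getattr(self, name)
            if name in PERCENT_METRICS:
                value *= 100.0
            out[name] = round_half_away(value, decimals)
        return out


def _ratio(num: float, den: float, name: str, degenerate: list) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """All ten metrics from one confusion matrix.

    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); kappa uses
    chance agreement p_e = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/N²; FM is
    the geometric mean of precision and recall, Gmean that of recall
    and specificity; Jaccard and CSI are both TP/(TP+FP+FN).  Zero
    denominators yield 0 with the metric flagged degenerate.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = cm.n
    deg: list = []
    accuracy = (tp + tn) / n
    precision = _ratio(tp, tp + fp, "precision", deg)
    recall = _ratio(tp, tp + fn, "recall", deg)
    specificity = _ratio(tn, tn + fp, "specificity", deg)
    # count form of 2PR/(P+R): exact at rounding boundaries
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", deg)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(float(tp) * tn - float(fp) * fn, mcc_den, "mcc", deg)
    fm = math.sqrt(precision * recall)
    jaccard = _ratio(tp, tp + fp + fn, "jaccard", deg)
    gmean = math.sqrt(recall * specificity)
    p_e = (float(tp + fp) * (tp + fn) + float(fn + tn) * (fp + tn)) / (n * n)
    kappa = _ratio(accuracy - p_e, 1.0 - p_e, "kappa", deg)
    return MetricSet(
        accuracy=accuracy, precision=precision, recall=recall,
        specificity=specificity, f1=f1, mcc=mcc, fm=fm,
        error_rate=1.0 - accuracy, jaccard=jaccard, csi=jaccard,
        gmean=gmean, kappa=kappa, degenerate=deg,
    )


# ---------------------------------------------------------------------------
# Inverse reconstruction from printed (accuracy, precision, F1)
# ---------------------------------------------------------------------------

def reconstruct_confusion(accuracy_pct: float, precision_pct: float,
                          f1_pct: float, n_pos: int, n_neg: int,
                          positive_label: object = 1,
                          ulp_slack: int = 0) -> list[ConfusionMatrix]:
    """Every integer confusion matrix with the given class totals whose
    recomputed accuracy/precision/F1 round (half away from zero, 2 dp)
    to the printed percentages.  Exhaustive over TP ∈ [0, n_pos],
    FP ∈ [0, n_neg]; an empty list means no consistent matrix exists.

    ``ulp_slack`` widens the match to that many last-printed-digit
    units (0.01 each); published tables occasionally carry a one-ulp
    rounding error, and slack 1 recovers the intended matrix while
    normally preserving uniqueness."""
    for name, v in (("accuracy", accuracy_pct), ("precision", precision_pct),
                    ("f1", f1_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class totals must be >= 1")
    n = n_pos + n_neg
    tp = np.arange(n_pos + 1)[:, None].astype(float)
    fp = np.arange(n_neg + 1)[None, :].astype(float)
    fn = n_pos - tp
    tn = n_neg - fp
    acc = 100.0 * (tp + tn) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, 100.0 * tp / (tp + fp), 0.0)
        f1 = np.where(2 * tp + fp + fn > 0, 100.0 * 2 * tp / (2 * tp + fp + fn), 0.0)

    def _round2(a):
        return np.floor(a * 100.0 + 0.5) / 100.0  # half away (all values >= 0)

    tol = ulp_slack * 0.01 + 1e-9
    ok = ((np.abs(_round2(acc) - round_half_away(accuracy_pct)) <= tol)
          & (np.abs(_round2(prec) - round_half_away(precision_pct)) <= tol)
          & (np.abs(_round2(f1) - round_half_away(f1_pct)) <= tol))
    result = [
        ConfusionMatrix(tp=int(i), fp=int(j), fn=int(n_pos - i), tn=int(n_neg - j),
                        positive_label=positive_label)
        for i, j in zip(*np.nonzero(ok))
    ]
    return result


# ---------------------------------------------------------------------------
# Descriptive statistics of extracted feature sets
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    mean: float
    variance: float
    std_dev: float
    skewness: float
    kurtosis: float
    n_constant_excluded: int


@dataclass
class StatProfile:
    group_a: GroupStats
    group_b: GroupStats
    pcc: float
    ttest_t: float
    ttest_p: float
    cca: float


def _group_stats(X: np.ndarray, excess_kurtosis: bool) -> GroupStats:
    X = np.asarray(X, dtype=float)
    variances = X.var(axis=0)
    keep = variances > 0
    skew = _stats.skew(X[:, keep], axis=0)
    kurt = _stats.kurtosis(X[:, keep], axis=0, fisher=excess_kurtosis)
    return GroupStats(
        mean=float(X.mean()),
        variance=float(variances.mean()),
        std_dev=float(np.sqrt(variances).mean()),
        skewness=float(skew.mean()) if keep.any() else float("nan"),
        kurtosis=float(kurt.mean()) if keep.any() else float("nan"),
        n_constant_excluded=int((~keep).sum()),
    )


def _first_canonical_correlation(A: np.ndarray, B: np.ndarray,
                                 max_columns: int = 30) -> float:
    n = min(A.shape[0], B.shape[0])
    c = min(A.shape[1], B.shape[1], max_columns, max(n - 2, 1))
    A = A[:n, :c] - A[:n, :c].mean(axis=0)
    B = B[:n, :c] - B[:n, :c].mean(axis=0)
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return float(np.clip(s.max(initial=0.0), 0.0, 1.0))


def descriptive_stats(features_a: np.ndarray, features_b: np.ndarray,
                      excess_kurtosis: bool = True) -> StatProfile:
    """Per-group moments plus cross-group association terms.

    Moments are averaged over feature columns (constant columns are
    excluded from skewness/kurtosis, with the exclusion count
    reported).  PCC is the mean Pearson correlation between matched
    feature columns (rows truncated to the smaller group); the t-test
    is Welch's on the per-feature column means of the two groups; CCA
    is the first canonical correlation, column-capped for stability.
    Kurtosis is excess (Fisher) by default; pass False for Pearson.
    """
    A = np.atleast_2d(np.asarray(features_a, dtype=float))
    B = np.atleast_2d(np.asarray(features_b, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("both groups must be non-empty")
    n = min(A.shape[0], B.shape[0])
    c = min(A.shape[1], B.shape[1])
    with np.errstate(invalid="ignore"):
        cors = [
            _stats.pearsonr(A[:n, j], B[:n, j]).statistic
            for j in range(c)
            if A[:n, j].std() > 0 and B[:n, j].std() > 0
        ]
    pcc = float(np.mean(cors)) if cors else float("nan")
    tt = _stats.ttest_ind(A.mean(axis=0), B.mean(axis=0), equal_var=False)
    return StatProfile(
        group_a=_group_stats(A, excess_kurtosis),
        group_b=_group_stats(B, excess_kurtosis),
        pcc=pcc,
        ttest_t=float(tt.statistic),
        ttest_p=float(tt.pvalue),
        cca=_first_canonical_correlation(A, B),
    )


# ---------------------------------------------------------------------------
# MCC / kappa region analysis
# ---------------------------------------------------------------------------

#: MCC bands: low (near-chance), middle, high-performance
REGION_BOUNDS = {"R1": (0.0, 0.3), "R2": (0.3, 0.5), "R3": (0.6, 0.7)}


@dataclass(frozen=True)
class RegionLabel:
    mcc: float
    kappa: float
    region: str  # R1, R2, R3 or unclassified


def classify_region(mcc: float) -> str:
    if 0.0 <= mcc <= 0.3:
        return "R1"
    if 0.3 < mcc <= 0.5:
        return "R2"
    if 0.6 <= mcc <= 0.7:
        return "R3"
    return "unclassified"


def mcc_kappa_analysis(rows) -> tuple[list[RegionLabel], float]:
    """Label each (MCC, kappa) pair with its MCC region and report the
    least-squares slope of kappa regressed on MCC."""
    rows = [(float(m), float(k)) for m, k in rows]
    if len(rows) < 2:
        raise ValueError("need at least 2 rows for a slope")
    labels = [RegionLabel(m, k, classify_region(m)) for m, k in rows]
    mcc = np.array([m for m, _ in rows])
    kappa = np.array([k for _, k in rows])
    slope = float(np.polyfit(mcc, kappa, 1)[0])
    return labels, slope


# ---------------------------------------------------------------------------
# Report aggregation
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["selection", "extraction", "classifier", "accuracy",
                  "precision", "f1", "mcc", "fm", "error_rate", "jaccard",
                  "csi", "gmean", "kappa"]


def aggregate_report(results) -> dict:
    """Assemble per-selection tables and overall averages.

    ``results`` is an iterable of (selection, extraction, classifier,
    MetricSet | published-row dict).  The overall average per selection
    table is the arithmetic mean of its accuracy column; averages use
    round-half-even at 2 dp, which reproduces published cross-table
    averages exactly (including the .025 boundary case), while
    individual rows keep half-away-from-zero.  The best configuration
    maximizes accuracy with ties broken by MCC, then by name.
    """
    rows = []
    for selection, extraction, classifier, res in results:
        row = res.to_published_row() if isinstance(res, MetricSet) else dict(res)
        rows.append({"selection": selection, "extraction": extraction,
                     "classifier": classifier, **row})
    if not rows:
        raise ValueError("no result rows")
    df = pd.DataFrame(rows)
    tables = {sel: sub.drop(columns="selection").reset_index(drop=True)
              for sel, sub in df.groupby("selection", sort=False)}
    overall = {sel: mean_2dp(sub["accuracy"])
               for sel, sub in df.groupby("selection", sort=False)}
    best = df.sort_values(
        by=["accuracy", "mcc", "selection", "extraction", "classifier"],
        ascending=[False, False, True, True, True], kind="stable").iloc[0]
    return {
        "tables": tables,
        "overall_average_accuracy": overall,
        "best_configuration": {
            "selection": best["selection"], "extraction": best["extraction"],
            "classifier": best["classifier"], "accuracy": float(best["accuracy"]),
        },
    }
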