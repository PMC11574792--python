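"""Discrimination, calibration and cohort-comparison statistics.

Discrimination: AUROC via the rank (Mann-Whitney) statistic with a DeLong
95% confidence interval and the DeLong test for paired (correlated) ROC
curves.  Calibration: Brier score, log loss (clipped at 1e-15), and
reliability-curve points.  Cohort comparison: Mann-Whitney U for continuous
variables, chi-squared (Yates-corrected 2x2) for categorical ones, and
Cohen's d effect sizes, including a pooled Bernoulli-SD variant for binary
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

LOG_EPS = 1e-15


@dataclass
class PredictionSet:
    """Per-subject predicted ORN probabilities paired with true labels."""

    subject_ids: list
    probabilities: np.ndarray
    labels: np.ndarray
    cohort: str = "internal"
    fold_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.probabilities.shape != self.labels.shape:
            raise ValueError("probabilities and labels must align")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.subject_ids) != self.labels.size:
            raise ValueError("one subject id per prediction required")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "probability": self.probabilities,
                "label": self.labels,
                "cohort": self.cohort,
            }
        )
        if self.fold_ids is not None:
            out["fold"] = self.fold_ids
        return out


@dataclass
class EvaluationReport:
    """Discrimination + calibration summary for one model/cohort."""

    auroc: float
    auroc_ci: tuple[float, float]
    brier: float
    log_loss: float
    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float
    delong_p: float | None = None
    calibration: list = field(default_factory=list)
    n: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------- AUROC / DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_structural(y_true: np.ndarray, scores: np.ndarray):
    """DeLong placement values for one score vector.

    Returns (auc, V10 placements for positives, V01 for negatives).
    """
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the Mann-Whitney rank statistic (ties get half credit)."""
    a, _, _ = _delong_structural(np.asarray(labels), np.asarray(scores))
    return float(a)


def auroc_with_ci(
    preds: PredictionSet, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUROC with a DeLong-variance normal-approximation confidence interval."""
    a, v10, v01 = _delong_structural(preds.labels, preds.probabilities)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(a), float(max(0.0, a - z * se)), float(min(1.0, a + z * se))


def delong_test(preds_a: PredictionSet, preds_b: PredictionSet) -> float:
    """Two-sided DeLong p-value for equality of two correlated AUROCs.

    Both prediction sets must cover the same subjects in the same order with
    identical labels.
    """
    if list(preds_a.subject_ids) != list(preds_b.subject_ids) or not np.array_equal(
        preds_a.labels, preds_b.labels
    ):
        raise ValueError("DeLong test requires paired predictions on identical subjects")
    aa, v10a, v01a = _delong_structural(preds_a.labels, preds_a.probabilities)
    ab, v10b, v01b = _delong_structural(preds_b.labels, preds_b.probabilities)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    if var <= 0:
        return 1.0
    z = (aa - ab) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------- calibration


def brier(preds: PredictionSet) -> float:
    """Mean squared difference between forecast probability and outcome."""
    return float(np.mean((preds.probabilities - preds.labels) ** 2))


def log_loss(preds: PredictionSet) -> float:
    """Negative mean Bernoulli log-likelihood, probabilities clipped at 1e-15."""
    p = np.clip(preds.probabilities, LOG_EPS, 1.0 - LOG_EPS)
    y = preds.labels
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def classification_metrics(
    preds: PredictionSet, threshold: float = 0.5
) -> dict[str, float]:
    """Confusion-matrix metrics at a probability threshold (ties -> positive)."""
    y = preds.labels
    yhat = (preds.probabilities >= threshold).astype(int)
    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))

    def safe(num, den):
        return float(num / den) if den > 0 else float("nan")

    recall = safe(tp, tp + fn)
    precision = safe(tp, tp + fp)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "accuracy": safe(tp + tn, y.size),
        "recall": recall,
        "specificity": safe(tn, tn + fp),
        "precision": precision,
        "f1": float(f1),
    }


def calibration_curve(preds: PredictionSet, n_bins: int = 10) -> pd.DataFrame:
    """Reliability-curve points: per-bin mean forecast vs observed ORN fraction.

    Equal-width bins on [0, 1]; empty bins are omitted.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(preds.probabilities, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "mean_predicted": float(preds.probabilities[sel].mean()),
                "observed_fraction": float(preds.labels[sel].mean()),
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def evaluate(
    preds: PredictionSet,
    comparator: PredictionSet | None = None,
    threshold: float = 0.5,
    n_bins: int = 10,
) -> EvaluationReport:
    """Full discrimination + calibration report for one prediction set."""
    a, lo, hi = auroc_with_ci(preds)
    cls = classification_metrics(preds, threshold)
    return EvaluationReport(
        auroc=a,
        auroc_ci=(lo, hi),
        brier=brier(preds),
        log_loss=log_loss(preds),
        delong_p=None if comparator is None else delong_test(preds, comparator),
        calibration=calibration_curve(preds, n_bins).to_dict("records"),
        n=preds.labels.size,
        **cls,
    )


# ---------------------------------------------------------------- effect sizes


def cohens_d_binary(k1: int, n1: int, k2: int, n2: int) -> float:
    """Cohen's d for two proportions using the pooled Bernoulli SD.

    ``d = (p1 - p2) / sqrt((p1(1-p1) + p2(1-p2)) / 2)``; positive when group 1
    (by convention the ORN+ group) has the higher proportion.  Returns 0.0
    exactly for equal proportions, also when both variances vanish.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    if p1 == p2:
        return 0.0
    s = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if s == 0:
        return float("inf") if p1 > p2 else float("-inf")
    return float((p1 - p2) / s)


def cohens_d_continuous(x1: np.ndarray, x2: np.ndarray) -> float:
    """Cohen's d with the pooled (n-1 denominator) standard deviation."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need at least 2 observations per group")
    s2 = (
        (x1.size - 1) * np.var(x1, ddof=1) + (x2.size - 1) * np.var(x2, ddof=1)
    ) / (x1.size + x2.size - 2)
    if s2 == 0:
        raise ValueError("zero pooled SD: Cohen's d undefined")
    return float((x1.mean() - x2.mean()) / np.sqrt(s2))


def mann_whitney(x1: np.ndarray, x2: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value (normal approximation, tie-corrected)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(x1), np.sort(x2)) and np.unique(x1).size == 1:
        return 1.0  # degenerate all-tied case: no evidence of difference
    res = stats.mannwhitneyu(x1, x2, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def chi_squared(table: np.ndarray) -> float:
    """Chi-squared p-value on a 2x2 table with Yates continuity correction."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("chi-squared comparison expects a 2x2 table")
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


BINARY_VARIABLES = ("gender", "smoking", "pre_rt_extractions", "port", "chemotherapy")


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """A case-vs-control clinical summary table for one cohort.

    One row per variable: per-group summaries (count/% for binary variables,
    median/IQR for age), Mann-Whitney or chi-squared p-value, and Cohen's d.
    Primary-site rows carry distributions only (matching variable, no test).
    """
    cases = records[records["orn_label"] == 1]
    controls = records[records["orn_label"] == 0]
    n1, n2 = len(cases), len(controls)
    rows = []

    for site in sorted(records["primary_site"].unique()):
        k1 = int((cases["primary_site"] == site).sum())
        k2 = int((controls["primary_site"] == site).sum())
        rows.append(
            {
                "variable": f"primary_site:{site}",
                "orn_summary": f"{k1} ({100 * k1 / max(n1, 1):.0f}%)",
                "control_summary": f"{k2} ({100 * k2 / max(n2, 1):.0f}%)",
                "p_value": np.nan,
                "cohens_d": np.nan,
            }
        )

    age_p = mann_whitney(cases["age"], controls["age"])
    q1, q2 = cases["age"].quantile([0.25, 0.75]), controls["age"].quantile([0.25, 0.75])
    rows.append(
        {
            "variable": "age",
            "orn_summary": f"{cases['age'].median():.0f} ({q1.iloc[1] - q1.iloc[0]:.0f})",
            "control_summary": f"{controls['age'].median():.0f} ({q2.iloc[1] - q2.iloc[0]:.0f})",
            "p_value": age_p,
            "cohens_d": cohens_d_continuous(cases["age"], controls["age"]),
        }
    )

    for var in BINARY_VARIABLES:
        k1 = int(cases[var].sum())
        k2 = int(controls[var].sum())
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        rows.append(
            {
                "variable": var,
                "orn_summary": f"{k1} ({100 * k1 / n1:.0f}%)",
                "control_summary": f"{k2} ({100 * k2 / n2:.0f}%)",
                "p_value": chi_squared(table) if 0 < k1 + k2 < n1 + n2 else 1.0,
                "cohens_d": cohens_d_binary(k1, n1, k2, n2),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def covariate_shift_report(
    internal: pd.DataFrame, external: pd.DataFrame, d_threshold: float = 0.3
) -> pd.DataFrame:
    """Flag covariates whose prevalence shifts between cohorts.

    Compares overall (case+control) prevalences via the binary Cohen's d and
    flags |d| >= ``d_threshold``.
    """
    rows = []
    for var in BINARY_VARIABLES:
        k1, n1 = int(internal[var].sum()), len(internal)
        k2, n2 = int(external[var].sum()), len(external)
        d = cohens_d_binary(k1, n1, k2, n2)
        rows.append(
            {
                "variable": var,
                "internal_prevalence": k1 / n1,
                "external_prevalence": k2 / n2,
                "cohens_d": d,
                "shifted": bool(abs(d) >= d_threshold),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
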