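"""Logistic-regression NTCP baseline on DVH metrics + clinical covariates.

Two-stage feature handling mirrors common NTCP practice: first a Spearman
correlation pre-filter removes one member of every feature pair with
|rho| > 0.8 (keeping the member more associated with the outcome), then
stepwise forward selection adds features greedily while the AIC improves.
Fits go through statsmodels maximum-likelihood logistic regression;
quasi-separated fits fall back to an L2-penalised solution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from dosemap_ntcp.metrics import PredictionSet


@dataclass
class LRModel:
    """A fitted stepwise logistic NTCP model.

    Coefficients are on the original feature scale; ``selection_trace``
    records the criterion value at each forward step.
    """

    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    selection_trace: list[dict] = field(default_factory=list)
    separation_flagged: bool = False

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise KeyError(f"feature columns missing from table: {missing}")
        lin = np.full(len(table), self.intercept)
        for f in self.selected_features:
            lin = lin + self.coefficients[f] * table[f].to_numpy(dtype=float)
        return lin

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected_features": self.selected_features,
                    "coefficients": self.coefficients,
                    "intercept": self.intercept,
                    "selection_trace": self.selection_trace,
                    "separation_flagged": self.separation_flagged,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LRModel":
        return cls(**json.loads(Path(path).read_text()))


def spearman_prefilter(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop one member of every feature pair with |Spearman rho| > threshold.

    The member with the larger absolute univariable (Spearman) association
    with the label is kept; without labels the earlier column wins.  Constant
    columns (undefined rho) are dropped with a warning.  Returns the reduced
    table and a log of dropped columns with the pair that triggered each drop.
    """
    if table.shape[1] < 2:
        raise ValueError("pre-filter needs at least two feature columns")
    if table.columns.duplicated().any():
        raise ValueError("feature column names must be unique")
    if table.isna().any().any():
        raise ValueError("missing values are not allowed (no imputation)")

    cols = list(table.columns)
    dropped: list[dict] = []

    constant = [c for c in cols if table[c].nunique() <= 1]
    for c in constant:
        warnings.warn(f"constant feature column dropped: {c}", stacklevel=2)
        dropped.append({"dropped": c, "against": None, "rho": np.nan})
    cols = [c for c in cols if c not in constant]

    if labels is not None:
        labels = np.asarray(labels, dtype=float)
        relevance = {
            c: abs(stats.spearmanr(table[c], labels).statistic) for c in cols
        }
    else:
        relevance = {c: 0.0 for c in cols}

    rho = table[cols].corr(method="spearman").abs()
    keep = list(cols)
    for i, ci in enumerate(cols):
        if ci not in keep:
            continue
        for cj in cols[i + 1 :]:
            if cj not in keep:
                continue
            if rho.loc[ci, cj] > threshold:
                # keep the member more associated with the outcome
                if relevance[cj] > relevance[ci]:
                    loser, winner = ci, cj
                else:
                    loser, winner = cj, ci
                keep.remove(loser)
                dropped.append(
                    {"dropped": loser, "against": winner, "rho": float(rho.loc[ci, cj])}
                )
                if loser == ci:
                    break
    return table[keep], dropped


def _fit_logit(
    X: pd.DataFrame, y: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """MLE logistic fit; returns (params incl. const, aic, separation_flag)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            # coefficients this large on standardised features mean the MLE
            # is running off to infinity (quasi/perfect separation)
            if np.all(np.isfinite(res.params)) and np.all(np.abs(res.params) < 15):
                return res.params.to_numpy(), float(res.aic), False
        except Exception:
            pass
        # quasi/perfect separation: small-ridge fallback keeps coefficients finite
        res = sm.Logit(y, Xc).fit_regularized(
            disp=0, alpha=1e-3, L1_wt=0.0, maxiter=500
        )
        params = np.asarray(res.params, dtype=float)
        ll = sm.Logit(y, Xc).loglike(params)
        aic = float(2 * Xc.shape[1] - 2 * ll)
        return params, aic, True


def stepwise_forward_lr(
    table: pd.DataFrame,
    labels: np.ndarray,
    criterion: str = "aic",
    p_enter: float = 0.05,
    standardise: bool = True,
) -> LRModel:
    """Greedy forward selection of logistic-regression features.

    At each step the candidate whose addition most improves the criterion
    (AIC decrease by default; alternatively a likelihood-ratio test with
    ``criterion='lrt'`` and entry p-value ``p_enter``) joins the model;
    selection stops when no candidate improves.  Features are standardised
    internally for numerical stability; reported coefficients are rescaled
    to the original feature units.  Deterministic given the column order.
    """
    labels = np.asarray(labels, dtype=int)
    if min((labels == 0).sum(), (labels == 1).sum()) < 5:
        raise ValueError("need at least 5 subjects per class")

    work = table.astype(float).copy()
    scale: dict[str, tuple[float, float]] = {}
    if standardise:
        for c in work.columns:
            mu, sd = work[c].mean(), work[c].std(ddof=0)
            sd = sd if sd > 0 else 1.0
            scale[c] = (mu, sd)
            work[c] = (work[c] - mu) / sd
    else:
        scale = {c: (0.0, 1.0) for c in work.columns}

    selected: list[str] = []
    trace: list[dict] = []
    sep_flag = False
    _, current_aic, _ = _fit_logit(work[[]], labels)
    current_ll = -(current_aic - 2 * 1) / 2.0

    while True:
        remaining = [c for c in work.columns if c not in selected]
        if not remaining:
            break
        best: tuple[float, str, np.ndarray, float, bool] | None = None
        for cand in remaining:
            params, aic, flagged = _fit_logit(work[selected + [cand]], labels)
            if best is None or aic < best[0]:
                best = (aic, cand, params, aic, flagged)
        assert best is not None
        aic, cand, params, _, flagged = best
        if criterion == "lrt":
            k = len(selected) + 2
            new_ll = -(aic - 2 * k) / 2.0
            lr_stat = 2.0 * (new_ll - current_ll)
            p = stats.chi2.sf(max(lr_stat, 0.0), df=1)
            improves = p < p_enter
            crit_value = float(p)
            current_ll = new_ll if improves else current_ll
        else:
            improves = aic < current_aic
            crit_value = float(aic)
        if not improves:
            break
        selected.append(cand)
        current_aic = aic
        sep_flag = sep_flag or flagged
        trace.append({"feature": cand, "criterion": crit_value})

    params, _, flagged = _fit_logit(work[selected], labels)
    sep_flag = sep_flag or flagged

    # undo internal standardisation: beta_orig = beta_std / sd,
    # intercept_orig = const - sum beta_std * mu / sd
    intercept = float(params[0])
    coefs: dict[str, float] = {}
    for i, f in enumerate(selected):
        mu, sd = scale[f]
        b = float(params[i + 1]) / sd
        coefs[f] = b
        intercept -= b * mu
    return LRModel(
        selected_features=selected,
        coefficients=coefs,
        intercept=intercept,
        selection_trace=trace,
        separation_flagged=sep_flag,
    )


def predict_lr(
    model: LRModel,
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    cohort: str = "internal",
) -> PredictionSet:
    """Predicted ORN probabilities via the logistic link."""
    lin = model.linear_predictor(table)
    p = 1.0 / (1.0 + np.exp(-lin))
    y = np.zeros(len(table), dtype=int) if labels is None else np.asarray(labels)
    return PredictionSet(
        subject_ids=list(table.index),
        probabilities=p,
        labels=y,
        cohort=cohort,
    )
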