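"""Stratified nested cross-validation and external validation.

Internal validation uses a stratified nested 5-fold scheme: the outer loop
estimates generalisation, the inner loop (on the outer training set only)
selects hyperparameters, so every subject's prediction comes from a model
that never saw it — neither during training nor during model selection.
Predictions are pooled across outer folds for metric computation.

External validation applies frozen models to an independent cohort with no
parameter updates; for cross-validated model families the deployed model is
the ensemble average of the outer-fold models (configurable to a single
refit model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Protocol

import numpy as np
from sklearn.model_selection import StratifiedKFold

from dosemap_ntcp.metrics import PredictionSet


class LeakageError(RuntimeError):
    """A subject appeared on both sides of a train/test boundary."""


@dataclass
class CVPlan:
    """Fold assignments of a stratified nested cross-validation.

    ``outer_assignments[i]`` is subject i's outer test fold.  For each outer
    fold, ``inner_assignments[k]`` maps the positions of the outer-training
    subjects (indices into the cohort) to inner folds.
    """

    outer_k: int
    inner_j: int
    seed: int
    outer_assignments: np.ndarray
    inner_assignments: dict[int, dict[int, int]] = field(default_factory=dict)

    def outer_test_indices(self, k: int) -> np.ndarray:
        return np.where(self.outer_assignments == k)[0]

    def outer_train_indices(self, k: int) -> np.ndarray:
        return np.where(self.outer_assignments != k)[0]

    def inner_folds(self, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train, validation) index pairs — cohort indices — for outer fold k."""
        assign = self.inner_assignments[k]
        subjects = np.array(sorted(assign))
        folds = np.array([assign[s] for s in subjects])
        return [
            (subjects[folds != j], subjects[folds == j])
            for j in range(self.inner_j)
        ]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "outer_k": self.outer_k,
                    "inner_j": self.inner_j,
                    "seed": self.seed,
                    "outer_assignments": self.outer_assignments.tolist(),
                    "inner_assignments": {
                        str(k): {str(i): int(f) for i, f in v.items()}
                        for k, v in self.inner_assignments.items()
                    },
                },
                indent=2,
            )
        )


def make_nested_cv(
    labels: np.ndarray, outer_k: int = 5, inner_j: int = 5, seed: int = 0
) -> CVPlan:
    """Build a stratified nested CV plan.

    Outer folds partition the cohort with the case:control ratio preserved
    within one subject per fold; each outer training set is further split
    into ``inner_j`` stratified folds used only for hyperparameter search.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < outer_k:
        raise ValueError(
            f"smallest class ({counts.min()}) has fewer members than outer_k={outer_k}"
        )
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    assignments = np.full(labels.size, -1, dtype=int)
    inner_assignments: dict[int, dict[int, int]] = {}
    for k, (train_idx, test_idx) in enumerate(outer.split(labels[:, None], labels)):
        assignments[test_idx] = k
        inner = StratifiedKFold(
            n_splits=inner_j, shuffle=True, random_state=seed + 1000 + k
        )
        fold_of: dict[int, int] = {}
        for j, (_, val_pos) in enumerate(
            inner.split(labels[train_idx, None], labels[train_idx])
        ):
            for pos in val_pos:
                fold_of[int(train_idx[pos])] = j
        inner_assignments[k] = fold_of
    return CVPlan(
        outer_k=outer_k,
        inner_j=inner_j,
        seed=seed,
        outer_assignments=assignments,
        inner_assignments=inner_assignments,
    )


class ModelFamily(Protocol):
    """What the nested-CV driver needs from a model family.

    ``grid`` lists hyperparameter candidates (a single ``None`` entry for
    families without tunable hyperparameters); ``fit`` trains on cohort
    indices; ``predict`` returns ORN probabilities for cohort indices;
    ``predict_external`` scores an external data payload.
    """

    grid: list

    def fit(self, idx: np.ndarray, hp: Any, seed: int) -> Any: ...

    def predict(self, model: Any, idx: np.ndarray) -> np.ndarray: ...

    def predict_external(self, model: Any, external: Any) -> np.ndarray: ...


def run_internal_validation(
    family: ModelFamily,
    labels: np.ndarray,
    subject_ids: list,
    plan: CVPlan,
    seed: int = 0,
) -> tuple[PredictionSet, list[Any], list[Any]]:
    """Nested-CV internal validation of a model family.

    For each outer fold: hyperparameters are chosen by mean inner-fold
    validation AUROC (deterministic first-wins tie-break), the model is
    refit on the full outer training set, and the held-out test subjects are
    scored.  Returns pooled predictions, the per-fold chosen hyperparameters
    and the per-fold fitted models.

    Every subject index touched during the inner search is recorded and
    intersected with the outer test set; any overlap raises
    :class:`LeakageError`.
    """
    from dosemap_ntcp.metrics import auroc

    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if plan.outer_assignments.size != n:
        raise ValueError("plan does not cover the cohort")

    probs = np.full(n, np.nan)
    fold_of = np.full(n, -1, dtype=int)
    chosen: list[Any] = []
    models: list[Any] = []
    for k in range(plan.outer_k):
        test_idx = plan.outer_test_indices(k)
        train_idx = plan.outer_train_indices(k)
        touched: set[int] = set()

        best_hp, best_score = None, -np.inf
        for hp in family.grid:
            scores = []
            for tr, va in plan.inner_folds(k):
                touched.update(tr.tolist())
                touched.update(va.tolist())
                inner_model = family.fit(tr, hp, seed=seed + 100 + k)
                p = family.predict(inner_model, va)
                scores.append(auroc(labels[va], p))
            mean_score = float(np.mean(scores))
            if mean_score > best_score:
                best_hp, best_score = hp, mean_score

        overlap = touched & set(test_idx.tolist())
        if overlap:
            raise LeakageError(
                f"outer fold {k}: test subjects seen during inner search: {sorted(overlap)}"
            )

        model = family.fit(train_idx, best_hp, seed=seed + k)
        probs[test_idx] = family.predict(model, test_idx)
        fold_of[test_idx] = k
        chosen.append(best_hp)
        models.append(model)

    preds = PredictionSet(
        subject_ids=list(subject_ids),
        probabilities=probs,
        labels=labels,
        cohort="internal",
        fold_ids=fold_of,
    )
    return preds, chosen, models


def run_external_validation(
    family: ModelFamily,
    models: list[Any],
    external: Any,
    external_labels: np.ndarray,
    external_ids: list,
    mode: str = "ensemble",
) -> PredictionSet:
    """Score a frozen model (or outer-fold ensemble) on an independent cohort.

    ``mode='ensemble'`` averages the predicted probabilities of the supplied
    outer-fold models; ``mode='single'`` uses exactly one supplied model.
    No parameters are updated from external data.
    """
    external_labels = np.asarray(external_labels, dtype=int)
    if external_labels.size == 0:
        raise ValueError("external cohort is empty")
    if not models:
        raise ValueError("no trained models supplied")
    if mode == "single" and len(models) != 1:
        raise ValueError("mode='single' expects exactly one model")
    stack = np.vstack([family.predict_external(m, external) for m in models])
    probs = stack.mean(axis=0)
    return PredictionSet(
        subject_ids=list(external_ids),
        probabilities=probs,
        labels=external_labels,
        cohort="external",
    )


# ------------------------------------------------------------------ families


class OracleFamily:
    """Predicts the planted ground-truth probability; used for pipeline audits."""

    grid = [None]

    def __init__(self, probabilities: np.ndarray) -> None:
        self.p = np.asarray(probabilities, dtype=float)

    def fit(self, idx, hp, seed):
        return None

    def predict(self, model, idx):
        return self.p[np.asarray(idx)]

    def predict_external(self, model, external):
        return np.asarray(external, dtype=float)


class ConstantFamily:
    """Predicts a fixed probability for everyone (a no-skill reference)."""

    grid = [None]

    def __init__(self, p: float = 0.5) -> None:
        self.p_const = p

    def fit(self, idx, hp, seed):
        return None

    def predict(self, model, idx):
        return np.full(np.asarray(idx).size, self.p_const)

    def predict_external(self, model, external):
        return np.full(len(external), self.p_const)


class LRFamily:
    """Stepwise logistic regression on a DVH + clinical feature table."""

    grid = [None]

    def __init__(self, table, labels, prefilter_threshold: float = 0.8) -> None:
        from dosemap_ntcp.lr_ntcp import spearman_prefilter

        self.labels = np.asarray(labels, dtype=int)
        self.table = table
        self.threshold = prefilter_threshold

    def fit(self, idx, hp, seed):
        from dosemap_ntcp.lr_ntcp import spearman_prefilter, stepwise_forward_lr

        idx = np.asarray(idx)
        sub = self.table.iloc[idx]
        filtered, _ = spearman_prefilter(
            sub, self.labels[idx], threshold=self.threshold
        )
        return stepwise_forward_lr(filtered, self.labels[idx])

    def predict(self, model, idx):
        idx = np.asarray(idx)
        lin = model.linear_predictor(self.table.iloc[idx])
        return 1.0 / (1.0 + np.exp(-lin))

    def predict_external(self, model, external):
        lin = model.linear_predictor(external)
        return 1.0 / (1.0 + np.exp(-lin))


class CNNFamily:
    """DenseNet-40 (dose-only or joint-fusion) over preprocessed dose maps."""

    def __init__(
        self,
        x: np.ndarray,
        labels: np.ndarray,
        config,
        grid: list,
        clinical: np.ndarray | None = None,
        augment_config=None,
    ) -> None:
        self.x = x
        self.labels = np.asarray(labels, dtype=int)
        self.clinical = clinical
        self.config = config
        self.grid = grid
        self.augment_config = augment_config
        self.modality = "dose" if clinical is None else "fusion"

    def fit(self, idx, hp, seed):
        from dataclasses import replace

        from dosemap_ntcp.nn.densenet import DenseNet3D
        from dosemap_ntcp.nn.train import train

        idx = np.asarray(idx)
        model = DenseNet3D(self.config, modality=self.modality, seed=seed)
        return train(
            model,
            self.x[idx],
            self.labels[idx],
            replace(hp, seed=seed),
            clinical=None if self.clinical is None else self.clinical[idx],
            augment_config=self.augment_config,
        )

    def predict(self, trained, idx):
        idx = np.asarray(idx)
        cl = None if self.clinical is None else self.clinical[idx]
        return trained.predict_proba(self.x[idx], cl)[:, 1]

    def predict_external(self, trained, external):
        x_ext, cl_ext = external
        return trained.predict_proba(x_ext, cl_ext)[:, 1]
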