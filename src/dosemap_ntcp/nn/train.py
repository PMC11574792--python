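"""Training, hyperparameter grid and grid search for the DenseNet classifiers.

Optimisation uses Adam with categorical cross-entropy, mirroring standard
practice for this architecture.  All randomness (shuffling, dropout,
augmentation) derives from the run seed, so a repeated run reproduces the
loss history exactly on fixed hardware.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from dosemap_ntcp import metrics as em
from dosemap_ntcp.nn import layers as L
from dosemap_ntcp.nn.densenet import ArchitectureConfig, DenseNet3D
from dosemap_ntcp.preprocess import AugmentConfig, augment

#: The published hyperparameter search grid (108 combinations).
HYPERPARAMETER_GRID: dict[str, tuple] = {
    "dropout": (0.6, 0.8),
    "learning_rate": (0.01, 0.001, 0.0001),
    "batch_size": (10, 16),
    "weight_decay": (0.01, 0.001, 0.0001),
    "epochs": (50, 100, 300),
}


@dataclass(frozen=True)
class Hyperparameters:
    dropout: float = 0.6
    learning_rate: float = 0.001
    batch_size: int = 10
    weight_decay: float = 0.001
    epochs: int = 50
    seed: int = 0


def enumerate_grid(grid: dict[str, tuple] | None = None) -> list[Hyperparameters]:
    """All grid points in deterministic (itertools.product) order."""
    grid = HYPERPARAMETER_GRID if grid is None else grid
    keys = list(grid)
    return [
        Hyperparameters(**dict(zip(keys, combo)))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


def scale_clinical(
    table, stats: dict | None = None
) -> tuple[np.ndarray, dict]:
    """Model-input scaling of the 6 covariates: binaries as {0,1}, age min-max
    scaled to [0,1] on the training set (stats reused for validation/external)."""
    from dosemap_ntcp.synthetic_cohort import MODEL_COVARIATES

    X = table[list(MODEL_COVARIATES)].to_numpy(dtype=float)
    if stats is None:
        stats = {"age_min": float(X[:, 0].min()), "age_max": float(X[:, 0].max())}
    rng_ = stats["age_max"] - stats["age_min"]
    X[:, 0] = np.clip(
        (X[:, 0] - stats["age_min"]) / (rng_ if rng_ > 0 else 1.0), 0.0, 1.0
    )
    return X, stats


@dataclass
class TrainedModel:
    """A trained classifier with its provenance (config, hyperparameters, history)."""

    model: DenseNet3D
    hyperparameters: Hyperparameters
    history: list[float] = field(default_factory=list)
    modality: str = "dose"
    clinical_stats: dict | None = None

    def predict_proba(self, x, clinical=None) -> np.ndarray:
        return self.model.predict_proba(x, clinical)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model.state_arrays())
        sidecar = {
            "architecture": asdict(self.model.config),
            "modality": self.modality,
            "seed": self.model.seed,
            "hyperparameters": asdict(self.hyperparameters),
            "history": self.history,
            "clinical_stats": self.clinical_stats,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = sidecar["architecture"]
        cfg["layers_per_block"] = tuple(cfg["layers_per_block"])
        config = ArchitectureConfig(**cfg)
        model = DenseNet3D(config, modality=sidecar["modality"], seed=sidecar["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_arrays(dict(data))
        return cls(
            model=model,
            hyperparameters=Hyperparameters(**sidecar["hyperparameters"]),
            history=sidecar["history"],
            modality=sidecar["modality"],
            clinical_stats=sidecar["clinical_stats"],
        )


class TrainingDivergedError(RuntimeError):
    pass


def train(
    model: DenseNet3D,
    x: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    clinical: np.ndarray | None = None,
    augment_config: AugmentConfig | None = None,
) -> TrainedModel:
    """Train in place with Adam + categorical cross-entropy.

    ``x`` is (N, 1, D, H, W) of normalised dose maps, ``y`` binary labels,
    ``clinical`` the scaled covariates for the fusion modality.  Augmentation,
    when given, resamples a rotation/zoom for every subject at every epoch
    (training data only — validation inference is never augmented).
    """
    y = np.asarray(y, dtype=int)
    model.set_dropout(hp.dropout)
    opt = L.Adam(
        model.all_layers(),
        learning_rate=hp.learning_rate,
        weight_decay=hp.weight_decay,
    )
    rng = np.random.default_rng(hp.seed)
    history: list[float] = []
    n = x.shape[0]
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb = x[idx]
            if augment_config is not None and augment_config.enabled:
                xb = np.stack(
                    [
                        augment(v[0], augment_config, rng)[None]
                        for v in xb
                    ]
                )
            cb = None if clinical is None else clinical[idx]
            logits = model.forward(xb, cb, train=True)
            loss, grad = L.cross_entropy_loss(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, lr={hp.learning_rate}, "
                    f"wd={hp.weight_decay}"
                )
            model.backward(grad)
            opt.step()
            epoch_loss += loss * idx.size
        history.append(epoch_loss / n)
    return TrainedModel(
        model=model, hyperparameters=hp, history=history, modality=model.modality
    )


def validation_auroc(
    model: DenseNet3D,
    x: np.ndarray,
    y: np.ndarray,
    clinical: np.ndarray | None = None,
) -> float:
    p = model.predict_proba(x, clinical)[:, 1]
    return em.auroc(np.asarray(y), p)


def grid_search(
    grid: list[Hyperparameters],
    x: np.ndarray,
    y: np.ndarray,
    inner_folds: list[tuple[np.ndarray, np.ndarray]],
    config: ArchitectureConfig,
    modality: str = "dose",
    clinical: np.ndarray | None = None,
    augment_config: AugmentConfig | None = None,
    seed: int = 0,
    touched_ids: set | None = None,
    subject_ids: list | None = None,
) -> tuple[Hyperparameters, list[dict]]:
    """Pick the grid point with the best mean inner-fold validation AUROC.

    Ties break to the first grid point in enumeration order.  When
    ``touched_ids``/``subject_ids`` are given, every subject index used here
    is recorded so the caller can audit that the search never saw outer test
    subjects.
    """
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    results = []
    best: tuple[float, int] | None = None
    for g_idx, hp in enumerate(grid):
        scores = []
        for f_idx, (tr, va) in enumerate(inner_folds):
            if touched_ids is not None and subject_ids is not None:
                touched_ids.update(subject_ids[i] for i in np.concatenate([tr, va]))
            model = DenseNet3D(config, modality=modality, seed=seed + f_idx)
            hp_fold = Hyperparameters(**{**asdict(hp), "seed": seed + 1000 * g_idx + f_idx})
            train(
                model,
                x[tr],
                y[tr],
                hp_fold,
                clinical=None if clinical is None else clinical[tr],
                augment_config=augment_config,
            )
            scores.append(
                validation_auroc(
                    model, x[va], y[va], None if clinical is None else clinical[va]
                )
            )
        mean_score = float(np.mean(scores))
        results.append({"hyperparameters": asdict(hp), "mean_auroc": mean_score})
        if best is None or mean_score > best[0]:
            best = (mean_score, g_idx)
    return grid[best[1]], results
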