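"""End-to-end workflow stages behind the command-line interface.

Each stage reads its upstream artefacts from the run directory, writes its
own outputs there, and registers every artefact with a content hash in
``run_manifest.json``, so a rerun with the same config and seed reproduces
identical hashes for the deterministic stages.  Stages never mutate another
stage's outputs.

Stage order: simulate -> preprocess -> dvh -> train-lr / train-cnn ->
validate-external -> report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dosemap_ntcp import dvh as dvh_mod
from dosemap_ntcp import metrics as em
from dosemap_ntcp import preprocess as pp
from dosemap_ntcp import synthetic_cohort as sc
from dosemap_ntcp import validation as val
from dosemap_ntcp.nn.densenet import ArchitectureConfig
from dosemap_ntcp.nn.train import Hyperparameters, scale_clinical


class ConfigError(ValueError):
    pass


class StageDataError(RuntimeError):
    """A required upstream artefact is missing; names the stage to run first."""


DEFAULT_CONFIG = {
    "output_dir": "runs/demo",
    "seed": 0,
    "cohort": {
        "n_internal_population": 300,
        "n_external_population": 140,
        "grid_shape": [24, 24, 24],
    },
    "preprocessing": {
        "alpha_beta": 3.0,
        "target_shape": [16, 16, 16],
        "margin": 2,
        "normalisation_scope": "development",
    },
    "models": ["lr", "dn40"],
    "cnn": {
        "initial_channels": 8,
        "growth_rate": 4,
        "layers_per_block": [2, 2, 2],
        "dropout": 0.6,
        "hyperparameters": {
            "learning_rate": 0.003,
            "batch_size": 16,
            "weight_decay": 0.0001,
            "epochs": 12,
        },
    },
    "cv": {"outer_k": 5, "inner_j": 3},
    "evaluation": {"threshold": 0.5, "bins": 10},
}


def load_config(path: str | Path | None) -> dict:
    """Load and schema-check a YAML/JSON run config, filling defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        for key, value in raw.items():
            if key not in config:
                raise ConfigError(f"unknown config key: {key}")
            if isinstance(config[key], dict):
                unknown = set(value) - set(config[key])
                if unknown:
                    raise ConfigError(f"unknown keys under '{key}': {sorted(unknown)}")
                config[key].update(value)
            else:
                config[key] = value
    if config["cv"]["outer_k"] < 2:
        raise ConfigError("cv.outer_k must be >= 2")
    for m in config["models"]:
        if m not in ("lr", "dn40", "mdn40"):
            raise ConfigError(f"unknown model '{m}'")
    return config


def _run_dir(config: dict) -> Path:
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _register(config: dict, *paths: Path) -> None:
    out = _run_dir(config)
    manifest_path = out / "run_manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"artefacts": {}}
    )
    manifest["config"] = config
    for p in paths:
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest["artefacts"][str(p.relative_to(out))] = digest
    manifest_path.write_text(json.dumps(manifest, indent=2))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageDataError(f"missing artefact {path.name}: run the '{stage}' stage first")
    return path


def simulate(config: dict) -> None:
    """Generate matched internal and external phantom cohorts on disk."""
    out = _run_dir(config)
    (out / "frozen_config.yaml").write_text(yaml.safe_dump(config))
    grid_shape = tuple(config["cohort"]["grid_shape"])
    seed = config["seed"]
    truth = sc.PlantedTruth()

    internal_cfg = sc.PhantomConfig(grid_shape=grid_shape, seed=seed)
    internal = sc.match_case_control(
        sc.generate_population(
            internal_cfg, truth, config["cohort"]["n_internal_population"]
        )
    )
    sc.write_cohort(internal, out / "cohort_internal")

    external_cfg = sc.external_config(seed=seed + 1, grid_shape=grid_shape)
    external = sc.match_case_control(
        sc.generate_population(
            external_cfg, truth, config["cohort"]["n_external_population"]
        )
    )
    sc.write_cohort(external, out / "cohort_external")
    _register(
        config,
        out / "cohort_internal" / "clinical.csv",
        out / "cohort_internal" / "manifest.json",
        out / "cohort_external" / "clinical.csv",
        out / "cohort_external" / "manifest.json",
        out / "frozen_config.yaml",
    )


def _load_cohort_arrays(config: dict, tag: str):
    out = _run_dir(config)
    cdir = _require(out / f"cohort_{tag}" / "clinical.csv", "simulate").parent
    return sc.read_cohort_volumes(cdir)


def preprocess(config: dict) -> None:
    """Mask, EQD2-correct, crop and normalise every subject's dose map.

    Normalisation statistics are fitted on the internal (development) cohort
    and reused, with clipping, for the external cohort.
    """
    out = _run_dir(config)
    p = config["preprocessing"]
    target = tuple(p["target_shape"])
    log_rows = []

    cohorts = {}
    for tag in ("internal", "external"):
        clinical, doses, masks = _load_cohort_arrays(config, tag)
        maps = {}
        for sid in clinical.index:
            eqd2 = pp.EQD2Params(
                alpha_beta=p["alpha_beta"],
                n_fractions=int(clinical.loc[sid, "n_fractions"]),
            )
            maps[sid] = pp.preprocess_subject(
                doses[sid], masks[sid], eqd2, None, target, p["margin"], subject_id=sid
            )
            log_rows.append(
                {
                    "subject_id": sid,
                    "cohort": tag,
                    "voxels_in_mask": int(maps[sid].mask.sum()),
                    "min_gy": float(maps[sid].values.min()),
                    "max_gy": float(maps[sid].values.max()),
                }
            )
        cohorts[tag] = (clinical, maps)

    stats = pp.fit_normalisation(
        [m.values for m in cohorts["internal"][1].values()],
        fit_scope=p["normalisation_scope"],
    )
    stats.to_json(out / "normalisation_stats.json")

    for tag, (clinical, maps) in cohorts.items():
        ids = list(clinical.index)
        x = np.stack(
            [pp.apply_normalisation(maps[s].values, stats) * maps[s].mask for s in ids]
        )[:, None]
        eqd2_voxels = {s: maps[s].in_mask_values for s in ids}
        np.savez_compressed(
            out / f"maps_{tag}.npz",
            x=x,
            labels=clinical["orn_label"].to_numpy(),
            ids=np.array(ids),
            **{f"voxels_{s}": v for s, v in eqd2_voxels.items()},
        )
    pd.DataFrame(log_rows).to_csv(out / "preprocess_log.csv", index=False)
    _register(config, out / "normalisation_stats.json", out / "preprocess_log.csv")


def dvh(config: dict) -> None:
    """DVH metric panels (on EQD2 dose in Gy) for both cohorts."""
    out = _run_dir(config)
    for tag in ("internal", "external"):
        path = _require(out / f"maps_{tag}.npz", "preprocess")
        with np.load(path, allow_pickle=False) as data:
            ids = list(data["ids"])
            voxels = {s: data[f"voxels_{s}"] for s in ids}
        table = dvh_mod.panel_table(voxels)
        table.to_csv(out / f"dvh_panel_{tag}.csv")
        _register(config, out / f"dvh_panel_{tag}.csv")


def _feature_table(config: dict, tag: str) -> tuple[pd.DataFrame, np.ndarray]:
    out = _run_dir(config)
    panel = pd.read_csv(
        _require(out / f"dvh_panel_{tag}.csv", "dvh"), index_col="subject_id"
    )
    clinical, _, _ = _load_cohort_arrays(config, tag)
    clinical = clinical.loc[panel.index]
    features = panel.join(clinical[list(sc.MODEL_COVARIATES)])
    return features, clinical["orn_label"].to_numpy()


def train_lr(config: dict) -> None:
    """Nested-CV internal validation of the stepwise LR baseline."""
    out = _run_dir(config)
    features, labels = _feature_table(config, "internal")
    plan = val.make_nested_cv(
        labels, config["cv"]["outer_k"], config["cv"]["inner_j"], config["seed"]
    )
    plan.to_json(out / "cv_plan.json")
    family = val.LRFamily(features, labels)
    preds, chosen, models = val.run_internal_validation(
        family, labels, list(features.index), plan, seed=config["seed"]
    )
    preds.to_frame().to_csv(out / "predictions_lr_internal.csv", index=False)
    models[0].to_json(out / "lr_model_fold0.json")
    # refit on the full internal cohort for external deployment
    family.fit(np.arange(len(labels)), None, seed=config["seed"]).to_json(
        out / "lr_model_full.json"
    )
    _register(
        config,
        out / "cv_plan.json",
        out / "predictions_lr_internal.csv",
        out / "lr_model_full.json",
    )


def _cnn_setup(config: dict, tag: str):
    out = _run_dir(config)
    path = _require(out / f"maps_{tag}.npz", "preprocess")
    with np.load(path, allow_pickle=False) as data:
        x = data["x"]
        labels = data["labels"]
        ids = [str(s) for s in data["ids"]]
    clinical, _, _ = _load_cohort_arrays(config, tag)
    clinical = clinical.loc[ids]
    return x, labels, ids, clinical


def train_cnn(config: dict) -> None:
    """Nested-CV internal validation of the DenseNet models in the config."""
    out = _run_dir(config)
    c = config["cnn"]
    arch = ArchitectureConfig(
        initial_channels=c["initial_channels"],
        growth_rate=c["growth_rate"],
        layers_per_block=tuple(c["layers_per_block"]),
        dropout=c["dropout"],
    )
    hp = Hyperparameters(dropout=c["dropout"], seed=config["seed"], **c["hyperparameters"])
    x, labels, ids, clinical = _cnn_setup(config, "internal")
    plan = val.make_nested_cv(
        labels, config["cv"]["outer_k"], config["cv"]["inner_j"], config["seed"]
    )
    scaled, stats = scale_clinical(clinical)
    (out / "clinical_scaling.json").write_text(json.dumps(stats))

    for model_name in [m for m in config["models"] if m != "lr"]:
        cl = scaled if model_name == "mdn40" else None
        family = val.CNNFamily(
            x, labels, arch, grid=[hp], clinical=cl, augment_config=None
        )
        preds, chosen, models = val.run_internal_validation(
            family, labels, ids, plan, seed=config["seed"]
        )
        preds.to_frame().to_csv(out / f"predictions_{model_name}_internal.csv", index=False)
        for k, trained in enumerate(models):
            trained.save(out / f"{model_name}_fold{k}")
        _register(config, out / f"predictions_{model_name}_internal.csv")


def validate_external(config: dict) -> None:
    """Frozen-model external validation of every trained model."""
    out = _run_dir(config)
    features_ext, labels_ext = _feature_table(config, "external")

    if "lr" in config["models"]:
        from dosemap_ntcp.lr_ntcp import LRModel, predict_lr

        model = LRModel.from_json(_require(out / "lr_model_full.json", "train-lr"))
        preds = predict_lr(model, features_ext, labels_ext, cohort="external")
        preds.to_frame().to_csv(out / "predictions_lr_external.csv", index=False)
        _register(config, out / "predictions_lr_external.csv")

    cnn_models = [m for m in config["models"] if m != "lr"]
    if cnn_models:
        from dosemap_ntcp.nn.train import TrainedModel

        x_ext, lab_ext, ids_ext, clinical_ext = _cnn_setup(config, "external")
        stats = json.loads(
            _require(out / "clinical_scaling.json", "train-cnn").read_text()
        )
        scaled_ext, _ = scale_clinical(clinical_ext, stats)
        for model_name in cnn_models:
            folds = sorted(out.glob(f"{model_name}_fold*.json"))
            if not folds:
                raise StageDataError(
                    f"no {model_name} checkpoints: run the 'train-cnn' stage first"
                )
            models = [TrainedModel.load(p.with_suffix("")) for p in folds]
            cl = scaled_ext if model_name == "mdn40" else None
            family = val.CNNFamily(x_ext, lab_ext, None, grid=[None], clinical=cl)
            preds = val.run_external_validation(
                family, models, (x_ext, cl), lab_ext, ids_ext, mode="ensemble"
            )
            preds.to_frame().to_csv(
                out / f"predictions_{model_name}_external.csv", index=False
            )
            _register(config, out / f"predictions_{model_name}_external.csv")


def report(config: dict) -> None:
    """Cohort-comparison tables, per-model evaluation reports, calibration points."""
    out = _run_dir(config)
    clin_int, _, _ = _load_cohort_arrays(config, "internal")
    clin_ext, _, _ = _load_cohort_arrays(config, "external")
    em.cohort_summary(clin_int).to_csv(out / "cohort_summary_internal.csv")
    em.cohort_summary(clin_ext).to_csv(out / "cohort_summary_external.csv")
    em.covariate_shift_report(clin_int, clin_ext).to_csv(out / "covariate_shift.csv")

    rows = []
    found = False
    for model_name in config["models"]:
        for tag in ("internal", "external"):
            path = out / f"predictions_{model_name}_{tag}.csv"
            if not path.exists():
                continue
            found = True
            frame = pd.read_csv(path)
            preds = em.PredictionSet(
                subject_ids=list(frame["subject_id"]),
                probabilities=frame["probability"].to_numpy(),
                labels=frame["label"].to_numpy(),
                cohort=tag,
            )
            rep = em.evaluate(
                preds,
                threshold=config["evaluation"]["threshold"],
                n_bins=config["evaluation"]["bins"],
            )
            pd.DataFrame(rep.calibration).to_csv(
                out / f"calibration_{model_name}_{tag}.csv", index=False
            )
            row = {"model": model_name, "cohort": tag, **rep.as_dict()}
            row.pop("calibration")
            rows.append(row)
    if not found:
        raise StageDataError(
            "no prediction files found: run the 'train-lr'/'train-cnn' "
            "(and optionally 'validate-external') stages first"
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "performance_table.csv", index=False)
    (out / "performance_table.md").write_text(
        "# Model performance\n\n```\n" + table.round(3).to_string(index=False) + "\n```\n"
    )
    _register(config, out / "performance_table.csv")
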