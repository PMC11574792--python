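"""Seeded phantom cohorts with a planted spatial dose--toxicity ground truth.

Real mandibular-ORN cohorts are not publicly available, so this module
generates matched case--control phantom cohorts that emulate their structure:

- a parametric half-torus ("horseshoe") mandible mask in voxel space with
  per-subject jitter of radius and thickness;
- a planned dose field built from prescription-scaled anisotropic Gaussian
  lobes centred lateral to the arch (mimicking target volumes adjacent to
  the mandible) on top of a low-dose bath, so the in-mask DVHs span the
  V5--V70 Gy range;
- clinical covariates drawn at configurable target prevalences (defaults
  mirror a UK head-and-neck case--control cohort; an external-cohort profile
  with shifted smoking/chemotherapy/extraction rates is provided to emulate
  domain shift);
- a binary ORN label drawn from a planted logistic NTCP whose linear
  predictor combines a DVH dose summary (D30% by default, following the
  classic mandible NTCP literature) and clinical covariates.

Everything is driven by one integer seed: the same (config, truth, n, seed)
reproduces the cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dosemap_ntcp.dvh import dose_at_volume
from dosemap_ntcp.preprocess import DoseGrid

#: The six covariates exposed to the NTCP models.
MODEL_COVARIATES = (
    "age",
    "gender",
    "smoking",
    "pre_rt_extractions",
    "port",
    "chemotherapy",
)

PRIMARY_SITES = ("oral_cavity", "oropharynx", "larynx", "other")

#: Covariate targets mirroring the development (internal) cohort.
INTERNAL_PREVALENCES = {
    "gender": 0.75,
    "smoking": 0.37,
    "pre_rt_extractions": 0.57,
    "port": 0.38,
    "chemotherapy": 0.63,
}
INTERNAL_SITE_PROBS = (0.304, 0.565, 0.033, 0.098)
INTERNAL_YEARS = (2011, 2022)

#: Covariate targets mirroring the external validation cohort (domain shift:
#: higher smoking and extraction rates, much lower chemotherapy rate).
EXTERNAL_PREVALENCES = {
    "gender": 0.74,
    "smoking": 0.60,
    "pre_rt_extractions": 0.78,
    "port": 0.35,
    "chemotherapy": 0.27,
}
EXTERNAL_SITE_PROBS = (0.43, 0.55, 0.02, 0.0)
EXTERNAL_YEARS = (2007, 2015)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, dosimetry and covariate targets of the phantom generator.

    Lengths are mm; doses are Gy.  ``arch_radius`` / ``arch_thickness`` define
    the mandible horseshoe; hotspot parameters shape the Gaussian dose lobes.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    arch_radius: float = 20.0
    arch_thickness: float = 5.0
    prescription_range: tuple[float, float] = (50.0, 70.0)
    fractions_options: tuple[int, ...] = (20, 30, 33, 35)
    hotspot_count: int = 2
    hotspot_width: float = 14.0
    bath_dose: float = 6.0
    prevalences: dict = field(default_factory=lambda: dict(INTERNAL_PREVALENCES))
    site_probs: tuple[float, ...] = INTERNAL_SITE_PROBS
    year_range: tuple[int, int] = INTERNAL_YEARS
    age_mean: float = 61.0
    age_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("degenerate grid: every axis needs >= 8 voxels")
        lo, hi = self.prescription_range
        if not (0.0 <= lo <= hi <= 80.0):
            raise ValueError("prescription_range must lie within [0, 80] Gy")


def external_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A :class:`PhantomConfig` with external-cohort covariate targets."""
    return PhantomConfig(
        prevalences=dict(EXTERNAL_PREVALENCES),
        site_probs=EXTERNAL_SITE_PROBS,
        year_range=EXTERNAL_YEARS,
        age_mean=59.0,
        seed=seed,
        **overrides,
    )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth logistic NTCP used to draw ORN labels.

    ``beta_dose`` acts on a DVH summary of the masked physical dose
    (D30% by default); ``beta_clinical`` maps covariate names to log-odds
    increments (age enters per decade to keep coefficients comparable).
    """

    beta0: float = -5.5
    beta_dose: float = 0.10
    dose_summary: str = "D30"
    beta_clinical: dict = field(
        default_factory=lambda: {"pre_rt_extractions": 0.7, "smoking": 0.4}
    )


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's clinical covariates, matching variables and ORN label."""

    subject_id: str
    age: float
    gender: int
    smoking: int
    pre_rt_extractions: int
    port: int
    chemotherapy: int
    primary_site: str
    treatment_year: int
    n_fractions: int
    orn_label: int

    def covariate_vector(self) -> np.ndarray:
        """The six model covariates, in :data:`MODEL_COVARIATES` order."""
        return np.array([getattr(self, c) for c in MODEL_COVARIATES], dtype=float)


@dataclass
class Subject:
    record: ClinicalRecord
    dose: DoseGrid
    mask: np.ndarray
    dose_summary: float  # planted DVH summary (Gy) on the masked dose
    planted_p: float


@dataclass
class Cohort:
    subjects: list[Subject]
    config: PhantomConfig
    truth: PlantedTruth
    exclusions: int = 0

    def __len__(self) -> int:
        return len(self.subjects)

    def clinical_table(self) -> pd.DataFrame:
        rows = [asdict(s.record) for s in self.subjects]
        return pd.DataFrame(rows).set_index("subject_id")

    def labels(self) -> np.ndarray:
        return np.array([s.record.orn_label for s in self.subjects])

    def planted_probabilities(self) -> np.ndarray:
        return np.array([s.planted_p for s in self.subjects])


def planted_probability(
    record: ClinicalRecord, dose_summary: float, truth: PlantedTruth
) -> float:
    """The planted logistic NTCP evaluated for one subject.

    ``p = expit(beta0 + beta_dose * summary + sum_c beta_c * covariate_c)``,
    with age contributing per decade.
    """
    if not np.isfinite(dose_summary):
        raise ValueError("dose summary must be finite")
    lin = truth.beta0 + truth.beta_dose * dose_summary
    for name, beta in truth.beta_clinical.items():
        value = getattr(record, name)
        if name == "age":
            value = value / 10.0
        lin += beta * value
    return float(1.0 / (1.0 + np.exp(-lin)))


def _mandible_mask(
    config: PhantomConfig, radius: float, thickness: float, coords: np.ndarray
) -> np.ndarray:
    """Half-torus horseshoe: anterior half-annulus in-plane, slab in z."""
    x, y, z = coords
    r_inplane = np.sqrt(x**2 + y**2)
    in_annulus = np.abs(r_inplane - radius) <= thickness
    anterior = y >= 0.0
    in_slab = np.abs(z) <= thickness
    return in_annulus & anterior & in_slab


def _dose_field(
    config: PhantomConfig,
    radius: float,
    prescription: float,
    coords: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Prescription-scaled anisotropic Gaussian lobes lateral to the arch + bath."""
    x, y, z = coords
    dose = np.full(x.shape, config.bath_dose)
    # per-subject proximity of the target volume to the mandible controls
    # how hot the bone gets, spreading the in-mask DVH across subjects
    proximity = rng.uniform(0.0, 14.0)
    for _ in range(config.hotspot_count):
        theta = rng.uniform(np.pi * 0.15, np.pi * 0.85)  # along the anterior arch
        cx = (radius + proximity) * np.cos(theta)
        cy = (radius + proximity) * np.sin(theta)
        cz = rng.uniform(-4.0, 4.0)
        w = config.hotspot_width * rng.uniform(0.8, 1.25)
        wz = w * rng.uniform(0.6, 1.0)
        g = np.exp(
            -(
                (x - cx) ** 2 / (2 * w**2)
                + (y - cy) ** 2 / (2 * w**2)
                + (z - cz) ** 2 / (2 * wz**2)
            )
        )
        dose = np.maximum(dose, prescription * g)
    return dose


def generate_population(
    config: PhantomConfig,
    truth: PlantedTruth,
    n: int,
    seed: int | None = None,
) -> Cohort:
    """Generate ``n`` phantom subjects with labels from the planted NTCP.

    The RNG is seeded from ``seed`` (falling back to ``config.seed``); the
    same arguments always reproduce the identical cohort.
    """
    if n < 2:
        raise ValueError("a population needs at least 2 subjects")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    shape = config.grid_shape
    spacing = config.voxel_spacing
    axes = [
        (np.arange(s) - (s - 1) / 2.0) * sp for s, sp in zip(shape, spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")

    subjects: list[Subject] = []
    for i in range(n):
        radius = config.arch_radius * rng.uniform(0.9, 1.1)
        thickness = config.arch_thickness * rng.uniform(0.85, 1.15)
        mask = _mandible_mask(config, radius, thickness, coords)
        if not mask.any():
            raise ValueError(
                "mandible horseshoe lies outside the grid: reduce arch_radius "
                "or enlarge grid_shape/voxel_spacing"
            )

        prescription = rng.uniform(*config.prescription_range)
        dose_values = _dose_field(config, radius, prescription, coords, rng)
        dose = DoseGrid(values=dose_values, spacing=spacing)

        site = PRIMARY_SITES[
            rng.choice(len(PRIMARY_SITES), p=np.asarray(config.site_probs) / sum(config.site_probs))
        ]
        record = ClinicalRecord(
            subject_id=f"S{i:05d}",
            age=float(np.round(rng.normal(config.age_mean, config.age_sd), 1)),
            gender=int(rng.random() < config.prevalences["gender"]),
            smoking=int(rng.random() < config.prevalences["smoking"]),
            pre_rt_extractions=int(
                rng.random() < config.prevalences["pre_rt_extractions"]
            ),
            port=int(rng.random() < config.prevalences["port"]),
            chemotherapy=int(rng.random() < config.prevalences["chemotherapy"]),
            primary_site=site,
            treatment_year=int(rng.integers(config.year_range[0], config.year_range[1] + 1)),
            n_fractions=int(rng.choice(config.fractions_options)),
            orn_label=0,
        )

        in_mask = dose_values[mask]
        level = float(truth.dose_summary.lstrip("D"))
        summary = dose_at_volume(in_mask, level)
        p = planted_probability(record, summary, truth)
        label = int(rng.random() < p)
        record = replace(record, orn_label=label)

        subjects.append(
            Subject(
                record=record,
                dose=dose,
                mask=mask.astype(np.uint8),
                dose_summary=summary,
                planted_p=p,
            )
        )
    return Cohort(subjects=subjects, config=config, truth=truth)


def match_case_control(cohort: Cohort) -> Cohort:
    """Exact case--control matching on primary site and treatment year.

    Every ORN case is paired with one unused control sharing primary site and
    treatment year; ties are broken by smallest subject id.  Cases with no
    feasible control (and leftover controls) are dropped; the dropped-case
    count is recorded in ``exclusions``.  The result is exactly
    class-balanced.
    """
    cases = sorted(
        (s for s in cohort.subjects if s.record.orn_label == 1),
        key=lambda s: s.record.subject_id,
    )
    controls: dict[tuple[str, int], list[Subject]] = {}
    for s in cohort.subjects:
        if s.record.orn_label == 0:
            key = (s.record.primary_site, s.record.treatment_year)
            controls.setdefault(key, []).append(s)
    for pool in controls.values():
        pool.sort(key=lambda s: s.record.subject_id)

    matched: list[Subject] = []
    excluded = 0
    for case in cases:
        key = (case.record.primary_site, case.record.treatment_year)
        pool = controls.get(key, [])
        if pool:
            matched.append(case)
            matched.append(pool.pop(0))
        else:
            excluded += 1
    matched.sort(key=lambda s: s.record.subject_id)
    return Cohort(
        subjects=matched, config=cohort.config, truth=cohort.truth, exclusions=excluded
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Persist dose/mask volumes as NIfTI, clinical table as CSV, manifest as JSON."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacing = cohort.config.voxel_spacing
    affine = np.diag([*spacing, 1.0])
    for s in cohort.subjects:
        sid = s.record.subject_id
        nib.save(
            nib.Nifti1Image(s.dose.values.astype(np.float32), affine),
            out_dir / f"{sid}_dose.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(s.mask.astype(np.uint8), affine),
            out_dir / f"{sid}_mask.nii.gz",
        )
    cohort.clinical_table().to_csv(out_dir / "clinical.csv")
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cohort.config).items()
        },
        "truth": asdict(cohort.truth),
        "n_subjects": len(cohort),
        "exclusions": cohort.exclusions,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort_volumes(
    in_dir: str | Path,
) -> tuple[pd.DataFrame, dict[str, DoseGrid], dict[str, np.ndarray]]:
    """Load a written cohort: clinical table plus per-subject dose grids and masks."""
    import nibabel as nib

    in_dir = Path(in_dir)
    clinical = pd.read_csv(in_dir / "clinical.csv", index_col="subject_id")
    doses: dict[str, DoseGrid] = {}
    masks: dict[str, np.ndarray] = {}
    for sid in clinical.index:
        dimg = nib.load(in_dir / f"{sid}_dose.nii.gz")
        mimg = nib.load(in_dir / f"{sid}_mask.nii.gz")
        spacing = tuple(float(z) for z in dimg.header.get_zooms()[:3])
        doses[sid] = DoseGrid(
            values=np.asarray(dimg.dataobj, dtype=float), spacing=spacing
        )
        masks[sid] = np.asarray(mimg.dataobj, dtype=np.uint8)
    return clinical, doses, masks
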