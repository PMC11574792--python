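"""Dose-map preprocessing: masking, EQD2, crop/resample, normalisation, augmentation.

The fixed pipeline order is mask -> EQD2 -> crop/resample -> normalise ->
(augment, training only).  EQD2 conversion uses the linear-quadratic model
with uniform fractionation per voxel: the per-voxel dose per fraction is the
total voxel dose divided by the subject's planned fraction count, and

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / n_fractions.

With alpha/beta = 3 Gy (late effects) the conversion is the identity exactly
at 2 Gy per fraction, amplifies doses above it and shrinks doses below it.

Normalisation is global min--max to [0, 1], fitted once on the development
cohort and persisted; external cohorts are transformed with the development
statistics and clipped into [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage


class GridIncompatibilityError(ValueError):
    """Dose and mask are not on the same grid."""


class EmptyStructureError(ValueError):
    """The mandible mask contains no voxels."""


class DegenerateRangeError(ValueError):
    """Min--max normalisation is undefined: all voxel values identical."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3D absorbed-dose field in Gy on a regular grid.

    ``spacing`` and ``origin`` are in mm, axis order (x, y, z) following the
    NIfTI affine convention.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise ValueError("dose values must be finite and non-negative")


@dataclass(frozen=True)
class EQD2Params:
    """Linear-quadratic conversion parameters: alpha/beta in Gy, fraction count."""

    alpha_beta: float = 3.0
    n_fractions: int = 30

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


@dataclass
class NormalisationStats:
    """Global min/max intensities (Gy) fitted on a cohort of dose maps."""

    global_min: float
    global_max: float
    fit_scope: str = "development"

    def __post_init__(self) -> None:
        if not self.global_max > self.global_min:
            raise DegenerateRangeError(
                "normalisation requires global_max > global_min"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalisationStats":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation: small 3D rotations and isotropic zoom.

    Rotation angles are drawn uniformly per axis from ``rotation_range``
    (radians) and the zoom factor from ``zoom_range``; both ranges contain
    the identity transform by construction of the defaults.
    """

    rotation_range: tuple[float, float] = (-0.1, 0.1)
    zoom_range: tuple[float, float] = (0.8, 1.2)
    enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range
        if not lo <= 0.0 <= hi:
            raise ValueError("rotation_range must contain 0")
        lo, hi = self.zoom_range
        if not lo <= 1.0 <= hi:
            raise ValueError("zoom_range must contain 1")


@dataclass
class MandibleDoseMap:
    """A masked, fixed-shape dose map ready for the network.

    ``values`` are zero outside ``mask`` and, once normalised, lie in [0, 1].
    ``meta`` records subject id, whether EQD2 was applied, and the crop
    bounding box in the source grid.
    """

    values: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask.astype(bool)]


def mask_dose(dose: DoseGrid, mask: np.ndarray) -> DoseGrid:
    """Zero every voxel outside the mandible mask; in-mask values are untouched."""
    mask = np.asarray(mask)
    if mask.shape != np.asarray(dose.values).shape:
        raise GridIncompatibilityError(
            f"mask shape {mask.shape} != dose shape {np.shape(dose.values)}"
        )
    mask = mask.astype(bool)
    if not mask.any():
        raise EmptyStructureError("mandible mask is empty")
    return DoseGrid(
        values=np.where(mask, dose.values, 0.0),
        spacing=dose.spacing,
        origin=dose.origin,
    )


def eqd2_correct(dose: DoseGrid, params: EQD2Params) -> DoseGrid:
    """Convert physical dose to EQD2 under uniform per-voxel fractionation."""
    d_per_fx = np.asarray(dose.values, dtype=float) / params.n_fractions
    factor = (d_per_fx + params.alpha_beta) / (2.0 + params.alpha_beta)
    out = np.asarray(dose.values, dtype=float) * factor
    return DoseGrid(values=out, spacing=dose.spacing, origin=dose.origin)


def fit_normalisation(
    maps: Iterable[np.ndarray | DoseGrid], fit_scope: str = "development"
) -> NormalisationStats:
    """Global min/max over every voxel of every map in the collection."""
    gmin, gmax = np.inf, -np.inf
    count = 0
    for m in maps:
        v = m.values if isinstance(m, DoseGrid) else np.asarray(m)
        gmin = min(gmin, float(v.min()))
        gmax = max(gmax, float(v.max()))
        count += 1
    if count == 0:
        raise ValueError("cannot fit normalisation on an empty collection")
    if not gmax > gmin:
        raise DegenerateRangeError("all voxel values identical across the cohort")
    return NormalisationStats(global_min=gmin, global_max=gmax, fit_scope=fit_scope)


def apply_normalisation(values: np.ndarray, stats: NormalisationStats) -> np.ndarray:
    """Min--max scale to [0, 1]; out-of-range values (reused stats) are clipped."""
    v = (np.asarray(values, dtype=float) - stats.global_min) / (
        stats.global_max - stats.global_min
    )
    return np.clip(v, 0.0, 1.0)


def denormalise(values: np.ndarray, stats: NormalisationStats) -> np.ndarray:
    """Inverse of :func:`apply_normalisation` inside the fit range."""
    return np.asarray(values, dtype=float) * (
        stats.global_max - stats.global_min
    ) + stats.global_min


def mask_bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    """Tight bounding box of the nonzero mask voxels."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyStructureError("mandible mask is empty")
    slices = []
    for axis in range(3):
        axes = tuple(a for a in range(3) if a != axis)
        prof = mask.any(axis=axes)
        idx = np.where(prof)[0]
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return tuple(slices)


def crop_resample(
    dose_values: np.ndarray,
    mask: np.ndarray,
    target_shape: Sequence[int],
    margin: int = 2,
    allow_resample: bool = True,
    subject_id: str = "",
    eqd2_applied: bool = False,
) -> MandibleDoseMap:
    """Crop to the mask bounding box (+margin) and fit to ``target_shape``.

    Crops smaller than the target along every axis are zero-padded and
    centred without interpolation; larger crops are resampled (linear for
    dose, nearest-neighbour for the mask) unless ``allow_resample`` is False.
    """
    dose_values = np.asarray(dose_values, dtype=float)
    mask = np.asarray(mask)
    if mask.shape != dose_values.shape:
        raise GridIncompatibilityError("dose/mask shape mismatch")
    target_shape = tuple(int(t) for t in target_shape)

    box = mask_bounding_box(mask)
    padded = tuple(
        slice(max(0, s.start - margin), min(n, s.stop + margin))
        for s, n in zip(box, dose_values.shape)
    )
    dose_c = dose_values[padded]
    mask_c = mask[padded].astype(float)

    if any(c > t for c, t in zip(dose_c.shape, target_shape)):
        if not allow_resample:
            raise ValueError(
                f"crop {dose_c.shape} exceeds target {target_shape} and "
                "resampling is disabled"
            )
        zoom = [t / c for t, c in zip(target_shape, dose_c.shape)]
        dose_c = ndimage.zoom(dose_c, zoom, order=1, grid_mode=True, mode="grid-constant")
        mask_c = ndimage.zoom(mask_c, zoom, order=0, grid_mode=True, mode="grid-constant")
        dose_c = dose_c[tuple(slice(0, t) for t in target_shape)]
        mask_c = mask_c[tuple(slice(0, t) for t in target_shape)]

    out_dose = np.zeros(target_shape)
    out_mask = np.zeros(target_shape)
    offsets = [(t - c) // 2 for t, c in zip(target_shape, dose_c.shape)]
    ins = tuple(slice(o, o + c) for o, c in zip(offsets, dose_c.shape))
    out_dose[ins] = dose_c
    out_mask[ins] = mask_c
    out_mask = (out_mask > 0.5).astype(np.uint8)
    out_dose *= out_mask

    meta = {
        "subject_id": subject_id,
        "eqd2_applied": eqd2_applied,
        "crop_bounding_box": [[s.start, s.stop] for s in padded],
    }
    return MandibleDoseMap(values=out_dose, mask=out_mask, meta=meta)


def sample_augmentation(
    config: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Draw per-axis rotation angles (rad) and a zoom factor from the config ranges."""
    angles = rng.uniform(*config.rotation_range, size=3)
    zoom = float(rng.uniform(*config.zoom_range))
    return angles, zoom


def augment(
    volume: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply a random small rotation + zoom about the volume centre.

    Linear interpolation; output clipped back into [0, 1] so augmented
    normalised maps remain valid network inputs.
    """
    if not config.enabled:
        return np.asarray(volume, dtype=float).copy()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    volume = np.asarray(volume, dtype=float)
    angles, zoom = sample_augmentation(config, rng)

    def rot(axis_angles):
        ax, ay, az = axis_angles
        rx = np.array(
            [[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]]
        )
        ry = np.array(
            [[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]]
        )
        rz = np.array(
            [[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]]
        )
        return rz @ ry @ rx

    matrix = rot(angles) / zoom
    centre = (np.array(volume.shape) - 1) / 2.0
    offset = centre - matrix @ centre
    out = ndimage.affine_transform(volume, matrix, offset=offset, order=1, mode="constant")
    return np.clip(out, 0.0, 1.0)


def preprocess_subject(
    dose: DoseGrid,
    mask: np.ndarray,
    eqd2: EQD2Params,
    stats: NormalisationStats | None,
    target_shape: Sequence[int],
    margin: int = 2,
    subject_id: str = "",
) -> MandibleDoseMap:
    """The full per-subject pipeline: mask -> EQD2 -> crop/resample -> normalise.

    When ``stats`` is None the map is left in Gy (used while the cohort-level
    normalisation is being fitted).
    """
    masked = mask_dose(dose, mask)
    corrected = eqd2_correct(masked, eqd2)
    dmap = crop_resample(
        corrected.values,
        mask,
        target_shape,
        margin=margin,
        subject_id=subject_id,
        eqd2_applied=True,
    )
    if stats is not None:
        dmap.values = apply_normalisation(dmap.values, stats) * dmap.mask
    return dmap
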