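"""Cumulative dose-volume histograms and the Dx% / VxGy metric panel.

DVH metrics are computed on physical (or EQD2-corrected) dose in Gy, never on
network-normalised values.  ``Dx%`` is the minimum dose received by the
hottest x% of the structure volume; ``VxGy`` is the percent of structure
volume receiving at least x Gy.  All voxels are assumed to have equal volume
(uniform grid), so relative volume is a voxel fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: x-values (percent volume) of the Dx% panel: D2, D5..D95 in steps of 5, D98.
DX_LEVELS: tuple[float, ...] = (2.0, *range(5, 100, 5), 98.0)
#: x-values (Gy) of the VxGy panel: V5, V10 .. V70.
VX_LEVELS: tuple[float, ...] = tuple(float(v) for v in range(5, 75, 5))


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: fraction of structure receiving >= each dose level.

    Attributes
    ----------
    dose_grid_points:
        Ascending dose values (Gy), left bin edges starting at 0.
    relative_volume:
        Percent of structure volume receiving at least the corresponding dose.
        Non-increasing, starts at 100 for dose 0.
    """

    dose_grid_points: np.ndarray
    relative_volume: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.relative_volume) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


@dataclass(frozen=True)
class DVHMetricPanel:
    """The DVH metric panel used by the logistic NTCP baseline.

    ``dx`` maps volume levels (%) to Dx% doses in Gy; ``vx`` maps dose levels
    (Gy) to VxGy relative volumes in percent.
    """

    dx: dict[float, float] = field(default_factory=dict)
    vx: dict[float, float] = field(default_factory=dict)

    def as_series(self, prefix_subject: str | None = None) -> pd.Series:
        """Flatten into a named series, e.g. ``D2`` ... ``D98``, ``V5`` ... ``V70``."""
        data: dict[str, float] = {}
        for x, v in self.dx.items():
            data[f"D{x:g}"] = v
        for x, v in self.vx.items():
            data[f"V{x:g}"] = v
        return pd.Series(data, name=prefix_subject)


def _as_voxels(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("DVH requires at least one in-mask voxel")
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValueError("dose values must be finite and non-negative")
    return values


def compute_dvh(values: np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of in-mask voxel doses with equal voxel volumes.

    Parameters
    ----------
    values:
        In-mask voxel doses in Gy (any shape; flattened).
    bin_width:
        Dose resolution of the curve in Gy (default 0.1).
    """
    values = _as_voxels(values)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = float(values.max()) + bin_width
    grid = np.arange(0.0, top + bin_width, bin_width)
    # % of voxels with dose >= grid point; tolerance absorbs float error in
    # the accumulated grid so doses landing exactly on a bin edge count
    rel = (values[None, :] >= grid[:, None] - 1e-9).mean(axis=1) * 100.0
    return DVHCurve(dose_grid_points=grid, relative_volume=rel)


def dose_at_volume(
    values: np.ndarray, x: float, interpolate: bool = False
) -> float:
    """Dx%: minimum dose received by the hottest ``x`` percent of the volume.

    Computed on the sorted voxel array.  With the default nearest-voxel
    convention the hottest ``ceil(x/100 * n)`` voxels are taken and their
    minimum returned; ``interpolate=True`` uses a linear quantile instead.
    """
    values = _as_voxels(values)
    if not 0 < x <= 100:
        raise ValueError("volume level x must be in (0, 100]")
    if interpolate:
        return float(np.quantile(values, 1.0 - x / 100.0, method="linear"))
    desc = np.sort(values)[::-1]
    k = math.ceil(x / 100.0 * values.size)
    return float(desc[k - 1])


def volume_at_dose(values: np.ndarray, x: float) -> float:
    """VxGy: percent of structure volume receiving >= ``x`` Gy (>= includes equality)."""
    values = _as_voxels(values)
    if x < 0:
        raise ValueError("dose level x must be non-negative")
    return float((values >= x).mean() * 100.0)


def extract_panel(values: np.ndarray, interpolate: bool = False) -> DVHMetricPanel:
    """Compute the full Dx%/VxGy panel from in-mask voxel doses."""
    values = _as_voxels(values)
    dx = {x: dose_at_volume(values, x, interpolate=interpolate) for x in DX_LEVELS}
    vx = {x: volume_at_dose(values, x) for x in VX_LEVELS}
    return DVHMetricPanel(dx=dx, vx=vx)


def panel_table(
    voxels_by_subject: dict[str, np.ndarray], interpolate: bool = False
) -> pd.DataFrame:
    """One row per subject, one column per panel metric (plus index subject_id)."""
    rows = {
        sid: extract_panel(v, interpolate=interpolate).as_series()
        for sid, v in voxels_by_subject.items()
    }
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    return table
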