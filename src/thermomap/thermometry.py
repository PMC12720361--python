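"""Per-region temperature extraction from IR temperature matrices.

Thermal cameras export a per-pixel temperature matrix alongside each IR
image; given the mapped region masks, region statistics are plain pixel
statistics over the mask.  Group reporting aggregates per-bird region means
across rearing density, age, and condition (experimental vs. control).  No
emissivity or distance correction is applied: the camera applies its
emissivity setting (0.96 here) internally, and the value travels as rig
metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyROIError,
    EmptyRegionWarning,
    InvalidInputError,
    ShapeError,
    TemperatureRangeWarning,
)
from .roi_mapping import HEAD_REGIONS, RegionLabel, ROISet

__all__ = [
    "TemperatureMatrix",
    "RegionTemperature",
    "GroupKey",
    "region_stats",
    "group_report",
    "read_temperature_csv",
    "write_temperature_csv",
]

PLAUSIBLE_RANGE_C = (-20.0, 80.0)


@dataclass
class TemperatureMatrix:
    """Per-pixel temperatures in degC aligned 1:1 with the IR pixel grid."""

    grid: np.ndarray
    frame_id: str | None = None
    timestamp: str | None = None  # capture label, e.g. "16:30"

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise InvalidInputError("temperature matrix must be 2-D")
        if not np.isfinite(g).all():
            raise InvalidInputError("temperatures must be finite")
        lo, hi = PLAUSIBLE_RANGE_C
        if g.min() < lo or g.max() > hi:
            warnings.warn(
                f"temperatures outside the plausible [{lo}, {hi}] degC range "
                f"(observed [{g.min():.1f}, {g.max():.1f}])",
                TemperatureRangeWarning,
                stacklevel=2,
            )
        self.grid = g

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class RegionTemperature:
    """Temperature statistics of one region in one frame."""

    region: RegionLabel
    mean: float
    min: float
    max: float
    pixel_count: int


@dataclass(frozen=True)
class GroupKey:
    """Experimental cell: rearing density (birds/m2), age (weeks), condition."""

    density: int
    age_weeks: int
    condition: str

    def __post_init__(self):
        if self.condition not in ("experimental", "control"):
            raise InvalidInputError("condition must be 'experimental' or 'control'")


def region_stats(
    t: TemperatureMatrix, roi: ROISet, *, regions=HEAD_REGIONS
) -> list[RegionTemperature]:
    """Mean/min/max temperature over each non-empty region mask.

    Empty regions are omitted with an :class:`EmptyRegionWarning`; if every
    requested region is empty an :class:`EmptyROIError` is raised.
    """
    if t.shape != roi.shape:
        raise ShapeError(
            f"temperature grid {t.shape} does not match ROI grid {roi.shape}"
        )
    out = []
    for region in regions:
        mask = roi.masks.get(region)
        if mask is None or not mask.any():
            warnings.warn(
                f"region {region.name.lower()} has an empty mask; omitted",
                EmptyRegionWarning,
                stacklevel=2,
            )
            continue
        vals = t.grid[mask]
        out.append(
            RegionTemperature(
                region=region,
                mean=float(vals.mean()),
                min=float(vals.min()),
                max=float(vals.max()),
                pixel_count=int(vals.size),
            )
        )
    if not out:
        raise EmptyROIError("every requested region mask is empty")
    return out


def group_report(records, *, pooled_pixels: bool = False) -> pd.DataFrame:
    """Aggregate region temperatures into group means.

    ``records`` is an iterable of ``(GroupKey, bird_id, RegionTemperature)``
    (or ``(GroupKey, RegionTemperature)``, treating every record as its own
    bird).  Default aggregation averages each bird's frame means first, then
    averages across birds (n = birds); ``pooled_pixels=True`` instead pools
    all pixels of the cell with pixel-count weights.

    Returns a long-format table with columns density, age_weeks, condition,
    region, mean_c, n, ordered by density, age, condition, region; cells with
    no records are simply absent.
    """
    rows = []
    for i, rec in enumerate(records):
        if len(rec) == 2:
            key, rt = rec
            bird = f"_bird{i}"
        else:
            key, bird, rt = rec
        rows.append(
            {
                "density": key.density,
                "age_weeks": key.age_weeks,
                "condition": key.condition,
                "region": rt.region.name.lower(),
                "bird": bird,
                "mean_c": rt.mean,
                "pixel_count": rt.pixel_count,
            }
        )
    if not rows:
        raise InvalidInputError("group_report needs at least one record")
    df = pd.DataFrame(rows)
    keys = ["density", "age_weeks", "condition", "region"]
    if pooled_pixels:
        df["wsum"] = df.mean_c * df.pixel_count
        g = df.groupby(keys, as_index=False).agg(
            wsum=("wsum", "sum"), px=("pixel_count", "sum"), n=("bird", "nunique")
        )
        g["mean_c"] = g.wsum / g.px
        out = g[keys + ["mean_c", "n"]]
    else:
        per_bird = df.groupby(keys + ["bird"], as_index=False).agg(
            mean_c=("mean_c", "mean")
        )
        out = per_bird.groupby(keys, as_index=False).agg(
            mean_c=("mean_c", "mean"), n=("bird", "size")
        )
    region_order = {r.name.lower(): int(r) for r in HEAD_REGIONS}
    out = out.assign(_r=out.region.map(region_order))
    out = (
        out.sort_values(["density", "age_weeks", "condition", "_r"])
        .drop(columns="_r")
        .reset_index(drop=True)
    )
    return out


def write_temperature_csv(t: TemperatureMatrix, path) -> None:
    """Headerless CSV of floats, one row per IR image row."""
    np.savetxt(path, t.grid, delimiter=",", fmt="%.6g")


def read_temperature_csv(path, frame_id=None, timestamp=None) -> TemperatureMatrix:
    grid = np.loadtxt(path, delimiter=",", ndmin=2)
    return TemperatureMatrix(grid, frame_id=frame_id, timestamp=timestamp)
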