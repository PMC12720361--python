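"""Mask-level RGB->IR transfer: contours out, mapped contours in, filled masks.

A label mask on the RGB grid is decomposed into per-region outer contours
(Moore-neighbor border following on 8-connected components), every contour
point is pushed through the per-point mapping chain, and the mapped contours
are closed and filled on the IR grid (nonzero winding, edge-inclusive pixel
centers) to form the regions of interest used for thermometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from . import camera_geometry as cg
from .errors import DegenerateContourWarning, InvalidInputError, LabelError

__all__ = [
    "RegionLabel",
    "HEAD_REGIONS",
    "LabelMask",
    "Contour",
    "ROISet",
    "extract_contours",
    "map_contour",
    "rasterize_contour",
    "map_label_mask",
    "read_label_mask",
    "write_label_mask",
    "read_roiset",
    "write_roiset",
]


class RegionLabel(IntEnum):
    """Fixed class table for the head-region masks."""

    BACKGROUND = 0
    COMB = 1
    EYE = 2
    BEAK = 3
    WATTLE = 4


#: The four thermometry regions, in the fixed code order.
HEAD_REGIONS = (RegionLabel.COMB, RegionLabel.EYE, RegionLabel.BEAK, RegionLabel.WATTLE)

#: Flattening order: later labels overwrite earlier ones, so the smallest
#: structures (eye last) win ties where mapped regions overlap.
FLATTEN_ORDER = (RegionLabel.COMB, RegionLabel.WATTLE, RegionLabel.BEAK, RegionLabel.EYE)


@dataclass
class LabelMask:
    """Integer-coded per-pixel region labels on one channel's grid."""

    grid: np.ndarray
    frame: str = "rgb"

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise InvalidInputError("label mask must be 2-D")
        if self.frame not in ("rgb", "ir"):
            raise InvalidInputError("frame must be 'rgb' or 'ir'")
        valid = {int(r) for r in RegionLabel}
        codes = set(np.unique(g).tolist())
        if not codes <= valid:
            raise LabelError(f"unknown label codes: {sorted(codes - valid)}")
        self.grid = g.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def region_mask(self, region: RegionLabel) -> np.ndarray:
        return self.grid == int(region)


@dataclass
class Contour:
    """Closed outer boundary of one connected region component.

    ``points`` is (N, 2) float in (u, v) = (column, row) order; the edge from
    the last point back to the first is implicit.  Orientation is normalized
    so the shoelace signed area in (u, v) axes is non-negative.
    """

    points: np.ndarray
    region: RegionLabel = RegionLabel.BACKGROUND

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError("contour points must be (N, 2)")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        p, q = self.points, np.roll(self.points, -1, axis=0)
        return 0.5 * float(np.sum(p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]))


@dataclass
class ROISet:
    """Per-region binary masks on the IR grid, with mapping provenance."""

    masks: dict[RegionLabel, np.ndarray]
    depth_used: float
    out_of_bounds_fraction: dict[RegionLabel, float] = field(default_factory=dict)
    source: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def flatten(self) -> np.ndarray:
        """Single IR label map; overlaps resolved by FLATTEN_ORDER."""
        out = np.zeros(self.shape, dtype=np.uint8)
        for region in FLATTEN_ORDER:
            if region in self.masks:
                out[self.masks[region]] = int(region)
        return out


# ---------------------------------------------------------------------------
# Contour extraction (Moore-neighbor border following)
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise screen order starting North (dr, dc).
_MOORE = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}


def _trace_boundary(comp: np.ndarray) -> np.ndarray:
    """Outer boundary pixels of a padded binary component, Moore tracing.

    ``comp`` must have a 1-pixel false border.  Returns (N, 2) int (row, col).
    """
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[rows == rows[0]].min()))
    back0 = (start[0], start[1] - 1)  # west of topmost-leftmost: background
    boundary = [start]
    cur, back = start, back0
    # the walk is a deterministic map on (pixel, backtrack) states, so the
    # first repeated state closes the tour; tracking them guarantees
    # termination even on shapes where the initial state is never re-entered
    seen = {(cur, back)}
    while True:
        k = _MOORE_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for step in range(1, 9):
            dr, dc = _MOORE[(k + step) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if comp[cand]:
                nxt = cand
                break
            back = cand
        if nxt is None:  # isolated pixel
            break
        cur = nxt
        if (cur, back) in seen:
            break
        seen.add((cur, back))
        boundary.append(cur)
    return np.asarray(boundary, dtype=int)


def extract_contours(
    mask: LabelMask, region: RegionLabel, *, min_area: int = 5
) -> list[Contour]:
    """Outer contour of each 8-connected component of ``region``.

    Components smaller than ``min_area`` pixels are suppressed (segmentation
    specks).  Contour points are pixel centers of the component's boundary
    pixels, ordered with non-negative shoelace area; an absent region yields
    an empty list.
    """
    binary = mask.region_mask(region)
    if not binary.any():
        return []
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    contours = []
    for sl, idx in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        comp = labeled[sl] == idx
        if comp.sum() < min_area:
            continue
        padded = np.pad(comp, 1)
        rc = _trace_boundary(padded)
        # back to full-image (u, v) coordinates
        uv = np.column_stack(
            [rc[:, 1] - 1 + sl[1].start, rc[:, 0] - 1 + sl[0].start]
        ).astype(float)
        c = Contour(uv, region)
        if c.signed_area < 0:
            c = Contour(uv[::-1], region)
        contours.append(c)
    return contours


# ---------------------------------------------------------------------------
# Mapping and rasterization
# ---------------------------------------------------------------------------


def map_contour(c: Contour, rig: cg.CameraRig, depth: float) -> Contour:
    """Map every contour vertex through the RGB->IR chain; order preserved."""
    mapped = cg.map_pixel_rgb_to_ir(c.points, rig, depth)
    return Contour(mapped, c.region)


def rasterize_contour(
    c: Contour | np.ndarray, height: int, width: int, *, eps: float = 1e-9
) -> np.ndarray:
    """Fill a closed polygon on a ``height`` x ``width`` pixel grid.

    A pixel (u, v) is set iff its center lies strictly inside the polygon
    under the nonzero winding rule, or exactly on an edge (within ``eps``).
    The polygon is clipped to the image bounds.  Fewer than 3 vertices yields
    an empty mask plus a :class:`DegenerateContourWarning`.

    Scanline implementation: per pixel row, signed edge crossings are
    accumulated left-to-right, which keeps the cost at O(rows x edges).
    """
    pts = c.points if isinstance(c, Contour) else np.asarray(c, dtype=float)
    out = np.zeros((height, width), dtype=bool)
    if len(pts) < 3:
        warnings.warn(
            f"contour with {len(pts)} point(s) cannot be filled",
            DegenerateContourWarning,
            stacklevel=2,
        )
        return out
    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    v_lo = max(0, int(np.ceil(y1.min() - eps)))
    v_hi = min(height - 1, int(np.floor(y1.max() + eps)))
    u_lo = max(0, int(np.ceil(x1.min() - eps)))
    u_hi = min(width - 1, int(np.floor(x1.max() + eps)))
    if v_lo > v_hi or u_lo > u_hi:
        return out
    px = np.arange(u_lo, u_hi + 1, dtype=float)
    horiz = np.abs(y1 - y2) <= eps
    for py in range(v_lo, v_hi + 1):
        up = (y1 <= py) & (py < y2)
        down = (y2 <= py) & (py < y1)
        cross = up | down
        row = np.zeros(len(px), dtype=bool)
        if cross.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                xc = x1[cross] + (py - y1[cross]) * (x2[cross] - x1[cross]) / (
                    y2[cross] - y1[cross]
                )
            dirs = np.where(up[cross], 1, -1)
            order = np.argsort(xc, kind="stable")
            xs, ds = xc[order], dirs[order]
            prefix = np.concatenate([[0], np.cumsum(ds)])
            wn = prefix[np.searchsorted(xs, px - eps, side="left")]
            on_edge = (np.abs(xs[:, None] - px[None, :]) <= eps).any(axis=0)
            row = (wn != 0) | on_edge
        hm = horiz & (np.abs(y1 - py) <= eps)
        if hm.any():
            for a, b in zip(x1[hm], x2[hm]):
                lo, hi = (a, b) if a <= b else (b, a)
                row |= (px >= lo - eps) & (px <= hi + eps)
        out[py, u_lo : u_hi + 1] = row
    return out


def _roiset_from_contours(
    contours_by_region: dict[RegionLabel, list[Contour]],
    rig: cg.CameraRig,
    depth: float,
    source: str | None = None,
) -> ROISet:
    """Map + rasterize pre-extracted contours (shared by sweep and map)."""
    h, w = rig.ir_shape
    masks, oob = {}, {}
    for region in HEAD_REGIONS:
        acc = np.zeros((h, w), dtype=bool)
        n_pts = n_oob = 0
        for c in contours_by_region.get(region, []):
            mapped, flags = cg.map_pixel_rgb_to_ir(
                c.points, rig, depth, return_out_of_bounds=True
            )
            n_pts += len(mapped)
            n_oob += int(flags.sum())
            acc |= rasterize_contour(Contour(mapped, region), h, w)
        masks[region] = acc
        oob[region] = (n_oob / n_pts) if n_pts else 0.0
    return ROISet(masks, depth_used=float(depth), out_of_bounds_fraction=oob, source=source)


def map_label_mask(
    mask: LabelMask,
    rig: cg.CameraRig,
    depth: float,
    *,
    min_area: int = 5,
    source: str | None = None,
) -> ROISet:
    """Map a full RGB label mask into per-region IR masks at one working depth.

    For each head region, the union of the rasterized mapped contours of all
    its connected components.  Regions absent from the input come out empty.
    """
    if mask.frame != "rgb":
        raise InvalidInputError("map_label_mask expects a mask on the RGB grid")
    contours = {
        region: extract_contours(mask, region, min_area=min_area)
        for region in HEAD_REGIONS
    }
    return _roiset_from_contours(contours, rig, depth, source=source)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_label_mask(mask: LabelMask, path) -> None:
    """8-bit single-channel PNG with the fixed code table."""
    Image.fromarray(mask.grid, mode="L").save(path)


def read_label_mask(path, frame: str = "rgb") -> LabelMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return LabelMask(arr, frame=frame)


def write_roiset(roi: ROISet, out_dir) -> None:
    """One binary PNG per region plus a JSON sidecar with provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for region, m in roi.masks.items():
        Image.fromarray((m.astype(np.uint8)) * 255, mode="L").save(
            out / f"roi_{region.name.lower()}.png"
        )
    sidecar = {
        "depth_used_mm": roi.depth_used,
        "out_of_bounds_fraction": {
            r.name.lower(): v for r, v in roi.out_of_bounds_fraction.items()
        },
        "source": roi.source,
    }
    with open(out / "roi.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def read_roiset(out_dir) -> ROISet:
    out = Path(out_dir)
    with open(out / "roi.json") as fh:
        sidecar = json.load(fh)
    masks, oob = {}, {}
    for region in HEAD_REGIONS:
        p = out / f"roi_{region.name.lower()}.png"
        if p.exists():
            masks[region] = np.asarray(Image.open(p).convert("L")) > 127
        frac = sidecar.get("out_of_bounds_fraction", {}).get(region.name.lower())
        if frac is not None:
            oob[region] = frac
    return ROISet(
        masks,
        depth_used=sidecar["depth_used_mm"],
        out_of_bounds_fraction=oob,
        source=sidecar.get("source"),
    )
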