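"""Synthetic dual-channel scenes: rigs, checkerboard corners, masks, temperatures.

No RGB-IR poultry dataset is publicly available, so every other module is
exercised against synthetic scenes: a plausible Hikvision-like rig (RGB
2688x1520, IR 384x288, X-dominant baseline), planar checkerboard corner
observations for calibration, head-region polygon templates placed on the
600 mm working plane, ground-truth IR masks obtained by *direct projection*
of the generating geometry (never through the mapping pipeline under test,
and rasterized with shapely rather than the toolkit's own rasterizer, so the
two paths stay independent), and smooth region-dependent temperature fields.

Region templates are stylized polygons (serrated crown for the comb, lobe
for the wattle, ellipse for the eye, triangle for the beak) sized like a
real bird's head appendages; biological realism beyond that is a non-goal.
Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon

from . import camera_geometry as cg
from .errors import InvalidInputError, PlacementError, RegionOverlapWarning
from .roi_mapping import (
    HEAD_REGIONS,
    Contour,
    LabelMask,
    RegionLabel,
    ROISet,
    rasterize_contour,
)
from .segmentation_support import DEFAULT_COLOR_TABLE
from .thermometry import TemperatureMatrix

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "make_rig",
    "make_checkerboard_observations",
    "make_scene",
    "make_scene_pair",
]

#: Region mean temperatures (degC) for the control condition; comb and
#: wattle warmest, as in side-view thermograms of heat-exposed birds.
DEFAULT_REGION_MEANS_C = {
    RegionLabel.COMB: 38.5,
    RegionLabel.EYE: 36.5,
    RegionLabel.BEAK: 33.5,
    RegionLabel.WATTLE: 38.0,
}

_PRESETS = ("realistic", "realistic-small", "zero-baseline", "identity")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; the defaults are the emulated acquisition conditions."""

    preset: str = "realistic"
    seed: int = 0
    depth_mm: float = 600.0
    condition: str = "control"  # or "experimental" (heat stress)
    region_means_c: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEANS_C)
    )
    heat_stress_delta_c: float = 2.5  # added to comb and wattle when experimental
    background_range_c: tuple[float, float] = (26.0, 30.0)
    noise_sigma_c: float = 0.3
    boundary_softness_px: float = 3.0  # gradual region-to-background transition
    scale: float = 1.0  # region template scale factor
    jitter: float = 0.05  # relative geometric jitter
    max_overlap_fraction: float = 0.05

    def __post_init__(self):
        if self.preset not in _PRESETS:
            raise InvalidInputError(f"unknown preset {self.preset!r}; one of {_PRESETS}")
        if self.depth_mm <= 0:
            raise InvalidInputError("depth must be positive")
        if self.noise_sigma_c < 0:
            raise InvalidInputError("noise sigma must be >= 0")
        if self.condition not in ("control", "experimental"):
            raise InvalidInputError("condition must be 'control' or 'experimental'")

    def effective_region_means(self) -> dict[RegionLabel, float]:
        means = dict(self.region_means_c)
        if self.condition == "experimental":
            for r in (RegionLabel.COMB, RegionLabel.WATTLE):
                means[r] = means[r] + self.heat_stress_delta_c
        return means


@dataclass
class SyntheticScene:
    """A generated frame pair: inputs plus the ground truth that produced them."""

    rig: cg.CameraRig
    rgb_mask: LabelMask
    rgb_color: np.ndarray  # (H, W, 3) uint8 color-coded regions
    gt_ir: ROISet  # ground-truth IR masks by direct projection
    temps: TemperatureMatrix
    spec: SceneSpec
    region_means: dict[RegionLabel, float]  # effective generating means, degC
    polygons_mm: dict[RegionLabel, np.ndarray]  # plane-frame generating geometry


# ---------------------------------------------------------------------------
# Rigs
# ---------------------------------------------------------------------------


def make_rig(
    preset: str = "realistic",
    seed: int = 0,
    *,
    baseline_mm: float | None = None,
    distortion_scale: float = 1.0,
    rotation_scale: float = 1.0,
) -> cg.CameraRig:
    """Deterministic synthetic rig for a given (preset, seed).

    ``realistic`` uses the printed sensor resolutions with plausible focal
    lengths (RGB ~2100 px, IR ~380 px) and a 47 mm X-dominant baseline;
    ``realistic-small`` is the same angular geometry at quarter resolution
    (672x380 / 96x72) for fast runs; ``zero-baseline`` has no translation
    (depth-independent mapping); ``identity`` has equal channels, no
    distortion and identity extrinsics (the mapping is the identity).
    ``distortion_scale=0`` and ``rotation_scale=0`` yield the pure-baseline,
    zero-distortion rigs used by the closed-form parallax analyses.
    """
    rng = np.random.default_rng(seed)
    if preset == "identity":
        intr = cg.Intrinsics(380.0, 380.0, 192.0, 144.0, 384, 288)
        ch = cg.CameraChannel(intr, cg.DistortionCoeffs())
        return cg.CameraRig(rgb=ch, ir=ch, extrinsics=cg.RigExtrinsics.identity())

    s = 0.25 if preset == "realistic-small" else 1.0
    jit = lambda lo, hi: float(rng.uniform(lo, hi))
    rgb_intr = cg.Intrinsics(
        2100.0 * (1 + jit(-0.02, 0.02)) * s,
        2100.0 * (1 + jit(-0.02, 0.02)) * s,
        (1344.0 + jit(-8, 8)) * s,
        (760.0 + jit(-8, 8)) * s,
        int(2688 * s),
        int(1520 * s),
    )
    ir_intr = cg.Intrinsics(
        380.0 * (1 + jit(-0.02, 0.02)) * s,
        380.0 * (1 + jit(-0.02, 0.02)) * s,
        (192.0 + jit(-3, 3)) * s,
        (144.0 + jit(-3, 3)) * s,
        int(384 * s),
        int(288 * s),
    )
    ds = distortion_scale
    rgb_dist = cg.DistortionCoeffs(
        k1=jit(-0.12, -0.05) * ds,
        k2=jit(0.01, 0.05) * ds,
        p1=jit(-8e-4, 8e-4) * ds,
        p2=jit(-8e-4, 8e-4) * ds,
        k3=0.0,
    )
    ir_dist = cg.DistortionCoeffs(
        k1=jit(-0.20, -0.08) * ds,
        k2=jit(0.02, 0.08) * ds,
        p1=jit(-5e-4, 5e-4) * ds,
        p2=jit(-5e-4, 5e-4) * ds,
        k3=0.0,
    )
    if preset == "zero-baseline":
        t = np.zeros(3)
    else:
        b = 47.0 if baseline_mm is None else float(baseline_mm)
        t = np.array(
            [b, rng.normal(0, 1.5) * rotation_scale, rng.normal(0, 1.5) * rotation_scale]
        )
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle_deg = jit(0.2, 0.8) * rotation_scale
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    return cg.CameraRig(
        rgb=cg.CameraChannel(rgb_intr, rgb_dist),
        ir=cg.CameraChannel(ir_intr, ir_dist),
        extrinsics=cg.RigExtrinsics(R, t),
    )


# ---------------------------------------------------------------------------
# Checkerboard observations
# ---------------------------------------------------------------------------


def _project_channel(pts_cam: np.ndarray, ch: cg.CameraChannel) -> np.ndarray:
    return cg.project_to_ir(pts_cam, ch.intrinsics, ch.distortion)


def make_checkerboard_observations(
    rig: cg.CameraRig,
    board: cg.CheckerboardSpec,
    n_poses: int,
    noise_sd_px: float = 0.0,
    seed: int = 0,
    *,
    max_attempts: int = 1000,
) -> cg.CornerObservations:
    """Project randomly posed planar boards through both channels.

    Poses are sampled (tilt up to ~30 degrees, varied standoff) and rejected
    until the full inner-corner grid is visible in both frames; optional
    Gaussian pixel noise is added per detection.  Raises
    :class:`PlacementError` if no visible pose is found in ``max_attempts``.
    """
    if n_poses < 1:
        raise InvalidInputError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    board_ij = board.corner_grid()
    pts_board = board.corner_points_mm(board_ij)
    center = pts_board.mean(axis=0)
    pts_board = pts_board - center
    margin = 4.0
    poses = []
    for pose_id in range(n_poses):
        for _ in range(max_attempts):
            rot = Rotation.from_euler(
                "xyz",
                [
                    rng.uniform(-28, 28),
                    rng.uniform(-28, 28),
                    rng.uniform(-180, 180),
                ],
                degrees=True,
            ).as_matrix()
            t = np.array(
                [rng.uniform(-40, 40), rng.uniform(-30, 30), rng.uniform(780, 1150)]
            )
            cam_rgb = pts_board @ rot.T + t
            if cam_rgb[:, 2].min() <= 1.0:
                continue
            cam_ir = cg.transform_rgb_to_ir(cam_rgb, rig.extrinsics)
            if cam_ir[:, 2].min() <= 1.0:
                continue
            px_rgb = _project_channel(cam_rgb, rig.rgb)
            px_ir = _project_channel(cam_ir, rig.ir)
            ok = True
            for px, intr in ((px_rgb, rig.rgb.intrinsics), (px_ir, rig.ir.intrinsics)):
                if (
                    px[:, 0].min() < margin
                    or px[:, 0].max() > intr.width - 1 - margin
                    or px[:, 1].min() < margin
                    or px[:, 1].max() > intr.height - 1 - margin
                ):
                    ok = False
                    break
            if not ok:
                continue
            if noise_sd_px > 0:
                px_rgb = px_rgb + rng.normal(0, noise_sd_px, px_rgb.shape)
                px_ir = px_ir + rng.normal(0, noise_sd_px, px_ir.shape)
            poses.append(
                cg.PoseCorners(pose_id, board_ij, {"rgb": px_rgb, "ir": px_ir})
            )
            break
        else:
            raise PlacementError(
                f"could not place pose {pose_id} visible in both channels "
                f"after {max_attempts} attempts"
            )
    return cg.CornerObservations(poses)


# ---------------------------------------------------------------------------
# Head-region geometry on the working plane
# ---------------------------------------------------------------------------


def _region_templates(rng: np.random.Generator, scale: float, jitter: float):
    """Plane-frame polygons (mm, X right / Y down) per region, jittered."""

    def j(v):
        return v * (1.0 + rng.uniform(-jitter, jitter))

    # comb: serrated crown above the head
    crown_top = [
        (-30, -35), (-25, -57), (-18, -40), (-11, -61), (-3, -42),
        (3, -63), (10, -43), (17, -59), (24, -39), (30, -35),
    ]
    comb = crown_top + [(30, -31), (-30, -31)]
    comb = np.array([(j(x), j(y)) for x, y in comb])

    # eye: ellipse, 24-gon
    th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    eye = np.column_stack(
        [8 + j(16.0) * np.cos(th), -8 + j(12.0) * np.sin(th)]
    )

    # beak: triangle pointing away from the head
    beak = np.array([(j(22), j(6)), (j(62), j(13)), (j(22), j(23))])

    # wattle: hanging lobe, radial-jitter 16-gon
    th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    rr = 1.0 + rng.uniform(-0.08, 0.08, size=th.size)
    wattle = np.column_stack(
        [j(-2) + 14.0 * rr * np.cos(th), 36 + 21.0 * rr * np.sin(th)]
    )

    head_off = np.array([rng.uniform(-30, 30), rng.uniform(-15, 15)])
    out = {}
    for region, poly in (
        (RegionLabel.COMB, comb),
        (RegionLabel.EYE, eye),
        (RegionLabel.BEAK, beak),
        (RegionLabel.WATTLE, wattle),
    ):
        out[region] = poly * scale + head_off
    return out


def _densify(poly: np.ndarray, max_step: float) -> np.ndarray:
    """Subdivide polygon edges so projected edges follow lens distortion."""
    out = []
    for a, b in zip(poly, np.roll(poly, -1, axis=0)):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / max_step)))
        for k in range(n):
            out.append(a + (b - a) * (k / n))
    return np.asarray(out)


def _shapely_rasterize(px_poly: np.ndarray, height: int, width: int) -> np.ndarray:
    """Boundary-inclusive pixel-center fill via shapely (oracle-grade path)."""
    poly = Polygon(px_poly)
    if not poly.is_valid:
        poly = poly.buffer(0)
    mask = np.zeros((height, width), dtype=bool)
    u_lo = max(0, int(np.floor(px_poly[:, 0].min())))
    u_hi = min(width - 1, int(np.ceil(px_poly[:, 0].max())))
    v_lo = max(0, int(np.floor(px_poly[:, 1].min())))
    v_hi = min(height - 1, int(np.ceil(px_poly[:, 1].max())))
    if u_lo > u_hi or v_lo > v_hi:
        return mask
    uu, vv = np.meshgrid(np.arange(u_lo, u_hi + 1), np.arange(v_lo, v_hi + 1))
    covered = shapely.intersects(shapely.points(uu.ravel(), vv.ravel()), poly)
    mask[v_lo : v_hi + 1, u_lo : u_hi + 1] = covered.reshape(uu.shape)
    return mask


def _background_field(
    rng: np.random.Generator, height: int, width: int, lo: float, hi: float
) -> np.ndarray:
    """Smooth low-order 2-D polynomial field scaled into [lo, hi] degC."""
    v, u = np.meshgrid(
        np.linspace(-1, 1, height), np.linspace(-1, 1, width), indexing="ij"
    )
    c = rng.uniform(-1, 1, size=6)
    f = c[0] + c[1] * u + c[2] * v + c[3] * u * v + c[4] * u * u + c[5] * v * v
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return lo + f * (hi - lo)


def make_scene(spec: SceneSpec, rig: cg.CameraRig | None = None) -> SyntheticScene:
    """Generate one fully reproducible synthetic frame pair.

    The RGB label mask is built by projecting the plane-frame region polygons
    through the RGB channel (with its forward distortion) and filling them at
    RGB resolution; the ground-truth IR masks come from projecting the *same
    3-D geometry* directly through the IR channel.  The temperature field is
    a smooth background with each region's pixels set to its generating mean,
    plus optional Gaussian noise, so noiseless region statistics recover the
    generating means exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if rig is None:
        rig = make_rig(spec.preset, seed=spec.seed)
    polys_mm = _region_templates(rng, spec.scale, spec.jitter)

    # overlap check on the generating geometry
    shapely_polys = {r: Polygon(p) for r, p in polys_mm.items()}
    for i, ra in enumerate(HEAD_REGIONS):
        for rb in HEAD_REGIONS[i + 1 :]:
            inter = shapely_polys[ra].intersection(shapely_polys[rb]).area
            frac = inter / min(shapely_polys[ra].area, shapely_polys[rb].area)
            if frac > spec.max_overlap_fraction:
                warnings.warn(
                    f"generated {ra.name.lower()} and {rb.name.lower()} overlap "
                    f"by {frac:.1%}",
                    RegionOverlapWarning,
                    stacklevel=2,
                )

    rgb_h, rgb_w = rig.rgb_shape
    ir_h, ir_w = rig.ir_shape
    rgb_grid = np.zeros((rgb_h, rgb_w), dtype=np.uint8)
    gt_masks: dict[RegionLabel, np.ndarray] = {}
    for region in HEAD_REGIONS:
        dense = _densify(polys_mm[region], max_step=2.0)
        pts3 = np.column_stack(
            [dense, np.full(len(dense), spec.depth_mm)]
        )
        pts3[:, 0] = dense[:, 0]
        pts3[:, 1] = dense[:, 1]
        px_rgb = _project_channel(pts3, rig.rgb)
        rgb_grid[rasterize_contour(Contour(px_rgb, region), rgb_h, rgb_w)] = int(region)
        pts3_ir = cg.transform_rgb_to_ir(pts3, rig.extrinsics)
        px_ir = _project_channel(pts3_ir, rig.ir)
        gt_masks[region] = _shapely_rasterize(px_ir, ir_h, ir_w)
    rgb_mask = LabelMask(rgb_grid, frame="rgb")
    gt_ir = ROISet(
        gt_masks,
        depth_used=spec.depth_mm,
        out_of_bounds_fraction={r: 0.0 for r in HEAD_REGIONS},
        source="ground-truth",
    )

    color = np.zeros((rgb_h, rgb_w, 3), dtype=np.uint8)
    for region, rgb_col in DEFAULT_COLOR_TABLE.items():
        color[rgb_grid == int(region)] = rgb_col

    means = spec.effective_region_means()
    temps = _background_field(rng, ir_h, ir_w, *spec.background_range_c)
    if spec.boundary_softness_px > 0:
        # thermal images are continuous: let each region's warmth decay
        # smoothly into the background instead of stepping at the boundary
        from scipy.ndimage import distance_transform_edt

        dists = np.stack(
            [distance_transform_edt(~gt_masks[r]) for r in HEAD_REGIONS]
        )
        nearest = np.argmin(dists, axis=0)
        dmin = np.min(dists, axis=0)
        w = np.exp(-(dmin**2) / (2.0 * spec.boundary_softness_px**2))
        near_mean = np.array([means[r] for r in HEAD_REGIONS])[nearest]
        outside = dmin > 0
        temps[outside] = (
            w[outside] * near_mean[outside] + (1.0 - w[outside]) * temps[outside]
        )
    for region in HEAD_REGIONS:
        temps[gt_masks[region]] = means[region]
    if spec.noise_sigma_c > 0:
        temps = temps + rng.normal(0, spec.noise_sigma_c, temps.shape)
    tm = TemperatureMatrix(temps, frame_id=f"scene-{spec.seed}", timestamp="16:30")

    return SyntheticScene(
        rig=rig,
        rgb_mask=rgb_mask,
        rgb_color=color,
        gt_ir=gt_ir,
        temps=tm,
        spec=spec,
        region_means=means,
        polygons_mm=polys_mm,
    )


def make_plane_disks_mask(
    rig: cg.CameraRig,
    depth_mm: float = 600.0,
    radius_mm: float = 100.0,
    seed: int = 0,
) -> LabelMask:
    """RGB label mask of four large disks (one per region) on the working plane.

    The generous footprint (~60 px radius on the full-resolution IR grid)
    keeps mask-centroid quantization well below the parallax signal, which is
    what the closed-form depth-sensitivity analyses need; the head-shaped
    templates of :func:`make_scene` are the realistic counterpart.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([[-110, -110], [110, -110], [-110, 110], [110, 110]], float)
    centers = centers + rng.uniform(-5, 5, centers.shape)
    th = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    grid = np.zeros(rig.rgb_shape, np.uint8)
    for region, c in zip(HEAD_REGIONS, centers):
        poly = np.column_stack(
            [c[0] + radius_mm * np.cos(th), c[1] + radius_mm * np.sin(th)]
        )
        pts3 = np.column_stack([poly, np.full(len(poly), depth_mm)])
        px = _project_channel(pts3, rig.rgb)
        grid[rasterize_contour(Contour(px, region), *rig.rgb_shape)] = int(region)
    return LabelMask(grid, "rgb")


def make_scene_pair(spec: SceneSpec, rig: cg.CameraRig | None = None):
    """Matched (control, experimental) scenes sharing rig and geometry.

    The experimental scene's comb and wattle run ``heat_stress_delta_c``
    hotter; everything else, including the noise draws, is identical, which
    emulates repeated imaging of comparable birds under the two conditions.
    """
    control = make_scene(replace(spec, condition="control"), rig=rig)
    stressed = make_scene(replace(spec, condition="experimental"), rig=rig)
    return control, stressed
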