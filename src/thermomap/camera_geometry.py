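"""Pinhole camera models for the dual RGB/IR rig and the per-point mapping chain.

The cross-modal coordinate mapping transfers a pixel observed in the RGB
channel to the corresponding pixel in the infrared channel under a
fronto-parallel working-plane assumption:

    pixel_rgb --undistort+normalize--> ray --x depth--> 3D point (RGB frame)
              --rigid transform--> 3D point (IR frame) --project+distort--> pixel_ir

All lengths are millimetres, pixel coordinates are 0-based ``(u, v) =
(column, row)`` with integer coordinates at pixel centers.  Lens distortion
follows the Brown-Conrady model ``(k1, k2, p1, p2, k3)`` acting on normalized
coordinates.  Rig calibration from planar checkerboard corner observations
uses Zhang's closed-form initialization followed by a joint nonlinear
refinement of both channels and the inter-channel rigid transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    ConditioningWarning,
    ConvergenceError,
    InsufficientDataError,
    InvalidDepthError,
    InvalidInputError,
    PrincipalPointWarning,
    ProjectionError,
)

__all__ = [
    "Intrinsics",
    "DistortionCoeffs",
    "RigExtrinsics",
    "CameraChannel",
    "CameraRig",
    "CheckerboardSpec",
    "CornerObservations",
    "PoseCorners",
    "normalize_pixel",
    "denormalize_point",
    "distort_normalized",
    "undistort_normalized",
    "backproject_at_depth",
    "transform_rgb_to_ir",
    "project_to_ir",
    "map_pixel_rgb_to_ir",
    "calibrate_rig",
    "read_rig",
    "write_rig",
    "read_corner_observations",
    "write_corner_observations",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Intrinsics:
    """Focal lengths and principal point of one channel, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if not (np.isfinite([self.fx, self.fy, self.cx, self.cy]).all()):
            raise InvalidInputError("intrinsics must be finite")
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidInputError("focal lengths must be positive")
        if int(self.width) <= 0 or int(self.height) <= 0:
            raise InvalidInputError("image dimensions must be positive integers")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            warnings.warn(
                f"principal point ({self.cx}, {self.cy}) outside "
                f"{self.width}x{self.height} image",
                PrincipalPointWarning,
                stacklevel=2,
            )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 camera matrix K."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class DistortionCoeffs:
    """Brown-Conrady radial (k1, k2, k3) and tangential (p1, p2) coefficients."""

    k1: float = 0.0
    k2: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    k3: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.as_array()).all():
            raise InvalidInputError("distortion coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])

    @property
    def is_zero(self) -> bool:
        return not self.as_array().any()


@dataclass(frozen=True)
class RigExtrinsics:
    """Rigid transform from the RGB camera frame to the IR camera frame.

    ``rotation`` is a 3x3 orthonormal matrix, ``translation`` a 3-vector in mm;
    a point ``p`` in the RGB frame maps to ``rotation @ p + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidInputError("rotation must be 3x3")
        if not np.isfinite(R).all() or not np.isfinite(t).all():
            raise InvalidInputError("extrinsics must be finite")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise InvalidInputError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise InvalidInputError("rotation determinant is not +1 within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigExtrinsics":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigExtrinsics":
        """Decompose a 4x4 homogeneous transform."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InvalidInputError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous transform."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @property
    def baseline_mm(self) -> float:
        """Euclidean length of the translation, mm."""
        return float(np.linalg.norm(self.translation))


@dataclass(frozen=True)
class CameraChannel:
    """One channel of the rig: intrinsics plus distortion."""

    intrinsics: Intrinsics
    distortion: DistortionCoeffs = field(default_factory=DistortionCoeffs)


@dataclass(frozen=True)
class CameraRig:
    """Full geometric description of the dual-channel RGB/IR camera.

    ``emissivity`` and ``temperature_accuracy`` are metadata carried from the
    thermal camera configuration; they are not applied to temperatures.
    """

    rgb: CameraChannel
    ir: CameraChannel
    extrinsics: RigExtrinsics
    rms_reprojection_error: float | None = None
    emissivity: float = 0.96
    temperature_accuracy: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.emissivity <= 1.0):
            raise InvalidInputError("emissivity must lie in (0, 1]")

    @property
    def ir_shape(self) -> tuple[int, int]:
        """(height, width) of the IR grid."""
        return (self.ir.intrinsics.height, self.ir.intrinsics.width)

    @property
    def rgb_shape(self) -> tuple[int, int]:
        return (self.rgb.intrinsics.height, self.rgb.intrinsics.width)


@dataclass(frozen=True)
class CheckerboardSpec:
    """Planar calibration board: squares_cols x squares_rows squares of square_size mm.

    The detectable inner-corner grid is (squares_cols-1) x (squares_rows-1).
    """

    squares_cols: int = 15
    squares_rows: int = 16
    square_size: float = 25.0

    def __post_init__(self):
        if self.squares_cols < 2 or self.squares_rows < 2:
            raise InvalidInputError("board needs at least 2x2 squares")
        if self.square_size <= 0:
            raise InvalidInputError("square size must be positive")

    @property
    def inner_cols(self) -> int:
        return self.squares_cols - 1

    @property
    def inner_rows(self) -> int:
        return self.squares_rows - 1

    @property
    def n_corners(self) -> int:
        return self.inner_cols * self.inner_rows

    def corner_grid(self) -> np.ndarray:
        """(n, 2) integer board indices (i, j), i along columns, j along rows."""
        jj, ii = np.meshgrid(
            np.arange(self.inner_rows), np.arange(self.inner_cols), indexing="ij"
        )
        return np.column_stack([ii.ravel(), jj.ravel()])

    def corner_points_mm(self, board_ij: np.ndarray) -> np.ndarray:
        """Board-frame 3D coordinates (mm, Z=0) of the given (i, j) indices."""
        ij = np.asarray(board_ij, dtype=float)
        pts = np.zeros((len(ij), 3))
        pts[:, :2] = ij * self.square_size
        return pts


@dataclass
class PoseCorners:
    """Matched corner detections of one board pose in both channels."""

    pose_id: int
    board_ij: np.ndarray  # (M, 2) int board indices, shared ordering
    pixels: dict[str, np.ndarray]  # channel -> (M, 2) float pixel coords

    def __post_init__(self):
        ij = np.asarray(self.board_ij, dtype=int)
        if ij.ndim != 2 or ij.shape[1] != 2:
            raise InvalidInputError("board_ij must be (M, 2)")
        if len(np.unique(ij, axis=0)) != len(ij):
            raise InvalidInputError(f"pose {self.pose_id}: duplicate board indices")
        self.board_ij = ij
        for ch, px in self.pixels.items():
            px = np.asarray(px, dtype=float)
            if px.shape != (len(ij), 2) or not np.isfinite(px).all():
                raise InvalidInputError(
                    f"pose {self.pose_id} channel {ch}: bad pixel array"
                )
            self.pixels[ch] = px


@dataclass
class CornerObservations:
    """Per-pose, per-channel checkerboard corner detections with a shared ordering."""

    poses: list[PoseCorners]

    @property
    def n_poses(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# Point operations (vectorised over trailing-axis-2 arrays)
# ---------------------------------------------------------------------------


def _as_points(p, name="points") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] != 2:
        raise InvalidInputError(f"{name} must have trailing dimension 2")
    if not np.isfinite(arr).all():
        raise InvalidInputError(f"{name} must be finite")
    return arr


def normalize_pixel(p, intr: Intrinsics) -> np.ndarray:
    """Pixel -> normalized image coordinates: ((u-cx)/fx, (v-cy)/fy)."""
    p = _as_points(p, "pixel")
    return np.stack(
        [(p[..., 0] - intr.cx) / intr.fx, (p[..., 1] - intr.cy) / intr.fy], axis=-1
    )


def denormalize_point(n, intr: Intrinsics) -> np.ndarray:
    """Normalized -> pixel coordinates: (fx*x + cx, fy*y + cy)."""
    n = _as_points(n, "normalized point")
    return np.stack(
        [intr.fx * n[..., 0] + intr.cx, intr.fy * n[..., 1] + intr.cy], axis=-1
    )


def distort_normalized(n, d: DistortionCoeffs) -> np.ndarray:
    """Apply the Brown-Conrady forward distortion model to normalized points."""
    n = _as_points(n, "normalized point")
    x, y = n[..., 0], n[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (d.k1 + r2 * (d.k2 + r2 * d.k3))
    xd = x * radial + 2.0 * d.p1 * x * y + d.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + d.p1 * (r2 + 2.0 * y * y) + 2.0 * d.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def undistort_normalized(
    n,
    d: DistortionCoeffs,
    *,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert the distortion model by fixed-point iteration.

    Iterates ``x <- (x_obs - tangential(x)) / radial(x)`` until the forward
    model reproduces the observed point within ``tol`` (on normalized
    coordinates).  Raises :class:`ConvergenceError` naming the worst point if
    the iteration does not converge, as happens for pathological coefficients
    far outside the model's valid branch.
    """
    n = _as_points(n, "normalized point")
    if d.is_zero:
        return n.copy()
    obs = n.reshape(-1, 2)
    cur = obs.copy()
    for _ in range(max_iter):
        x, y = cur[:, 0], cur[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + r2 * (d.k1 + r2 * (d.k2 + r2 * d.k3))
        tx = 2.0 * d.p1 * x * y + d.p2 * (r2 + 2.0 * x * x)
        ty = d.p1 * (r2 + 2.0 * y * y) + 2.0 * d.p2 * x * y
        with np.errstate(divide="ignore", invalid="ignore"):
            nxt = np.column_stack(
                [(obs[:, 0] - tx) / radial, (obs[:, 1] - ty) / radial]
            )
        if not np.isfinite(nxt).all():
            bad = obs[~np.isfinite(nxt).any(axis=1)][0] if np.isfinite(obs).all() else obs[0]
            raise ConvergenceError(
                f"undistortion diverged at normalized point ({bad[0]:g}, {bad[1]:g})"
            )
        cur = nxt
        resid = np.abs(distort_normalized(cur, d) - obs).max(axis=1)
        if resid.max() < tol:
            return cur.reshape(n.shape)
    resid = np.abs(distort_normalized(cur, d) - obs).max(axis=1)
    worst = obs[int(np.argmax(resid))]
    raise ConvergenceError(
        f"undistortion did not converge within {max_iter} iterations at "
        f"normalized point ({worst[0]:g}, {worst[1]:g}); residual {resid.max():g}"
    )


def backproject_at_depth(n, depth: float) -> np.ndarray:
    """Lift normalized points onto the plane Z = depth: (x*depth, y*depth, depth)."""
    if not np.isfinite(depth) or depth <= 0:
        raise InvalidDepthError(f"depth must be > 0 mm, got {depth}")
    n = _as_points(n, "normalized point")
    out = np.empty(n.shape[:-1] + (3,))
    out[..., 0] = n[..., 0] * depth
    out[..., 1] = n[..., 1] * depth
    out[..., 2] = depth
    return out


def transform_rgb_to_ir(p, ext: RigExtrinsics) -> np.ndarray:
    """Apply the rigid RGB->IR transform to 3D points (trailing axis 3)."""
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise InvalidInputError("3D points must have trailing dimension 3")
    return p @ ext.rotation.T + ext.translation


def project_to_ir(p, intr: Intrinsics, d: DistortionCoeffs) -> np.ndarray:
    """Project 3D camera-frame points to pixels: perspective divide, distort, K."""
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise InvalidInputError("3D points must have trailing dimension 3")
    z = p[..., 2]
    if np.any(z <= 0):
        bad = np.asarray(p).reshape(-1, 3)[np.asarray(z <= 0).ravel()][0]
        raise ProjectionError(
            f"point ({bad[0]:g}, {bad[1]:g}, {bad[2]:g}) is at or behind the camera"
        )
    n = np.stack([p[..., 0] / z, p[..., 1] / z], axis=-1)
    return denormalize_point(distort_normalized(n, d), intr)


def in_ir_bounds(p, intr: Intrinsics) -> np.ndarray:
    """Boolean array: pixel centers within [0, width-1] x [0, height-1]."""
    p = _as_points(p, "pixel")
    return (
        (p[..., 0] >= 0)
        & (p[..., 0] <= intr.width - 1)
        & (p[..., 1] >= 0)
        & (p[..., 1] <= intr.height - 1)
    )


def map_pixel_rgb_to_ir(
    p, rig: CameraRig, depth: float, *, return_out_of_bounds: bool = False
):
    """Map RGB pixels to IR pixels through the full per-point chain.

    Composes undistort+normalize (RGB), back-projection onto the plane
    ``Z = depth`` (mm), the rigid RGB->IR transform, and projection through
    the IR channel including its forward distortion.  Mapped points falling
    outside the IR image are returned, not rejected; with
    ``return_out_of_bounds=True`` a boolean flag array accompanies them.
    """
    if not np.isfinite(depth) or depth <= 0:
        raise InvalidDepthError(f"depth must be > 0 mm, got {depth}")
    n = normalize_pixel(p, rig.rgb.intrinsics)
    n = undistort_normalized(n, rig.rgb.distortion)
    p3 = backproject_at_depth(n, depth)
    p3 = transform_rgb_to_ir(p3, rig.extrinsics)
    mapped = project_to_ir(p3, rig.ir.intrinsics, rig.ir.distortion)
    if return_out_of_bounds:
        return mapped, ~in_ir_bounds(mapped, rig.ir.intrinsics)
    return mapped


# ---------------------------------------------------------------------------
# Rig file I/O
# ---------------------------------------------------------------------------


def _channel_to_dict(ch: CameraChannel) -> dict:
    i, d = ch.intrinsics, ch.distortion
    return {
        "fx": i.fx,
        "fy": i.fy,
        "cx": i.cx,
        "cy": i.cy,
        "width": i.width,
        "height": i.height,
        "dist": [d.k1, d.k2, d.p1, d.p2, d.k3],
    }


def _channel_from_dict(d: dict) -> CameraChannel:
    dist = d.get("dist", [0.0] * 5)
    return CameraChannel(
        Intrinsics(d["fx"], d["fy"], d["cx"], d["cy"], int(d["width"]), int(d["height"])),
        DistortionCoeffs(*dist),
    )


def write_rig(rig: CameraRig, path) -> None:
    """Write a rig JSON file (bit-exact round-trip with :func:`read_rig`)."""
    doc = {
        "rgb": _channel_to_dict(rig.rgb),
        "ir": _channel_to_dict(rig.ir),
        "extrinsics": {
            "rotation": [float(v) for v in rig.extrinsics.rotation.ravel()],
            "translation_mm": [float(v) for v in rig.extrinsics.translation],
        },
        "metadata": {
            "emissivity": rig.emissivity,
            "temperature_accuracy_c": rig.temperature_accuracy,
        },
    }
    if rig.rms_reprojection_error is not None:
        doc["metadata"]["rms_reprojection_error_px"] = rig.rms_reprojection_error
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_rig(path) -> CameraRig:
    """Read a rig JSON file.

    The ``extrinsics`` block may give either ``rotation`` (9 row-major
    floats) plus ``translation_mm``, or a 16-float ``matrix_4x4`` which is
    decomposed.
    """
    with open(path) as fh:
        doc = json.load(fh)
    ex = doc["extrinsics"]
    if "matrix_4x4" in ex:
        extr = RigExtrinsics.from_matrix(np.asarray(ex["matrix_4x4"], float).reshape(4, 4))
    else:
        extr = RigExtrinsics(
            np.asarray(ex["rotation"], dtype=float).reshape(3, 3),
            np.asarray(ex["translation_mm"], dtype=float),
        )
    meta = doc.get("metadata", {})
    return CameraRig(
        rgb=_channel_from_dict(doc["rgb"]),
        ir=_channel_from_dict(doc["ir"]),
        extrinsics=extr,
        rms_reprojection_error=meta.get("rms_reprojection_error_px"),
        emissivity=meta.get("emissivity", 0.96),
        temperature_accuracy=meta.get("temperature_accuracy_c", 0.5),
    )


def write_corner_observations(obs: CornerObservations, path) -> None:
    """Write observations to CSV (pose_id, channel, board_i, board_j, u, v)."""
    rows = []
    for pose in obs.poses:
        for ch, px in pose.pixels.items():
            for (bi, bj), (u, v) in zip(pose.board_ij, px):
                rows.append((pose.pose_id, ch, int(bi), int(bj), u, v))
    pd.DataFrame(
        rows, columns=["pose_id", "channel", "board_i", "board_j", "u", "v"]
    ).to_csv(path, index=False)


def read_corner_observations(path) -> CornerObservations:
    """Read corner observations from CSV, restoring a canonical corner order."""
    df = pd.read_csv(path)
    poses = []
    for pose_id, pose_df in df.groupby("pose_id", sort=True):
        chans = {}
        key_ref = None
        for ch, ch_df in pose_df.groupby("channel"):
            ch_df = ch_df.sort_values(["board_j", "board_i"])
            key = ch_df[["board_i", "board_j"]].to_numpy()
            if key_ref is None:
                key_ref = key
            elif not np.array_equal(key, key_ref):
                raise InvalidInputError(
                    f"pose {pose_id}: channels observe different corner sets"
                )
            chans[ch] = ch_df[["u", "v"]].to_numpy(dtype=float)
        poses.append(PoseCorners(int(pose_id), key_ref, chans))
    return CornerObservations(poses)


# ---------------------------------------------------------------------------
# Zhang calibration
# ---------------------------------------------------------------------------


def _homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Plane-to-image homography by normalized DLT."""

    def _norm(pts):
        c = pts.mean(axis=0)
        s = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
        h = np.column_stack([pts, np.ones(len(pts))]) @ T.T
        return h[:, :2], T

    sn, Ts = _norm(src)
    dn, Td = _norm(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = -sn
    A[0::2, 2] = -1.0
    A[0::2, 6:8] = sn * dn[:, :1]
    A[0::2, 8] = dn[:, 0]
    A[1::2, 3:5] = -sn
    A[1::2, 5] = -1.0
    A[1::2, 6:8] = sn * dn[:, 1:2]
    A[1::2, 8] = dn[:, 1]
    _, _, vt = np.linalg.svd(A)
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / H[2, 2]


def _intrinsics_from_homographies(Hs: list[np.ndarray], width: int, height: int) -> Intrinsics:
    """Zhang closed-form intrinsics from >= 3 plane homographies."""

    def v(H, i, j):
        return np.array(
            [
                H[0, i] * H[0, j],
                H[0, i] * H[1, j] + H[1, i] * H[0, j],
                H[1, i] * H[1, j],
                H[2, i] * H[0, j] + H[0, i] * H[2, j],
                H[2, i] * H[1, j] + H[1, i] * H[2, j],
                H[2, i] * H[2, j],
            ]
        )

    V = []
    for H in Hs:
        V.append(v(H, 0, 1))
        V.append(v(H, 0, 0) - v(H, 1, 1))
    V = np.asarray(V)
    _, s, vt = np.linalg.svd(V)
    degenerate = s[-2] < 1e-6 * s[0]
    if degenerate:
        warnings.warn(
            "near-degenerate pose set for intrinsics estimation "
            "(e.g. near-duplicate board poses); returning best-effort result",
            ConditioningWarning,
            stacklevel=3,
        )
    b11, b12, b22, b13, b23, b33 = vt[-1]
    denom = b11 * b22 - b12 * b12
    cy = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13 * b13 + cy * (b12 * b13 - b11 * b23)) / b11
    fx2 = lam / b11
    fy2 = lam * b11 / denom
    if fx2 <= 0 or fy2 <= 0:
        # sign ambiguity of the SVD null vector
        b11, b12, b22, b13, b23, b33 = -vt[-1]
        denom = b11 * b22 - b12 * b12
        cy = (b12 * b13 - b11 * b23) / denom
        lam = b33 - (b13 * b13 + cy * (b12 * b13 - b11 * b23)) / b11
        fx2 = lam / b11
        fy2 = lam * b11 / denom
    if fx2 <= 0 or fy2 <= 0:
        # conic constraints unusable (degenerate geometry): fall back to a
        # generic initial guess and let the bundle refinement do what it can
        if not degenerate:
            warnings.warn(
                "closed-form intrinsics failed; using a generic initial guess",
                ConditioningWarning,
                stacklevel=3,
            )
        guess = 1.2 * max(width, height)
        return Intrinsics(guess, guess, width / 2.0, height / 2.0, width, height)
    fx, fy = float(np.sqrt(fx2)), float(np.sqrt(fy2))
    skew = -b12 * fx * fx * fy / lam
    cx = skew * cy / fy - b13 * fx * fx / lam
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PrincipalPointWarning)
        return Intrinsics(fx, fy, float(cx), float(cy), width, height)


def _pose_from_homography(H: np.ndarray, K: np.ndarray):
    """Board->camera (rotvec, tvec) from a plane homography."""
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = (Kinv @ H).T[:3]
    lam = 1.0 / np.linalg.norm(h1)
    r1, r2, t = lam * h1, lam * h2, lam * h3
    if t[2] < 0:
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return Rotation.from_matrix(R).as_rotvec(), t


def _project_board(pts_cam: np.ndarray, intr_v: np.ndarray, dist_v: np.ndarray) -> np.ndarray:
    """Project camera-frame points with an unpacked parameter vector."""
    fx, fy, cx, cy = intr_v
    d = DistortionCoeffs(*dist_v)
    n = pts_cam[:, :2] / pts_cam[:, 2:3]
    nd = distort_normalized(n, d)
    return np.column_stack([fx * nd[:, 0] + cx, fy * nd[:, 1] + cy])


def calibrate_rig(
    board: CheckerboardSpec,
    obs: CornerObservations,
    *,
    ir_resolution: tuple[int, int] | None = None,
    rgb_resolution: tuple[int, int] | None = None,
    emissivity: float = 0.96,
    temperature_accuracy: float = 0.5,
) -> CameraRig:
    """Calibrate both channels and the inter-channel transform from corner data.

    Runs Zhang's closed-form initialization per channel, per-channel bundle
    refinement (intrinsics, Brown-Conrady distortion, board poses), then a
    joint refinement that ties the two channels through a single rigid
    RGB->IR transform.  ``*_resolution`` are (width, height); when omitted
    they are inferred from the extent of the observations (generous bounds),
    so passing the true sensor sizes is recommended.
    """
    if obs.n_poses < 3:
        raise InsufficientDataError(
            f"need >= 3 poses for calibration, got {obs.n_poses}"
        )
    for pose in obs.poses:
        for ch in ("rgb", "ir"):
            if ch not in pose.pixels:
                raise InsufficientDataError(f"pose {pose.pose_id} missing channel {ch}")
        if len(pose.board_ij) < 8:
            raise InsufficientDataError(
                f"pose {pose.pose_id}: too few corners ({len(pose.board_ij)})"
            )

    def _resolution(ch, given):
        if given is not None:
            return int(given[0]), int(given[1])
        allpx = np.vstack([p.pixels[ch] for p in obs.poses])
        return int(np.ceil(allpx[:, 0].max())) + 1, int(np.ceil(allpx[:, 1].max())) + 1

    res = {"rgb": _resolution("rgb", rgb_resolution), "ir": _resolution("ir", ir_resolution)}
    board_pts = {
        id(p): board.corner_points_mm(p.board_ij) for p in obs.poses
    }

    # -- per-channel Zhang init + refinement ------------------------------
    chan_params = {}
    chan_poses = {}
    for ch in ("rgb", "ir"):
        Hs = [
            _homography_dlt(board_pts[id(p)][:, :2], p.pixels[ch]) for p in obs.poses
        ]
        w, h = res[ch]
        intr0 = _intrinsics_from_homographies(Hs, w, h)
        K0 = intr0.matrix
        poses0 = [_pose_from_homography(H, K0) for H in Hs]
        x0 = np.concatenate(
            [
                [intr0.fx, intr0.fy, intr0.cx, intr0.cy],
                np.zeros(5),
                np.concatenate([np.concatenate([rv, tv]) for rv, tv in poses0]),
            ]
        )

        def _resid_single(x, ch=ch):
            intr_v, dist_v = x[:4], x[4:9]
            out = []
            for i, p in enumerate(obs.poses):
                rv = x[9 + 6 * i : 12 + 6 * i]
                tv = x[12 + 6 * i : 15 + 6 * i]
                cam = board_pts[id(p)] @ Rotation.from_rotvec(rv).as_matrix().T + tv
                out.append((_project_board(cam, intr_v, dist_v) - p.pixels[ch]).ravel())
            return np.concatenate(out)

        sol = least_squares(
            _resid_single, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=100
        )
        chan_params[ch] = sol.x[:9].copy()
        chan_poses[ch] = [
            (sol.x[9 + 6 * i : 12 + 6 * i].copy(), sol.x[12 + 6 * i : 15 + 6 * i].copy())
            for i in range(obs.n_poses)
        ]

    # -- initial relative pose: average of per-pose relative transforms ---
    rel_rots, rel_ts = [], []
    for (rv_r, t_r), (rv_i, t_i) in zip(chan_poses["rgb"], chan_poses["ir"]):
        Rr = Rotation.from_rotvec(rv_r).as_matrix()
        Ri = Rotation.from_rotvec(rv_i).as_matrix()
        Rrel = Ri @ Rr.T
        rel_rots.append(Rotation.from_matrix(Rrel))
        rel_ts.append(t_i - Rrel @ t_r)
    rel_rv = Rotation.mean(Rotation.concatenate(rel_rots)).as_rotvec()
    rel_t = np.mean(rel_ts, axis=0)

    # -- joint refinement: both channels share board poses + one rig transform
    x0 = np.concatenate(
        [
            chan_params["rgb"],
            chan_params["ir"],
            rel_rv,
            rel_t,
            np.concatenate(
                [np.concatenate([rv, tv]) for rv, tv in chan_poses["rgb"]]
            ),
        ]
    )

    def _resid_joint(x):
        prgb, pir = x[:9], x[9:18]
        Rrel = Rotation.from_rotvec(x[18:21]).as_matrix()
        trel = x[21:24]
        out = []
        for i, p in enumerate(obs.poses):
            rv = x[24 + 6 * i : 27 + 6 * i]
            tv = x[27 + 6 * i : 30 + 6 * i]
            cam_rgb = board_pts[id(p)] @ Rotation.from_rotvec(rv).as_matrix().T + tv
            cam_ir = cam_rgb @ Rrel.T + trel
            out.append((_project_board(cam_rgb, prgb[:4], prgb[4:]) - p.pixels["rgb"]).ravel())
            out.append((_project_board(cam_ir, pir[:4], pir[4:]) - p.pixels["ir"]).ravel())
        return np.concatenate(out)

    sol = least_squares(
        _resid_joint, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=100
    )
    resid = _resid_joint(sol.x)
    rms = float(np.sqrt(np.mean(resid**2)))

    def _mk_channel(vec, whch):
        w, h = res[whch]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PrincipalPointWarning)
            intr = Intrinsics(*(float(v) for v in vec[:4]), w, h)
        return CameraChannel(intr, DistortionCoeffs(*(float(v) for v in vec[4:9])))

    Rrel = Rotation.from_rotvec(sol.x[18:21]).as_matrix()
    # re-orthonormalize to survive the strict RigExtrinsics invariant
    u, _, vt = np.linalg.svd(Rrel)
    Rrel = u @ vt
    return CameraRig(
        rgb=_mk_channel(sol.x[:9], "rgb"),
        ir=_mk_channel(sol.x[9:18], "ir"),
        extrinsics=RigExtrinsics(Rrel, sol.x[21:24]),
        rms_reprojection_error=rms,
        emissivity=emissivity,
        temperature_accuracy=temperature_accuracy,
    )
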