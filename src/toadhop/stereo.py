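"""Stereo geometry: camera models, flash synchronization, DLT resectioning,
calibration QC and triangulation of snout/cloaca landmark streams.

Conventions: world coordinates in cm, z up; pixel origin at the top-left
corner of the image; frame indices are 0-based; a camera is a 3x4 projective
operator mapping homogeneous world points to homogeneous pixels, with the
third output coordinate positive for points in front of the camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    ParameterError,
    SynchronizationError,
    TrajectoryGapError,
    TriangulationError,
)

LANDMARKS = ("snout", "cloaca")

#: Default synthetic sensor: a 4K-class high-speed camera.
IMAGE_SIZE = (4096, 2160)

#: Minimum angle (degrees) between the two viewing rays below which a
#: triangulation is considered unreliable.
MIN_RAY_ANGLE_DEG = 0.05

#: Default brightness prominence (flash units above the trace median)
#: required to accept a flash spike.
FLASH_PROMINENCE = 50.0


# --------------------------------------------------------------------------
# camera model
# --------------------------------------------------------------------------

@dataclass
class CameraModel:
    """A finite projective camera.

    Parameters
    ----------
    projection
        3x4 matrix mapping homogeneous world coordinates (cm) to
        homogeneous pixel coordinates.
    image_size
        ``(width, height)`` in pixels.
    rms_reprojection
        RMS reprojection error (pixels) of the resection that produced this
        camera, when applicable.
    """

    projection: np.ndarray
    image_size: tuple[int, int] = IMAGE_SIZE
    rms_reprojection: float | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.projection, dtype=float)
        if P.shape != (3, 4):
            raise ParameterError(f"projection must be 3x4, got {P.shape}")
        if np.linalg.matrix_rank(P) != 3:
            raise ParameterError("projection must have rank 3")
        if abs(np.linalg.det(P[:, :3])) < 1e-12:
            raise ParameterError("leading 3x3 block of projection is singular")
        self.projection = P

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates (right null space of P)."""
        _, _, vt = np.linalg.svd(self.projection)
        c = vt[-1]
        return c[:3] / c[3]

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project ``(n, 3)`` world points.

        Returns ``(pixels, depths)`` where ``pixels`` is ``(n, 2)`` and
        ``depths`` the homogeneous scale (positive in front of the camera).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.hstack([pts, np.ones((len(pts), 1))])
        proj = h @ self.projection.T
        depth = proj[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            px = proj[:, :2] / depth[:, None]
        return px, depth

    def visible(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: point in front of the camera and inside the image."""
        px, depth = self.project(points)
        w, h = self.image_size
        return (
            (depth > 0)
            & (px[:, 0] >= 0) & (px[:, 0] < w)
            & (px[:, 1] >= 0) & (px[:, 1] < h)
        )


def make_camera(
    focal_px: float,
    center_world: np.ndarray,
    look_at: np.ndarray,
    up: np.ndarray = (0.0, 0.0, 1.0),
    image_size: tuple[int, int] = IMAGE_SIZE,
) -> CameraModel:
    """Build a pinhole camera from its pose.

    The optical axis points from ``center_world`` towards ``look_at``; ``up``
    fixes the roll (world z by default, so image rows stay horizontal).
    """
    c = np.asarray(center_world, dtype=float)
    fwd = np.asarray(look_at, dtype=float) - c
    n = np.linalg.norm(fwd)
    if n == 0:
        raise ParameterError("look_at coincides with the camera centre")
    fwd = fwd / n
    up = np.asarray(up, dtype=float)
    right = np.cross(fwd, up)
    rn = np.linalg.norm(right)
    if rn < 1e-12:
        raise ParameterError("up vector parallel to the optical axis")
    right /= rn
    down = np.cross(fwd, right)  # +v grows downward in the image
    R = np.vstack([right, down, fwd])  # world -> camera rotation
    t = -R @ c
    w, h = image_size
    K = np.array([[focal_px, 0.0, w / 2.0],
                  [0.0, focal_px, h / 2.0],
                  [0.0, 0.0, 1.0]])
    P = K @ np.hstack([R, t[:, None]])
    return CameraModel(P, image_size=image_size)


# --------------------------------------------------------------------------
# flash synchronization
# --------------------------------------------------------------------------

def estimate_sync_offset(
    brightness_left: np.ndarray,
    brightness_right: np.ndarray,
    prominence: float = FLASH_PROMINENCE,
) -> int:
    """Frame offset of the right camera relative to the left from the flash.

    Each trace must contain one dominant brightness spike (the synchronizing
    camera flash). The offset is ``argmax(right) - argmax(left)``: a right
    frame ``f`` corresponds to left frame ``f - offset``.
    """
    out = []
    for name, trace in (("left", brightness_left), ("right", brightness_right)):
        tr = np.asarray(trace, dtype=float)
        if tr.ndim != 1 or len(tr) < 2:
            raise SynchronizationError(f"{name} brightness trace too short")
        peak = int(np.argmax(tr))
        if tr[peak] - np.median(tr) < prominence:
            raise SynchronizationError(
                f"no flash spike above prominence {prominence} in {name} trace"
            )
        out.append(peak)
    return out[1] - out[0]


# --------------------------------------------------------------------------
# resectioning (normalized DLT)
# --------------------------------------------------------------------------

def _normalize_points(pts: np.ndarray, target: float) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid to origin, mean norm to ``target``."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = target / d if d > 0 else 1.0
    dim = pts.shape[1]
    T = np.eye(dim + 1)
    T[:dim, :dim] *= s
    T[:dim, dim] = -s * centroid
    return (pts - centroid) * s, T


def resect_camera(
    points_3d: np.ndarray,
    points_2d: np.ndarray,
    image_size: tuple[int, int] = IMAGE_SIZE,
    coplanarity_tol: float = 1e-6,
) -> CameraModel:
    """Estimate a camera by normalized DLT from 3D-2D correspondences.

    Requires at least 6 correspondences whose 3D points are not all
    coplanar (correspondences may, and typically do, span several
    checkerboard poses). The returned camera carries its RMS reprojection
    error in pixels.
    """
    X = np.asarray(points_3d, dtype=float)
    x = np.asarray(points_2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or x.shape != (len(X), 2):
        raise ParameterError("expected (n,3) world points and (n,2) pixels")
    n = len(X)
    if n < 6:
        raise DegenerateGeometryError(f"resection needs >=6 points, got {n}")
    # coplanarity test: smallest singular value of centred cloud
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    extent = s[0] if s[0] > 0 else 1.0
    if s[-1] / extent < coplanarity_tol:
        raise DegenerateGeometryError(
            "3D points are coplanar: camera resection is ambiguous "
            "(use correspondences from several board poses)"
        )
    Xn, T3 = _normalize_points(X, np.sqrt(3.0))
    xn, T2 = _normalize_points(x, np.sqrt(2.0))
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([Xn, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, 1:2] * Xh
    _, _, vt = np.linalg.svd(A)
    Pn = vt[-1].reshape(3, 4)
    P = np.linalg.inv(T2) @ Pn @ T3
    # fix scale/sign: unit principal ray, points in front
    P = P / np.linalg.norm(P[2, :3])
    depths = np.hstack([X, np.ones((n, 1))]) @ P[2]
    if np.median(depths) < 0:
        P = -P
    cam = CameraModel(P, image_size=image_size)
    px, _ = cam.project(X)
    cam.rms_reprojection = float(np.sqrt(np.mean(np.sum((px - x) ** 2, axis=1))))
    return cam


# --------------------------------------------------------------------------
# triangulation
# --------------------------------------------------------------------------

def triangulate_point(
    left_px: np.ndarray,
    right_px: np.ndarray,
    left: CameraModel,
    right: CameraModel,
    min_ray_angle_deg: float = MIN_RAY_ANGLE_DEG,
) -> tuple[np.ndarray, float]:
    """Linear (homogeneous DLT) two-view triangulation.

    Returns ``(point_cm, residual_px)`` where the residual is the RMS
    reprojection error over the two views. Raises
    :class:`TriangulationError` when the viewing rays are closer to
    parallel than ``min_ray_angle_deg`` (e.g. coincident cameras).
    """
    cl, cr = left.center, right.center
    if np.linalg.norm(cl - cr) < 1e-9:
        raise TriangulationError("cameras are coincident: rays cannot intersect")
    u1 = np.asarray(left_px, dtype=float)
    u2 = np.asarray(right_px, dtype=float)
    A = np.vstack([
        u1[0] * left.projection[2] - left.projection[0],
        u1[1] * left.projection[2] - left.projection[1],
        u2[0] * right.projection[2] - right.projection[0],
        u2[1] * right.projection[2] - right.projection[1],
    ])
    _, _, vt = np.linalg.svd(A)
    Xh = vt[-1]
    if abs(Xh[3]) < 1e-15:
        raise TriangulationError("triangulated point at infinity")
    X = Xh[:3] / Xh[3]
    r1, r2 = X - cl, X - cr
    denom = np.linalg.norm(r1) * np.linalg.norm(r2)
    if denom == 0:
        raise TriangulationError("degenerate ray geometry")
    cosang = np.clip(np.dot(r1, r2) / denom, -1.0, 1.0)
    if np.degrees(np.arccos(cosang)) < min_ray_angle_deg:
        raise TriangulationError(
            f"ray angle below {min_ray_angle_deg} deg: unreliable triangulation"
        )
    pl, _ = left.project(X)
    pr, _ = right.project(X)
    residual = float(np.sqrt((np.sum((pl[0] - u1) ** 2) + np.sum((pr[0] - u2) ** 2)) / 2.0))
    return X, residual


def triangulate_points(
    left_px: np.ndarray,
    right_px: np.ndarray,
    left: CameraModel,
    right: CameraModel,
) -> np.ndarray:
    """Vector-friendly wrapper around :func:`triangulate_point`."""
    lp = np.atleast_2d(left_px)
    rp = np.atleast_2d(right_px)
    return np.array([triangulate_point(a, b, left, right)[0] for a, b in zip(lp, rp)])


# --------------------------------------------------------------------------
# calibration QC ("1% inaccuracy" rule)
# --------------------------------------------------------------------------

@dataclass
class CalibrationQCReport:
    """Per-view stereo-accuracy report.

    ``inaccuracy`` is the RMS discrepancy between the triangulated corners
    and the rigidly fitted known board model, relative to the board width.
    Views above ``threshold`` (1% by default) are rejected.
    """

    view_id: int
    inaccuracy: float
    threshold: float = 0.01
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.reason is None and self.inaccuracy <= self.threshold


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch: proper rotation R and translation t minimizing |R src + t - dst|."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, dc - R @ sc


def stereo_qc(
    views,
    left: CameraModel,
    right: CameraModel,
    threshold: float = 0.01,
) -> list[CalibrationQCReport]:
    """Score each checkerboard view against the calibrated stereo pair.

    For each view the corners are triangulated from the two pixel sets, the
    known board geometry is rigidly fitted to the reconstruction, and the
    relative inaccuracy is the RMS corner discrepancy divided by the board
    width. A view visible in only one camera is rejected with a reason.
    """
    reports = []
    for i, view in enumerate(views):
        vid = getattr(view, "board_id", i)
        if view.corners_px_left is None or view.corners_px_right is None:
            reports.append(CalibrationQCReport(vid, np.inf, threshold,
                                               reason="visible in one camera only"))
            continue
        try:
            recon = triangulate_points(view.corners_px_left, view.corners_px_right,
                                       left, right)
        except TriangulationError as exc:
            reports.append(CalibrationQCReport(vid, np.inf, threshold,
                                               reason=f"triangulation failed: {exc}"))
            continue
        R, t = _rigid_fit(view.corners_3d, recon)
        fitted = view.corners_3d @ R.T + t
        rms = np.sqrt(np.mean(np.sum((fitted - recon) ** 2, axis=1)))
        width = np.ptp(view.corners_3d, axis=0).max()
        reports.append(CalibrationQCReport(vid, float(rms / width), threshold))
    return reports


def calibrate_rig(
    views,
    threshold: float = 0.01,
    image_size: tuple[int, int] = IMAGE_SIZE,
) -> tuple[CameraModel, CameraModel, list[CalibrationQCReport]]:
    """Resect both cameras from checkerboard views with QC suppression.

    Cameras are estimated by DLT from the world-frame corners of all views;
    views failing the relative-inaccuracy threshold are suppressed one at a
    time (worst first) and the cameras re-estimated, until every remaining
    view passes. Returns the final cameras and the QC reports of the last
    pass (suppressed views keep their failing report).
    """
    views = list(views)
    if not views:
        raise ParameterError("no calibration views supplied")
    active = {getattr(v, "board_id", i): v for i, v in enumerate(views)}
    rejected: dict[int, CalibrationQCReport] = {}
    while True:
        pts3 = np.vstack([v.corners_world for v in active.values()])
        pxl = np.vstack([v.corners_px_left for v in active.values()])
        pxr = np.vstack([v.corners_px_right for v in active.values()])
        left = resect_camera(pts3, pxl, image_size=image_size)
        right = resect_camera(pts3, pxr, image_size=image_size)
        reports = stereo_qc(active.values(), left, right, threshold)
        failing = [r for r in reports if not r.accepted]
        if not failing:
            final = reports + list(rejected.values())
            final.sort(key=lambda r: r.view_id)
            return left, right, final
        worst = max(failing, key=lambda r: r.inaccuracy)
        rejected[worst.view_id] = worst
        del active[worst.view_id]
        if len(active) < 2:
            raise DegenerateGeometryError(
                "fewer than 2 calibration views survive QC suppression"
            )


# --------------------------------------------------------------------------
# trajectory container and reconstruction
# --------------------------------------------------------------------------

@dataclass
class Trajectory3D:
    """Time-stamped 3D snout and cloaca positions for one hop (cm).

    ``timestamps`` are uniformly spaced at ``1 / frame_rate``; ``aligned``
    marks trajectories already rotated to the standard jump plane.
    """

    timestamps: np.ndarray
    snout: np.ndarray
    cloaca: np.ndarray
    frame_rate: float
    aligned: bool = False
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.snout = np.asarray(self.snout, dtype=float)
        self.cloaca = np.asarray(self.cloaca, dtype=float)
        n = len(self.timestamps)
        if self.snout.shape != (n, 3) or self.cloaca.shape != (n, 3):
            raise ParameterError("snout/cloaca must be (n, 3) arrays")
        if n >= 2:
            steps = np.diff(self.timestamps)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ParameterError("timestamps must increase with constant step")
        if np.any(np.linalg.norm(self.snout - self.cloaca, axis=1) <= 0):
            raise ParameterError("snout and cloaca coincide in some frame")
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def body_vectors(self) -> np.ndarray:
        """Cloaca-to-snout vectors per frame."""
        return self.snout - self.cloaca


def _fill_gaps(values: np.ndarray, valid: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of interior gaps of length <= max_gap."""
    out = values.copy()
    interp = np.zeros(len(values), dtype=bool)
    idx = np.flatnonzero(valid)
    gaps = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a > 1:
            gaps.append((a + 1, b - 1))
    for g0, g1 in gaps:
        if g1 - g0 + 1 > max_gap:
            raise TrajectoryGapError(
                f"gap of {g1 - g0 + 1} frames exceeds maximum of {max_gap}",
                gaps=[(g0, g1)],
            )
        for j in range(g0, g1 + 1):
            w = (j - (g0 - 1)) / (g1 + 1 - (g0 - 1))
            out[j] = (1 - w) * values[g0 - 1] + w * values[g1 + 1]
            interp[j] = True
    return out, interp


def reconstruct_trajectory(
    landmarks: pd.DataFrame,
    left: CameraModel,
    right: CameraModel,
    sync_offset: int,
    fps: float,
    min_coverage: float = 0.9,
    max_gap: int = 2,
) -> Trajectory3D:
    """Triangulate a snout/cloaca landmark table into a raw 3D trajectory.

    ``landmarks`` has columns camera/frame/landmark/u/v/visible; right-camera
    frame indices are corrected by ``sync_offset`` before the per-frame join.
    Interior gaps of up to ``max_gap`` frames are linearly interpolated (and
    flagged); longer gaps or coverage below ``min_coverage`` reject the
    trajectory.
    """
    if fps <= 0:
        raise ParameterError("fps must be positive")
    df = landmarks.copy()
    df["frame"] = df["frame"].astype(int)
    df.loc[df["camera"] == "right", "frame"] -= sync_offset
    per_landmark = {}
    frames_all = []
    for lm in LANDMARKS:
        sub = df[(df["landmark"] == lm) & df["visible"].astype(bool)]
        lft = sub[sub["camera"] == "left"].set_index("frame")[["u", "v"]]
        rgt = sub[sub["camera"] == "right"].set_index("frame")[["u", "v"]]
        common = lft.index.intersection(rgt.index)
        if len(common) == 0:
            raise TrajectoryGapError(f"landmark {lm!r} never visible in both views")
        per_landmark[lm] = (lft, rgt, common)
        frames_all.append(common)
    f0 = max(c.min() for c in frames_all)
    f1 = min(c.max() for c in frames_all)
    if f1 <= f0:
        raise TrajectoryGapError("no overlapping frame range across landmarks")
    frames = np.arange(f0, f1 + 1)
    positions = {}
    interp_any = np.zeros(len(frames), dtype=bool)
    for lm in LANDMARKS:
        lft, rgt, common = per_landmark[lm]
        valid = np.isin(frames, common)
        coverage = valid.mean()
        if coverage < min_coverage:
            raise TrajectoryGapError(
                f"landmark {lm!r} visible in both views for only "
                f"{coverage:.0%} of frames (< {min_coverage:.0%})"
            )
        pts = np.full((len(frames), 3), np.nan)
        for i, f in enumerate(frames):
            if valid[i]:
                pts[i] = triangulate_point(
                    lft.loc[f].to_numpy(), rgt.loc[f].to_numpy(), left, right
                )[0]
        pts, interp = _fill_gaps(pts, valid, max_gap)
        if np.isnan(pts).any():
            raise TrajectoryGapError(
                f"landmark {lm!r} missing at the start or end of the "
                f"common frame range"
            )
        interp_any |= interp
        positions[lm] = pts
    return Trajectory3D(
        timestamps=frames / fps,
        snout=positions["snout"],
        cloaca=positions["cloaca"],
        frame_rate=fps,
        interpolated=interp_any,
    )
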