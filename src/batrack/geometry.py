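"""Pinhole stereo camera model: projection, triangulation, the bulb calibration target.

World frame convention (anchored at the left camera): x lateral (baseline
direction), y range from the camera plane (the viewing direction), z height.
All world coordinates are millimetres; pixels are sub-pixel floats with the
origin at the top-left pixel centre, u rightward, v downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CameraIntrinsics",
    "CameraExtrinsics",
    "Camera",
    "StereoRig",
    "CalibrationTarget",
    "BehindCameraError",
    "TriangulationError",
    "triangulate",
]


class BehindCameraError(ValueError):
    """A point with non-positive depth was projected."""


class TriangulationError(ValueError):
    """Rays are too close to parallel for a stable intersection."""


# Rotation taking world axes (x lateral, y range, z height) to camera axes
# (x right, y down, z forward) for a camera looking along +y with no tilt.
_R_LOOK_ALONG_Y = np.array([[1.0, 0.0, 0.0],
                            [0.0, 0.0, -1.0],
                            [0.0, 1.0, 0.0]])


@dataclass
class CameraIntrinsics:
    """Focal lengths and principal point in pixels, optional radial distortion.

    Distortion is the standard two-term radial model: a normalised image
    point at radius r is displaced by the factor ``1 + k1 r^2 + k2 r^4``.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    def distort(self, xy: np.ndarray) -> np.ndarray:
        """Apply radial distortion to normalised image coordinates (n, 2)."""
        r2 = np.sum(xy ** 2, axis=-1, keepdims=True)
        return xy * (1.0 + self.k1 * r2 + self.k2 * r2 ** 2)

    def undistort(self, xy: np.ndarray, iterations: int = 12) -> np.ndarray:
        """Invert the radial distortion by fixed-point iteration."""
        if self.k1 == 0.0 and self.k2 == 0.0:
            return np.asarray(xy, dtype=float)
        xy = np.asarray(xy, dtype=float)
        undist = xy.copy()
        for _ in range(iterations):
            r2 = np.sum(undist ** 2, axis=-1, keepdims=True)
            undist = xy / (1.0 + self.k1 * r2 + self.k2 * r2 ** 2)
        return undist


@dataclass
class CameraExtrinsics:
    """World-to-camera rigid transform: X_cam = R @ X_world + t (t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must have determinant +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def camera_centre(self) -> np.ndarray:
        """Camera centre in world coordinates (mm)."""
        return -self.rotation.T @ self.translation


@dataclass
class Camera:
    intrinsics: CameraIntrinsics
    extrinsics: CameraExtrinsics

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project world points (mm) to pixel coordinates.

        Accepts a single (3,) point or an (n, 3) array; returns matching
        (2,) or (n, 2) pixel coordinates. Raises :class:`BehindCameraError`
        if any point has non-positive depth.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cam = pts @ self.extrinsics.rotation.T + self.extrinsics.translation
        depth = cam[:, 2]
        if np.any(depth <= 0):
            raise BehindCameraError(
                f"{int(np.sum(depth <= 0))} point(s) at or behind the camera plane"
            )
        xy = cam[:, :2] / depth[:, None]
        xy = self.intrinsics.distort(xy)
        uv = np.empty_like(xy)
        uv[:, 0] = self.intrinsics.fx * xy[:, 0] + self.intrinsics.cx
        uv[:, 1] = self.intrinsics.fy * xy[:, 1] + self.intrinsics.cy
        return uv[0] if np.asarray(points).ndim == 1 else uv

    def visible(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of points in front of the camera and inside the image."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cam = pts @ self.extrinsics.rotation.T + self.extrinsics.translation
        ok = cam[:, 2] > 1.0
        uv = np.full((len(pts), 2), np.nan)
        if np.any(ok):
            xy = cam[ok, :2] / cam[ok, 2][:, None]
            xy = self.intrinsics.distort(xy)
            uv[ok, 0] = self.intrinsics.fx * xy[:, 0] + self.intrinsics.cx
            uv[ok, 1] = self.intrinsics.fy * xy[:, 1] + self.intrinsics.cy
        ok &= (uv[:, 0] >= margin) & (uv[:, 0] <= self.intrinsics.width - 1 - margin)
        ok &= (uv[:, 1] >= margin) & (uv[:, 1] <= self.intrinsics.height - 1 - margin)
        return ok

    def ray(self, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Back-project pixels to (origin, unit direction) in world frame."""
        uv = np.atleast_2d(np.asarray(pixels, dtype=float))
        xy = np.empty_like(uv)
        xy[:, 0] = (uv[:, 0] - self.intrinsics.cx) / self.intrinsics.fx
        xy[:, 1] = (uv[:, 1] - self.intrinsics.cy) / self.intrinsics.fy
        xy = self.intrinsics.undistort(xy)
        dirs_cam = np.column_stack([xy, np.ones(len(xy))])
        dirs = dirs_cam @ self.extrinsics.rotation  # R^T @ d, batched
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        origin = self.extrinsics.camera_centre
        return origin, dirs


def _look_along_y_extrinsics(centre_mm: np.ndarray,
                             pan_deg: float = 0.0,
                             tilt_deg: float = 0.0) -> CameraExtrinsics:
    """Extrinsics for a camera at ``centre_mm`` viewing along +y,
    panned about z (towards +x for positive pan) and tilted about x."""
    R_world = Rotation.from_euler("zx", [-pan_deg, tilt_deg], degrees=True).as_matrix()
    R = _R_LOOK_ALONG_Y @ R_world.T
    t = -R @ np.asarray(centre_mm, dtype=float)
    return CameraExtrinsics(R, t)


@dataclass
class StereoRig:
    """Two calibrated cameras sharing the world frame.

    The default geometry follows the field set-up: two 640x480 cameras with
    33 degree lenses at equal height, 4 m apart, viewing along +y. The exact
    mounting convergence in the field is ambiguous, so the pan angle of each
    camera is configurable; the default is parallel axes.
    """

    left: Camera
    right: Camera
    rms_reprojection_px: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_mm <= 0:
            raise ValueError("baseline must be positive")

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(
            self.left.extrinsics.camera_centre - self.right.extrinsics.camera_centre
        ))

    @classmethod
    def default(cls, baseline_mm: float = 4000.0, fov_deg: float = 33.0,
                pan_deg: float = 0.0, k1: float = 0.0, k2: float = 0.0,
                width: int = 640, height: int = 480) -> "StereoRig":
        f = (width / 2.0) / np.tan(np.radians(fov_deg / 2.0))
        intr = dict(fx=f, fy=f, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0,
                    k1=k1, k2=k2, width=width, height=height)
        left = Camera(CameraIntrinsics(**intr),
                      _look_along_y_extrinsics(np.zeros(3), pan_deg=pan_deg))
        right = Camera(CameraIntrinsics(**intr),
                       _look_along_y_extrinsics(np.array([baseline_mm, 0.0, 0.0]),
                                                pan_deg=-pan_deg))
        return cls(left, right)

    def joint_visible(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        return self.left.visible(points, margin) & self.right.visible(points, margin)


def triangulate(pixel_left: np.ndarray, pixel_right: np.ndarray,
                rig: StereoRig, parallel_tol: float = 1e-8
                ) -> tuple[np.ndarray, float]:
    """Triangulate one cross-camera pixel pair to a world point (mm).

    Uses the midpoint of the shortest segment between the two back-projected
    rays, then reports the mean reprojection error over both cameras as the
    residual. Raises :class:`TriangulationError` when the rays are too close
    to parallel for a stable intersection.
    """
    o1, d1 = rig.left.ray(pixel_left)
    o2, d2 = rig.right.ray(pixel_right)
    d1, d2 = d1[0], d2[0]
    # Solve [d1 -d2] [s, t]^T = o2 - o1 in the least-squares sense.
    b = o2 - o1
    d11 = d1 @ d1
    d12 = d1 @ d2
    d22 = d2 @ d2
    denom = d11 * d22 - d12 ** 2
    if denom < parallel_tol * d11 * d22:
        raise TriangulationError("rays are near-parallel; depth is unresolvable")
    s = (d22 * (d1 @ b) - d12 * (d2 @ b)) / denom
    t = (d12 * (d1 @ b) - d11 * (d2 @ b)) / denom
    point = 0.5 * ((o1 + s * d1) + (o2 + t * d2))
    res_l = np.linalg.norm(rig.left.project(point) - np.asarray(pixel_left, float))
    res_r = np.linalg.norm(rig.right.project(point) - np.asarray(pixel_right, float))
    return point, float(0.5 * (res_l + res_r))


def triangulate_many(pixels_left: np.ndarray, pixels_right: np.ndarray,
                     rig: StereoRig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised midpoint triangulation of paired pixel arrays (n, 2).

    Returns (points (n, 3) mm, residuals (n,) px). Near-parallel pairs get
    NaN points and infinite residuals instead of raising.
    """
    pl = np.atleast_2d(np.asarray(pixels_left, dtype=float))
    pr = np.atleast_2d(np.asarray(pixels_right, dtype=float))
    o1, d1 = rig.left.ray(pl)
    o2, d2 = rig.right.ray(pr)
    b = np.broadcast_to(o2 - o1, d1.shape)
    d11 = np.einsum("ij,ij->i", d1, d1)
    d12 = np.einsum("ij,ij->i", d1, d2)
    d22 = np.einsum("ij,ij->i", d2, d2)
    denom = d11 * d22 - d12 ** 2
    ok = denom > 1e-8 * d11 * d22
    pts = np.full((len(pl), 3), np.nan)
    res = np.full(len(pl), np.inf)
    if np.any(ok):
        d1b = np.einsum("ij,ij->i", d1, b)
        d2b = np.einsum("ij,ij->i", d2, b)
        s = (d22 * d1b - d12 * d2b)[ok] / denom[ok]
        t = (d12 * d1b - d11 * d2b)[ok] / denom[ok]
        pts[ok] = 0.5 * ((o1 + s[:, None] * d1[ok]) + (o2 + t[:, None] * d2[ok]))
        # reprojection residuals; points behind either camera stay at inf
        for i in np.flatnonzero(ok):
            try:
                rl = np.linalg.norm(rig.left.project(pts[i]) - pl[i])
                rr = np.linalg.norm(rig.right.project(pts[i]) - pr[i])
                res[i] = 0.5 * (rl + rr)
            except BehindCameraError:
                pts[i] = np.nan
    return pts, res


@dataclass
class CalibrationTarget:
    """The bespoke thermal calibration cross: thirty 11 mm tungsten bulbs
    on four arms — three arms of eight evenly spaced bulbs, and one arm of
    six bulbs arranged in three pairs so the target's orientation can be
    identified in thermal footage.

    Bulbs live in the target plane (z = 0 of the target frame). The arm
    length and in-pair spacing are configurable (the as-built dimensions are
    not published); defaults use 1 m arms.
    """

    arm_length_mm: float = 1000.0
    pair_gap_mm: float = 60.0
    bulb_diameter_mm: float = 11.0
    points: np.ndarray = field(init=False)
    arm_of_bulb: np.ndarray = field(init=False)

    # arm unit directions in the target frame, in bulb-id order
    _ARMS = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])

    def __post_init__(self) -> None:
        spacing = self.arm_length_mm / 8.0
        pts: list[list[float]] = []
        arm_ids: list[int] = []
        for a in range(3):  # three identical 8-bulb arms
            d = self._ARMS[a]
            for i in range(1, 9):
                pts.append(list(d * spacing * i) + [0.0])
                arm_ids.append(a)
        # the 6-bulb arm: three pairs, pair centres evenly spaced
        d = self._ARMS[3]
        centres = [self.arm_length_mm * f for f in (0.3, 0.6, 0.9)]
        for c in centres:
            for off in (-self.pair_gap_mm / 2.0, self.pair_gap_mm / 2.0):
                pts.append(list(d * (c + off)) + [0.0])
                arm_ids.append(3)
        self.points = np.asarray(pts)
        self.arm_of_bulb = np.asarray(arm_ids)
        assert len(self.points) == 30
        assert int(np.sum(self.arm_of_bulb == 3)) == 6

    @property
    def n_bulbs(self) -> int:
        return len(self.points)

    def plane_coordinates(self) -> np.ndarray:
        """(30, 2) in-plane coordinates (the target is planar)."""
        return self.points[:, :2].copy()
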