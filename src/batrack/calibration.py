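"""Stereo calibration from the thermal bulb target.

The target is planar, so intrinsics are initialised per camera with Zhang's
homography method, per-pose target poses follow from the homographies, the
relative camera pose is averaged over poses, and everything is then refined
jointly by minimising the reprojection error over both cameras
(scipy.optimize.least_squares).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import (Camera, CameraExtrinsics, CameraIntrinsics,
                       CalibrationTarget, StereoRig, _R_LOOK_ALONG_Y)

__all__ = [
    "CalibrationError",
    "PoseRejected",
    "LabelledPose",
    "identify_target",
    "calibrate_stereo",
]


class CalibrationError(RuntimeError):
    """Calibration could not be completed (degenerate or insufficient poses)."""


class PoseRejected(ValueError):
    """A single calibration pose could not be labelled unambiguously."""


@dataclass
class LabelledPose:
    """Bulb correspondences for one target pose: pixel coordinates per camera
    indexed by bulb id (NaN rows for undetected bulbs)."""

    pose_id: int
    pixels_left: np.ndarray   # (30, 2)
    pixels_right: np.ndarray  # (30, 2)

    def detected(self) -> np.ndarray:
        return ~(np.isnan(self.pixels_left[:, 0]) | np.isnan(self.pixels_right[:, 0]))


# ---------------------------------------------------------------------------
# Target identification
# ---------------------------------------------------------------------------

def _fit_two_lines(uv: np.ndarray, tol_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Split blob pixels into the two bars of the cross by exhaustive
    two-point line hypotheses (RANSAC-style but deterministic)."""
    n = len(uv)
    best = None
    for i, j in itertools.combinations(range(min(n, 18)), 2):
        p, q = uv[i], uv[j]
        d = q - p
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            continue
        normal = np.array([-d[1], d[0]]) / norm
        dist = np.abs((uv - p) @ normal)
        inliers = dist < tol_px
        score = int(inliers.sum())
        if best is None or score > best[0]:
            best = (score, inliers)
    if best is None or best[0] < 10:
        raise PoseRejected("could not find a line of bulbs (first bar)")
    bar1 = best[1]
    rest = ~bar1
    if int(rest.sum()) < 8:
        raise PoseRejected("too few bulbs left for the second bar")
    # second bar: fit a line through the remaining points by total least squares
    pts = uv[rest]
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre)
    normal = vt[1]
    dist = np.abs((uv - centre) @ normal)
    bar2 = (dist < tol_px) & rest
    if int(bar2.sum()) < 8:
        raise PoseRejected("second bar of bulbs is not collinear")
    return bar1, bar2


def _order_along(uv: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order point indices along their common line; return (ordered idx, direction)."""
    pts = uv[idx]
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre)
    direction = vt[0]
    t = (pts - centre) @ direction
    order = np.argsort(t)
    return idx[order], direction


def _split_arms(uv: np.ndarray, ordered: np.ndarray, line_dir: np.ndarray,
                centre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split one bar's ordered bulb indices into the two arms either side of
    the cross centre, each ordered from the centre outward."""
    t = (uv[ordered] - centre) @ line_dir
    neg = ordered[t < 0][::-1]  # nearest-to-centre first
    pos = ordered[t > 0]
    return pos, neg


def _is_pair_arm(uv: np.ndarray, arm: np.ndarray, centre: np.ndarray) -> bool:
    """Six bulbs in three pairs give an alternating small/large gap pattern."""
    if len(arm) != 6:
        return False
    t = np.linalg.norm(uv[arm] - centre, axis=1)
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        return False
    small = gaps[[1, 3]].max() if len(gaps) == 5 else np.inf
    in_pair = gaps[[0, 2, 4]]
    between = gaps[[1, 3]]
    return in_pair.max() < 0.8 * between.min()


def identify_target(blobs_px: np.ndarray, target: CalibrationTarget,
                    tol_px: float = 2.0) -> np.ndarray:
    """Assign bulb ids to unlabelled blob pixels from one camera and pose.

    Returns a (30, 2) array of pixel coordinates in bulb-id order (NaN for
    bulbs not detected). The 6-bulb pair arm disambiguates the target's
    orientation; its in-image handedness relative to the 8-bulb bar resolves
    the remaining 180-degree ambiguity. Raises :class:`PoseRejected` when
    fewer than 25 bulbs are detected or the assignment is ambiguous.
    """
    uv = np.atleast_2d(np.asarray(blobs_px, dtype=float))
    if len(uv) < 25:
        raise PoseRejected(f"only {len(uv)} of 30 bulbs detected (need >= 25)")
    bar1, bar2 = _fit_two_lines(uv, tol_px)
    idx1, dir1 = _order_along(uv, np.flatnonzero(bar1))
    idx2, dir2 = _order_along(uv, np.flatnonzero(bar2))
    # cross centre = intersection of the two bar lines
    c1 = uv[idx1].mean(axis=0)
    c2 = uv[idx2].mean(axis=0)
    A = np.column_stack([dir1, -dir2])
    try:
        st = np.linalg.solve(A, c2 - c1)
    except np.linalg.LinAlgError as exc:
        raise PoseRejected("bars are parallel in the image") from exc
    centre = c1 + st[0] * dir1

    arms = []
    for ordered, d in ((idx1, dir1), (idx2, dir2)):
        pos, neg = _split_arms(uv, ordered, d, centre)
        arms.extend([pos, neg])
    pair_arms = [k for k, a in enumerate(arms) if _is_pair_arm(uv, a, centre)]
    if len(pair_arms) != 1:
        raise PoseRejected(
            f"{len(pair_arms)} candidate pair arms found; orientation ambiguous")
    k_pair = pair_arms[0]
    pair_arm = arms[k_pair]
    opposite = arms[k_pair ^ 1]           # other arm of the same bar -> +y arm
    side_a, side_b = [a for k, a in enumerate(arms) if k not in (k_pair, k_pair ^ 1)]
    if len(opposite) != 8 or len(side_a) < 6 or len(side_b) < 6:
        raise PoseRejected("arm bulb counts do not match the target layout")

    # handedness: in the target frame, rotating the -y (pair) arm direction by
    # +90 degrees gives the +x arm. Projection from the front preserves
    # orientation, but pixel coordinates run v-down, so the cross-product
    # sign is flipped relative to the target frame.
    d_pair = uv[pair_arm[-1]] - centre
    d_a = uv[side_a[-1]] - centre
    cross = d_pair[0] * d_a[1] - d_pair[1] * d_a[0]
    plus_x, minus_x = (side_a, side_b) if cross < 0 else (side_b, side_a)

    out = np.full((target.n_bulbs, 2), np.nan)
    for arm_id, arm in ((0, plus_x), (1, minus_x), (2, opposite), (3, pair_arm)):
        bulb_ids = np.flatnonzero(target.arm_of_bulb == arm_id)
        if len(arm) > len(bulb_ids):
            raise PoseRejected("more bulbs on an arm than the target layout allows")
        out[bulb_ids[: len(arm)]] = uv[arm]
    return out


# ---------------------------------------------------------------------------
# Zhang initialisation
# ---------------------------------------------------------------------------

def _homography(plane_xy: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """DLT homography with Hartley normalisation, plane (mm) -> pixels."""
    def normalise(p):
        c = p.mean(axis=0)
        s = np.sqrt(2.0) / np.mean(np.linalg.norm(p - c, axis=1))
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        ph = np.column_stack([p, np.ones(len(p))]) @ T.T
        return ph, T

    src, T1 = normalise(plane_xy)
    dst, T2 = normalise(uv)
    A = []
    for (x, y, _), (u, v, _) in zip(src, dst):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, vt = np.linalg.svd(np.asarray(A))
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(T2) @ H @ T1
    return H / H[2, 2]


def _zhang_intrinsics(homographies: list[np.ndarray],
                      width: int, height: int) -> CameraIntrinsics:
    """Closed-form intrinsics from plane homographies (zero skew enforced)."""
    def v_ij(H, i, j):
        return np.array([
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ])

    rows = []
    for H in homographies:
        rows.append(v_ij(H, 0, 1))
        rows.append(v_ij(H, 0, 0) - v_ij(H, 1, 1))
    V = np.asarray(rows)
    # zero-skew constraint: B12 = 0
    V = np.vstack([V, [0, 1e3, 0, 0, 0, 0]])
    sv = np.linalg.svd(V, compute_uv=False)
    cond = sv[0] / max(sv[-2], 1e-300)
    if cond > 1e12:
        raise CalibrationError(
            "degenerate pose set: calibration normal equations are rank-deficient "
            "(poses likely coplanar/fronto-parallel; vary depth and tilt)")
    _, _, vt = np.linalg.svd(V)
    b = vt[-1]
    if b[0] < 0:
        b = -b
    b11, b12, b22, b13, b23, b33 = b
    try:
        v0 = (b12 * b13 - b11 * b23) / (b11 * b22 - b12 ** 2)
        lam = b33 - (b13 ** 2 + v0 * (b12 * b13 - b11 * b23)) / b11
        alpha = np.sqrt(lam / b11)
        beta = np.sqrt(lam * b11 / (b11 * b22 - b12 ** 2))
        u0 = -b13 * alpha ** 2 / lam
    except (FloatingPointError, ValueError) as exc:
        raise CalibrationError("degenerate pose set for intrinsics") from exc
    if not np.isfinite([alpha, beta, u0, v0]).all() or alpha <= 0 or beta <= 0:
        raise CalibrationError("Zhang initialisation produced non-physical intrinsics")
    # the closed form is only a starting value: with pixel noise the principal
    # point can land outside the image; clamp it and let refinement recover it
    u0 = float(np.clip(u0, 1.0, width - 2.0))
    v0 = float(np.clip(v0, 1.0, height - 2.0))
    return CameraIntrinsics(fx=float(alpha), fy=float(beta), cx=u0,
                            cy=v0, width=width, height=height)


def _pose_from_homography(H: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Target pose (R, t): X_cam = R @ [X, Y, 0] + t, from one homography."""
    M = np.linalg.inv(K) @ H
    lam = 1.0 / np.linalg.norm(M[:, 0])
    if M[2, 2] < 0:  # target must be in front of the camera
        lam = -lam
    r1 = lam * M[:, 0]
    r2 = lam * M[:, 1]
    t = lam * M[:, 2]
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    # closest rotation
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1, 1, -1]) @ Vt
    return R, t


# ---------------------------------------------------------------------------
# Joint refinement
# ---------------------------------------------------------------------------

def _pack(intr: CameraIntrinsics, with_distortion: bool) -> list[float]:
    p = [intr.fx, intr.fy, intr.cx, intr.cy]
    if with_distortion:
        p += [intr.k1, intr.k2]
    return p


def _project_cam(params_K, with_distortion, R, t, plane_pts):
    fx, fy, cx, cy = params_K[:4]
    k1, k2 = (params_K[4], params_K[5]) if with_distortion else (0.0, 0.0)
    X = np.column_stack([plane_pts, np.zeros(len(plane_pts))])
    cam = X @ R.T + t
    xy = cam[:, :2] / cam[:, 2][:, None]
    r2 = np.sum(xy ** 2, axis=1, keepdims=True)
    xy = xy * (1 + k1 * r2 + k2 * r2 ** 2)
    return np.column_stack([fx * xy[:, 0] + cx, fy * xy[:, 1] + cy])


def calibrate_stereo(poses: list[LabelledPose], target: CalibrationTarget,
                     with_distortion: bool = False,
                     min_poses: int = 10) -> StereoRig:
    """Estimate both cameras' intrinsics and the stereo extrinsics from
    labelled bulb correspondences over >= ``min_poses`` target poses.

    Linear initialisation (homographies + Zhang closed form) is refined by a
    joint bundle adjustment over both intrinsics, the per-pose target poses
    relative to the left camera, and the left-to-right relative pose. The
    returned rig is expressed in the package's world frame (left camera at
    the origin, y the viewing direction) and carries the RMS reprojection
    error in pixels.
    """
    if len(poses) < min_poses:
        raise CalibrationError(f"need >= {min_poses} poses, got {len(poses)}")
    plane = target.plane_coordinates()
    W, Hpx = 640, 480

    Hs_l, Hs_r, keep = [], [], []
    for p in poses:
        det = p.detected()
        if int(det.sum()) < 6:
            continue
        Hs_l.append(_homography(plane[det], p.pixels_left[det]))
        Hs_r.append(_homography(plane[det], p.pixels_right[det]))
        keep.append(p)
    if len(keep) < min_poses:
        raise CalibrationError("too few usable poses after detection filtering")

    K_l = _zhang_intrinsics(Hs_l, W, Hpx)
    K_r = _zhang_intrinsics(Hs_r, W, Hpx)

    poses_l, rel_rots, rel_ts = [], [], []
    for Hl, Hr in zip(Hs_l, Hs_r):
        Rl, tl = _pose_from_homography(Hl, K_l.matrix)
        Rr, tr = _pose_from_homography(Hr, K_r.matrix)
        poses_l.append((Rl, tl))
        # X_r = R_rel @ X_l + t_rel
        R_rel = Rr @ Rl.T
        rel_rots.append(Rotation.from_matrix(R_rel))
        rel_ts.append(tr - R_rel @ tl)
    R_rel0 = Rotation.mean(Rotation.concatenate(rel_rots)).as_matrix()
    t_rel0 = np.mean(rel_ts, axis=0)

    nK = 6 if with_distortion else 4
    x0 = np.concatenate([
        _pack(K_l, with_distortion), _pack(K_r, with_distortion),
        Rotation.from_matrix(R_rel0).as_rotvec(), t_rel0,
        np.concatenate([np.concatenate([Rotation.from_matrix(R).as_rotvec(), t])
                        for R, t in poses_l]),
    ])
    masks = [p.detected() for p in keep]

    def residuals(x):
        Kl = x[:nK]
        Kr = x[nK:2 * nK]
        R_rel = Rotation.from_rotvec(x[2 * nK:2 * nK + 3]).as_matrix()
        t_rel = x[2 * nK + 3:2 * nK + 6]
        out = []
        off = 2 * nK + 6
        for i, p in enumerate(keep):
            rv = x[off + 6 * i: off + 6 * i + 3]
            tv = x[off + 6 * i + 3: off + 6 * i + 6]
            Rl = Rotation.from_rotvec(rv).as_matrix()
            det = masks[i]
            uv_l = _project_cam(Kl, with_distortion, Rl, tv, plane[det])
            Rr = R_rel @ Rl
            tr = R_rel @ tv + t_rel
            uv_r = _project_cam(Kr, with_distortion, Rr, tr, plane[det])
            out.append((uv_l - p.pixels_left[det]).ravel())
            out.append((uv_r - p.pixels_right[det]).ravel())
        return np.concatenate(out)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14,
                        max_nfev=4000)
    if not np.isfinite(sol.cost):
        raise CalibrationError("bundle adjustment diverged")
    r = sol.fun
    rms = float(np.sqrt(np.mean(r ** 2)))

    x = sol.x
    def unpack_K(v):
        kw = dict(fx=v[0], fy=v[1], cx=v[2], cy=v[3], width=W, height=Hpx)
        if with_distortion:
            kw.update(k1=v[4], k2=v[5])
        return CameraIntrinsics(**kw)

    Kl = unpack_K(x[:nK])
    Kr = unpack_K(x[nK:2 * nK])
    R_rel = Rotation.from_rotvec(x[2 * nK:2 * nK + 3]).as_matrix()
    t_rel = x[2 * nK + 3:2 * nK + 6]

    # anchor the world frame at the left camera, y = viewing direction
    R_wl = _R_LOOK_ALONG_Y
    left = Camera(Kl, CameraExtrinsics(R_wl, np.zeros(3)))
    right = Camera(Kr, CameraExtrinsics(R_rel @ R_wl, t_rel.copy()))
    rig = StereoRig(left, right, rms_reprojection_px=rms)
    return rig
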