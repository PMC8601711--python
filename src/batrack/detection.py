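"""2D localisation from thermal frame stacks.

Background subtraction (adjacent-frame differencing, as in the original
analysis, or a rolling-median background model) followed by thresholding and
connected-component centroid extraction, plus the empirical threshold-
selection step that picks the pixel threshold maximising the number of
usable trajectories at minimal noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Detection2D",
    "background_subtract",
    "threshold_detect",
    "detect_stack",
    "select_threshold",
    "ThresholdSelectionError",
]


class ThresholdSelectionError(RuntimeError):
    """No candidate threshold yielded any trajectory."""


@dataclass
class Detection2D:
    """One above-threshold blob: intensity-weighted sub-pixel centroid."""

    camera: str
    frame: int          # 0-based
    u: float
    v: float
    area_px: int
    peak: float


def background_subtract(stack: np.ndarray, mode: str = "rolling_median",
                        window: int = 21) -> np.ndarray:
    """Return a non-negative difference stack, same shape as the input.

    ``adjacent_frame``: absolute difference from the previous frame (frame 0
    is all zeros); a moving blob appears twice per difference image (old and
    new position), mirroring differencing between individual frames.
    ``rolling_median``: subtracts a per-pixel rolling-median background over
    ``window`` frames, clipped at zero — the robust default, yielding one
    response per object. The window must comfortably exceed twice the number
    of frames a slow-moving blob dwells on one pixel, or the median absorbs
    the blob itself.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or len(stack) < 2:
        raise ValueError("need a (frames, h, w) stack with at least 2 frames")
    s = stack.astype(np.float64)
    if mode == "adjacent_frame":
        out = np.zeros_like(s)
        out[1:] = np.abs(s[1:] - s[:-1])
        return out
    if mode == "rolling_median":
        n = len(s)
        w = min(window, n)
        out = np.empty_like(s)
        for i in range(n):
            lo = max(0, min(i - w // 2, n - w))
            bg = np.median(s[lo:lo + w], axis=0)
            out[i] = np.clip(s[i] - bg, 0.0, None)
        return out
    raise ValueError(f"unknown background mode {mode!r}")


def threshold_detect(diff_frame: np.ndarray, pixel_threshold: float,
                     min_blob_area: int = 2, camera: str = "left",
                     frame: int = 0) -> list[Detection2D]:
    """Connected components above ``pixel_threshold``, area-filtered, with
    intensity-weighted sub-pixel centroids. An empty list is a valid result."""
    if pixel_threshold <= 0:
        raise ValueError("pixel threshold must be positive")
    mask = np.asarray(diff_frame) > pixel_threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    img = np.asarray(diff_frame, dtype=float)
    out = []
    areas = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    coms = ndimage.center_of_mass(img, labels, index=np.arange(1, n + 1))
    peaks = ndimage.maximum(img, labels, index=np.arange(1, n + 1))
    for k in range(n):
        if areas[k] < min_blob_area:
            continue
        v, u = coms[k]
        out.append(Detection2D(camera, frame, float(u), float(v),
                               int(areas[k]), float(peaks[k])))
    return out


def detect_stack(stack: np.ndarray, pixel_threshold: float,
                 min_blob_area: int = 2, camera: str = "left",
                 mode: str = "rolling_median", window: int = 21
                 ) -> list[Detection2D]:
    """Background-subtract a stack and detect every frame."""
    diff = background_subtract(stack, mode=mode, window=window)
    out: list[Detection2D] = []
    for f in range(len(diff)):
        out.extend(threshold_detect(diff[f], pixel_threshold, min_blob_area,
                                    camera=camera, frame=f))
    return out


def detections_frame(dets: list[Detection2D]) -> pd.DataFrame:
    cols = ["camera", "frame", "u", "v", "area_px", "peak"]
    return pd.DataFrame([(d.camera, d.frame, d.u, d.v, d.area_px, d.peak)
                         for d in dets], columns=cols)


def select_threshold(stack_left: np.ndarray, stack_right: np.ndarray, rig,
                     candidate_thresholds, linking_params=None,
                     min_blob_area: int = 2, mode: str = "rolling_median",
                     noise_weight: float = 0.1, max_residual_px: float = 2.0,
                     ) -> tuple[float, pd.DataFrame]:
    """Empirical pixel-threshold selection.

    For each candidate threshold the full detect -> pair -> link -> QC chain
    is run and scored as ``n_qc_trajectories - noise_weight * n_discarded``,
    where the discarded count is the number of 2D detections that never make
    it into a QC-passing trajectory (the operational stand-in for "noise":
    a threshold that is too low admits insect blobs and erroneous
    localisations, one too high loses real bats). Ties go to the higher
    threshold. Returns the chosen threshold and the per-candidate
    diagnostics table.
    """
    from .tracking import (LinkingParams, build_trajectories, pair_stereo,
                           qc_shared_points, qc_speed_consistency)

    candidates = sorted(set(float(t) for t in candidate_thresholds))
    if len(candidates) < 1:
        raise ValueError("need at least one candidate threshold")
    linking_params = linking_params or LinkingParams()
    rows = []
    for thr in candidates:
        det_l = detect_stack(stack_left, thr, min_blob_area, "left", mode)
        det_r = detect_stack(stack_right, thr, min_blob_area, "right", mode)
        locs = pair_stereo(det_l, det_r, rig, max_residual_px=max_residual_px)
        trajs = build_trajectories(locs, linking_params)
        trajs = qc_shared_points(trajs)
        trajs = [t for t in trajs if qc_speed_consistency(t)[0]]
        used = sum(len(t.localisations) for t in trajs)
        n_det = len(det_l) + len(det_r)
        discarded = n_det - 2 * used
        score = len(trajs) - noise_weight * max(discarded, 0)
        rows.append((thr, len(trajs), n_det, max(discarded, 0), score))
    diag = pd.DataFrame(rows, columns=["threshold", "n_trajectories",
                                       "n_detections", "n_discarded", "score"])
    if diag["n_trajectories"].sum() == 0:
        raise ThresholdSelectionError(
            "no candidate threshold produced a trajectory; widen the grid")
    # argmax, ties resolved to the higher threshold
    best = diag.sort_values(["score", "threshold"]).iloc[-1]
    return float(best["threshold"]), diag
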