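"""Per-trajectory flight variables.

Instantaneous speed is the 3D distance between subsequent localisations
divided by the time between frames (0.032 s per frame by default); mean
trajectory speed is the mean of the instantaneous speeds. Trajectory length
is the sum of all distance segments, net displacement the first-to-last
distance, and the tortuosity value their ratio divided by 10 so a straight
path scores exactly 0.1. Distance from the deterrents is the mean y
coordinate plus a 15 m offset (the speakers stood behind the cameras); the
un-offset mean y is reported alongside so both conventions stay available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Trajectory

__all__ = [
    "TrajectoryMetrics",
    "instantaneous_speeds",
    "mean_speed",
    "total_length_and_net",
    "tortuosity_value",
    "distance_and_height",
    "compute_metrics",
    "metrics_frame",
]

log = logging.getLogger(__name__)

DETERRENT_OFFSET_M = 15.0


def _positions_frames(traj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(traj, Trajectory):
        return traj.positions_mm, traj.frames
    pos, frames = traj
    return np.asarray(pos, dtype=float), np.asarray(frames, dtype=int)


def instantaneous_speeds(traj, dt: float = 0.032) -> np.ndarray:
    """Per-segment speeds in m/s; frame gaps scale the time denominator."""
    pos, frames = _positions_frames(traj)
    if len(pos) < 2:
        raise ValueError("need at least two localisations")
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1) / 1000.0
    gaps = np.diff(frames)
    return steps / (gaps * dt)


def mean_speed(traj, dt: float = 0.032) -> float:
    """Mean of all instantaneous speeds (m/s)."""
    return float(np.mean(instantaneous_speeds(traj, dt)))


def total_length_and_net(traj) -> tuple[float, float]:
    """(total travelled distance, net displacement), both metres.

    Segments spanning frame gaps contribute their straight-line length.
    """
    pos, _ = _positions_frames(traj)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    total = float(np.sum(steps)) / 1000.0
    net = float(np.linalg.norm(pos[-1] - pos[0])) / 1000.0
    return total, net


def tortuosity_value(traj) -> float:
    """(total / net) / 10; exactly 0.1 for a straight path.

    Undefined (NaN, with a logged reason) when the net displacement is zero;
    such trajectories are excluded from tortuosity analyses.
    """
    total, net = total_length_and_net(traj)
    if net <= 0:
        log.info("tortuosity undefined: zero net displacement")
        return float("nan")
    return (total / net) / 10.0


def distance_and_height(traj, deterrent_offset_m: float = DETERRENT_OFFSET_M
                        ) -> tuple[float, float, float]:
    """(mean y in m, distance from deterrent in m, mean height in m)."""
    pos, _ = _positions_frames(traj)
    mean_y = float(np.mean(pos[:, 1])) / 1000.0
    mean_z = float(np.mean(pos[:, 2])) / 1000.0
    return mean_y, mean_y + deterrent_offset_m, mean_z


@dataclass
class TrajectoryMetrics:
    trajectory_id: int
    mean_speed_ms: float
    total_length_m: float
    net_displacement_m: float
    tortuosity: float
    mean_y_m: float
    distance_from_deterrent_m: float
    mean_height_m: float
    n_localisations: int
    n_segments: int


def compute_metrics(traj: Trajectory, dt: float = 0.032,
                    deterrent_offset_m: float = DETERRENT_OFFSET_M
                    ) -> TrajectoryMetrics:
    total, net = total_length_and_net(traj)
    mean_y, dist, height = distance_and_height(traj, deterrent_offset_m)
    return TrajectoryMetrics(
        trajectory_id=traj.trajectory_id,
        mean_speed_ms=mean_speed(traj, dt),
        total_length_m=total,
        net_displacement_m=net,
        tortuosity=tortuosity_value(traj),
        mean_y_m=mean_y,
        distance_from_deterrent_m=dist,
        mean_height_m=height,
        n_localisations=len(traj),
        n_segments=len(traj) - 1,
    )


def metrics_frame(trajectories: list[Trajectory], dt: float = 0.032,
                  deterrent_offset_m: float = DETERRENT_OFFSET_M) -> pd.DataFrame:
    """One metrics row per trajectory."""
    rows = [compute_metrics(t, dt, deterrent_offset_m).__dict__
            for t in trajectories]
    return pd.DataFrame(rows)
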