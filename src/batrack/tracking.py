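"""Stereo pairing, trajectory linking and quality control.

Detections from the two cameras are paired per frame by global minimum-cost
assignment on triangulation reprojection residual, then linked into 3D
trajectories under the published parameter set: maximum speed 15 m/s,
maximum frame gap 15, maximum step 1000 mm, minimum length 6 localisations.
QC removes trajectories sharing more than three localisations with another,
those with inconsistent speeds (jumps above 3 m/s between subsequent
instantaneous speeds), and single erroneous localisations are removed only
while they stay below 10% of a trajectory's points — otherwise the whole
trajectory is rejected as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection2D
from .geometry import StereoRig, triangulate_many

__all__ = [
    "Localisation3D",
    "LinkingParams",
    "Trajectory",
    "pair_stereo",
    "build_trajectories",
    "qc_shared_points",
    "qc_speed_consistency",
    "smooth_trajectory",
    "brute_force_link",
]


@dataclass
class Localisation3D:
    """A triangulated per-frame 3D position (mm) with reprojection residual."""

    frame: int
    x: float
    y: float
    z: float
    residual_px: float
    source_left: int = -1   # index into the left detection list
    source_right: int = -1

    @property
    def p(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class LinkingParams:
    """The published linking parameter set."""

    vmax_ms: float = 15.0
    max_frame_gap: int = 15
    max_step_mm: float = 1000.0
    min_length: int = 6
    dt: float = 0.032

    def __post_init__(self) -> None:
        if min(self.vmax_ms, self.max_frame_gap, self.max_step_mm, self.dt) <= 0:
            raise ValueError("linking parameters must be strictly positive")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")

    def step_legal(self, p0: np.ndarray, f0: int, p1: np.ndarray, f1: int) -> bool:
        gap = f1 - f0
        if gap < 1 or gap > self.max_frame_gap:
            return False
        step = float(np.linalg.norm(p1 - p0))
        if step > self.max_step_mm:
            return False
        return step / 1000.0 / (gap * self.dt) <= self.vmax_ms


@dataclass
class Trajectory:
    """An ordered sequence of 3D localisations satisfying the linking rules."""

    trajectory_id: int
    localisations: list[Localisation3D]
    qc_flags: dict = dc_field(default_factory=dict)

    @property
    def frames(self) -> np.ndarray:
        return np.array([l.frame for l in self.localisations])

    @property
    def positions_mm(self) -> np.ndarray:
        return np.array([[l.x, l.y, l.z] for l in self.localisations])

    def __len__(self) -> int:
        return len(self.localisations)

    def validate(self, params: LinkingParams) -> None:
        """Assert every linking invariant; raises AssertionError on violation."""
        assert len(self) >= params.min_length, "trajectory shorter than min_length"
        f = self.frames
        assert np.all(np.diff(f) >= 1), "frames must strictly increase"
        assert np.all(np.diff(f) <= params.max_frame_gap), "frame gap too large"
        p = self.positions_mm
        steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
        assert np.all(steps <= params.max_step_mm + 1e-9), "step exceeds max_step"
        speeds = steps / 1000.0 / (np.diff(f) * params.dt)
        assert np.all(speeds <= params.vmax_ms + 1e-9), "speed exceeds vmax"


def pair_stereo(detections_left: list[Detection2D],
                detections_right: list[Detection2D], rig: StereoRig,
                max_residual_px: float = 2.0) -> list[Localisation3D]:
    """Pair detections across cameras frame by frame.

    All cross-camera pairs within a frame are scored by triangulation
    reprojection residual; a global minimum-cost one-to-one assignment keeps
    the best pairing, and pairs above ``max_residual_px`` are dropped.
    Detections seen by only one camera yield no localisation.
    """
    by_frame_l: dict[int, list[int]] = {}
    by_frame_r: dict[int, list[int]] = {}
    for i, d in enumerate(detections_left):
        by_frame_l.setdefault(d.frame, []).append(i)
    for i, d in enumerate(detections_right):
        by_frame_r.setdefault(d.frame, []).append(i)

    out: list[Localisation3D] = []
    for f in sorted(set(by_frame_l) & set(by_frame_r)):
        li = by_frame_l[f]
        ri = by_frame_r[f]
        pl = np.array([[detections_left[i].u, detections_left[i].v] for i in li])
        pr = np.array([[detections_right[j].u, detections_right[j].v] for j in ri])
        # all pairs: triangulate and score
        ii, jj = np.meshgrid(np.arange(len(li)), np.arange(len(ri)), indexing="ij")
        pts, res = triangulate_many(pl[ii.ravel()], pr[jj.ravel()], rig)
        cost = res.reshape(len(li), len(ri))
        big = 1e6
        cost = np.where(np.isfinite(cost), cost, big)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] > max_residual_px:
                continue
            p = pts[r * len(ri) + c]
            if not np.all(np.isfinite(p)):
                continue
            out.append(Localisation3D(f, p[0], p[1], p[2], float(cost[r, c]),
                                      source_left=li[r], source_right=ri[c]))
    return out


def build_trajectories(localisations: list[Localisation3D],
                       params: LinkingParams | None = None) -> list[Trajectory]:
    """Link localisations into trajectories, greedily across frames with a
    global minimum-cost assignment per frame.

    A candidate extension of an open track is legal iff its frame gap is at
    most ``max_frame_gap``, the 3D step at most ``max_step_mm``, and the
    implied speed at most ``vmax_ms``; cost is the 3D gap distance, with
    equal-cost ties resolved by smaller frame gap. Tracks shorter than
    ``min_length`` are discarded. Every returned trajectory satisfies all
    the linking invariants (asserted before return).
    """
    params = params or LinkingParams()
    by_frame: dict[int, list[Localisation3D]] = {}
    for loc in localisations:
        by_frame.setdefault(loc.frame, []).append(loc)

    open_tracks: list[list[Localisation3D]] = []
    closed: list[list[Localisation3D]] = []
    big = 1e12
    for f in sorted(by_frame):
        # retire tracks that can no longer be extended
        still_open = []
        for t in open_tracks:
            if f - t[-1].frame > params.max_frame_gap:
                closed.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open

        locs = by_frame[f]
        if open_tracks:
            cost = np.full((len(open_tracks), len(locs)), big)
            for a, t in enumerate(open_tracks):
                last = t[-1]
                for b, loc in enumerate(locs):
                    if params.step_legal(last.p, last.frame, loc.p, loc.frame):
                        gap = loc.frame - last.frame
                        # tiny gap penalty implements the smaller-gap tie-break
                        cost[a, b] = (np.linalg.norm(loc.p - last.p)
                                      + 1e-6 * gap + 1e-9 * loc.residual_px)
            rows, cols = linear_sum_assignment(cost)
            assigned = set()
            for a, b in zip(rows, cols):
                if cost[a, b] < big:
                    open_tracks[a].append(locs[b])
                    assigned.add(b)
            for b, loc in enumerate(locs):
                if b not in assigned:
                    open_tracks.append([loc])
        else:
            open_tracks.extend([loc] for loc in locs)
    closed.extend(open_tracks)

    out = []
    for t in closed:
        if len(t) >= params.min_length:
            traj = Trajectory(len(out), t)
            traj.validate(params)
            out.append(traj)
    return out


def brute_force_link(localisations: list[Localisation3D],
                     params: LinkingParams | None = None) -> list[Trajectory]:
    """Independent reference linker for small scenes.

    Builds the graph of every legal link and requires each localisation to
    have at most one legal predecessor and successor, i.e. scenes whose
    correct partition is unambiguous (well-separated bats); the trajectories
    are then the connected chains. Raises ``ValueError`` when the scene is
    ambiguous, rather than guessing.
    """
    params = params or LinkingParams()
    n = len(localisations)
    succ: list[list[int]] = [[] for _ in range(n)]
    pred: list[list[int]] = [[] for _ in range(n)]
    order = sorted(range(n), key=lambda i: localisations[i].frame)
    for ai in range(n):
        for bi in range(n):
            a, b = localisations[ai], localisations[bi]
            if b.frame > a.frame and params.step_legal(a.p, a.frame, b.p, b.frame):
                succ[ai].append(bi)
                pred[bi].append(ai)
    # keep only nearest-in-time successors; chains must still be unambiguous
    for i in range(n):
        if len(succ[i]) > 1:
            fmin = min(localisations[j].frame for j in succ[i])
            succ[i] = [j for j in succ[i] if localisations[j].frame == fmin]
        if len(succ[i]) > 1:
            raise ValueError("ambiguous scene: multiple legal successors")
    pred = [[] for _ in range(n)]
    for i in range(n):
        for j in succ[i]:
            pred[j].append(i)
    if any(len(p) > 1 for p in pred):
        raise ValueError("ambiguous scene: multiple legal predecessors")
    seen = [False] * n
    chains = []
    for i in order:
        if seen[i] or pred[i]:
            continue
        chain = [i]
        seen[i] = True
        while succ[chain[-1]]:
            nxt = succ[chain[-1]][0]
            if seen[nxt]:
                break
            chain.append(nxt)
            seen[nxt] = True
        chains.append(chain)
    out = []
    for chain in chains:
        if len(chain) >= params.min_length:
            out.append(Trajectory(len(out), [localisations[i] for i in chain]))
    return out


def qc_shared_points(trajectories: list[Trajectory],
                     max_shared: int = 3) -> list[Trajectory]:
    """Remove trajectories sharing more than ``max_shared`` localisations
    with any other trajectory; sharing exactly ``max_shared`` is allowed.
    Shared-point counts are recorded in each trajectory's QC flags."""
    keys = [set((l.frame, round(l.x, 6), round(l.y, 6), round(l.z, 6))
                for l in t.localisations) for t in trajectories]
    out = []
    for i, t in enumerate(trajectories):
        worst = 0
        for j, other in enumerate(trajectories):
            if i != j:
                worst = max(worst, len(keys[i] & keys[j]))
        t.qc_flags["max_shared_points"] = worst
        if worst <= max_shared:
            out.append(t)
    return out


def _instant_speeds(traj: Trajectory, dt: float) -> np.ndarray:
    p = traj.positions_mm
    f = traj.frames
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return steps / 1000.0 / (np.diff(f) * dt)


def qc_speed_consistency(traj: Trajectory, max_jump_ms: float = 3.0,
                         dt: float = 0.032) -> tuple[bool, list[int]]:
    """Fail iff any difference between subsequent instantaneous speeds
    exceeds ``max_jump_ms`` (the >3 m/s rule). Returns (pass, offending
    segment indices)."""
    if len(traj) < 3:
        raise ValueError("need at least 3 localisations for speed consistency")
    v = _instant_speeds(traj, dt)
    jumps = np.abs(np.diff(v))
    bad = list(np.flatnonzero(jumps > max_jump_ms))
    ok = len(bad) == 0
    traj.qc_flags["speed_consistency"] = ok
    return ok, bad


def smooth_trajectory(traj: Trajectory, params: LinkingParams | None = None,
                      max_jump_ms: float = 3.0,
                      max_fraction: float = 0.10) -> Trajectory | None:
    """Remove isolated erroneous localisations, or reject the trajectory.

    A localisation is erroneous iff both of its adjacent segments imply a
    speed jump above ``max_jump_ms`` or a step above ``max_step_mm`` and
    removing it restores consistency. If the erroneous points exceed
    ``max_fraction`` of the localisations the whole trajectory is rejected
    (returns None): removing more points than that risks biasing the data,
    so it is better to exclude the trajectory.
    """
    params = params or LinkingParams()
    locs = list(traj.localisations)
    removed = 0
    budget = int(np.floor(max_fraction * len(locs)))

    def speed(a: Localisation3D, b: Localisation3D) -> float:
        return (float(np.linalg.norm(b.p - a.p)) / 1000.0
                / ((b.frame - a.frame) * params.dt))

    def step(a: Localisation3D, b: Localisation3D) -> float:
        return float(np.linalg.norm(b.p - a.p))

    changed = True
    while changed:
        changed = False
        for i in range(1, len(locs) - 1):
            a, b, c = locs[i - 1], locs[i], locs[i + 1]
            v_bridge = speed(a, c)
            left_bad = (step(a, b) > params.max_step_mm
                        or abs(speed(a, b) - v_bridge) > max_jump_ms)
            right_bad = (step(b, c) > params.max_step_mm
                         or abs(speed(b, c) - v_bridge) > max_jump_ms)
            # removal must restore consistency: the bridging segment has to
            # be legal AND agree with the surrounding segments' speeds,
            # otherwise we would be deleting a neighbour of the outlier
            restores = (step(a, c) <= params.max_step_mm
                        and v_bridge <= params.vmax_ms)
            if restores and i >= 2:
                restores = abs(v_bridge - speed(locs[i - 2], a)) <= max_jump_ms
            if restores and i + 2 < len(locs):
                restores = abs(speed(c, locs[i + 2]) - v_bridge) <= max_jump_ms
            if not (left_bad and right_bad and restores):
                continue
            removed += 1
            if removed > budget:
                traj.qc_flags["smoothing"] = "rejected (>10% erroneous)"
                return None
            del locs[i]
            changed = True
            break
    if removed == 0:
        traj.qc_flags["smoothing"] = "unchanged"
        return traj
    return Trajectory(traj.trajectory_id, locs,
                      dict(traj.qc_flags, smoothing=f"removed {removed}"))
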