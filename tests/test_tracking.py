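"""Stereo pairing, linking rules, QC and the smoothing rule."""

import numpy as np
import pytest

from batrack.detection import Detection2D
from batrack.simulate import FlightRegime, simulate_trajectory
from batrack.tracking import (LinkingParams, Localisation3D, Trajectory,
                              brute_force_link, build_trajectories,
                              pair_stereo, qc_shared_points,
                              qc_speed_consistency, smooth_trajectory)

BIG_VOLUME = ((-50000.0, 50000.0), (-50000.0, 50000.0), (-50000.0, 50000.0))


def dets_from_paths(paths, rig, camera):
    cam = getattr(rig, camera)
    out = []
    for p in paths:
        vis = cam.visible(p.positions_mm, margin=1.0)
        for k in np.flatnonzero(vis):
            uv = cam.project(p.positions_mm[k])
            out.append(Detection2D(camera, int(p.frames[k]),
                                   float(uv[0]), float(uv[1]), 5, 100.0))
    return out


def line_locs(n, step_mm=100.0, frame0=0, frame_step=1):
    return [Localisation3D(frame0 + i * frame_step, i * step_mm, 10000.0, 0.0, 0.0)
            for i in range(n)]


def locs_with_speeds(speeds_ms, dt=0.032):
    """Consecutive-frame localisations whose instantaneous speeds are given."""
    xs = np.concatenate([[0.0], np.cumsum(np.asarray(speeds_ms) * dt * 1000.0)])
    return [Localisation3D(i, x, 10000.0, 0.0, 0.0) for i, x in enumerate(xs)]


class TestPairStereo:
    def test_single_bat_recovers_true_positions(self, converged_rig):
        p = simulate_trajectory(FlightRegime.foraging(), 30, seed=0,
                                start_mm=np.array([2000.0, 12000.0, 0.0]))
        dl = dets_from_paths([p], converged_rig, "left")
        dr = dets_from_paths([p], converged_rig, "right")
        locs = pair_stereo(dl, dr, converged_rig, max_residual_px=2.0)
        binocular = {d.frame for d in dl} & {d.frame for d in dr}
        assert len(locs) == len(binocular)
        for loc in locs:
            k = loc.frame
            assert np.linalg.norm(loc.p - p.positions_mm[k]) < 1e-3

    def test_two_bats_no_identity_swaps(self, converged_rig):
        # two bats 1 m apart laterally at ~15 m range over 100 frames, at
        # different heights: cross-camera ghost pairings then violate the
        # epipolar constraint and are rejected by the residual threshold
        regime = FlightRegime("straight", 4.5, 0.0, 1e12, 0.0)
        a = simulate_trajectory(regime, 100, volume=BIG_VOLUME, seed=1,
                                start_mm=np.array([1500.0, 14000.0, 0.0]),
                                heading_rad=np.pi / 2)
        b = simulate_trajectory(regime, 100, volume=BIG_VOLUME, seed=2,
                                start_mm=np.array([2500.0, 15000.0, 900.0]),
                                heading_rad=np.pi / 2)
        dl = dets_from_paths([a, b], converged_rig, "left")
        dr = dets_from_paths([a, b], converged_rig, "right")
        locs = pair_stereo(dl, dr, converged_rig, max_residual_px=2.0)
        by_frame = {}
        for loc in locs:
            by_frame.setdefault(loc.frame, []).append(loc)
        swaps = 0
        for f, ll in by_frame.items():
            for loc in ll:
                d_a = np.linalg.norm(loc.p - a.positions_mm[f])
                d_b = np.linalg.norm(loc.p - b.positions_mm[f])
                if min(d_a, d_b) > 1.0:
                    swaps += 1
        assert swaps == 0

    def test_monocular_detection_yields_no_localisation(self, rig):
        dl = [Detection2D("left", 0, 320.0, 240.0, 5, 10.0)]
        assert pair_stereo(dl, [], rig) == []


class TestLinkingRules:
    def test_seven_points_one_trajectory(self):
        trajs = build_trajectories(line_locs(7))
        assert len(trajs) == 1 and len(trajs[0]) == 7

    def test_five_points_below_minimum_length(self):
        assert build_trajectories(line_locs(5)) == []

    def test_step_above_1000_mm_never_linked(self):
        locs = line_locs(6) + [Localisation3D(6, 500.0 + 1200.0, 10000.0,
                                              0.0, 0.0)]
        trajs = build_trajectories(locs)
        assert len(trajs) == 1 and len(trajs[0]) == 6

    def test_exactly_1000_mm_is_linkable(self):
        # 1000 mm per single 0.032 s frame would be 31 m/s > vmax, so use a
        # 3-frame gap: 1000 mm / 0.096 s = 10.4 m/s, legal on every rule
        locs = [Localisation3D(i * 3, i * 1000.0, 10000.0, 0.0, 0.0)
                for i in range(7)]
        trajs = build_trajectories(locs)
        assert len(trajs) == 1 and len(trajs[0]) == 7

    def test_speed_above_vmax_never_linked(self):
        # 600 mm in one 0.032 s frame = 18.75 m/s > 15 m/s
        locs = [Localisation3D(i, i * 600.0, 10000.0, 0.0, 0.0)
                for i in range(12)]
        assert build_trajectories(locs) == []

    def test_frame_gap_16_splits_candidates(self):
        first = line_locs(6)
        second = line_locs(6, frame0=5 + 16)
        for loc in second:
            loc.x += 500.0
        trajs = build_trajectories(first + second)
        assert len(trajs) == 2
        assert sorted(len(t) for t in trajs) == [6, 6]

    def test_frame_gap_15_bridges(self):
        first = line_locs(6)
        second = [Localisation3D(5 + 15 + i, 500.0 + 400.0 + i * 100.0,
                                 10000.0, 0.0, 0.0) for i in range(6)]
        trajs = build_trajectories(first + second)
        assert len(trajs) == 1 and len(trajs[0]) == 12

    def test_outputs_satisfy_invariants(self, rng):
        params = LinkingParams()
        locs = []
        for f in range(40):
            for _ in range(rng.integers(0, 4)):
                locs.append(Localisation3D(
                    f, rng.uniform(-5000, 5000), rng.uniform(8000, 20000),
                    rng.uniform(-500, 2000), 0.0))
        for t in build_trajectories(locs, params):
            t.validate(params)  # raises on any violation


class TestOracleEquivalence:
    def make_scene(self, n_bats, n_frames=25, seed=0):
        paths = []
        for k in range(n_bats):
            paths.append(simulate_trajectory(
                FlightRegime.foraging(), n_frames, volume=BIG_VOLUME,
                seed=seed * 10 + k, path_id=k,
                start_mm=np.array([k * 8000.0, 10000.0, 0.0])))
        locs = []
        for p in paths:
            for i in range(p.n_frames):
                locs.append(Localisation3D(int(p.frames[i]),
                                           *p.positions_mm[i], 0.0))
        return paths, locs

    @pytest.mark.parametrize("n_bats", [1, 2, 3])
    def test_partition_matches_ground_truth_and_brute_force(self, n_bats):
        paths, locs = self.make_scene(n_bats, seed=n_bats)
        greedy = build_trajectories(locs)
        brute = brute_force_link(locs)
        assert len(greedy) == len(brute) == n_bats

        def as_sets(trajs):
            return {frozenset((l.frame, l.x, l.y, l.z) for l in t.localisations)
                    for t in trajs}

        truth = {frozenset((int(p.frames[i]), *p.positions_mm[i])
                           for i in range(p.n_frames)) for p in paths}
        assert as_sets(greedy) == as_sets(brute) == truth

    def test_brute_force_rejects_ambiguous_scene(self):
        # two bats closer than max_step: multiple legal successors
        locs = []
        for f in range(8):
            locs.append(Localisation3D(f, f * 100.0, 10000.0, 0.0, 0.0))
            locs.append(Localisation3D(f, f * 100.0 + 200.0, 10000.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="ambiguous"):
            brute_force_link(locs)


class TestQC:
    def test_disjoint_trajectories_all_retained(self):
        t1 = Trajectory(0, line_locs(8))
        t2 = Trajectory(1, [Localisation3D(i, i * 100.0, 15000.0, 0.0, 0.0)
                            for i in range(8)])
        assert len(qc_shared_points([t1, t2])) == 2

    @pytest.mark.parametrize("n_shared,kept", [(4, 0), (3, 2)])
    def test_shared_point_boundary(self, n_shared, kept):
        shared = line_locs(n_shared)
        t1 = Trajectory(0, shared + [Localisation3D(n_shared + i, 5000.0 + i * 100.0,
                                                    10000.0, 0.0, 0.0)
                                     for i in range(6)])
        t2 = Trajectory(1, shared + [Localisation3D(n_shared + i, -5000.0 - i * 100.0,
                                                    10000.0, 0.0, 0.0)
                                     for i in range(6)])
        assert len(qc_shared_points([t1, t2])) == kept

    def test_constant_speed_passes(self):
        ok, bad = qc_speed_consistency(Trajectory(0, line_locs(10)))
        assert ok and bad == []

    def test_jump_above_3_fails(self):
        t = Trajectory(0, locs_with_speeds([4.0, 4.0, 7.5, 7.5]))
        ok, bad = qc_speed_consistency(t)
        assert not ok and len(bad) == 1

    def test_jump_of_2_9_passes(self):
        t = Trajectory(0, locs_with_speeds([4.0, 4.0, 6.9, 6.9]))
        ok, _ = qc_speed_consistency(t)
        assert ok


class TestSmoothing:
    def clean(self, n=20):
        return Trajectory(0, line_locs(n, step_mm=140.0))

    def test_clean_trajectory_unchanged(self):
        t = self.clean()
        out = smooth_trajectory(t)
        assert out is t
        assert t.qc_flags["smoothing"] == "unchanged"

    def test_single_outlier_removed(self):
        t = self.clean(20)
        t.localisations[10].z += 800.0  # one displaced localisation
        truth = [(l.frame, l.x) for i, l in enumerate(t.localisations)
                 if i != 10]
        out = smooth_trajectory(t)
        assert out is not None
        assert len(out) == 19
        assert [(l.frame, l.x) for l in out.localisations] == truth

    def test_three_outliers_in_twenty_rejected_whole(self):
        t = self.clean(20)
        for i in (5, 10, 15):
            t.localisations[i].z += 800.0
        assert smooth_trajectory(t) is None
        assert "rejected" in t.qc_flags["smoothing"]

    def test_two_outliers_in_twenty_still_smoothed(self):
        t = self.clean(20)
        for i in (6, 13):
            t.localisations[i].z += 800.0
        out = smooth_trajectory(t)
        assert out is not None and len(out) == 18
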