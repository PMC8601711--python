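"""Synthetic generators: determinism, kinematic separation, conservation."""

import logging

import numpy as np
import pytest

from batrack.detection import threshold_detect
from batrack.simulate import (CallParamSimParams, CountSimParams,
                              DeterrentResponse, FlightRegime, RenderNoise,
                              apply_deterrent_response, render_frames,
                              simulate_call_params, simulate_counts,
                              simulate_trajectory)
from batrack.soundfield import SoundFieldParams

BIG_VOLUME = ((-50000.0, 50000.0), (-50000.0, 50000.0), (-50000.0, 50000.0))


def straight_regime(speed=4.86):
    return FlightRegime("straight", mean_speed=speed, speed_sd=0.0,
                        turn_concentration=1e12, vertical_sd=0.0)


class TestTrajectories:
    def test_determinism(self):
        a = simulate_trajectory(FlightRegime.foraging(), 40, seed=9)
        b = simulate_trajectory(FlightRegime.foraging(), 40, seed=9)
        assert np.array_equal(a.positions_mm, b.positions_mm)

    def test_straight_line_has_tortuosity_point_one(self):
        p = simulate_trajectory(straight_regime(), 30, seed=1)
        assert p.tortuosity_value() == pytest.approx(0.1, abs=1e-12)
        assert p.mean_speed_ms() == pytest.approx(4.86, abs=1e-9)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            simulate_trajectory(FlightRegime.foraging(), 5, seed=0)

    def test_truncation_at_boundary_is_logged(self, caplog):
        tiny = ((-200.0, 200.0), (-200.0, 200.0), (-200.0, 200.0))
        with caplog.at_level(logging.WARNING, logger="batrack.simulate"):
            p = simulate_trajectory(FlightRegime.commuting(), 50,
                                    volume=tiny, seed=0,
                                    start_mm=np.zeros(3))
        assert p.n_frames < 50
        assert any("truncated" in r.message for r in caplog.records)

    def test_foraging_more_tortuous_than_commuting(self):
        tort = {}
        speeds = {}
        for regime in (FlightRegime.foraging(), FlightRegime.commuting()):
            vals = []
            sp = []
            for seed in range(1000):
                p = simulate_trajectory(regime, 40, volume=BIG_VOLUME,
                                        seed=seed, start_mm=np.zeros(3))
                vals.append(p.tortuosity_value())
                sp.append(p.mean_speed_ms())
            tort[regime.name] = np.mean(vals)
            speeds[regime.name] = np.asarray(sp)
        assert tort["foraging"] > tort["commuting"]
        # stochastic dominance of commuting speeds over foraging speeds
        qs = np.linspace(0.05, 0.95, 19)
        assert np.all(np.quantile(speeds["commuting"], qs)
                      > np.quantile(speeds["foraging"], qs))


class TestDeterrentResponse:
    field = SoundFieldParams(source_position_mm=np.array([0.0, -15000.0, 0.0]))

    def make_path(self, seed=0):
        return simulate_trajectory(FlightRegime.foraging(), 60,
                                   volume=BIG_VOLUME, seed=seed,
                                   start_mm=np.array([0.0, 8000.0, 0.0]))

    def test_zero_switch_prob_is_identity(self):
        p = self.make_path()
        q = apply_deterrent_response(p, self.field,
                                     DeterrentResponse(switch_prob=0.0), seed=1)
        assert q is p
        assert not q.responded_to_deterrent

    def test_threshold_above_field_maximum_is_identity(self):
        p = self.make_path()
        q = apply_deterrent_response(
            p, self.field, DeterrentResponse(spl_threshold_db=120.0,
                                             switch_prob=1.0), seed=1)
        assert q is p

    def test_responders_end_further_from_source(self):
        resp = DeterrentResponse(spl_threshold_db=10.0, switch_prob=1.0,
                                 away_bias=0.9)
        src = self.field.source_position_mm
        d_resp, d_ctrl = [], []
        for seed in range(500):
            p = self.make_path(seed)
            q = apply_deterrent_response(p, self.field, resp, seed=seed + 1,
                                         volume=BIG_VOLUME)
            d_ctrl.append(np.linalg.norm(p.positions_mm[-1] - src))
            d_resp.append(np.linalg.norm(q.positions_mm[-1] - src))
        assert np.mean(d_resp) > np.mean(d_ctrl)

    def test_regime_switch_is_recorded(self):
        p = self.make_path(3)
        q = apply_deterrent_response(
            p, self.field, DeterrentResponse(spl_threshold_db=10.0,
                                             switch_prob=1.0), seed=4,
            volume=BIG_VOLUME)
        assert q.responded_to_deterrent
        assert q.regime[-1] == "commuting"
        assert q.regime[0] == "foraging"


class TestRendering:
    def test_same_seed_bit_identical(self, rig):
        p = simulate_trajectory(FlightRegime.foraging(), 12, seed=0,
                                start_mm=np.array([2000.0, 10000.0, 0.0]))
        a = render_frames([p], rig, RenderNoise(), seed=5)
        b = render_frames([p], rig, RenderNoise(), seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_blob_centroids_match_projection(self, rig):
        p = simulate_trajectory(straight_regime(), 10, seed=2,
                                start_mm=np.array([2000.0, 10000.0, 0.0]),
                                heading_rad=np.pi / 2)
        noise = RenderNoise(background_sd=0.0, blob_amplitude=2000.0)
        left, _ = render_frames([p], rig, noise, seed=0)
        for k in range(p.n_frames):
            uv = rig.left.project(p.positions_mm[k])
            dets = threshold_detect(left[k].astype(float), 20.0, frame=k)
            assert len(dets) == 1
            assert abs(dets[0].u - uv[0]) < 0.05
            assert abs(dets[0].v - uv[1]) < 0.05

    def test_blob_count_equals_visible_bats(self, rig):
        # parallel straight flights stay well separated in pixel space, so
        # no blobs merge and the count is conserved exactly
        paths = [simulate_trajectory(straight_regime(), 15, seed=s,
                                     start_mm=np.array([1500.0 + 800 * s,
                                                        11000.0, 0.0]),
                                     heading_rad=np.pi / 2)
                 for s in range(3)]
        noise = RenderNoise(background_sd=0.0, clutter_rate=0.0,
                            blob_amplitude=2000.0)
        left, _ = render_frames(paths, rig, noise, seed=0)
        for k in range(15):
            pts = np.array([p.positions_mm[k] for p in paths])
            n_vis = int(rig.left.visible(pts, margin=1.0).sum())
            dets = threshold_detect(left[k].astype(float), 20.0)
            assert len(dets) == n_vis

    def test_out_of_view_path_absent_not_error(self, rig):
        p = simulate_trajectory(FlightRegime.foraging(), 10, seed=1,
                                volume=BIG_VOLUME,
                                start_mm=np.array([-30000.0, 9000.0, 0.0]))
        left, right = render_frames([p], rig,
                                    RenderNoise(background_sd=0.0), seed=0)
        assert left.sum() == 0 and right.sum() == 0


class TestCounts:
    def test_determinism(self):
        a = simulate_counts(CountSimParams(seed=11))
        b = simulate_counts(CountSimParams(seed=11))
        assert a.equals(b)

    def test_design_labels(self):
        df = simulate_counts(CountSimParams(seed=0))
        assert df["site"].nunique() == 3
        assert df["night"].nunique() == 9
        per_night = df.groupby(["site", "night"])["block"].nunique()
        assert (per_night == 12).all()
        # blocks alternate control/treatment starting with control
        sched = df[["block", "treatment"]].drop_duplicates().sort_values("block")
        expected = ["control" if b % 2 == 1 else "deterrent"
                    for b in sched["block"]]
        assert list(sched["treatment"]) == expected

    def test_poisson_limit_mean_matches_baseline(self):
        # rate_ratio 1, no random effects, dispersion -> inf: law of large
        # numbers over ~10^4 blocks
        params = CountSimParams(
            rates={("P. pygmaeus", "pass"): (40.0, 1.0)},
            dispersion=np.inf, sd_site=0.0, sd_night=0.0, sd_block=0.0,
            n_sites=10, n_nights_per_site=10, n_blocks_per_night=100, seed=3)
        df = simulate_counts(params)
        assert len(df) == 10000
        assert np.mean(df["count"]) == pytest.approx(40.0, rel=0.02)

    def test_rate_ratio_shows_in_arm_means(self):
        params = CountSimParams(
            rates={("P. pygmaeus", "pass"): (40.0, 0.70)},
            dispersion=np.inf, sd_site=0.0, sd_night=0.0, sd_block=0.0,
            n_sites=10, n_nights_per_site=10, n_blocks_per_night=100, seed=4)
        df = simulate_counts(params)
        means = df.groupby("treatment")["count"].mean()
        assert means["deterrent"] / means["control"] == pytest.approx(0.70,
                                                                      abs=0.02)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            CountSimParams(rates={("x", "pass"): (-1.0, 0.7)})
        with pytest.raises(ValueError):
            CountSimParams(rates={("x", "pass"): (1.0, 0.0)})


class TestCallParams:
    def test_bandwidth_identity_exact(self):
        df = simulate_call_params(CallParamSimParams(seed=0), 60)
        assert np.allclose(df["bandwidth"],
                           df["start_frequency"] - df["end_frequency"])

    def test_zero_shift_gives_equal_arm_means(self):
        p = CallParamSimParams(shift_bandwidth=0.0, shift_start=0.0,
                               sd_site=0.0, sd_night=0.0, sd_pair=0.0,
                               sd_block=0.0, sd_sequence=0.0, seed=1)
        df = simulate_call_params(p, 2000)
        means = df.groupby("treatment")["bandwidth"].mean()
        assert abs(means["deterrent"] - means["control"]) < 0.3

    def test_default_shift_appears_in_arm_means(self):
        p = CallParamSimParams(sd_site=0.0, sd_night=0.0, sd_pair=0.0,
                               sd_block=0.0, seed=2)
        df = simulate_call_params(p, 3000)
        means = df.groupby("treatment")["bandwidth"].mean()
        assert means["deterrent"] - means["control"] == pytest.approx(-5.79,
                                                                      abs=0.4)

    def test_three_calls_per_pass_and_determinism(self):
        p = CallParamSimParams(seed=5)
        df = simulate_call_params(p, 30)
        assert (df.groupby("sequence").size() == 3).all()
        assert df.equals(simulate_call_params(CallParamSimParams(seed=5), 30))
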