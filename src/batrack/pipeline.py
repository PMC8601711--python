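"""End-to-end orchestration: simulate -> calibrate -> detect -> track ->
metrics -> analyze, with every intermediate written to the run directory.

A run is deterministic given its config (all stage seeds derive from the
config seed), resumable (stages whose outputs already exist are skipped),
and fails loudly with the stage named; intermediates from completed stages
are preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .calibration import calibrate_stereo
from .detection import detect_stack, select_threshold
from .geometry import CalibrationTarget, StereoRig
from .metrics import metrics_frame
from .simulate import (CallParamSimParams, CountSimParams, DeterrentResponse,
                       FlightRegime, RenderNoise, apply_deterrent_response,
                       render_frames, simulate_calibration_sequence,
                       simulate_counts, simulate_call_params,
                       simulate_trajectory)
from .soundfield import spl_at_distance
from .stats import (SparseDataError, composition_table, fit_call_param_model,
                    fit_count_model, fit_trajectory_models, percent_reduction)
from .tracking import (build_trajectories, pair_stereo, qc_shared_points,
                       qc_speed_consistency, smooth_trajectory)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(log, run_dir: Path, name: str, outputs: list[str], fn) -> None:
    paths = [run_dir / o for o in outputs]
    if all(p.exists() for p in paths):
        log.info("stage %s: outputs exist, skipping", name)
        return
    log.info("stage %s: running", name)
    try:
        fn()
    except Exception as exc:  # noqa: BLE001 - reraised with stage context
        log.error("stage %s failed: %s", name, exc)
        raise PipelineError(name, exc) from exc
    log.info("stage %s: done", name)


def _ground_truth_frame(paths) -> pd.DataFrame:
    rows = []
    for p in paths:
        for k in range(p.n_frames):
            rows.append((p.path_id, int(p.frames[k]), *p.positions_mm[k],
                         p.regime[k]))
    return pd.DataFrame(rows, columns=bio.SCHEMAS["ground_truth"])


def _simulate_block_paths(cfg, rng, treatment: str, n_paths: int,
                          n_frames: int, field_, id_offset: int = 0,
                          rig: StereoRig | None = None):
    """Foraging paths; in deterrent blocks each may switch to commuting.

    With a rig given, start positions are rejection-sampled into the joint
    field of view and headings run along the corridor (+/- y), as bats
    following a linear landscape element do — otherwise most flights would
    miss the stereo view volume entirely.
    """
    out = []
    response = DeterrentResponse(cfg.spl_threshold_db, cfg.switch_prob,
                                 cfg.away_bias)
    for k in range(n_paths):
        seed = int(rng.integers(2 ** 31 - 1))
        heading = None
        for _ in range(200):
            start = np.array([rng.uniform(-1000, 5000),
                              rng.uniform(8000, 20000),
                              rng.uniform(-500, 2000)])
            if rig is None or rig.joint_visible(start[None, :], margin=5.0)[0]:
                break
        if rig is not None:
            heading = float(rng.choice([np.pi / 2, -np.pi / 2])
                            + rng.normal(0, 0.2))
        p = simulate_trajectory(FlightRegime.foraging(), n_frames,
                                seed=seed, path_id=id_offset + k,
                                start_mm=start, heading_rad=heading,
                                dt=cfg.dt)
        if treatment == "deterrent":
            p = apply_deterrent_response(p, field_, response,
                                         seed=seed + 1, dt=cfg.dt)
        out.append(p)
    return out


def run_pipeline(cfg: bio.ExperimentConfig) -> Path:
    """Run every stage; returns the run directory."""
    if cfg.rig_file and not Path(cfg.rig_file).exists():
        raise FileNotFoundError(
            f"config error: rig file {cfg.rig_file!r} does not exist")
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log = bio.setup_run_logging(run_dir)
    log.info("config: %s", cfg.to_yaml().replace("\n", "; "))
    (run_dir / "config.yaml").write_text(cfg.to_yaml())
    master = np.random.default_rng(cfg.seed)
    seeds = {name: int(s) for name, s in zip(
        ["calib", "scene", "counts", "calls", "survey"],
        master.integers(2 ** 31 - 1, size=5))}
    field_ = cfg.sound_field()
    true_rig = StereoRig.default(cfg.baseline_mm, cfg.fov_deg)

    # -- sound field table ---------------------------------------------------
    def do_soundfield():
        d = np.arange(1.0, 41.0 + 1e-9, 1.0)
        tab = pd.DataFrame({"distance_m": d, "spl_db": spl_at_distance(field_, d)})
        tab.to_csv(run_dir / "soundfield.csv", index=False)

    _stage(log, run_dir, "soundfield", ["soundfield.csv"], do_soundfield)

    # -- calibration ---------------------------------------------------------
    def do_calibrate():
        if cfg.rig_file:
            rig = bio.read_rig(cfg.rig_file)
        else:
            seq = simulate_calibration_sequence(
                true_rig, CalibrationTarget(), cfg.n_calibration_poses,
                seed=seeds["calib"],
                pixel_noise_px=cfg.calibration_pixel_noise_px)
            rig = calibrate_stereo([lp for _, lp in seq], CalibrationTarget())
            log.info("calibration RMS reprojection: %.4f px",
                     rig.rms_reprojection_px)
        bio.write_rig(run_dir / "rig.yaml", rig)

    _stage(log, run_dir, "calibrate", ["rig.yaml"], do_calibrate)
    rig = bio.read_rig(run_dir / "rig.yaml")

    # -- scene: one control and one deterrent block get rendered video ------
    def do_scene():
        rng = np.random.default_rng(seeds["scene"])
        noise = RenderNoise(cfg.background_sd, cfg.blob_sigma_px,
                            cfg.blob_amplitude, cfg.clutter_rate)
        gt_frames = []
        for bi, treatment in enumerate(["control", "deterrent"]):
            paths = _simulate_block_paths(cfg, rng, treatment,
                                          cfg.n_paths_per_block, cfg.n_frames,
                                          field_, id_offset=100 * bi,
                                          rig=true_rig)
            left, right = render_frames(paths, true_rig, noise,
                                        seed=seeds["scene"] + bi,
                                        n_frames=cfg.n_frames)
            bio.write_stack(run_dir / f"{treatment}_left.tif", left)
            bio.write_stack(run_dir / f"{treatment}_right.tif", right)
            gt = _ground_truth_frame(paths)
            gt["treatment"] = treatment
            gt_frames.append(gt)
        pd.concat(gt_frames).to_csv(run_dir / "ground_truth.csv", index=False)

    _stage(log, run_dir, "scene",
           ["control_left.tif", "control_right.tif", "deterrent_left.tif",
            "deterrent_right.tif", "ground_truth.csv"], do_scene)

    # -- detect + track ------------------------------------------------------
    def do_track():
        params = cfg.linking_params()
        all_traj = []
        all_det = []
        for bi, treatment in enumerate(["control", "deterrent"]):
            left = bio.read_stack(run_dir / f"{treatment}_left.tif")
            right = bio.read_stack(run_dir / f"{treatment}_right.tif")
            thr, diag = select_threshold(left, right, rig, cfg.threshold_grid,
                                         params,
                                         max_residual_px=cfg.max_residual_px)
            log.info("block %s: selected pixel threshold %.1f", treatment, thr)
            diag.to_csv(run_dir / f"threshold_diagnostics_{treatment}.csv",
                        index=False)
            det_l = detect_stack(left, thr, camera="left")
            det_r = detect_stack(right, thr, camera="right")
            locs = pair_stereo(det_l, det_r, rig, cfg.max_residual_px)
            trajs = build_trajectories(locs, params)
            trajs = qc_shared_points(trajs)
            trajs = [t for t in trajs if qc_speed_consistency(t)[0]]
            trajs = [s for t in trajs
                     if (s := smooth_trajectory(t, params)) is not None]
            tf = bio.trajectories_to_frame(trajs)
            tf["treatment"] = treatment
            tf["trajectory_id"] = tf["trajectory_id"] + 1000 * bi
            all_traj.append(tf)
            dd = pd.DataFrame([(d.camera, d.frame, d.u, d.v, d.area_px, d.peak)
                               for d in det_l + det_r],
                              columns=bio.SCHEMAS["detections"])
            dd["treatment"] = treatment
            all_det.append(dd)
        pd.concat(all_det).to_csv(run_dir / "detections.csv", index=False)
        pd.concat(all_traj).to_csv(run_dir / "trajectories.csv", index=False)

    _stage(log, run_dir, "track", ["detections.csv", "trajectories.csv"],
           do_track)

    # -- metrics -------------------------------------------------------------
    def do_metrics():
        tf = pd.read_csv(run_dir / "trajectories.csv")
        rows = []
        for (tid, treatment), grp in tf.groupby(["trajectory_id", "treatment"]):
            trajs = bio.trajectories_from_frame(
                grp.drop(columns=["treatment"]))
            m = metrics_frame(trajs, dt=cfg.dt,
                              deterrent_offset_m=cfg.deterrent_offset_m)
            m["treatment"] = treatment
            rows.append(m)
        out = (pd.concat(rows) if rows
               else pd.DataFrame(columns=bio.SCHEMAS["metrics"] + ["treatment"]))
        out.to_csv(run_dir / "metrics.csv", index=False)

    _stage(log, run_dir, "metrics", ["metrics.csv"], do_metrics)

    # -- flight survey for trajectory statistics -----------------------------
    def do_survey():
        rng = np.random.default_rng(seeds["survey"])
        rows = []
        night_no = 0
        for s in range(3):
            for n in range(3):
                night_no += 1
                for b in range(1, 13):
                    treatment = "control" if b % 2 == 1 else "deterrent"
                    paths = _simulate_block_paths(
                        cfg, rng, treatment, cfg.survey_paths_per_block,
                        cfg.survey_frames, field_)
                    m = metrics_frame(
                        [_path_as_traj(p) for p in paths], dt=cfg.dt,
                        deterrent_offset_m=cfg.deterrent_offset_m)
                    m["site"] = f"site{s + 1}"
                    m["night"] = f"night{night_no}"
                    m["block"] = b
                    m["treatment"] = treatment
                    rows.append(m)
        pd.concat(rows).to_csv(run_dir / "survey_metrics.csv", index=False)

    _stage(log, run_dir, "survey", ["survey_metrics.csv"], do_survey)

    # -- counts + calls ------------------------------------------------------
    def do_counts():
        counts = simulate_counts(CountSimParams(seed=seeds["counts"]))
        bio.write_table(run_dir / "counts.csv", counts, kind="counts")
        calls = simulate_call_params(CallParamSimParams(seed=seeds["calls"]),
                                     cfg.n_call_passes_per_arm)
        bio.write_table(run_dir / "calls.csv", calls[bio.SCHEMAS["calls"]],
                        kind="calls")

    _stage(log, run_dir, "simulate_counts", ["counts.csv", "calls.csv"],
           do_counts)

    # -- analyze -------------------------------------------------------------
    def do_analyze():
        counts = bio.read_table(run_dir / "counts.csv", kind="counts")
        comp, summary = composition_table(counts)
        comp.to_csv(run_dir / "composition.csv", index=False)
        rows = []
        for species in counts["species_group"].unique():
            try:
                res = fit_count_model(counts, species)
            except SparseDataError as exc:
                log.info("count model refused: %s", exc)
                continue
            red = percent_reduction(counts, [species], ["pass"], model=res)
            rows.append({
                "species_group": species, "family": res.family,
                "treatment_coef": res.coef("treatment[deterrent]"),
                "rate_ratio": float(np.exp(res.coef("treatment[deterrent]"))),
                "raw_reduction_pct": red["raw_pct"],
                "model_reduction_pct": red["model_pct"],
                "lrt_chi2": res.lrt_treatment["chi2"],
                "lrt_p": res.lrt_treatment["p"],
                "aicc": res.aicc,
            })
        pd.DataFrame(rows).to_csv(run_dir / "count_models.csv", index=False)
        overall = percent_reduction(counts)
        pd.DataFrame([overall]).to_csv(run_dir / "overall_reduction.csv",
                                       index=False)

        surv = pd.read_csv(run_dir / "survey_metrics.csv")
        tm = fit_trajectory_models(surv)
        trows = []
        for name, res in tm.items():
            t = res.fixed[res.fixed["term"].str.contains("treatment")]
            trows.append({
                "response": name, "family": res.family,
                "treatment_estimate": (float(t["estimate"].iloc[0])
                                       if len(t) else np.nan),
                "lrt_chi2": res.lrt_treatment["chi2"],
                "lrt_p": res.lrt_treatment["p"],
                "aicc": res.aicc,
            })
        pd.DataFrame(trows).to_csv(run_dir / "trajectory_models.csv", index=False)

        calls = bio.read_table(run_dir / "calls.csv", kind="calls")
        crows = []
        for response in ("bandwidth", "start_frequency"):
            res = fit_call_param_model(calls, response)
            crows.append({
                "response": response,
                "treatment_shift_khz": res.coef("treatment[deterrent]"),
                "lrt_p": res.lrt_treatment["p"],
                "lrt_p_adjusted": res.lrt_treatment["p_adjusted"],
            })
        pd.DataFrame(crows).to_csv(run_dir / "call_models.csv", index=False)

    _stage(log, run_dir, "analyze",
           ["composition.csv", "count_models.csv", "overall_reduction.csv",
            "trajectory_models.csv", "call_models.csv"], do_analyze)

    bio.write_manifest(run_dir, {"seed": cfg.seed})
    log.info("run complete: %s", run_dir)
    return run_dir


def _path_as_traj(p):
    """View a ground-truth path as a Trajectory for metric computation."""
    from .tracking import Localisation3D, Trajectory
    locs = [Localisation3D(int(f), *xyz, 0.0)
            for f, xyz in zip(p.frames, p.positions_mm)]
    return Trajectory(p.path_id, locs)
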