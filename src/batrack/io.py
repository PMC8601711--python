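"""File formats and run configuration.

Frame stacks travel as multi-page 16-bit grayscale TIFF; all tabular
interchange is headered CSV (0-based frame indices, millimetre world units,
metres only in metrics outputs); rigs and configs are YAML; logs are plain
text with ISO-8601 timestamps. Readers validate schemas and name the
missing column in errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import Camera, CameraExtrinsics, CameraIntrinsics, StereoRig
from .tracking import Localisation3D, Trajectory

__all__ = [
    "SchemaError",
    "read_stack", "write_stack",
    "rig_to_yaml", "rig_from_yaml", "write_rig", "read_rig",
    "write_table", "read_table",
    "trajectories_to_frame", "trajectories_from_frame",
    "ExperimentConfig", "load_config",
    "write_manifest", "setup_run_logging",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table is missing required columns."""


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

def write_stack(path, stack: np.ndarray) -> None:
    """Write a (frames, h, w) uint16 stack as a multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.dtype != np.uint16:
        raise ValueError("frame stacks are 16-bit grayscale (uint16)")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


# ---------------------------------------------------------------------------
# Rig YAML
# ---------------------------------------------------------------------------

def _intr_dict(i: CameraIntrinsics) -> dict:
    return dict(fx=float(i.fx), fy=float(i.fy), cx=float(i.cx), cy=float(i.cy),
                k1=float(i.k1), k2=float(i.k2), width=int(i.width),
                height=int(i.height))


def rig_to_yaml(rig: StereoRig) -> str:
    d = {}
    for name, cam in (("left", rig.left), ("right", rig.right)):
        d[name] = dict(
            intrinsics=_intr_dict(cam.intrinsics),
            rotation=[[float(v) for v in row] for row in cam.extrinsics.rotation],
            translation_mm=[float(v) for v in cam.extrinsics.translation],
        )
    d["rms_reprojection_px"] = (None if rig.rms_reprojection_px is None
                                else float(rig.rms_reprojection_px))
    return yaml.safe_dump(d, sort_keys=False)


def rig_from_yaml(text: str) -> StereoRig:
    d = yaml.safe_load(text)
    cams = {}
    for name in ("left", "right"):
        if name not in d:
            raise SchemaError(f"rig YAML is missing the {name!r} camera")
        c = d[name]
        cams[name] = Camera(
            CameraIntrinsics(**c["intrinsics"]),
            CameraExtrinsics(np.asarray(c["rotation"], dtype=float),
                             np.asarray(c["translation_mm"], dtype=float)))
    return StereoRig(cams["left"], cams["right"],
                     rms_reprojection_px=d.get("rms_reprojection_px"))


def write_rig(path, rig: StereoRig) -> None:
    Path(path).write_text(rig_to_yaml(rig))


def read_rig(path) -> StereoRig:
    return rig_from_yaml(Path(path).read_text())


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

SCHEMAS = {
    "detections": ["camera", "frame", "u", "v", "area_px", "peak"],
    "localisations": ["frame", "x_mm", "y_mm", "z_mm", "residual_px"],
    "trajectories": ["trajectory_id", "frame", "x_mm", "y_mm", "z_mm",
                     "residual_px"],
    "ground_truth": ["path_id", "frame", "x_mm", "y_mm", "z_mm", "regime"],
    "metrics": ["trajectory_id", "mean_speed_ms", "total_length_m",
                "net_displacement_m", "tortuosity", "mean_y_m",
                "distance_from_deterrent_m", "mean_height_m",
                "n_localisations", "n_segments"],
    "counts": ["site", "night", "block", "treatment", "species_group",
               "event_type", "count"],
    "calls": ["site", "night", "block_pair", "time_block", "sequence",
              "treatment", "n_bats", "start_frequency", "end_frequency",
              "bandwidth", "fmaxe", "duration", "pulse_interval"],
}


def write_table(path, df: pd.DataFrame, kind: str | None = None) -> None:
    if kind is not None:
        _check_schema(df, kind)
    df.to_csv(path, index=False)


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if kind is not None:
        _check_schema(df, kind)
    return df


def _check_schema(df: pd.DataFrame, kind: str) -> None:
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing column(s): {missing}")


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        for l in t.localisations:
            rows.append((t.trajectory_id, l.frame, l.x, l.y, l.z, l.residual_px))
    return pd.DataFrame(rows, columns=SCHEMAS["trajectories"])


def trajectories_from_frame(df: pd.DataFrame) -> list[Trajectory]:
    _check_schema(df, "trajectories")
    out = []
    for tid, grp in df.groupby("trajectory_id"):
        grp = grp.sort_values("frame")
        locs = [Localisation3D(int(r.frame), r.x_mm, r.y_mm, r.z_mm,
                               r.residual_px)
                for r in grp.itertuples()]
        out.append(Trajectory(int(tid), locs))
    return out


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything a full synthetic run needs, in one YAML-serialisable bag.

    The block schedule is fixed by design: twelve 5-min blocks per night,
    alternating treatment and starting with a control block.
    """

    seed: int = 0
    out_dir: str = "runs/demo"
    # rig: either geometry parameters or a calibration file
    rig_file: str | None = None
    baseline_mm: float = 4000.0
    fov_deg: float = 33.0
    # calibration stage
    n_calibration_poses: int = 24
    calibration_pixel_noise_px: float = 0.2
    # scene stage (one control and one deterrent block get rendered video)
    n_paths_per_block: int = 4
    n_frames: int = 64
    background_sd: float = 1.5
    blob_amplitude: float = 1200.0
    blob_sigma_px: float = 2.0
    clutter_rate: float = 0.0
    # detection/tracking
    threshold_grid: tuple = (10.0, 20.0, 40.0)
    max_residual_px: float = 2.0
    vmax_ms: float = 15.0
    max_frame_gap: int = 15
    max_step_mm: float = 1000.0
    min_length: int = 6
    dt: float = 0.032
    deterrent_offset_m: float = 15.0
    # flight survey for the trajectory statistics (ground-truth paths)
    survey_paths_per_block: int = 4
    survey_frames: int = 48
    # call-parameter stream
    n_call_passes_per_arm: int = 150
    # deterrent sound field / response
    source_level_db: float = 98.0
    frequency_khz: float = 50.0
    temperature_c: float = 14.0
    relative_humidity: float = 90.0
    pressure_kpa: float = 101.325
    spl_threshold_db: float = 18.0
    switch_prob: float = 0.5
    away_bias: float = 0.5

    def linking_params(self):
        from .tracking import LinkingParams
        return LinkingParams(self.vmax_ms, self.max_frame_gap,
                             self.max_step_mm, self.min_length, self.dt)

    def sound_field(self):
        from .soundfield import SoundFieldParams
        return SoundFieldParams(self.source_level_db, self.frequency_khz,
                                self.temperature_c, self.relative_humidity,
                                self.pressure_kpa)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["threshold_grid"] = list(d["threshold_grid"])
        return yaml.safe_dump(d, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(d) - names
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    if "threshold_grid" in d:
        d["threshold_grid"] = tuple(d["threshold_grid"])
    return ExperimentConfig(**d)


# ---------------------------------------------------------------------------
# Manifest and logging
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir, extra: dict | None = None) -> Path:
    """Record a sha256 per output file so a rerun can be checked byte-for-byte."""
    run_dir = Path(run_dir)
    files = sorted(p for p in run_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {"files": {str(p.relative_to(run_dir)): _sha256(p) for p in files}}
    if extra:
        manifest.update(extra)
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def setup_run_logging(run_dir) -> logging.Logger:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("batrack.run")
    logger.setLevel(logging.INFO)
    for h in list(logger.handlers):
        logger.removeHandler(h)
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S"))
    logger.addHandler(fh)
    return logger
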