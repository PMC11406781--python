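"""Readers/writers for the pipeline's file formats, run configuration and
cohort reporting.

Formats (all plain text):

* trajectory CSV — ``frame,time_s,side,landmark,x_m,y_m,missing_flag``, one
  row per landmark-frame, metric y-up coordinates, 0-based frames;
* events JSON — ``{"side": {"ic_frames": [...], "to_frames": [...]}}``;
* kinematics CSV — per-cycle normalized curves,
  ``side,cycle,angle,pct,value_deg`` plus a toe-off row per cycle;
* features/classification JSON;
* frames — zero-padded PNG sequence ``frame_000001.png...`` with a
  ``scene.yaml`` holding the scene configuration;
* cohort summary CSV with mean/SD/min/max bottom rows.

Floats are written with 6 significant digits; write-then-read returns the
data model within that formatting precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anthropometry import Anthropometry
from .patterns import GaitPatternSpec
from .walker import LANDMARKS, SIDES, WalkerTrajectory

__all__ = ["write_trajectory_csv", "read_trajectory_csv",
           "write_events_json", "read_events_json",
           "write_kinematics_csv", "read_kinematics_csv",
           "write_features_json", "read_features_json",
           "write_frames", "read_frames",
           "RunConfig", "TrialRecord", "report"]


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


def write_trajectory_csv(traj, path) -> None:
    rows = []
    ts = np.asarray(traj.timestamps)
    for side in SIDES:
        lm = traj.sides[side]
        for name in LANDMARKS:
            arr = np.asarray(lm[name], float)
            for f in range(arr.shape[0]):
                missing = bool(np.isnan(arr[f]).any())
                rows.append({
                    "frame": f, "time_s": f"{ts[f]:.6g}", "side": side,
                    "landmark": name,
                    "x_m": "" if missing else f"{arr[f, 0]:.6g}",
                    "y_m": "" if missing else f"{arr[f, 1]:.6g}",
                    "missing_flag": int(missing),
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectory_csv(path, fps: float = 30.0,
                        foreground_side: str = "right") -> WalkerTrajectory:
    df = pd.read_csv(path)
    required = {"frame", "time_s", "side", "landmark", "x_m", "y_m",
                "missing_flag"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SchemaError(f"trajectory CSV lacks columns: {sorted(missing_cols)}")
    if len(df) == 0:
        raise SchemaError("trajectory CSV is empty")
    bad_side = ~df["side"].isin(SIDES)
    if bad_side.any():
        row = int(df.index[bad_side][0]) + 2  # header + 1-based
        raise SchemaError(f"invalid side value at row {row}: "
                          f"{df.loc[bad_side.idxmax(), 'side']!r}")
    bad_lm = ~df["landmark"].isin(LANDMARKS)
    if bad_lm.any():
        row = int(df.index[bad_lm][0]) + 2
        raise SchemaError(f"invalid landmark value at row {row}")
    n = int(df["frame"].max()) + 1
    sides = {s: {k: np.full((n, 2), np.nan) for k in LANDMARKS} for s in SIDES}
    ok = df["missing_flag"] == 0
    for (_, r) in df[ok].iterrows():
        sides[r["side"]][r["landmark"]][int(r["frame"])] = (
            float(r["x_m"]), float(r["y_m"]))
    ts = np.arange(n) / fps
    return WalkerTrajectory(
        timestamps=ts, sides=sides,
        true_events={s: {"ic": [], "to": []} for s in SIDES},
        true_curves={}, pattern=GaitPatternSpec(curve_variability_sd=0.0),
        anthro=Anthropometry(), fps=fps, foreground_side=foreground_side,
        meta={"source": str(path)})


def write_events_json(events, path, true_events=False) -> None:
    if true_events:  # a WalkerTrajectory ground-truth block
        payload = {s: {"ic_frames": list(map(int, ev["ic"])),
                       "to_frames": list(map(int, ev["to"]))}
                   for s, ev in events.items()}
    else:
        payload = {s: {"ic_frames": list(map(int, events.ic[s])),
                       "to_frames": list(map(int, events.to[s]))}
                   for s in events.ic}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events_json(path):
    from .events import GaitEvents

    data = json.loads(Path(path).read_text())
    ev = GaitEvents()
    for side, block in data.items():
        if side not in SIDES:
            raise SchemaError(f"invalid side {side!r} in events file")
        ev.ic[side] = [int(f) for f in block["ic_frames"]]
        ev.to[side] = [int(f) for f in block["to_frames"]]
    return ev


def write_kinematics_csv(kin_by_side: dict, path) -> None:
    rows = []
    for side, kin in kin_by_side.items():
        for ci, cyc in enumerate(kin.cycles):
            for angle, curve in cyc["curves"].items():
                for pct, val in enumerate(curve):
                    rows.append({"side": side, "cycle": ci, "angle": angle,
                                 "pct": pct, "value_deg": f"{val:.6g}"})
            rows.append({"side": side, "cycle": ci, "angle": "toe_off_pct",
                         "pct": -1, "value_deg": f"{cyc['toe_off_pct']:.6g}"})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_kinematics_csv(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for side, sdf in df.groupby("side"):
        cycles = []
        for _, cdf in sdf.groupby("cycle"):
            curves = {}
            to_pct = np.nan
            for angle, adf in cdf.groupby("angle"):
                if angle == "toe_off_pct":
                    to_pct = float(adf["value_deg"].iloc[0])
                else:
                    curves[angle] = adf.sort_values("pct")["value_deg"].to_numpy(float)
            cycles.append({"curves": curves, "toe_off_pct": to_pct,
                           "cycle": None})
        out[side] = cycles
    return out


def write_features_json(features_by_side: dict, path,
                        classification: dict | None = None) -> None:
    payload = {}
    for side, feat in features_by_side.items():
        payload[side] = {
            "features": {k: float(v) for k, v in feat.values.items()},
            "gait_speed": None if np.isnan(feat.gait_speed) else float(feat.gait_speed),
            "step_length": None if np.isnan(feat.step_length) else float(feat.step_length),
            "n_cycles": feat.n_cycles,
        }
        if classification and side in classification:
            res = classification[side]
            payload[side]["classification"] = {
                "type": res.type,
                "deviation_flags": sorted(res.deviation_flags),
                "rule_trace": res.rule_trace,
            }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_features_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_frames(frame_seq, out_dir) -> None:
    """PNG sequence + scene.yaml (+ depth-proxy PNGs when present)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(frame_seq.frames):
        iio.imwrite(out / f"frame_{i + 1:06d}.png", img)
    if frame_seq.depth is not None:
        for i, d in enumerate(frame_seq.depth):
            iio.imwrite(out / f"depth_{i + 1:06d}.png", d)
    (out / "scene.yaml").write_text(yaml.safe_dump(frame_seq.scene.to_dict()))


def read_frames(in_dir):
    import imageio.v3 as iio

    from .scene import FrameSequence, SceneConfig

    src = Path(in_dir)
    scene_d = yaml.safe_load((src / "scene.yaml").read_text())
    for key in ("background_rgb", "right_sock_rgb", "left_sock_rgb",
                "mark_rgb", "limb_rgb", "bg_limb_rgb"):
        scene_d[key] = tuple(scene_d[key])
    scene = SceneConfig(**scene_d)
    frames = [np.asarray(iio.imread(p))
              for p in sorted(src.glob("frame_*.png"))]
    if not frames:
        raise SchemaError(f"no frame_*.png files in {src}")
    depth_files = sorted(src.glob("depth_*.png"))
    depth = [np.asarray(iio.imread(p)) for p in depth_files] or None
    ts = np.arange(len(frames)) / 30.0
    return FrameSequence(frames=frames, timestamps=ts, scene=scene,
                         depth=depth)


# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Every tunable parameter of one pipeline run, serializable to YAML."""

    seed: int = 0
    pattern: str = "normal"
    n_cycles: int = 3
    cycle_duration: float = 1.1
    step_length_target: float = 0.38
    jitter_sd: float = 0.005
    dropout: float = 0.0
    curve_variability_sd: float = 2.0
    pixels_per_meter: float = 130.0
    smooth_cutoff_hz: float = 6.0
    v_thresh: float = 0.10
    dwell: int = 3
    max_gap_frames: int = 5
    min_valid_fraction: float = 0.8
    toe_walk_foot_threshold: float = 10.0
    band_n_sd: float = 1.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def pattern_spec(self) -> GaitPatternSpec:
        from .patterns import NoiseSpec

        return GaitPatternSpec(
            pattern_name=self.pattern, cycle_duration=self.cycle_duration,
            step_length_target=self.step_length_target,
            curve_variability_sd=self.curve_variability_sd,
            noise=NoiseSpec(self.jitter_sd, self.dropout), seed=self.seed)


@dataclass
class TrialRecord:
    """Bookkeeping for one recorded/simulated trial."""

    participant: str
    side: str
    trial: int
    support_aid: str = ""
    frames_path: str = ""
    trajectory_path: str = ""
    status: str = "pending"       # pending | processed | rejected
    reject_reason: str = ""

    @property
    def key(self):
        return (self.participant, self.side, self.trial)


def report(side_rows: pd.DataFrame, out_csv=None) -> pd.DataFrame:
    """Cohort report: participant-side rows plus mean/SD/min/max rows.

    ``side_rows`` must carry ``participant`` and ``side`` columns plus
    numeric parameter columns.  Deterministic: equal inputs give
    byte-identical CSV output.
    """
    from .spatiotemporal import cohort_table

    stats = cohort_table(side_rows)
    summary_rows = []
    for stat in ("mean", "sd", "min", "max"):
        row = {"participant": stat, "side": ""}
        for col in stats.columns:
            row[col] = stats.loc[stat, col]
        summary_rows.append(row)
    out = pd.concat([side_rows, pd.DataFrame(summary_rows)],
                    ignore_index=True)
    if out_csv is not None:
        out.to_csv(out_csv, index=False, float_format="%.6g")
    return out
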