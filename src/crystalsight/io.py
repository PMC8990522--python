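"""Reading and writing experiment directories and feature tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .frames import GrayFrame
from .signals import FeatureSeries
from .synth import ExperimentConfig, SyntheticExperiment, TemperaturePhase

__all__ = [
    "write_experiment", "read_frames", "read_log",
    "write_features_csv", "read_features_csv", "load_config",
]

LOG_COLUMNS = ["frame_index", "time_s", "temperature_C", "transmission_pct",
               "x_c_truth_mg_per_mL"]


def write_experiment(exp: SyntheticExperiment, out_dir) -> Path:
    """Write frames as 8-bit PNGs plus the per-frame CSV log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(exp.frames):
        iio.imwrite(out / f"frame_{i:05d}.png", f.pixels)
    log = pd.DataFrame({
        "frame_index": np.arange(len(exp.frames)),
        "time_s": exp.times_s,
        "temperature_C": exp.temperatures_C,
        "transmission_pct": exp.transmission,
        "x_c_truth_mg_per_mL": exp.x_c_truth,
    })
    log.to_csv(out / "log.csv", index=False)
    return out


def read_log(path) -> pd.DataFrame:
    log = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS[:4] if c not in log.columns]
    if missing:
        raise ValueError(f"log is missing columns {missing}")
    return log


def read_frames(images_dir, log: pd.DataFrame) -> list[GrayFrame]:
    """Load the PNG frame sequence of an experiment directory."""
    images_dir = Path(images_dir)
    frames = []
    for _, row in log.iterrows():
        px = iio.imread(images_dir / f"frame_{int(row.frame_index):05d}.png")
        frames.append(GrayFrame(np.asarray(px, dtype=np.uint8),
                                time_s=float(row.time_s),
                                temperature_C=float(row.temperature_C)))
    return frames


def write_features_csv(series: FeatureSeries, path, manifest: dict | None = None):
    """One row per frame: metadata columns then registry-ordered features;
    an optional sidecar JSON manifest records the registry for provenance."""
    df = pd.DataFrame({"time_s": series.times_s,
                       "temperature_C": series.temperatures_C,
                       "transmission_pct": series.transmission_pct})
    for j, name in enumerate(series.names):
        df[name] = series.values[:, j]
    path = Path(path)
    df.to_csv(path, index=False)
    if manifest is not None:
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_features_csv(path) -> FeatureSeries:
    df = pd.read_csv(path)
    meta = ["time_s", "temperature_C", "transmission_pct"]
    names = [c for c in df.columns if c not in meta]
    return FeatureSeries(df["time_s"].to_numpy(),
                         df["temperature_C"].to_numpy(),
                         df["transmission_pct"].to_numpy(),
                         df[names].to_numpy(), names)


def load_config(path) -> ExperimentConfig:
    """Experiment configuration from a YAML file with nested phases."""
    raw = yaml.safe_load(Path(path).read_text())
    phases = tuple(
        TemperaturePhase(kind=p["kind"], T_start=p["T_start"],
                         T_end=p.get("T_end", p["T_start"]),
                         rate=p.get("rate", 0.5),
                         duration=p.get("duration", 30.0))
        for p in raw.pop("profile", [])
    )
    if "solvent_ratio" in raw:
        raw["solvent_ratio"] = tuple(raw["solvent_ratio"])
    if "image_shape" in raw:
        raw["image_shape"] = tuple(raw["image_shape"])
    return ExperimentConfig(profile=phases, **raw)
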