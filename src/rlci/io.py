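"""Serialization: trial logs, kernels, curves, configs and run manifests.

Tabular artifacts are CSV; per-trial noise movies go into one compressed
array container (``noise.npz``) keyed by ``noise_ref``; configs are YAML
with full defaults.  Every command writes a ``manifest.yaml`` from which
a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .kernels import ClassificationImage, ImpactCurves
from .observer import ExperimentLog, ModelParams, TrialRecord
from .stimulus import StimulusConfig

TRIAL_COLUMNS = [
    "trial_id", "alpha", "target_side", "choice", "rt_ms", "correct",
    "timeout", "crossing_frame", "stimulus_seed", "noise_seed", "noise_ref",
]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

def save_config(obj, path) -> None:
    """Write a StimulusConfig or ModelParams as a YAML mapping."""
    d = dataclasses.asdict(obj)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _load_yaml(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def load_stimulus_config(path) -> StimulusConfig:
    data = _load_yaml(path)
    known = {f.name for f in dataclasses.fields(StimulusConfig)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"{path}: unknown stimulus config keys {sorted(bad)}")
    if "target_bars" in data:
        data["target_bars"] = tuple(data["target_bars"])
    return StimulusConfig(**data)


def load_model_params(path) -> ModelParams:
    data = _load_yaml(path)
    known = {f.name for f in dataclasses.fields(ModelParams)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"{path}: unknown model parameter keys {sorted(bad)}")
    return ModelParams(**data)


# ---------------------------------------------------------------------------
# Trial logs
# ---------------------------------------------------------------------------

def save_experiment(log: ExperimentLog, outdir) -> Path:
    """Write ``trials.csv`` + ``noise.npz`` + config snapshots; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    arrays: Dict[str, np.ndarray] = {}
    for r in log.records:
        ref = f"t{r.trial_id}"
        rows.append(
            {
                "trial_id": r.trial_id,
                "alpha": r.alpha,
                "target_side": r.target_side,
                "choice": r.choice,
                "rt_ms": r.rt_ms if r.rt_ms is not None else np.nan,
                "correct": r.correct,
                "timeout": r.timeout,
                "crossing_frame": r.crossing_frame if r.crossing_frame is not None else -1,
                "stimulus_seed": r.stimulus_seed,
                "noise_seed": r.seed,
                "noise_ref": ref,
            }
        )
        arrays[f"{ref}_left"] = r.noise_left.astype(np.float32)
        arrays[f"{ref}_right"] = r.noise_right.astype(np.float32)
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(outdir / "trials.csv", index=False)
    np.savez_compressed(outdir / "noise.npz", **arrays)
    save_config(log.config, outdir / "stimulus_config.yaml")
    save_config(log.params, outdir / "model_params.yaml")
    return outdir


def load_experiment(indir) -> ExperimentLog:
    """Read a trial log written by :func:`save_experiment`."""
    indir = Path(indir)
    df = pd.read_csv(indir / "trials.csv")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{indir}/trials.csv: missing columns {sorted(missing)}")
    config = load_stimulus_config(indir / "stimulus_config.yaml")
    params = load_model_params(indir / "model_params.yaml")
    with np.load(indir / "noise.npz") as noise:
        records: List[TrialRecord] = []
        for i, row in enumerate(df.itertuples()):
            for col, val in (("choice", row.choice), ("target_side", row.target_side)):
                if col == "choice" and val not in ("left", "right", "timeout"):
                    raise ValueError(f"trials.csv row {i}: bad choice {val!r}")
                if col == "target_side" and val not in ("left", "right"):
                    raise ValueError(f"trials.csv row {i}: bad target_side {val!r}")
            records.append(
                TrialRecord(
                    noise_left=noise[f"{row.noise_ref}_left"].astype(float),
                    noise_right=noise[f"{row.noise_ref}_right"].astype(float),
                    alpha=float(row.alpha),
                    target_side=row.target_side,
                    choice=row.choice,
                    rt_ms=None if np.isnan(row.rt_ms) else float(row.rt_ms),
                    correct=bool(row.correct),
                    seed=int(row.noise_seed),
                    stimulus_seed=int(row.stimulus_seed),
                    crossing_frame=None if row.crossing_frame < 0 else int(row.crossing_frame),
                    trial_id=int(row.trial_id),
                )
            )
    return ExperimentLog(records=records, config=config, params=params, seed=-1)


# ---------------------------------------------------------------------------
# Kernels and curves
# ---------------------------------------------------------------------------

def save_kernel(ci: ClassificationImage, path) -> None:
    """CSV matrix: one row per bar, header row of lag ms, plus a counts row."""
    df = pd.DataFrame(ci.kernel, columns=[f"{v:.10g}" for v in ci.lag_ms])
    df.insert(0, "bar", ci.space_axis)
    counts = pd.DataFrame(
        [["counts"] + list(ci.n_trials_per_lag)], columns=df.columns
    )
    pd.concat([df, counts]).to_csv(path, index=False)


def load_kernel(path) -> ClassificationImage:
    df = pd.read_csv(path)
    counts = df[df["bar"] == "counts"].iloc[0, 1:].to_numpy(dtype=float).astype(int)
    body = df[df["bar"] != "counts"]
    lag_ms = np.array([float(c) for c in df.columns[1:]])
    return ClassificationImage(
        kernel=body.iloc[:, 1:].to_numpy(dtype=float),
        n_trials_per_lag=counts,
        lag_ms=lag_ms,
        space_axis=body["bar"].to_numpy(dtype=int),
    )


def save_curves(curves: ImpactCurves, path) -> None:
    pd.DataFrame(
        {
            "lag_ms": curves.lag_ms,
            "central": curves.central,
            "adjacent": curves.adjacent,
        }
    ).to_csv(path, index=False)


def load_curves(path) -> ImpactCurves:
    df = pd.read_csv(path)
    for col in ("lag_ms", "central", "adjacent"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return ImpactCurves(
        central=df["central"].to_numpy(),
        adjacent=df["adjacent"].to_numpy(),
        lag_ms=df["lag_ms"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(
    outdir,
    command: str,
    seed: Optional[int],
    config_snapshot: dict,
    inputs: Optional[List[str]] = None,
    outputs: Optional[List[str]] = None,
) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "master_seed": seed,
        "package_version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "config": config_snapshot,
        "inputs": inputs or [],
        "outputs": outputs or [],
    }
    path = Path(outdir) / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
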