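"""On-disk formats: delimited session/trace tables with structured sidecars.

Sessions are stored as a comma-separated UTF-8 table (header row; columns
``trial, task, block, forced, choice, active, reward, reversal, shock``)
with the task configuration and seed in a ``<stem>.meta.yaml`` sidecar.
Photometry traces are a two-part artifact: a ``(time_s, value)`` sample
table plus a ``<stem>.events.csv`` event table of ``(time_s, label)`` rows.
Floats are serialized with 10 significant digits, the documented round-trip
precision.  Writes are atomic (write to a temporary file, then rename).
"""

from __future__ import annotations

import os
import tempfile
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .photometry import PhotometryTrace
from .task import SESSION_COLUMNS, SessionLog, TaskConfig

__all__ = [
    "read_session",
    "write_session",
    "read_trace",
    "write_trace",
]

FLOAT_FORMAT = "%.10g"


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _config_to_dict(config: TaskConfig) -> dict:
    return {
        "task_kind": config.task_kind,
        "n_trials": config.n_trials,
        "criterion_run": config.criterion_run,
        "block_odds": [str(Fraction(p)) for p in config.block_odds],
        "variant": config.variant,
        "forced_per_block": config.forced_per_block,
        "free_per_block": config.free_per_block,
        "reward_safe": config.reward_safe,
        "reward_risky": config.reward_risky,
        "shock_schedule": [[int(t), str(Fraction(p))] for t, p in config.shock_schedule],
    }


def _config_from_dict(d: dict) -> TaskConfig:
    return TaskConfig(
        task_kind=d["task_kind"],
        n_trials=int(d["n_trials"]),
        criterion_run=int(d["criterion_run"]),
        block_odds=tuple(Fraction(p) for p in d["block_odds"]),
        variant=d["variant"],
        forced_per_block=int(d["forced_per_block"]),
        free_per_block=int(d["free_per_block"]),
        reward_safe=int(d["reward_safe"]),
        reward_risky=int(d["reward_risky"]),
        shock_schedule=tuple((int(t), Fraction(p)) for t, p in d["shock_schedule"]),
    )


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_session(session: SessionLog, path) -> Path:
    """Write a session table and its config/seed sidecar; returns the path."""
    path = Path(path)
    _atomic_write(path, session.trials[SESSION_COLUMNS].to_csv(index=False))
    meta = {"seed": session.seed, "config": _config_to_dict(session.config)}
    _atomic_write(_meta_path(path), yaml.safe_dump(meta, sort_keys=False))
    return path


def read_session(path) -> SessionLog:
    """Read a session table (and sidecar, if present) with validation."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in SESSION_COLUMNS]
    if extra:
        raise ValueError(f"{path.name}: unexpected columns {extra}")
    if not np.issubdtype(df["trial"].dtype, np.integer):
        raise ValueError(f"{path.name}: trial indices must be integers")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["trial"].to_numpy(), expected):
        raise ValueError(f"{path.name}: trial indices must be contiguous 1..{len(df)}")
    if (df["reward"] < 0).any():
        raise ValueError(f"{path.name}: negative reward values")
    df = df.astype(
        {"block": np.int64, "forced": bool, "reward": np.int64,
         "reversal": bool, "shock": bool}
    )
    for col in ("task", "choice", "active"):
        df[col] = df[col].astype(str)
    meta_path = _meta_path(path)
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text(encoding="utf-8"))
        config = _config_from_dict(meta["config"])
        seed = meta["seed"]
    else:
        kinds = df["task"].unique()
        if len(kinds) != 1:
            raise ValueError(f"{path.name}: mixed task kinds {kinds}")
        config = TaskConfig(task_kind=str(kinds[0]), n_trials=len(df))
        seed = None
    return SessionLog(config, seed, df)


def _events_path(path: Path) -> Path:
    return path.with_suffix(".events.csv")


def write_trace(trace: PhotometryTrace, path) -> Path:
    """Write a trace as a (time_s, value) table plus an events sidecar."""
    path = Path(path)
    t = np.arange(len(trace.values)) / trace.rate_hz
    samples = pd.DataFrame({"time_s": t, "value": trace.values})
    _atomic_write(path, samples.to_csv(index=False, float_format=FLOAT_FORMAT))
    events = pd.DataFrame(trace.events, columns=["time_s", "label"])
    _atomic_write(
        _events_path(path), events.to_csv(index=False, float_format=FLOAT_FORMAT)
    )
    return path


def read_trace(path, require_positive: bool = True) -> PhotometryTrace:
    """Read a trace written by :func:`write_trace`, checking uniform sampling.

    Raw fluorescence must be strictly positive (the dF/F division needs it);
    pass ``require_positive=False`` for already-normalized dF/F traces,
    which are legitimately signed.
    """
    path = Path(path)
    samples = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in samples.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    t = samples["time_s"].to_numpy(dtype=float)
    v = samples["value"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path.name}: trace needs at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.any(np.abs(dt - dt[0]) > 1e-6 * dt[0]):
        raise ValueError(f"{path.name}: sampling is not uniform")
    if require_positive and np.any(v <= 0):
        raise ValueError(f"{path.name}: non-positive fluorescence values")
    rate = 1.0 / dt.mean()
    events_path = _events_path(path)
    events = []
    if events_path.exists():
        ev = pd.read_csv(events_path)
        if len(ev):
            if (ev["time_s"] < 0).any():
                raise ValueError(f"{events_path.name}: event at negative time")
            events = list(zip(ev["time_s"].astype(float), ev["label"].astype(str)))
    return PhotometryTrace(rate, v, events)
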