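"""Delimited-text readers and writers and YAML run configuration.

All interchange is comma-separated text with a header row; units are fixed
package-wide (µm, s, rad).  Floats are written with their shortest exact
decimal representation so every table round-trips bit-identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .collective import CollectiveConfig, MsdCurve
from .dynamics import DynamicsParams
from .field import FieldParams

__all__ = [
    "read_trajectories", "write_trajectories",
    "write_events", "read_events",
    "write_msd", "read_msd",
    "write_profiles", "read_profiles",
    "load_config", "save_config",
]

_REQUIRED = ["droplet_id", "t", "x", "y"]


def read_trajectories(path) -> pd.DataFrame:
    """Read a trajectory table (droplet_id, t, x, y[, z][, nx, ny[, nz]]).

    Rows are canonicalised: sorted by (droplet_id, t).  Duplicate
    timestamps within a droplet are a parse error reported with file line
    numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in df.columns:
        if col != "droplet_id":
            df[col] = df[col].astype(float)
    df = df.sort_values(["droplet_id", "t"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["droplet_id", "t"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise ValueError(
            f"{path}: duplicate (droplet_id, t) timestamps near line(s) {lines[:5]}"
        )
    return df


def write_trajectories(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_events(path, events) -> None:
    """One row per interaction event; header-only file for an empty list."""
    rows = [{
        "event_id": i,
        "leader_id": ev.leader_id,
        "follower_id": ev.follower_id,
        "theta_inc": ev.theta_inc,
        "delta_t": ev.delta_t,
        "t0": ev.t0,
        "outcome": ev.outcome,
        "max_turn_rate": ev.max_turn_rate,
    } for i, ev in enumerate(events)]
    cols = ["event_id", "leader_id", "follower_id", "theta_inc", "delta_t",
            "t0", "outcome", "max_turn_rate"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_msd(path, curve: MsdCurve) -> None:
    """MSD curve as CSV with '#'-prefixed metadata; absent crossovers are NA."""
    def fmt(v):
        return "NA" if v is None else repr(float(v))

    with open(path, "w") as fh:
        fh.write(f"# crossover_to_caging: {fmt(curve.crossover_to_caging)}\n")
        fh.write(f"# crossover_to_escape: {fmt(curve.crossover_to_escape)}\n")
        fh.write(f"# plateau_height: {fmt(curve.plateau_height)}\n")
        fh.write("lag,msd\n")
        for lag, m in zip(curve.lags, curve.msd):
            fh.write(f"{float(lag)!r},{float(m)!r}\n")


def read_msd(path) -> MsdCurve:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            val = val.strip()
            meta[key.strip()] = None if val == "NA" else float(val)
        else:
            body.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), float_precision="round_trip")
    return MsdCurve(
        lags=df["lag"].to_numpy(float),
        msd=df["msd"].to_numpy(float),
        crossover_to_caging=meta.get("crossover_to_caging"),
        crossover_to_escape=meta.get("crossover_to_escape"),
        plateau_height=meta.get("plateau_height"),
    )


def write_profiles(path, ps) -> None:
    """Profile series in long format (t, x, intensity)."""
    T, X = np.meshgrid(ps.times, ps.x, indexing="ij")
    pd.DataFrame({"t": T.ravel(), "x": X.ravel(),
                  "intensity": ps.intensity.ravel()}).to_csv(path, index=False)


def read_profiles(path):
    from .fluorescence import ProfileSeries

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "x", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    times = np.unique(df["t"].to_numpy(float))
    x = np.unique(df["x"].to_numpy(float))
    pivot = df.pivot_table(index="t", columns="x", values="intensity")
    return ProfileSeries(x=x, times=times, intensity=pivot.to_numpy(float))


def save_config(path, cfg: CollectiveConfig) -> None:
    payload = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> CollectiveConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    dyn = DynamicsParams(**payload.pop("dynamics", {}))
    fld = FieldParams(**payload.pop("field", {}))
    return CollectiveConfig(dynamics=dyn, field=fld, **payload)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
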