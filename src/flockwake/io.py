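"""Readers, writers and run configuration.

All files are plain CSV with a header row; model parameters travel as the
JSON rule-base config so any result can be re-derived from its artifacts.
Timestamps are accepted as seconds (float) or ISO-8601 and normalised to
seconds from the first sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .fnn import FNNConfig
from .frames import FlockDataset
from .wake_model import WakeModelConfig

log = logging.getLogger("flockwake")

POSITION_COLUMNS = ["bird_id", "timestamp", "x", "y", "z"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, echoable to JSON."""

    wake: WakeModelConfig = field(default_factory=WakeModelConfig)
    fnn: FNNConfig = field(default_factory=FNNConfig)
    rate_hz: float = 5.0
    bootstrap_reps: int = 1000
    seed: int = 0
    split_bouts_on_leader_change: bool = True
    include_singletons: bool = False
    agreement_mode: str = "both"

    def to_json(self, path) -> None:
        d = {
            "wake": self.wake.__dict__,
            "fnn": self.fnn.__dict__,
            "rate_hz": self.rate_hz,
            "bootstrap_reps": self.bootstrap_reps,
            "seed": self.seed,
            "split_bouts_on_leader_change": self.split_bouts_on_leader_change,
            "include_singletons": self.include_singletons,
            "agreement_mode": self.agreement_mode,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        return cls(
            wake=WakeModelConfig(**d.get("wake", {})),
            fnn=FNNConfig(**d.get("fnn", {})),
            rate_hz=d.get("rate_hz", 5.0),
            bootstrap_reps=d.get("bootstrap_reps", 1000),
            seed=d.get("seed", 0),
            split_bouts_on_leader_change=d.get("split_bouts_on_leader_change", True),
            include_singletons=d.get("include_singletons", False),
            agreement_mode=d.get("agreement_mode", "both"),
        )


def _normalise_timestamps(raw: pd.Series) -> pd.Series:
    """Seconds-as-float passthrough, or ISO-8601 → seconds from first fix."""
    as_num = pd.to_numeric(raw, errors="coerce")
    if as_num.notna().all():
        return as_num.astype(float)
    as_dt = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if as_dt.notna().all():
        return (as_dt - as_dt.min()).dt.total_seconds()
    bad = int(np.argmax(as_num.isna() & as_dt.isna().to_numpy()))
    raise ParseError(f"unparseable timestamp {raw.iloc[bad]!r}", line=bad + 2)


def read_positions(path, rate_hz: float = 5.0) -> FlockDataset:
    """Read a long-format positions CSV into a validated FlockDataset.

    Expected header: ``bird_id,timestamp,x,y,z``; metres in a shared local
    tangent frame.  Malformed rows are reported with their line number
    (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"positions file not found: {path}")
    df = pd.read_csv(path, dtype={"bird_id": str})
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing} in {path}")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.argmax(vals.isna().to_numpy()))
            raise ParseError(f"non-numeric {col}={df[col].iloc[row]!r}", line=row + 2)
        df[col] = vals
    df["timestamp"] = _normalise_timestamps(df["timestamp"])
    dup = df.duplicated(["bird_id", "timestamp"])
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise ParseError(
            f"duplicate (bird_id, timestamp) = "
            f"({df['bird_id'].iloc[row]!r}, {df['timestamp'].iloc[row]!r})",
            line=row + 2,
        )
    flock = FlockDataset.from_frame(df, rate_hz=rate_hz)
    for b in flock.bird_ids:
        log.info("bird %s: %d samples", b, len(flock.trajectories[b]))
    return flock


def write_positions(flock: FlockDataset, path) -> None:
    flock.to_frame().to_csv(path, index=False)


def write_relative(rels: pd.DataFrame, path) -> None:
    """Relative-position CSV: follower,leader,timestamp,ew,ns,ud,dist3d."""
    rels[["follower", "leader", "timestamp", "ew", "ns", "ud", "dist3d"]].to_csv(
        path, index=False
    )


def write_assignments(assignments: pd.DataFrame, path, model: str = "fis") -> None:
    """Per-follower assignment CSV with a model column for joint comparison."""
    out = assignments.copy()
    out["model"] = model
    out.to_csv(path, index=False)


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"follower": str})
    if "leader" in df.columns:
        df["leader"] = df["leader"].astype(object).where(df["leader"].notna(), None)
    return df


def write_strengths(scored: pd.DataFrame, path) -> None:
    """Rule-strength CSV: timestamp,follower,leader,r1..r5,output,zero_fire."""
    cols = ["timestamp", "follower", "leader", "r1", "r2", "r3", "r4", "r5",
            "output", "zero_fire"]
    scored[cols].to_csv(path, index=False)
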