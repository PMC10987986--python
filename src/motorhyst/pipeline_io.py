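"""File formats, configuration, seeding and run provenance.

Interchange is plain CSV with a header.  The trial table schema
(units: mm for positions, ms for times) is::

    participant_id, experiment, block_type, condition, trial_index,
    obstacle_x_mm, coded_position, side, outcome, failure_type, rt_ms

Trajectory tables carry ``participant_id, trial_uid, t_ms, x_mm, y_mm,
phase``; posterior draws carry ``chain, draw, cost_scaler, bias_scaler,
bias_rate``.  Foreign tables (e.g. a deposited processed-data export)
are ingested through a column-mapping dictionary.  All randomness flows
from one root seed through named substreams, and every artifact can be
stamped with the seed and a config hash that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "read_trajectory",
    "write_trajectory",
    "write_posterior",
    "read_posterior",
    "substream",
    "config_hash",
    "RunManifest",
]

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "block_type",
    "condition",
    "trial_index",
    "obstacle_x_mm",
    "coded_position",
    "side",
    "outcome",
    "failure_type",
    "rt_ms",
]
MANDATORY_TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "block_type",
    "condition",
    "trial_index",
    "obstacle_x_mm",
    "side",
    "outcome",
]
TRAJECTORY_COLUMNS = ["participant_id", "trial_uid", "t_ms", "x_mm", "y_mm", "phase"]


def read_trials(
    path, column_map: Optional[Mapping[str, str]] = None, sep: str = ","
) -> pd.DataFrame:
    """Read a trial table (CSV/TSV with header) into the project schema.

    ``column_map`` maps foreign column names to project names, letting a
    differently labelled export be ingested unchanged.  Missing
    mandatory columns are reported by name; unknown extra columns are
    preserved.  Trial indices are 0-based internally.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing columns: {missing}")
    if "coded_position" not in df.columns:
        from .geometry import code_position

        df["coded_position"] = [code_position(x) for x in df["obstacle_x_mm"]]
    if "rt_ms" not in df.columns:
        df["rt_ms"] = np.nan
    if "failure_type" not in df.columns:
        df["failure_type"] = ""
    df["failure_type"] = df["failure_type"].fillna("")
    df["side"] = df["side"].fillna("none")
    df["experiment"] = df["experiment"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table in canonical column order (lossless round trip)."""
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS + extra, float_format="%.10g")


def write_trajectory(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS, float_format="%.6f")


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table {path} is missing columns: {missing}")
    return df


def write_posterior(draws, path) -> None:
    """Write posterior draws (one row per draw with its chain label)."""
    draws.to_frame().to_csv(path, index=False)


def read_posterior(path):
    from .inference import PosteriorDraws

    df = pd.read_csv(path)
    n_chains = df["chain"].nunique()
    n_draws = len(df) // n_chains
    chains = (
        df[["cost_scaler", "bias_scaler", "bias_rate"]]
        .to_numpy()
        .reshape(n_chains, n_draws, 3)
    )
    return PosteriorDraws(chains=chains, rhat={}, ess={}, converged=True)


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child random stream of a single root seed."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    """Provenance for one pipeline run, written atomically at run end."""

    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record_stage(self, name: str, n_records: int, elapsed_s: float) -> None:
        self.stages.append(
            {"stage": name, "n_records": int(n_records), "elapsed_s": float(elapsed_s)}
        )

    def write(self, path) -> None:
        path = Path(path)
        payload = {
            "config": self.config,
            "config_hash": config_hash(self.config),
            "seed": self.seed,
            "stages": self.stages,
            "wall_time_s": time.time() - self.started,
        }
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(json.dumps(payload, indent=2))
        tmp.replace(path)
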