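"""CSV/JSON/YAML input-output for datasets, trajectories and posteriors.

One canonical tidy-CSV dialect is used throughout: comma separated,
dot-decimal, header required, concentration columns carrying their unit
in the column name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .inference import Posterior
from .simulate import Trajectory
from .synthetic import TimeCourseDataset

__all__ = ["read_timecourse_csv", "write_timecourse_csv",
           "write_posterior", "read_posterior", "write_trajectory_csv",
           "RunConfig", "load_config", "config_hash"]


def write_timecourse_csv(dataset: TimeCourseDataset, path) -> None:
    """Write the tidy dataset plus a ``.provenance.json`` sidecar."""
    path = Path(path)
    dataset.data.to_csv(path, index=False)
    side = path.with_suffix(path.suffix + ".provenance.json")
    side.write_text(json.dumps(dataset.provenance, indent=1, default=float))


def read_timecourse_csv(path) -> TimeCourseDataset:
    """Schema-validated load of a time-course CSV.

    The header must carry the canonical unit-bearing column names;
    malformed or negative rows raise with their row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = list(TimeCourseDataset.REQUIRED)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} "
                         "(units are asserted from the header)")
    bad_rows = []
    for col in ("concentration_uM", "time_min", "replicate", "product_nM"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_rows += list(df.index[vals.isna()] + 2)  # +2: header + 1-based
        df[col] = vals
    neg = df.index[df["product_nM"] < 0] + 2
    if len(neg):
        bad_rows += list(neg)
    if bad_rows:
        raise ValueError(f"{path}: malformed rows (negative or non-numeric) "
                         f"at lines {sorted(set(bad_rows))}")
    prov_path = path.with_suffix(path.suffix + ".provenance.json")
    prov = json.loads(prov_path.read_text()) if prov_path.exists() else {
        "kind": "experimental"}
    return TimeCourseDataset(df, prov)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Tidy trajectory table: time_min, species, value (µM)."""
    rows = []
    for i, t in enumerate(traj.times):
        for j, nm in enumerate(traj.names):
            rows.append((t, nm, traj.states[i, j]))
    pd.DataFrame(rows, columns=["time_min", "species", "value"]).to_csv(
        path, index=False)


def write_posterior(post: Posterior, stem) -> None:
    """Particles to ``<stem>.csv``, metadata to ``<stem>.json``."""
    stem = Path(stem)
    df = post.particles.copy()
    df["weight"] = post.weights
    df["distance"] = post.distances
    df.to_csv(stem.with_suffix(".csv"), index=False)
    meta = {"epsilons": [float(e) for e in post.epsilons],
            "acceptance_rates": [float(a) for a in post.acceptance_rates],
            "seed": int(post.seed), "distance_id": post.distance_id,
            "converged": bool(post.converged)}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_posterior(stem) -> Posterior:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    w = df.pop("weight").to_numpy()
    d = df.pop("distance").to_numpy()
    return Posterior(df, w, d, meta["epsilons"], meta["acceptance_rates"],
                     meta["seed"], meta["distance_id"], meta["converged"])


# --------------------------------------------------------------------- config
_CONFIG_KEYS = {"model", "models", "parameters", "priors", "dataset",
                "design", "protocol", "solver", "seed", "outdir",
                "n_particles", "noise_sd"}


@dataclass
class RunConfig:
    """Validated run configuration for the command-line interface."""

    model: Optional[str] = None
    models: Optional[list] = None
    parameters: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    dataset: Optional[str] = None
    design: Optional[str] = None
    protocol: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"
    n_particles: int = 100
    noise_sd: float = 0.05


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
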