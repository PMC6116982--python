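"""Dataset and configuration I/O.

Datasets travel as flat CSV with one row per subject x replicate:

    subject_id, replicate, w_ee, w_es, y_ee, y_es, gender, age, bmi

Gold-standard columns (w_ee, w_es) may be absent for calibration-only
inputs.  The latent truth of a simulated dataset is written to a sidecar
CSV with one row per subject: subject_id, x_ee, x_ei, x_es.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import simulate as sim
from .models import MeasurementDataset
from .samplers import ChainConfig

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_truth",
    "read_truth",
    "load_generator_config",
    "load_chain_config",
    "write_manifest",
]

_REQUIRED = ["subject_id", "replicate", "y_ee", "y_es", "gender", "age", "bmi"]
_GOLD = ["w_ee", "w_es"]


def read_dataset(path) -> MeasurementDataset:
    """Parse and validate a measurement CSV into subject x replicate arrays."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset file {path} is missing columns: {missing}")
    value_cols = [c for c in _REQUIRED[2:] + _GOLD if c in frame.columns]
    bad = [c for c in value_cols if not np.issubdtype(frame[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric values in columns: {bad}")
    if frame[value_cols].isna().any().any():
        raise ValueError("dataset contains missing values")

    counts = frame.groupby("subject_id").size()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced replicate counts per subject "
            f"(found {sorted(counts.unique())}); the models assume a common J"
        )
    frame = frame.sort_values(["subject_id", "replicate"])
    subjects = frame["subject_id"].unique()
    n, j = subjects.size, int(counts.iloc[0])

    def grid(col):
        if col not in frame.columns:
            return None
        return frame[col].to_numpy(dtype=float).reshape(n, j)

    per_subject = frame.groupby("subject_id", sort=False).first()
    z = per_subject[["gender", "bmi", "age"]].to_numpy(dtype=float)
    return MeasurementDataset(
        w_ee=grid("w_ee"),
        w_es=grid("w_es"),
        y_ee=grid("y_ee"),
        y_es=grid("y_es"),
        z=z,
        subject_id=subjects,
    )


def _dataset_frame(ds: MeasurementDataset) -> pd.DataFrame:
    n, j = ds.n, ds.n_replicates
    ids = ds.subject_id if ds.subject_id is not None else np.arange(1, n + 1)
    rows = {
        "subject_id": np.repeat(ids, j),
        "replicate": np.tile(np.arange(1, j + 1), n),
        "y_ee": ds.y_ee.ravel(),
        "y_es": ds.y_es.ravel(),
        "gender": np.repeat(ds.z[:, 0], j),
        "age": np.repeat(ds.z[:, 2], j),
        "bmi": np.repeat(ds.z[:, 1], j),
    }
    if ds.w_ee is not None:
        rows["w_ee"] = ds.w_ee.ravel()
        rows["w_es"] = ds.w_es.ravel()
    order = [c for c in ["subject_id", "replicate", "w_ee", "w_es", "y_ee", "y_es", "gender", "age", "bmi"] if c in rows]
    return pd.DataFrame(rows)[order]


def write_dataset(ds, path) -> None:
    """Write a MeasurementDataset (or SimulatedDataset) to flat CSV."""
    if isinstance(ds, sim.SimulatedDataset):
        ds = MeasurementDataset.from_simulated(ds)
    _dataset_frame(ds).to_csv(path, index=False)


def write_truth(simulated: sim.SimulatedDataset, path) -> None:
    lat = simulated.latents
    pd.DataFrame(
        {
            "subject_id": np.arange(1, lat.n + 1),
            "x_ee": lat.x_ee,
            "x_ei": lat.x_ei,
            "x_es": lat.x_es,
        }
    ).to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_generator_config(path=None, **overrides) -> sim.GeneratorConfig:
    """GeneratorConfig from a YAML file plus keyword overrides.

    Recognised keys mirror the config dataclass fields; nested ``within``
    and ``mixture`` blocks build the corresponding specs.
    """
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "within" in raw and isinstance(raw["within"], dict):
        raw["within"] = sim.WithinPersonSpec(**raw["within"])
    if "mixture" in raw and isinstance(raw["mixture"], dict):
        mix = dict(raw["mixture"])
        if "counts" in mix:
            mix["counts"] = tuple(mix["counts"])
        if "scale" in mix:
            raw["mixture"] = sim.MixtureSpec(**mix)
        else:
            raw["mixture"] = sim.MixtureSpec.calibrated(**mix)
    for key in ("gamma_ee", "gamma_es"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return sim.GeneratorConfig(**raw)


def load_chain_config(path=None, **overrides) -> ChainConfig:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "move_probs" in raw:
        raw["move_probs"] = tuple(raw["move_probs"])
    return ChainConfig(**raw)


def write_manifest(directory, *, seed, config) -> None:
    """Reproducibility record: config hash, seed, package versions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "ebcal": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (directory / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
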