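"""Readers/writers, run configuration and the packaged clinical tally.

Trial tables travel as comma-separated text with header
``observer_id,group,condition,contrast,correct``; lines starting with ``#``
are metadata comments (the writer embeds the producing config hash there).
The migraine-group clinical-features table ships as a packaged CSV fixture
so its tallies need no external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import BASELINE, SessionDesign, condition_distance
from .simulate import (
    DEFAULT_BETA,
    DEFAULT_GROUP_SIZES,
    DEFAULT_SIGMA_RE,
    GROUPS,
    PopulationParams,
    TRIAL_COLUMNS,
    ValidationError,
)

__all__ = [
    "read_trials",
    "write_trials",
    "load_clinical_table",
    "tally_clinical",
    "RunConfig",
    "config_hash",
]

#: Missing-data token used in the printed clinical table.
NDI = "NDI"


def _validate_trials(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing required columns {missing}")
    if df.empty:
        return df
    df = df.copy()
    df["condition"] = df["condition"].astype(str)

    def _bad_condition(tok: str) -> bool:
        try:
            condition_distance(tok)
            return False
        except ValueError:
            return True

    contrast = pd.to_numeric(df["contrast"], errors="coerce")
    correct = pd.to_numeric(df["correct"], errors="coerce")
    checks = {
        "unknown group label": ~df["group"].isin(GROUPS),
        "correct must be 0 or 1": ~correct.isin((0, 1)),
        "contrast outside (0, 1]": ~((contrast > 0) & (contrast <= 1)),
        "unknown condition token": df["condition"].map(_bad_condition),
    }
    problems = []
    for message, mask in checks.items():
        rows = list(df.index[mask.to_numpy(dtype=bool)][:10])
        if rows:
            problems.append(f"{message} at rows {rows}")
    if problems:
        raise ValidationError(f"{source}: malformed rows:\n  " + "\n  ".join(problems))
    df["contrast"] = contrast
    df["correct"] = df["correct"].astype(np.int64)
    df["contrast"] = df["contrast"].astype(float)
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table; ``#`` lines are ignored."""
    df = pd.read_csv(path, comment="#", dtype={"condition": str, "observer_id": str})
    return _validate_trials(df, str(path))


def write_trials(df: pd.DataFrame, path, config_hash_: str | None = None) -> None:
    """Write a trial table; optionally embeds the producing config hash."""
    _validate_trials(df, "in-memory table")
    path = Path(path)
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    ordered = df[list(TRIAL_COLUMNS) + extra]
    with open(path, "w") as fh:
        if config_hash_:
            fh.write(f"# config_hash: {config_hash_}\n")
        ordered.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# clinical table


def load_clinical_table(path=None) -> pd.DataFrame:
    """Load the migraine-group clinical-features table.

    Defaults to the packaged transcription; NDI ("non-disclosed information")
    entries parse as missing, never as zero.
    """
    if path is None:
        source = resources.files("latmask.data").joinpath("clinical_table.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    required = {"observer", "sex", "age", "excluded"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns {sorted(missing)}")
    bad_sex = set(df["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise ValidationError(f"unknown sex tokens {sorted(bad_sex)}")
    df["excluded"] = df["excluded"].astype(int).astype(bool)
    for col in ("age", "age_started"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace(NDI, np.nan), errors="coerce")
    return df


def tally_clinical(table: pd.DataFrame) -> dict[str, int]:
    """Counts over included rows: total, female, male."""
    included = table[~table["excluded"]]
    female = int((included["sex"] == "F").sum())
    male = int((included["sex"] == "M").sum())
    return {"included_n": len(included), "female_n": female, "male_n": male}


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    design: dict = field(default_factory=dict)          # SessionDesign overrides
    population: dict = field(default_factory=dict)      # PopulationParams overrides
    fit: dict = field(default_factory=dict)             # n_quad, coding, tolerances
    bootstrap: dict = field(default_factory=dict)       # n_samples, covariance_mode
    seed: int = 0
    output_dir: str = "."

    def session_design(self) -> SessionDesign:
        return SessionDesign(**self.design)

    def population_params(self) -> PopulationParams:
        kwargs = {
            "beta": DEFAULT_BETA,
            "sigma_re": DEFAULT_SIGMA_RE,
            "group_sizes": DEFAULT_GROUP_SIZES,
        }
        kwargs.update(self.population)
        return PopulationParams(**kwargs)

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "population": self.population,
            "fit": self.fit,
            "bootstrap": self.bootstrap,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def config_hash(config: RunConfig | dict) -> str:
    """Stable short hash of a config, for artifact provenance stamps."""
    payload = config.to_dict() if isinstance(config, RunConfig) else config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path, config_hash_: str | None = None) -> None:
    """Atomic JSON write (temp file + rename), numpy-scalar tolerant."""
    payload = dict(payload)
    if config_hash_:
        payload["config_hash"] = config_hash_
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    tmp.replace(path)
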