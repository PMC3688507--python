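"""Dataset and lookup-table readers/writers plus experiment config.

The canonical on-disk dataset is a plain CSV with header
``rec_id,entity_id,first_name,surname,sex,dob,postcode[,...]``, ISO
dates and empty strings for missing values.  ``read_dataset`` also
accepts foreign dialects via a column map and can recover the truth
label from structured record ids (``rec-12-dup-3`` style) when no
entity column is present.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "DataError",
    "ConfigError",
    "CANONICAL_COLUMNS",
    "read_dataset",
    "write_dataset",
    "read_lookup_csv",
    "ExperimentConfig",
    "load_experiment_config",
    "RunLog",
]

CANONICAL_COLUMNS = ("rec_id", "entity_id", "first_name", "surname", "sex", "dob", "postcode")
OPTIONAL_COLUMNS = ("middle_name", "address", "suburb", "state")
MANDATORY = ("rec_id", "first_name", "surname", "sex", "dob", "postcode")


class DataError(ValueError):
    """Malformed input data (CLI exit code 3)."""


class ConfigError(ValueError):
    """Malformed configuration (CLI exit code 2)."""


def read_dataset(
    path,
    column_map: dict[str, str] | None = None,
    entity_from_rec_id: str | None = r"^(?:rec|ent)[-_](\d+)",
) -> pd.DataFrame:
    """Read a person dataset from CSV.

    ``column_map`` maps file column names to canonical names.  Empty
    strings become missing.  If the file has no entity column and
    ``entity_from_rec_id`` is set, the truth label is derived from the
    record id by regex (first group), accepting files where duplicates
    are keyed ``rec-<n>-dup-<k>`` in any row order.  Unmapped extra
    columns are preserved as-is.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [c.strip() for c in df.columns]
    missing_cols = [c for c in MANDATORY if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: missing mandatory columns {missing_cols}")
    df = df.astype(object)
    df = df.where(df != "", None)
    dup = df["rec_id"][df["rec_id"].duplicated()]
    if len(dup):
        raise DataError(f"{path}: duplicate rec_id {dup.iloc[0]!r}")
    if "entity_id" not in df.columns:
        if entity_from_rec_id:
            pat = re.compile(entity_from_rec_id)
            def derive(rid):
                m = pat.match(str(rid))
                if not m:
                    raise DataError(f"{path}: cannot derive entity id from rec_id {rid!r}")
                return f"ent-{m.group(1)}"
            df["entity_id"] = df["rec_id"].map(derive)
        else:
            df["entity_id"] = None
    order = [c for c in CANONICAL_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in CANONICAL_COLUMNS
    ]
    return df[order]


def write_dataset(ds: pd.DataFrame, path) -> None:
    """Write a dataset as canonical CSV (missing values as empty strings)."""
    out = ds.copy()
    order = [c for c in CANONICAL_COLUMNS if c in out.columns] + [
        c for c in out.columns if c not in CANONICAL_COLUMNS
    ]
    out[order].to_csv(path, index=False, na_rep="")


def read_lookup_csv(path, key_col: int = 0, value_col: int = 1) -> dict[str, str]:
    """Two-column lookup CSV (e.g. nickname,canonical) to a dict."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, key_col].str.upper(), df.iloc[:, value_col].str.upper()))


@dataclass
class RunLog:
    """Machine-readable run log: one JSON object per stage."""

    entries: list[dict] = dc_field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.entries.append({"stage": stage, **info})

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, default=str) + "\n")


@dataclass
class ExperimentConfig:
    """Fully serialisable description of an end-to-end experiment run."""

    seed: int = 0
    n_total: int = 20000
    dataset_path: str | None = None  # when set, load instead of generating
    plans: tuple[str, ...] = ("none", "minimal", "high")
    sweep_step: float = 0.5
    sweep_patience: int = 10
    weight_method: str = "truth_counting"
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_total": self.n_total,
            "dataset_path": self.dataset_path,
            "plans": list(self.plans),
            "sweep_step": self.sweep_step,
            "sweep_patience": self.sweep_patience,
            "weight_method": self.weight_method,
            "out_dir": self.out_dir,
        }


def load_experiment_config(path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    known = {f for f in ExperimentConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "plans" in raw:
        raw["plans"] = tuple(raw["plans"])
    try:
        return ExperimentConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
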