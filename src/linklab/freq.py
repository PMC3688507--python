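"""Value frequency tables driving synthetic person generation.

A :class:`FrequencyTable` holds the relative frequencies of a field's
values (surnames, forenames by sex, postcodes, sex itself).  Tables load
from two-column CSV (``value,count`` or ``value,frequency``); raw counts
below a privacy floor are dropped before normalisation, mirroring how
population-derived lookup tables are released.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FrequencyTable", "load_frequency_table", "default_tables"]


@dataclass
class FrequencyTable:
    field_name: str
    values: np.ndarray  # dtype=object, unique
    frequencies: np.ndarray  # float, sum to 1, all > 0
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=object)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.values) == 0:
            raise ValueError(f"empty frequency table for {self.field_name!r}")
        if len(set(self.values)) != len(self.values):
            raise ValueError(f"duplicate values in table for {self.field_name!r}")
        if np.any(self.frequencies <= 0):
            raise ValueError(f"non-positive frequency in table for {self.field_name!r}")
        self.frequencies = self.frequencies / self.frequencies.sum()
        self._cum = np.cumsum(self.frequencies)

    def __len__(self) -> int:
        return len(self.values)

    def prob(self, value: str) -> float:
        idx = np.nonzero(self.values == value)[0]
        return float(self.frequencies[idx[0]]) if len(idx) else 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values i.i.d. from the table."""
        u = rng.random(size)
        idx = np.searchsorted(self._cum, u, side="right").clip(0, len(self) - 1)
        return self.values[idx]

    def collision_probability(self) -> float:
        """P(two independent draws agree) = sum of squared frequencies."""
        return float(np.sum(self.frequencies**2))


def load_frequency_table(path, field_name: str, count_floor: int = 5) -> FrequencyTable:
    """Read a two-column CSV frequency table.

    The file must have a header ``value,count`` or ``value,frequency``.
    When counts are given, values with count below ``count_floor`` are
    excluded before normalisation (the release rule for the population
    tables this emulates); the floor does not apply to pre-normalised
    frequency files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={0: str})
    cols = [c.strip().lower() for c in df.columns]
    if len(cols) < 2 or cols[0] != "value" or cols[1] not in ("count", "frequency"):
        raise ValueError(f"{path}: expected columns value,count or value,frequency")
    weights = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    if np.any(weights < 0):
        raise ValueError(f"{path}: negative counts/frequencies")
    values = df.iloc[:, 0].astype(str).str.strip().str.upper().to_numpy(object)
    if cols[1] == "count":
        keep = weights >= count_floor
        values, weights = values[keep], weights[keep]
    else:
        keep = weights > 0
        values, weights = values[keep], weights[keep]
    if len(values) == 0:
        raise ValueError(f"{path}: table empty after truncation")
    return FrequencyTable(field_name, values, weights)


def _packaged(name: str):
    return resources.files("linklab.data").joinpath(name)


def default_tables() -> dict[str, FrequencyTable]:
    """The packaged synthetic lookup tables (see data/*_synthetic.csv).

    These are authored stand-ins whose top values match the published
    marginals of the Western-Australian-roll-derived tables; the
    originals are not redistributable.
    """
    return {
        "surname": load_frequency_table(_packaged("surname_freq_synthetic.csv"), "surname"),
        "first_name_m": load_frequency_table(
            _packaged("first_name_male_freq_synthetic.csv"), "first_name"
        ),
        "first_name_f": load_frequency_table(
            _packaged("first_name_female_freq_synthetic.csv"), "first_name"
        ),
        "sex": load_frequency_table(_packaged("sex_freq_synthetic.csv"), "sex"),
        "postcode": load_frequency_table(_packaged("postcode_freq_synthetic.csv"), "postcode"),
    }
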