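"""Field-level data-cleaning techniques and graded cleaning plans.

Each technique is a total, idempotent transformation of one field value
(failures map to missing rather than raising), and a
:class:`CleaningPlan` composes techniques into the three graded presets
studied by the package's experiments:

* ``none``    — the dataset untouched;
* ``minimal`` — invalid dates of birth and invalid postcodes removed,
  punctuation and spaces stripped from name fields;
* ``high``    — minimal, plus nicknames mapped to their canonical name
  and missing sex imputed from the forename.

Cleaning never alters ``rec_id`` or ``entity_id``, and plan application
returns a new dataset, leaving the input untouched.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from importlib import resources

import pandas as pd

__all__ = [
    "reformat_date",
    "remove_punctuation",
    "InvalidValueList",
    "remove_invalid_values",
    "NicknameTable",
    "nickname_lookup",
    "default_nickname_table",
    "default_invalid_values",
    "SexImputationTable",
    "build_sex_table",
    "impute_sex",
    "CleaningPlan",
    "preset_plan",
    "apply_plan",
]

DEFAULT_DATE_DIALECTS = ("%Y-%m-%d", "%d/%m/%Y", "%d/%m/%y", "%d %B %Y", "%d %b %Y")

_ORDINAL = re.compile(r"(\d{1,2})(ST|ND|RD|TH)\b", re.IGNORECASE)


def reformat_date(
    raw,
    dialects: tuple[str, ...] = DEFAULT_DATE_DIALECTS,
    two_digit_pivot: int = 30,
) -> str | None:
    """Parse a date string against an ordered list of dialects.

    The first dialect that parses wins; output is ISO-8601.  Ordinal
    suffixes (``11th August 1986``) are stripped before parsing.
    Two-digit years at or below ``two_digit_pivot`` fall in the 2000s,
    the rest in the 1900s.  Unparseable or impossible calendar dates
    (``31/02/1990``) return ``None``.
    """
    if not dialects:
        raise ValueError("dialects must be non-empty")
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = _ORDINAL.sub(r"\1", str(raw).strip())
    if not text:
        return None
    for fmt in dialects:
        try:
            parsed = datetime.strptime(text, fmt)
        except ValueError:
            continue
        year = parsed.year
        if "%y" in fmt:
            yy = year % 100
            year = 2000 + yy if yy <= two_digit_pivot else 1900 + yy
        return f"{year:04d}-{parsed.month:02d}-{parsed.day:02d}"
    return None


def remove_punctuation(raw) -> str | None:
    """Upper-case and strip every character outside A-Z; empty -> missing."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    cleaned = re.sub(r"[^A-Z]", "", str(raw).upper())
    return cleaned or None


@dataclass
class InvalidValueList:
    """Exact values and anchored wildcard patterns marking a field invalid."""

    field_name: str
    exact_values: frozenset[str] = frozenset()
    patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.exact_values = frozenset(v.strip().upper() for v in self.exact_values)
        self.patterns = tuple(p.strip().upper() for p in self.patterns)

    def matches(self, raw) -> bool:
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            return False
        text = str(raw).strip().upper()
        if text in self.exact_values:
            return True
        return any(fnmatch.fnmatchcase(text, p) for p in self.patterns)

    @classmethod
    def from_lines(cls, field_name: str, lines) -> "InvalidValueList":
        exact, patterns = [], []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            (patterns if ("*" in line or "?" in line) else exact).append(line)
        return cls(field_name, frozenset(exact), tuple(patterns))


def remove_invalid_values(raw, invalid: InvalidValueList):
    """Missing iff the value matches the invalid list; otherwise unchanged."""
    return None if invalid.matches(raw) else raw


def default_invalid_values() -> dict[str, InvalidValueList]:
    out = {}
    for field_name, fname in [
        ("postcode", "invalid_postcode.txt"),
        ("first_name", "invalid_name.txt"),
        ("address", "invalid_address.txt"),
    ]:
        text = resources.files("linklab.data").joinpath(fname).read_text()
        out[field_name] = InvalidValueList.from_lines(field_name, text.splitlines())
    return out


@dataclass
class NicknameTable:
    """Case-folded nickname -> canonical forename map; chain-free."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        self.entries = {k.strip().upper(): v.strip().upper() for k, v in self.entries.items()}
        chained = [k for k, v in self.entries.items() if v in self.entries]
        if chained:
            raise ValueError(f"nickname table has chained entries: {sorted(chained)[:5]}")


def nickname_lookup(name, table: NicknameTable):
    """Canonicalise a nickname; unknown names pass through upper-cased."""
    if name is None or (isinstance(name, float) and pd.isna(name)):
        return None
    text = str(name).strip().upper()
    return table.entries.get(text, text)


def default_nickname_table() -> NicknameTable:
    text = resources.files("linklab.data").joinpath("nicknames.csv").read_text()
    entries = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        nick, canon = line.split(",")
        entries[nick] = canon
    return NicknameTable(entries)


@dataclass
class SexImputationTable:
    """Forename -> (majority sex, support count, majority proportion >= 0.5)."""

    entries: dict[str, tuple[str, int, float]]

    def lookup(self, name) -> tuple[str, int, float] | None:
        if name is None or (isinstance(name, float) and pd.isna(name)):
            return None
        return self.entries.get(str(name).strip().upper())


def build_sex_table(ds: pd.DataFrame, min_support: int = 1) -> SexImputationTable:
    """Majority sex per forename from the dataset's own records.

    Only records with both forename and sex present contribute; names
    with fewer than ``min_support`` such records are omitted.  Exact
    50/50 names get proportion 0.5 (callers treat them as ambiguous).
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    sub = ds[["first_name", "sex"]].dropna()
    sub = sub[sub["sex"].isin(["M", "F"])]
    entries: dict[str, tuple[str, int, float]] = {}
    grouped = sub.groupby(sub["first_name"].str.strip().str.upper())["sex"]
    for name, sexes in grouped:
        support = len(sexes)
        if support < min_support:
            continue
        n_m = int((sexes == "M").sum())
        prop = max(n_m, support - n_m) / support
        majority = "M" if n_m * 2 >= support else "F"
        entries[name] = (majority, support, prop)
    return SexImputationTable(entries)


def impute_sex(
    rec: dict | pd.Series,
    table: SexImputationTable,
    min_proportion: float = 0.9,
) -> dict:
    """Fill a missing sex from the forename's majority sex.

    Non-missing sex is never overwritten; imputation requires the name
    to be in the table with majority proportion strictly above 0.5 and
    at least ``min_proportion``.
    """
    out = dict(rec)
    sex = out.get("sex")
    if sex is not None and not (isinstance(sex, float) and pd.isna(sex)):
        return out
    entry = table.lookup(out.get("first_name"))
    if entry is None:
        return out
    majority, _support, prop = entry
    if prop > 0.5 and prop >= min_proportion:
        out["sex"] = majority
    return out


# ---------------------------------------------------------------------------
# plans

NAME_FIELDS = ("first_name", "surname")


@dataclass
class CleaningPlan:
    """Ordered list of (technique id, target fields, parameters)."""

    name: str
    steps: list[tuple[str, tuple[str, ...], dict]] = dc_field(default_factory=list)


TECHNIQUES = (
    "remove_invalid_dates",
    "remove_invalid_values",
    "remove_punctuation",
    "nickname_lookup",
    "sex_imputation",
    "soundex_encode",
    "nysiis_encode",
)


def preset_plan(
    name: str,
    nickname_table: NicknameTable | None = None,
    invalid_values: dict[str, InvalidValueList] | None = None,
    sex_min_proportion: float = 0.5,
    sex_min_support: int = 1,
) -> CleaningPlan:
    """The graded presets ``none`` / ``minimal`` / ``high``.

    ``high`` imputes sex by simple forename majority (strict majority,
    any support) to mirror the most-common-value rule; pass a higher
    ``sex_min_proportion``/``sex_min_support`` for a conservative variant.
    """
    if name == "none":
        return CleaningPlan("none", [])
    invalid = invalid_values if invalid_values is not None else default_invalid_values()
    minimal_steps = [
        ("remove_invalid_dates", ("dob",), {}),
        ("remove_invalid_values", ("postcode",), {"invalid": invalid["postcode"]}),
        ("remove_punctuation", NAME_FIELDS, {}),
    ]
    if name == "minimal":
        return CleaningPlan("minimal", minimal_steps)
    if name == "high":
        nick = nickname_table if nickname_table is not None else default_nickname_table()
        return CleaningPlan(
            "high",
            minimal_steps
            + [
                ("nickname_lookup", ("first_name",), {"table": nick}),
                (
                    "sex_imputation",
                    ("sex",),
                    {
                        "min_proportion": sex_min_proportion,
                        "min_support": sex_min_support,
                    },
                ),
            ],
        )
    raise ValueError(f"unknown preset {name!r}")


def _apply_technique(df: pd.DataFrame, technique: str, fields, params: dict) -> int:
    """Apply one technique in place; returns the number of changed cells."""
    from .phonetics import nysiis, soundex

    changed = 0
    if technique == "sex_imputation":
        table = params.get("table") or build_sex_table(
            df, min_support=params.get("min_support", 1)
        )
        min_prop = params.get("min_proportion", 0.5)
        missing = df["sex"].isna()
        for idx in df.index[missing]:
            entry = table.lookup(df.at[idx, "first_name"])
            if entry is not None and entry[2] > 0.5 and entry[2] >= min_prop:
                df.at[idx, "sex"] = entry[0]
                changed += 1
        return changed

    per_value = {
        "remove_invalid_dates": lambda v: reformat_date(
            v, params.get("dialects", DEFAULT_DATE_DIALECTS)
        )
        and v,  # keep the original string when valid, else missing
        "remove_invalid_values": lambda v: remove_invalid_values(v, params["invalid"]),
        "remove_punctuation": remove_punctuation,
        "nickname_lookup": lambda v: nickname_lookup(v, params["table"]),
        "soundex_encode": soundex,
        "nysiis_encode": nysiis,
    }
    if technique not in per_value:
        raise ValueError(f"unknown technique {technique!r}")
    fn = per_value[technique]
    for f in fields:
        if f not in df.columns:
            raise ValueError(f"field {f!r} not in dataset")
        old = df[f]
        new = old.map(lambda v: fn(v) if not pd.isna(v) else None)
        changed += int((old.fillna("\0") != new.fillna("\0")).sum())
        df[f] = new
    return changed


def apply_plan(ds: pd.DataFrame, plan: CleaningPlan) -> tuple[pd.DataFrame, dict]:
    """Apply a cleaning plan to a copy of the dataset.

    Returns the cleaned dataset and a log of per-step change counts.
    Identifier columns are never touched.
    """
    df = ds.copy()
    log = {"plan": plan.name, "steps": []}
    for technique, fields, params in plan.steps:
        if any(f in ("rec_id", "entity_id") for f in fields):
            raise ValueError("cleaning must not target identifier columns")
        n = _apply_technique(df, technique, fields, params)
        log["steps"].append({"technique": technique, "fields": list(fields), "changed": n})
    return df, log
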