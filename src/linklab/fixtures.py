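"""Deterministic desk-scale fixture dataset.

``fixture_small`` builds a 200-record dataset that provably exercises
every error operator the generator knows: 120 originals are drawn from
the packaged tables, then 80 duplicates are created by cycling through
the error-type list and forcing one occurrence each (on a record whose
fields make the operator applicable), so provenance tags contain at
least one instance of every type at any seed.  Oracle tests use it as a
small stand-in for a full generated file.
"""

from __future__ import annotations

import numpy as np

from .cleaning import default_nickname_table
from .freq import default_tables
from .synthetic import (
    ERROR_TYPES,
    ErrorModel,
    SyntheticDataset,
    generate_originals,
    make_duplicate,
    true_pair_count,
)

__all__ = ["fixture_small"]

# a canonical field on which each operator is always applicable
_FORCE_FIELD = {
    "typo_insert": "surname",
    "typo_delete": "first_name",
    "typo_substitute": "surname",
    "typo_transpose": "postcode",
    "phonetic_misspelling": "surname",
    "nickname_substitution": "first_name",
    "name_reversal": "first_name",
    "surname_change": "surname",
    "postcode_change": "postcode",
    "set_missing": "postcode",
    "hyphenation": "surname",
}


def fixture_small(seed: int = 0, n_total: int = 200, n_originals: int = 120) -> SyntheticDataset:
    """Deterministic dataset with elevated error rates and full coverage."""
    rng = np.random.default_rng(seed)
    tables = default_tables()
    originals = generate_originals(
        n_originals,
        tables,
        rng,
        missing_rates={"surname": 0.02, "first_name": 0.02, "sex": 0.05,
                       "dob": 0.01, "postcode": 0.02},
    )
    nick_canonicals = sorted(set(default_nickname_table().entries.values()))
    model = ErrorModel()
    rows = []
    errors = []
    n_dups = n_total - n_originals
    for j in range(n_dups):
        etype = ERROR_TYPES[j % len(ERROR_TYPES)]
        field = _FORCE_FIELD[etype]
        i = j % n_originals
        row = originals.iloc[i].to_dict()
        # make the forced operator applicable in place on the original
        if row.get(field) is None or (field == "first_name" and row.get("surname") is None):
            row[field] = "SMITH" if field != "postcode" else "6000"
            originals.iloc[i, originals.columns.get_loc(field)] = row[field]
        if etype == "nickname_substitution":
            canon = nick_canonicals[int(rng.integers(0, len(nick_canonicals)))]
            row["first_name"] = canon
            originals.iloc[i, originals.columns.get_loc("first_name")] = canon
        if etype == "name_reversal" and row.get("surname") is None:
            row["surname"] = "JONES"
            originals.iloc[i, originals.columns.get_loc("surname")] = "JONES"
        for attempt in range(20):  # a draw can no-op (e.g. resampled same value)
            rec, applied = make_duplicate(
                row, model, rng, tables,
                record_id=f"rec-{i}-dup-{j}", forced=(field, etype),
            )
            if any(e["type"] == etype for e in applied):
                break
        rows.append(rec)
        errors.extend({"rec_id": rec["rec_id"], **e} for e in applied)

    import pandas as pd

    df = pd.concat([originals, pd.DataFrame(rows, columns=originals.columns)],
                   ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    ds = SyntheticDataset(
        df,
        {
            "generator": "linklab.fixtures.fixture_small",
            "seed": seed,
            "n_originals": n_originals,
            "n_duplicates": n_dups,
            "errors": errors,
            "error_types_present": sorted({e["type"] for e in errors}),
            "true_pairs": true_pair_count(df["entity_id"]),
        },
    )
    missing = set(ERROR_TYPES) - set(ds.provenance["error_types_present"])
    if missing:  # pragma: no cover - construction guarantees coverage
        raise AssertionError(f"fixture failed to exercise error types: {missing}")
    return ds
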