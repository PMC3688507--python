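import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for reference_impls

from linklab import GeneratorConfig, generate_dataset
from linklab.fixtures import fixture_small


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Tiny hand-built dataset; fills rec ids when absent."""
    df = pd.DataFrame(rows)
    if "rec_id" not in df.columns:
        df.insert(0, "rec_id", [f"r{i}" for i in range(len(df))])
    for col in ("entity_id", "first_name", "surname", "sex", "dob", "postcode"):
        if col not in df.columns:
            df[col] = None
    return df.astype(object).where(df.notna(), None)


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic 200-record dataset exercising every error operator."""
    return fixture_small(seed=3)


@pytest.fixture(scope="session")
def midsize_dataset():
    """A 2,000-record generated dataset shared by slower unit tests."""
    return generate_dataset(GeneratorConfig(n_total=2000, seed=7), record_errors=True)


@pytest.fixture(scope="session")
def name_corpus():
    """1,000-name fuzz corpus: table draws plus corrupted variants."""
    from linklab.freq import default_tables
    from linklab.synthetic import _phonetic, _typo

    rng = np.random.default_rng(12345)
    tables = default_tables()
    base = list(tables["surname"].sample(rng, 400)) + list(
        tables["first_name_m"].sample(rng, 150)
    ) + list(tables["first_name_f"].sample(rng, 150))
    out = [str(v) for v in base]
    for v in base[:300]:
        kind = rng.choice(["typo_insert", "typo_delete", "typo_substitute", "typo_transpose"])
        mutated = _typo(str(v), str(kind), rng) if rng.random() < 0.7 else _phonetic(str(v), rng)
        out.append(mutated)
    return out[:1000]
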