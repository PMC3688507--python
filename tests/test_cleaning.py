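import pandas as pd
import pytest

from conftest import make_records
from linklab import (
    InvalidValueList,
    NicknameTable,
    apply_plan,
    build_sex_table,
    impute_sex,
    nickname_lookup,
    preset_plan,
    reformat_date,
    remove_invalid_values,
    remove_punctuation,
)
from linklab.cleaning import CleaningPlan, default_invalid_values, default_nickname_table


class TestReformatDate:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("11/08/86", "1986-08-11"),  # day-first, two-digit pivot
            ("11th August 1986", "1986-08-11"),
            ("1986-08-11", "1986-08-11"),
            ("31/02/1990", None),  # impossible calendar date
            ("05/07/12", "2012-07-05"),  # <= pivot -> 2000s
            ("not a date", None),
            ("", None),
            (None, None),
        ],
    )
    def test_dialects(self, raw, expected):
        assert reformat_date(raw) == expected

    def test_dialect_order_wins(self):
        # ambiguous 03/04: the first listed dialect decides the reading
        assert reformat_date("03/04/2000", dialects=("%m/%d/%Y", "%d/%m/%Y")) == "2000-03-04"
        assert reformat_date("03/04/2000", dialects=("%d/%m/%Y", "%m/%d/%Y")) == "2000-04-03"

    def test_empty_dialects_rejected(self):
        with pytest.raises(ValueError):
            reformat_date("x", dialects=())


def test_remove_punctuation_examples():
    assert remove_punctuation("O'Brien-Smith") == "OBRIENSMITH"
    assert remove_punctuation("MARY ANNE") == "MARYANNE"
    assert remove_punctuation("---") is None
    assert remove_punctuation(None) is None


def test_remove_invalid_values_exact_and_patterns():
    invalid = default_invalid_values()
    assert remove_invalid_values("9999", invalid["postcode"]) is None
    assert remove_invalid_values("6000", invalid["postcode"]) == "6000"
    assert remove_invalid_values("NO FIXED ADDRESS", invalid["address"]) is None
    assert remove_invalid_values("TWIN ONE OF MARTHA", invalid["first_name"]) is None
    assert remove_invalid_values("MARTHA", invalid["first_name"]) == "MARTHA"
    # case-insensitive after trim
    assert remove_invalid_values("  baby of rachael ", invalid["first_name"]) is None


def test_nickname_lookup_examples():
    table = default_nickname_table()
    assert nickname_lookup("BILL", table) == "WILLIAM"
    assert nickname_lookup("bill", table) == "WILLIAM"
    assert nickname_lookup("WILLIAM", table) == "WILLIAM"  # canonical fixed point
    assert nickname_lookup("XQZR", table) == "XQZR"  # unknown passthrough
    assert nickname_lookup(None, table) is None


def test_nickname_table_rejects_chains():
    with pytest.raises(ValueError, match="chain"):
        NicknameTable({"A": "B", "B": "C"})


def test_build_sex_table_majorities():
    rows = (
        [{"first_name": "PAT", "sex": "M"}] * 80
        + [{"first_name": "PAT", "sex": "F"}] * 20
        + [{"first_name": "RARE", "sex": "M"}]
        + [{"first_name": "SAM", "sex": "M"}] * 50
        + [{"first_name": "SAM", "sex": "F"}] * 50
    )
    ds = make_records(rows)
    table = build_sex_table(ds, min_support=5)
    assert table.entries["PAT"] == ("M", 100, 0.8)
    assert "RARE" not in table.entries  # below support
    assert table.entries["SAM"][2] == 0.5  # ambiguous tie


def test_impute_sex_rules():
    table = build_sex_table(
        make_records(
            [{"first_name": "JOHN", "sex": "M"}] * 98
            + [{"first_name": "JOHN", "sex": "F"}] * 2
            + [{"first_name": "SAM", "sex": "M"}] * 5
            + [{"first_name": "SAM", "sex": "F"}] * 5
        )
    )
    rec = {"first_name": "JOHN", "sex": None}
    assert impute_sex(rec, table, min_proportion=0.9)["sex"] == "M"
    # never overwrites a present value
    assert impute_sex({"first_name": "JOHN", "sex": "F"}, table)["sex"] == "F"
    # ambiguous name stays missing
    assert impute_sex({"first_name": "SAM", "sex": None}, table, 0.5)["sex"] is None
    # unknown name stays missing
    assert impute_sex({"first_name": "ZZZ", "sex": None}, table)["sex"] is None


def test_plan_none_is_identity(midsize_dataset):
    cleaned, log = apply_plan(midsize_dataset.records, preset_plan("none"))
    pd.testing.assert_frame_equal(cleaned, midsize_dataset.records)
    assert log["steps"] == []


def test_plan_minimal_composition():
    ds = make_records(
        [{"entity_id": "e0", "surname": "O'NEIL", "postcode": "9999", "dob": "1990-02-31"}]
    )
    cleaned, _ = apply_plan(ds, preset_plan("minimal"))
    row = cleaned.iloc[0]
    assert row["surname"] == "ONEIL"
    assert row["postcode"] is None
    assert row["dob"] is None  # impossible date removed


def test_plan_minimal_keeps_valid_values():
    ds = make_records(
        [{"entity_id": "e0", "surname": "SMITH", "postcode": "6000", "dob": "1990-02-28"}]
    )
    cleaned, _ = apply_plan(ds, preset_plan("minimal"))
    row = cleaned.iloc[0]
    assert (row["surname"], row["postcode"], row["dob"]) == ("SMITH", "6000", "1990-02-28")


def test_plan_high_nickname_and_sex_imputation():
    rows = [{"entity_id": f"e{i}", "first_name": "WILLIAM", "sex": "M"} for i in range(20)]
    rows.append({"entity_id": "e99", "first_name": "BILL", "sex": None})
    ds = make_records(rows)
    cleaned, _ = apply_plan(ds, preset_plan("high"))
    target = cleaned[cleaned["entity_id"] == "e99"].iloc[0]
    assert target["first_name"] == "WILLIAM"
    assert target["sex"] == "M"  # imputed from the canonicalised name


def test_plans_never_touch_identifiers(midsize_dataset):
    for name in ("minimal", "high"):
        cleaned, _ = apply_plan(midsize_dataset.records, preset_plan(name))
        assert (cleaned["rec_id"] == midsize_dataset.records["rec_id"]).all()
        assert (cleaned["entity_id"] == midsize_dataset.records["entity_id"]).all()


@pytest.mark.parametrize("plan_name", ["none", "minimal", "high"])
def test_plan_idempotence(midsize_dataset, plan_name):
    """Applying a shipped plan twice equals applying it once."""
    plan = preset_plan(plan_name)
    once, _ = apply_plan(midsize_dataset.records, plan)
    twice, _ = apply_plan(once, plan)
    pd.testing.assert_frame_equal(once, twice)


@pytest.mark.parametrize("technique,params", [
    ("remove_punctuation", {}),
    ("soundex_encode", {}),
    ("nickname_lookup", {"table": None}),
])
def test_variability_never_increases(midsize_dataset, technique, params):
    """Merging transformations cannot grow a field's distinct-value count."""
    if technique == "nickname_lookup":
        params = {"table": default_nickname_table()}
    df = midsize_dataset.records
    plan = CleaningPlan("t", [(technique, ("first_name", "surname"), params)])
    cleaned, _ = apply_plan(df, plan)
    for f in ("first_name", "surname"):
        assert cleaned[f].nunique() <= df[f].nunique()


def test_invalid_removal_missingness_monotone(midsize_dataset):
    df = midsize_dataset.records
    plan = CleaningPlan(
        "inv", [("remove_invalid_values", ("postcode",), {"invalid": default_invalid_values()["postcode"]})]
    )
    cleaned, _ = apply_plan(df, plan)
    assert cleaned["postcode"].isna().sum() >= df["postcode"].isna().sum()
    # values not on the list are untouched
    keep = df["postcode"].notna() & cleaned["postcode"].notna()
    assert (df.loc[keep, "postcode"] == cleaned.loc[keep, "postcode"]).all()


def test_unknown_technique_rejected():
    ds = make_records([{"entity_id": "e0", "surname": "X"}])
    with pytest.raises(ValueError, match="unknown technique"):
        apply_plan(ds, CleaningPlan("bad", [("frobnicate", ("surname",), {})]))


def test_invalid_value_list_wildcards():
    lst = InvalidValueList("first_name", frozenset({"UNKNOWN"}), ("TWIN * OF *",))
    assert lst.matches("twin one of martha")
    assert lst.matches(" UNKNOWN ")
    assert not lst.matches("TWINKLE")
    assert not lst.matches(None)
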