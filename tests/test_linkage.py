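import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_records
from linklab import (
    BlockingScheme,
    FieldComparatorSpec,
    FieldWeights,
    candidate_pairs,
    classify,
    estimate_weights,
    score_pairs,
    sweep_threshold,
)
from linklab.linkage import comparison_values, default_comparators
from linklab.synthetic import true_pair_count
from reference_impls import candidate_pairs_brute


def test_field_weights_closed_forms():
    w = FieldWeights("f", m=0.9, u=0.1)
    assert w.agreement_weight == pytest.approx(math.log2(9))
    assert w.disagreement_weight == pytest.approx(-math.log2(9))
    z = FieldWeights("f", m=0.3, u=0.3)
    assert z.agreement_weight == 0 and z.disagreement_weight == 0


def test_blocking_examples():
    ds = make_records(
        [
            {"surname": "AAA", "first_name": "X", "dob": "1980-01-01"},
            {"surname": "BBB", "first_name": "Y", "dob": "1980-01-01"},
            {"surname": "CCC", "first_name": "Z", "dob": "1980-01-01"},
        ]
    )
    pairs = candidate_pairs(ds)
    assert len(pairs) == 3  # C(3,2) via the shared birth date


def test_pair_in_both_blocks_counted_once():
    ds = make_records(
        [
            {"surname": "SMITH", "first_name": "ANN", "dob": "1980-01-01"},
            {"surname": "SMITH", "first_name": "ANNA", "dob": "1980-01-01"},
        ]
    )
    assert candidate_pairs(ds) == {("r0", "r1")}


def test_missing_key_fields_join_no_block():
    ds = make_records(
        [
            {"surname": None, "first_name": "ANN", "dob": None},
            {"surname": "SMITH", "first_name": "ANN", "dob": "1980-01-01"},
            {"surname": "SMITH", "first_name": "ANN", "dob": "1980-01-01"},
        ]
    )
    pairs = candidate_pairs(ds)
    assert pairs == {("r1", "r2")}


def test_candidate_pairs_equal_brute_force(small_fixture):
    ds = small_fixture.records
    scheme = BlockingScheme()
    fast = candidate_pairs(ds, scheme)
    brute = candidate_pairs_brute(
        ds, [scheme.key_series(ds, k) for k in scheme.keys]
    )
    assert fast == brute


def test_truth_counting_weights_closed_form():
    # 100 entities of size 2, field uniform over 100 values, all true pairs agree
    rows = []
    for e in range(100):
        for r in range(2):
            rows.append({"rec_id": f"r{e}-{r}", "entity_id": f"e{e}", "surname": f"V{e % 100}"})
    ds = make_records(rows)
    w = estimate_weights(ds, [FieldComparatorSpec("surname", "exact")])["surname"]
    assert w.m == pytest.approx(1.0, abs=1e-5)
    assert w.u == pytest.approx(0.01, abs=1e-9)
    assert w.agreement_weight == pytest.approx(math.log2(100), abs=1e-3)


def test_truth_counting_m_counts_disagreements():
    rows = [
        {"rec_id": "a", "entity_id": "e0", "surname": "SMITH"},
        {"rec_id": "b", "entity_id": "e0", "surname": "SMYTH"},
        {"rec_id": "c", "entity_id": "e1", "surname": "JONES"},
        {"rec_id": "d", "entity_id": "e1", "surname": "JONES"},
    ]
    w = estimate_weights(make_records(rows), [FieldComparatorSpec("surname", "exact")])["surname"]
    assert w.m == pytest.approx(0.5)  # one of two true pairs agrees


def test_dob_components_compared_separately():
    ds = make_records([{"dob": "1986-08-11"}, {"dob": "1986-11-08"}])
    assert list(comparison_values(ds, "dob_year")) == ["1986", "1986"]
    assert list(comparison_values(ds, "dob_month")) == ["08", "11"]
    assert list(comparison_values(ds, "dob_day")) == ["11", "08"]
    assert comparison_values(make_records([{"dob": None}]), "dob_day")[0] is None


def unit_weights(fields):
    return {f: FieldWeights(f, 0.9, 0.1) for f in fields}


BASIC = [FieldComparatorSpec("surname", "string_similarity"),
         FieldComparatorSpec("postcode", "exact")]


def test_score_all_agree_sums_agreement_weights():
    ds = make_records(
        [
            {"entity_id": "e0", "surname": "SMITH", "postcode": "6000"},
            {"entity_id": "e0", "surname": "SMITH", "postcode": "6000"},
        ]
    )
    w = unit_weights(["surname", "postcode"])
    scores = score_pairs(ds, [("r0", "r1")], w, BASIC)
    expected = w["surname"].agreement_weight + w["postcode"].agreement_weight
    assert scores["score"].iloc[0] == pytest.approx(expected)
    assert bool(scores["is_true"].iloc[0])


def test_missing_value_contributes_zero():
    ds = make_records(
        [
            {"entity_id": "e0", "surname": "SMITH", "postcode": None},
            {"entity_id": "e0", "surname": "SMITH", "postcode": "6000"},
        ]
    )
    w = unit_weights(["surname", "postcode"])
    scores = score_pairs(ds, [("r0", "r1")], w, BASIC)
    assert scores["score"].iloc[0] == pytest.approx(w["surname"].agreement_weight)


def test_string_similarity_interpolation_boundaries():
    from linklab import jaro_winkler

    w = unit_weights(["surname"])
    spec = [FieldComparatorSpec("surname", "string_similarity", similarity_floor=0.7)]
    wa, wd = w["surname"].agreement_weight, w["surname"].disagreement_weight

    ds = make_records([{"surname": "SMITH"}, {"surname": "SMITH"}])
    assert score_pairs(ds, [("r0", "r1")], w, spec)["score"].iloc[0] == pytest.approx(wa)

    ds = make_records([{"surname": "ABC"}, {"surname": "XYZ"}])  # sim 0 <= floor
    assert score_pairs(ds, [("r0", "r1")], w, spec)["score"].iloc[0] == pytest.approx(wd)

    ds = make_records([{"surname": "SMITH"}, {"surname": "SMYTHE"}])
    sim = jaro_winkler("SMITH", "SMYTHE")
    assert 0.7 < sim < 1.0
    expected = wa - (wa - wd) * (1 - sim) / (1 - 0.7)
    assert score_pairs(ds, [("r0", "r1")], w, spec)["score"].iloc[0] == pytest.approx(expected)


def test_score_is_symmetric(small_fixture):
    ds = small_fixture.records
    weights = estimate_weights(ds)
    pairs = sorted(candidate_pairs(ds))[:50]
    fwd = score_pairs(ds, pairs, weights)
    rev_ds = ds.iloc[::-1].reset_index(drop=True)
    rev = score_pairs(rev_ds, pairs, weights)
    assert np.allclose(fwd["score"], rev["score"])


def test_classify_strict_inequality_and_monotone():
    scores = pd.DataFrame({"id_a": ["a", "b"], "id_b": ["x", "y"], "score": [5.0, 7.0]})
    assert len(classify(scores, 5.0)) == 1  # equal-to-threshold excluded
    assert len(classify(scores, 4.0)) == 2
    m1 = set(map(tuple, classify(scores, 4.0)[["id_a", "id_b"]].values))
    m2 = set(map(tuple, classify(scores, 6.0)[["id_a", "id_b"]].values))
    assert m2 <= m1


def make_scores(vals, truths):
    return pd.DataFrame(
        {
            "id_a": [f"a{i}" for i in range(len(vals))],
            "id_b": [f"b{i}" for i in range(len(vals))],
            "score": vals,
            "is_true": truths,
        }
    )


def test_sweep_finds_unimodal_peak():
    """Grid-search oracle: the walk must land on the brute-force argmax."""
    scores = make_scores(
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [False, False, False, True, True, True]
    )
    total_true = 3
    res = sweep_threshold(scores, total_true, start=1.0, step=0.5, patience=10)
    from linklab.evaluation import pairwise_metrics_from_scores

    grid = np.arange(-2.0, 10.0, 0.5)
    best = max(grid, key=lambda t: (pairwise_metrics_from_scores(scores, total_true, t).f_measure, -t))
    assert res.best_threshold == pytest.approx(best)
    assert res.best_metrics.f_measure == pytest.approx(1.0)
    assert set(res.trace.columns) == {"threshold", "precision", "recall", "f_measure"}


def test_sweep_flat_curve_returns_start():
    scores = make_scores([10.0, 10.0], [True, True])
    res = sweep_threshold(scores, 2, start=3.0, step=0.5, patience=3)
    assert res.best_threshold == 3.0


def test_sweep_patience_can_miss_distant_peak():
    """A dip longer than the patience hides a further peak; the trace records it."""
    scores = make_scores(
        [1.0, 2.0, 3.0, 4.0, 5.0], [True, False, False, False, True]
    )
    # t<1: P=2/5,R=1,F=4/7; the curve dips through the false positives and
    # peaks again at t in [4,5): P=1,R=1/2,F=2/3
    res_impatient = sweep_threshold(scores, 2, start=0.0, step=0.5, patience=1)
    res_patient = sweep_threshold(scores, 2, start=0.0, step=0.5, patience=12)
    assert res_impatient.best_metrics.f_measure == pytest.approx(4 / 7)
    assert res_patient.best_metrics.f_measure == pytest.approx(2 / 3)
    assert res_patient.best_threshold == pytest.approx(4.0)
    assert (res_impatient.trace["threshold"] <= 1.0).all()


def test_sweep_requires_scores():
    with pytest.raises(ValueError):
        sweep_threshold(make_scores([], []), 0, start=0.0)


def test_em_weights_recover_separation(midsize_dataset):
    """EM without truth should broadly agree with truth-counted estimates.

    Blocking-correlated fields (surname) are excluded: among blocked
    non-matches surname agreement is common by construction.
    """
    ds = midsize_dataset.records
    em = estimate_weights(ds, method="em")
    truth = estimate_weights(ds, method="truth_counting")
    for f in ("first_name", "dob_year", "dob_month", "dob_day", "postcode"):
        assert em[f].m > em[f].u  # agreement is evidence for a match
        assert abs(em[f].m - truth[f].m) < 0.15


def test_true_pairs_outscore_random_pairs_on_clean_data():
    """With truth-counted weights on error-free duplicates, separation is total."""
    rng = np.random.default_rng(0)
    rows = []
    for e in range(30):
        base = {
            "first_name": f"NAME{e}",
            "surname": f"SURN{e}",
            "sex": "M" if e % 2 else "F",
            "dob": f"19{50 + e % 40:02d}-01-{1 + e % 27:02d}",
            "postcode": f"6{e:03d}",
        }
        rows.append({"rec_id": f"r{e}a", "entity_id": f"e{e}", **base})
        rows.append({"rec_id": f"r{e}b", "entity_id": f"e{e}", **base})
    ds = make_records(rows)
    weights = estimate_weights(ds)
    ids = list(ds["rec_id"])
    pairs = {(a, b) for a, b in zip(ids, ids[1:])} | {
        (ids[i], ids[j]) for i, j in zip(rng.integers(0, 60, 40), rng.integers(0, 60, 40)) if ids[i] < ids[j]
    }
    pairs = {tuple(sorted(p)) for p in pairs if p[0] != p[1]}
    scores = score_pairs(ds, sorted(pairs), weights)
    true_scores = scores.loc[scores["is_true"], "score"]
    false_scores = scores.loc[~scores["is_true"], "score"]
    assert true_scores.min() > false_scores.max()


def test_recall_degrades_with_error_rate():
    """More injected error means fewer true pairs found at the swept threshold."""
    from linklab import ErrorModel, GeneratorConfig, generate_dataset

    recalls = []
    for scale in (0.4, 0.8, 1.2):
        em = ErrorModel(
            errors_per_duplicate={
                0: max(0.0, 1 - 0.3 * scale - 0.25 * scale - 0.1 * scale),
                1: 0.3 * scale,
                2: 0.25 * scale,
                3: 0.1 * scale,
            }
        )
        ds = generate_dataset(GeneratorConfig(n_total=1500, seed=21, error_model=em))
        weights = estimate_weights(ds.records)
        pairs = candidate_pairs(ds.records)
        scores = score_pairs(ds.records, pairs, weights)
        start = sum(w.agreement_weight for w in weights.values()) / 2
        res = sweep_threshold(scores, ds.true_pair_count(), start=start)
        recalls.append(res.best_metrics.recall)
    assert recalls[0] > recalls[1] > recalls[2]
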