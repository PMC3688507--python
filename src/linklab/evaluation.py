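"""Linkage-quality statistics.

Quality is measured pairwise against truth labels: precision is the
share of declared pairs that are true, recall the share of true pairs
that were declared, and the F-measure their harmonic mean.  The same
three statistics applied to the rule "two records agree exactly on this
field" give a field's *predictive ability*, which is how the effect of
an individual cleaning technique is quantified: the relative change in
the field's F before and after the transformation.

All counting statistics are computed from value/entity frequency
identities (sums of C(k,2)) rather than pair enumeration, so they scale
to large files, and they agree exactly with brute-force enumeration on
small ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaning import CleaningPlan, apply_plan
from .linkage import (
    BlockingScheme,
    FieldComparatorSpec,
    candidate_pairs,
    default_comparators,
    estimate_weights,
    score_pairs,
    sweep_threshold,
)
from .synthetic import true_pair_count

__all__ = [
    "QualityMetrics",
    "VariablePredictiveness",
    "TechniqueReport",
    "f_measure",
    "relative_change_pct",
    "pairwise_metrics",
    "pairwise_metrics_from_scores",
    "variable_predictiveness",
    "technique_report",
    "overall_quality_experiment",
]


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2pr/(p+r); 0 when both rates are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def relative_change_pct(before: float, after: float) -> float:
    """Relative (not percentage-point) change, in percent."""
    if before == 0:
        raise ZeroDivisionError("relative change undefined for a zero baseline")
    return 100.0 * (after - before) / before


@dataclass
class QualityMetrics:
    true_positives: int
    false_positives: int
    false_negatives: int
    zero_division: bool = False  # set when precision hit the 0/0 convention

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def f_measure(self) -> float:
        return f_measure(self.precision, self.recall)


def _truth_map(ds: pd.DataFrame) -> dict[str, object]:
    if "entity_id" not in ds.columns:
        raise ValueError("dataset has no entity_id truth column")
    return dict(zip(ds["rec_id"], ds["entity_id"]))


def pairwise_metrics(predicted_pairs, ds: pd.DataFrame) -> QualityMetrics:
    """Compare a declared pair set against the dataset's truth labels.

    The recall denominator is every truth pair in the dataset, whether
    or not it was ever a candidate.
    """
    ent = _truth_map(ds)
    tp = 0
    for a, b in predicted_pairs:
        if a not in ent or b not in ent:
            raise ValueError(f"pair references unknown rec_id: {(a, b)}")
        ea, eb = ent[a], ent[b]
        if ea is not None and not pd.isna(ea) and ea == eb:
            tp += 1
    n_pred = len(predicted_pairs)
    total_true = true_pair_count(ds["entity_id"])
    zero_div = n_pred == 0
    return QualityMetrics(tp, n_pred - tp, total_true - tp, zero_division=zero_div)


def pairwise_metrics_from_scores(
    scores: pd.DataFrame, total_true_pairs: int, threshold: float
) -> QualityMetrics:
    """Metrics of ``score > threshold`` given pre-labelled scored pairs."""
    declared = scores["score"].to_numpy() > threshold
    is_true = scores["is_true"].to_numpy(bool)
    tp = int((declared & is_true).sum())
    fp = int((declared & ~is_true).sum())
    return QualityMetrics(tp, fp, total_true_pairs - tp, zero_division=not declared.any())


@dataclass
class VariablePredictiveness:
    field_name: str
    agreeing_pairs: int
    agreeing_true_pairs: int
    total_true_pairs: int

    @property
    def precision(self) -> float:
        return self.agreeing_true_pairs / self.agreeing_pairs if self.agreeing_pairs else 0.0

    @property
    def recall(self) -> float:
        return self.agreeing_true_pairs / self.total_true_pairs if self.total_true_pairs else 0.0

    @property
    def f_measure(self) -> float:
        return f_measure(self.precision, self.recall)


def variable_predictiveness(ds: pd.DataFrame, field_name: str) -> VariablePredictiveness:
    """Predictive ability of exact agreement on one field.

    Over the universe of all C(n,2) record pairs of the dataset:
    agreeing pairs are counted per shared non-missing value
    (sum of C(n_v,2)), agreeing true pairs per (entity, value) cell, and
    the recall denominator is every truth pair.  Pairs with a missing
    value never count as agreeing.
    """
    if field_name not in ds.columns:
        raise ValueError(f"unknown field {field_name!r}")
    vals = ds[field_name]
    if vals.isna().all():
        raise ValueError(f"field {field_name!r} has no values")

    def pairs_of(counts: np.ndarray) -> int:
        return int((counts.astype(np.int64) * (counts - 1) // 2).sum())

    agreeing = pairs_of(vals.dropna().value_counts().to_numpy())
    sub = ds[[field_name, "entity_id"]].dropna()
    cell = sub.groupby(["entity_id", field_name], sort=False).size().to_numpy()
    agreeing_true = pairs_of(cell)
    total_true = true_pair_count(ds["entity_id"])
    return VariablePredictiveness(field_name, agreeing, agreeing_true, total_true)


@dataclass
class TechniqueReport:
    technique: str
    per_field: pd.DataFrame  # field, f_before, f_after, pct_change (+ skipped flag)
    average_pct_change: float


def technique_report(
    ds: pd.DataFrame,
    technique: str,
    fields: tuple[str, ...],
    params: dict | None = None,
) -> TechniqueReport:
    """Relative change in per-field predictive ability under one technique.

    Runs the technique alone (as a single-step plan) on the listed
    fields and reports 100*(F_after - F_before)/F_before per field plus
    the unweighted mean over fields; a field with F_before = 0 is
    reported but excluded from the mean.
    """
    plan = CleaningPlan(f"only-{technique}", [(technique, tuple(fields), params or {})])
    cleaned, _ = apply_plan(ds, plan)
    rows = []
    changes = []
    for f in fields:
        before = variable_predictiveness(ds, f)
        after = variable_predictiveness(cleaned, f)
        row = {
            "field": f,
            "precision_before": before.precision,
            "precision_after": after.precision,
            "recall_before": before.recall,
            "recall_after": after.recall,
            "f_before": before.f_measure,
            "f_after": after.f_measure,
        }
        if before.f_measure == 0:
            row["pct_change"] = float("nan")
        else:
            row["pct_change"] = relative_change_pct(before.f_measure, after.f_measure)
            changes.append(row["pct_change"])
        rows.append(row)
    avg = float(np.mean(changes)) if changes else float("nan")
    return TechniqueReport(technique, pd.DataFrame(rows), avg)


def overall_quality_experiment(
    ds: pd.DataFrame,
    plans: list[CleaningPlan],
    scheme: BlockingScheme | None = None,
    comparators: list[FieldComparatorSpec] | None = None,
    weight_method: str = "truth_counting",
    sweep_step: float = 0.5,
    sweep_patience: int = 10,
    sweep_start: float | None = None,
) -> pd.DataFrame:
    """Best swept F-measure per cleaning plan (the overall-quality table).

    For each plan the dataset is cleaned, weights are re-estimated on
    the cleaned data, candidate pairs are blocked, scored and the
    threshold swept in 0.5-weight steps; the row records the best
    threshold and its precision/recall/F.  ``sweep_start`` defaults to
    half the summed agreement weights of the plan's own estimates.
    """
    scheme = scheme or BlockingScheme()
    comparators = comparators or default_comparators()
    total_true = true_pair_count(ds["entity_id"])
    rows = []
    for plan in plans:
        cleaned, _log = apply_plan(ds, plan)
        weights = estimate_weights(cleaned, comparators, method=weight_method)
        pairs = candidate_pairs(cleaned, scheme)
        scores = score_pairs(cleaned, pairs, weights, comparators)
        start = sweep_start
        if start is None:
            start = sum(w.agreement_weight for w in weights.values()) / 2.0
        res = sweep_threshold(scores, total_true, start, sweep_step, sweep_patience)
        rows.append(
            {
                "plan": plan.name,
                "candidate_pairs": len(pairs),
                "best_threshold": res.best_threshold,
                "precision": res.best_metrics.precision,
                "recall": res.best_metrics.recall,
                "f_measure": res.best_metrics.f_measure,
            }
        )
    return pd.DataFrame(rows)
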