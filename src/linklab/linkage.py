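"""Fellegi-Sunter probabilistic internal linkage (deduplication).

The engine follows the classical recipe: candidate pairs are drawn from
the union of blocking keys (by default Soundex of surname plus first
initial, and full date of birth); each candidate pair is compared field
by field, using Jaro-Winkler similarity for name fields and exact
comparison elsewhere, with day, month and year of birth compared
separately; per-field agreement and disagreement weights are
``log2(m/u)`` and ``log2((1-m)/(1-u))``; field scores are summed and a
pair is declared a match when its total strictly exceeds the matching
threshold.  A comparison involving a missing value contributes zero.

Weights can be estimated either by truth counting (``m`` from labelled
true pairs, ``u`` from value-frequency collision probabilities) or by a
two-class EM over agreement patterns when no truth is available.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .phonetics import soundex
from .strcompare import jaro_winkler

__all__ = [
    "BlockingScheme",
    "FieldComparatorSpec",
    "FieldWeights",
    "default_comparators",
    "comparison_values",
    "candidate_pairs",
    "estimate_weights",
    "score_pairs",
    "classify",
    "sweep_threshold",
]

_PROB_CLAMP = (1e-6, 1.0 - 1e-6)
_DOB_RE = re.compile(r"(\d+)[-/](\d+)[-/](\d+)")


@dataclass
class FieldComparatorSpec:
    field_name: str  # may be a derived component: dob_day, dob_month, dob_year
    kind: str = "exact"  # "exact" | "string_similarity"
    similarity_floor: float = 0.7

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "string_similarity"):
            raise ValueError(f"unknown comparator kind {self.kind!r}")
        if not (0.0 <= self.similarity_floor < 1.0):
            raise ValueError("similarity_floor must be in [0, 1)")


def default_comparators() -> list[FieldComparatorSpec]:
    return [
        FieldComparatorSpec("first_name", "string_similarity"),
        FieldComparatorSpec("surname", "string_similarity"),
        FieldComparatorSpec("sex", "exact"),
        FieldComparatorSpec("dob_day", "exact"),
        FieldComparatorSpec("dob_month", "exact"),
        FieldComparatorSpec("dob_year", "exact"),
        FieldComparatorSpec("postcode", "exact"),
    ]


def comparison_values(ds: pd.DataFrame, field_name: str) -> pd.Series:
    """The value series a comparator sees, deriving dob components."""
    if field_name.startswith("dob_"):
        part = {"dob_year": 0, "dob_month": 1, "dob_day": 2}[field_name]
        extracted = ds["dob"].astype("string").str.extract(_DOB_RE.pattern)
        return extracted[part].astype(object).where(extracted[part].notna(), None)
    if field_name not in ds.columns:
        raise ValueError(f"unknown field {field_name!r}")
    return ds[field_name]


@dataclass
class BlockingScheme:
    """Named blocking keys; candidate pairs are the union over keys."""

    keys: tuple[str, ...] = ("surname_soundex_first_initial", "dob")

    def key_series(self, ds: pd.DataFrame, key: str) -> pd.Series:
        if key == "surname_soundex_first_initial":
            sdx = ds["surname"].map(lambda v: None if pd.isna(v) else soundex(v))
            initial = ds["first_name"].map(
                lambda v: None if pd.isna(v) or not str(v) else str(v)[0].upper()
            )
            return pd.Series(
                [None if s is None or i is None else f"{s}|{i}" for s, i in zip(sdx, initial)],
                index=ds.index,
                dtype=object,
            )
        if key in ds.columns:
            return ds[key]
        raise ValueError(f"unknown blocking key {key!r}")


def candidate_pairs(ds: pd.DataFrame, scheme: BlockingScheme | None = None) -> set[tuple[str, str]]:
    """Unordered rec_id pairs sharing at least one blocking key.

    A record with a missing key component joins no block for that key;
    pairs found under several keys appear once.
    """
    scheme = scheme or BlockingScheme()
    ids = ds["rec_id"].to_numpy()
    pairs: set[tuple[str, str]] = set()
    for key in scheme.keys:
        series = scheme.key_series(ds, key)
        groups: dict = {}
        for rid, val in zip(ids, series):
            if val is None or (isinstance(val, float) and pd.isna(val)) or pd.isna(val):
                continue
            groups.setdefault(val, []).append(rid)
        for members in groups.values():
            if len(members) < 2:
                continue
            for a, b in itertools.combinations(members, 2):
                pairs.add((a, b) if a < b else (b, a))
    return pairs


@dataclass
class FieldWeights:
    field_name: str
    m: float
    u: float

    def __post_init__(self) -> None:
        lo, hi = _PROB_CLAMP
        self.m = min(max(self.m, lo), hi)
        self.u = min(max(self.u, lo), hi)

    @property
    def agreement_weight(self) -> float:
        return math.log2(self.m / self.u)

    @property
    def disagreement_weight(self) -> float:
        return math.log2((1.0 - self.m) / (1.0 - self.u))


def _true_pair_index(ds: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Positional index arrays (ia, ib) of all truth pairs."""
    ia, ib = [], []
    for _, idx in ds.groupby("entity_id").indices.items():
        if len(idx) > 1:
            for a, b in itertools.combinations(idx, 2):
                ia.append(a)
                ib.append(b)
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


def estimate_weights(
    ds: pd.DataFrame,
    comparators: list[FieldComparatorSpec] | None = None,
    method: str = "truth_counting",
    scheme: BlockingScheme | None = None,
    em_max_iter: int = 100,
    em_tol: float = 1e-6,
) -> dict[str, FieldWeights]:
    """Estimate m/u probabilities per compared field.

    ``truth_counting``: m is the share of labelled true pairs agreeing
    exactly on the field (string fields count similarity 1 only), over
    true pairs where both values are present; u is the value-frequency
    collision probability, the chance two random non-missing values
    coincide.  ``em``: two-class EM over exact-agreement patterns of the
    candidate pairs.  If an estimate comes out with m <= u the field is
    kept (its weights just stop rewarding agreement) and a warning is
    recorded on the result.
    """
    comparators = comparators or default_comparators()
    out: dict[str, FieldWeights] = {}
    if method == "truth_counting":
        if "entity_id" not in ds.columns or ds["entity_id"].isna().all():
            raise ValueError("truth_counting requires entity ids")
        ia, ib = _true_pair_index(ds)
        for spec in comparators:
            vals = comparison_values(ds, spec.field_name).to_numpy(object)
            if pd.isna(vals).all():
                raise ValueError(f"field {spec.field_name!r} has no values")
            a, b = vals[ia], vals[ib]
            ok = ~(pd.isna(a) | pd.isna(b))
            n_ok = int(ok.sum())
            m = float((a[ok] == b[ok]).mean()) if n_ok else 0.5
            p = pd.Series(vals).dropna().value_counts(normalize=True).to_numpy()
            u = float(np.sum(p**2))
            out[spec.field_name] = FieldWeights(spec.field_name, m, u)
        return out
    if method == "em":
        return _em_weights(ds, comparators, scheme, em_max_iter, em_tol)
    raise ValueError(f"unknown method {method!r}")


def _em_weights(ds, comparators, scheme, max_iter, tol) -> dict[str, FieldWeights]:
    pairs = sorted(candidate_pairs(ds, scheme))
    if len(pairs) < 10:
        raise ValueError("too few candidate pairs for EM")
    pos = {rid: i for i, rid in enumerate(ds["rec_id"])}
    ia = np.array([pos[a] for a, _ in pairs])
    ib = np.array([pos[b] for _, b in pairs])
    K = len(comparators)
    agree = np.zeros((len(pairs), K))
    known = np.zeros((len(pairs), K), dtype=bool)
    for k, spec in enumerate(comparators):
        vals = comparison_values(ds, spec.field_name).to_numpy(object)
        a, b = vals[ia], vals[ib]
        ok = ~(pd.isna(a) | pd.isna(b))
        known[:, k] = ok
        agree[ok, k] = (a[ok] == b[ok]).astype(float)
    m = np.full(K, 0.9)
    u = np.full(K, 0.1)
    lam = 0.05
    lo, hi = _PROB_CLAMP
    for _ in range(max_iter):
        log_m = np.where(known, agree * np.log(m) + (1 - agree) * np.log(1 - m), 0.0).sum(axis=1)
        log_u = np.where(known, agree * np.log(u) + (1 - agree) * np.log(1 - u), 0.0).sum(axis=1)
        log_post = np.log(lam) + log_m
        log_den = np.logaddexp(log_post, np.log(1 - lam) + log_u)
        g = np.exp(log_post - log_den)
        new_m = ((g[:, None] * agree * known).sum(0) / np.maximum((g[:, None] * known).sum(0), 1e-12)).clip(lo, hi)
        new_u = ((((1 - g)[:, None]) * agree * known).sum(0) / np.maximum(((1 - g)[:, None] * known).sum(0), 1e-12)).clip(lo, hi)
        new_lam = float(g.mean().clip(lo, hi))
        delta = max(np.abs(new_m - m).max(), np.abs(new_u - u).max(), abs(new_lam - lam))
        m, u, lam = new_m, new_u, new_lam
        if delta < tol:
            break
    # orient the latent classes: matches are the class agreement argues for
    if float(np.log(m / u).sum()) < 0:
        m, u, lam = u, m, 1.0 - lam
    return {
        spec.field_name: FieldWeights(spec.field_name, float(m[k]), float(u[k]))
        for k, spec in enumerate(comparators)
    }


def score_pairs(
    ds: pd.DataFrame,
    pairs,
    weights: dict[str, FieldWeights],
    comparators: list[FieldComparatorSpec] | None = None,
) -> pd.DataFrame:
    """Score candidate pairs; returns id_a, id_b, score, is_true (if truth present).

    Exact fields contribute the agreement weight on equality and the
    disagreement weight otherwise.  String fields interpolate linearly:
    similarity 1 earns the agreement weight, similarity at or below the
    floor the disagreement weight.  Missing values contribute zero.
    """
    comparators = comparators or default_comparators()
    pairs = sorted(pairs) if not isinstance(pairs, list) else pairs
    pos = {rid: i for i, rid in enumerate(ds["rec_id"])}
    try:
        ia = np.array([pos[a] for a, _ in pairs], dtype=int)
        ib = np.array([pos[b] for _, b in pairs], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"pair references unknown rec_id {exc}") from exc
    total = np.zeros(len(pairs))
    for spec in comparators:
        w = weights.get(spec.field_name)
        if w is None:
            raise ValueError(f"no weights for field {spec.field_name!r}")
        vals = comparison_values(ds, spec.field_name).to_numpy(object)
        a, b = vals[ia], vals[ib]
        ok = ~(pd.isna(a) | pd.isna(b))
        wa, wd = w.agreement_weight, w.disagreement_weight
        contrib = np.zeros(len(pairs))
        if spec.kind == "exact":
            eq = np.zeros(len(pairs), dtype=bool)
            eq[ok] = a[ok] == b[ok]
            contrib[ok] = np.where(eq[ok], wa, wd)
        else:
            floor = spec.similarity_floor
            idx = np.nonzero(ok)[0]
            sims = np.array([jaro_winkler(str(a[i]), str(b[i])) for i in idx])
            c = np.where(
                sims >= 1.0,
                wa,
                np.where(sims <= floor, wd, wa - (wa - wd) * (1.0 - sims) / (1.0 - floor)),
            )
            contrib[idx] = c
        total += contrib
    out = pd.DataFrame(
        {
            "id_a": [a for a, _ in pairs],
            "id_b": [b for _, b in pairs],
            "score": total,
        }
    )
    if "entity_id" in ds.columns and ds["entity_id"].notna().any():
        ent = ds["entity_id"].to_numpy(object)
        ea, eb = ent[ia], ent[ib]
        out["is_true"] = (~pd.isna(ea)) & (~pd.isna(eb)) & (ea == eb)
    return out


def classify(scores: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Pairs whose total score strictly exceeds the threshold."""
    return scores[scores["score"] > threshold].reset_index(drop=True)


@dataclass
class SweepResult:
    best_threshold: float
    best_metrics: "object"  # evaluation.QualityMetrics
    trace: pd.DataFrame  # threshold, precision, recall, f_measure


def sweep_threshold(
    scores: pd.DataFrame,
    total_true_pairs: int,
    start: float,
    step: float = 0.5,
    patience: int = 10,
) -> SweepResult:
    """Walk the threshold in both directions to maximise the F-measure.

    Starting at ``start``, thresholds ``start ± k*step`` are evaluated,
    each direction stopping after ``patience`` consecutive evaluations
    that fail to improve the best F seen so far.  The recall denominator
    is ``total_true_pairs`` — all labelled pairs, including any that
    blocking never produced.  The incumbent is replaced only on a strict
    improvement, so on a flat curve the start threshold is returned; the
    full trace is part of the result.
    """
    from .evaluation import QualityMetrics, pairwise_metrics_from_scores

    if step <= 0:
        raise ValueError("step must be > 0")
    if len(scores) == 0:
        raise ValueError("no scored pairs to sweep")

    def metrics_at(t: float) -> "QualityMetrics":
        return pairwise_metrics_from_scores(scores, total_true_pairs, t)

    evaluated: list[tuple[float, "QualityMetrics"]] = []
    best_t = start
    best = metrics_at(start)
    evaluated.append((start, best))
    for direction in (+1, -1):
        misses = 0
        k = 1
        while misses < patience:
            t = start + direction * k * step
            m = metrics_at(t)
            evaluated.append((t, m))
            if m.f_measure > best.f_measure + 1e-12:
                best, best_t = m, t
                misses = 0
            else:
                misses += 1
            k += 1
    trace = pd.DataFrame(
        {
            "threshold": [t for t, _ in evaluated],
            "precision": [m.precision for _, m in evaluated],
            "recall": [m.recall for _, m in evaluated],
            "f_measure": [m.f_measure for _, m in evaluated],
        }
    ).sort_values("threshold", ignore_index=True)
    return SweepResult(best_t, best, trace)
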