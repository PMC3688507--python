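"""Independent reference implementations used as test oracles.

Each function here re-derives a quantity by a different route than the
package: brute-force pair enumeration for the counting statistics and
blocking, and structurally different transcriptions of the published
string/phonetic algorithms.  They are deliberately slow and simple.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import pandas as pd


# --- string similarity ------------------------------------------------------

def jaro_ref(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    window = max(max(len(a), len(b)) // 2 - 1, 0)
    available = defaultdict(list)
    for j, c in enumerate(b):
        available[c].append(j)
    a_hits, b_hits = [], []
    for i, c in enumerate(a):
        for j in available[c]:
            if i - window <= j <= i + window:
                available[c].remove(j)
                a_hits.append(i)
                b_hits.append(j)
                break
    m = len(a_hits)
    if m == 0:
        return 0.0
    seq_a = [a[i] for i in a_hits]
    seq_b = [b[j] for j in sorted(b_hits)]
    t_half = sum(1 for x, y in zip(seq_a, seq_b) if x != y) / 2.0
    return (m / len(a) + m / len(b) + (m - t_half) / m) / 3.0


def jaro_winkler_ref(a: str, b: str, p: float = 0.1, max_l: int = 4) -> float:
    base = jaro_ref(a, b)
    l = 0
    while l < min(len(a), len(b), max_l) and a[l] == b[l]:
        l += 1
    return base + l * p * (1.0 - base)


# --- phonetics --------------------------------------------------------------

_SDX = str.maketrans(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ",
    "*123*12**22455*12623*1*2*2",
)
# '*' marks vowels+Y (run separators); H and W are handled by deletion


def soundex_ref(name) -> str | None:
    s = "".join(c for c in str(name or "").upper() if c.isalpha())
    if not s:
        return None
    # drop H/W entirely (they are transparent), translate, collapse runs
    tagged = s[0].translate(_SDX) + "".join(
        ch.translate(_SDX) for ch in s[1:] if ch not in "HW"
    )
    collapsed = []
    for ch in tagged:
        if collapsed and collapsed[-1] == ch:
            continue
        collapsed.append(ch)
    digits = [c for c in collapsed[1:] if c != "*"]
    # if the first letter's own code began a run it was collapsed above
    return s[0] + "".join(digits[:3]).ljust(3, "0")


_NY_VOWELS = "AEIOU"


def nysiis_ref(name) -> str | None:
    s = "".join(c for c in str(name or "").upper() if c.isalpha())
    if not s:
        return None
    heads = [("MAC", "MCC"), ("KN", "NN"), ("K", "C"), ("PH", "FF"), ("PF", "FF"), ("SCH", "SSS")]
    for a, b in heads:
        if s.startswith(a):
            s = b + s[len(a):]
            break
    tails = [("EE", "Y"), ("IE", "Y"), ("DT", "D"), ("RT", "D"), ("RD", "D"), ("NT", "D"), ("ND", "D")]
    for a, b in tails:
        if s.endswith(a):
            s = s[: -len(a)] + b
            break
    chars = list(s)
    key = [chars[0]]
    i = 1
    while i < len(chars):
        two, three = s[i : i + 2], s[i : i + 3]
        if two == "EV":
            out, i = "AF", i + 2
        elif chars[i] in _NY_VOWELS:
            out, i = "A", i + 1
        elif chars[i] == "Q":
            out, i = "G", i + 1
        elif chars[i] == "Z":
            out, i = "S", i + 1
        elif chars[i] == "M":
            out, i = "N", i + 1
        elif two == "KN":
            out, i = "N", i + 2
        elif chars[i] == "K":
            out, i = "C", i + 1
        elif three == "SCH":
            out, i = "SSS", i + 3
        elif two == "PH":
            out, i = "FF", i + 2
        elif chars[i] == "H" and (
            chars[i - 1] not in _NY_VOWELS
            or (i + 1 < len(chars) and chars[i + 1] not in _NY_VOWELS)
        ):
            out, i = chars[i - 1], i + 1
        elif chars[i] == "W" and chars[i - 1] in _NY_VOWELS:
            out, i = chars[i - 1], i + 1
        else:
            out, i = chars[i], i + 1
        for c in out:
            if c != key[-1]:
                key.append(c)
    if key[-1] == "S" and len(key) > 1:
        key.pop()
    if key[-2:] == ["A", "Y"]:
        key = key[:-2] + ["Y"]
    if key[-1] == "A" and len(key) > 1:
        key.pop()
    return "".join(key)


# --- brute-force counting oracles ------------------------------------------

def all_pairs(df: pd.DataFrame):
    ids = list(df["rec_id"])
    return itertools.combinations(ids, 2)


def true_pairs_brute(df: pd.DataFrame) -> set[tuple[str, str]]:
    ent = dict(zip(df["rec_id"], df["entity_id"]))
    out = set()
    for a, b in all_pairs(df):
        ea, eb = ent[a], ent[b]
        if ea is not None and eb is not None and not pd.isna(ea) and ea == eb:
            out.add(tuple(sorted((a, b))))
    return out


def pairwise_metrics_brute(predicted, df: pd.DataFrame) -> tuple[int, int, int]:
    truth = true_pairs_brute(df)
    pred = {tuple(sorted(p)) for p in predicted}
    tp = len(pred & truth)
    return tp, len(pred - truth), len(truth - pred)


def variable_predictiveness_brute(df: pd.DataFrame, field: str) -> tuple[int, int, int]:
    """(agreeing_pairs, agreeing_true_pairs, total_true_pairs) by enumeration."""
    vals = dict(zip(df["rec_id"], df[field]))
    ent = dict(zip(df["rec_id"], df["entity_id"]))
    agree = agree_true = total_true = 0
    for a, b in all_pairs(df):
        is_true = ent[a] is not None and not pd.isna(ent[a]) and ent[a] == ent[b]
        total_true += is_true
        va, vb = vals[a], vals[b]
        if va is None or vb is None or pd.isna(va) or pd.isna(vb):
            continue
        if va == vb:
            agree += 1
            agree_true += is_true
    return agree, agree_true, total_true


def candidate_pairs_brute(df: pd.DataFrame, key_series_list) -> set[tuple[str, str]]:
    ids = list(df["rec_id"])
    keysets = []
    for series in key_series_list:
        keysets.append(dict(zip(df["rec_id"], series)))
    out = set()
    for a, b in itertools.combinations(ids, 2):
        for ks in keysets:
            ka, kb = ks[a], ks[b]
            if ka is None or kb is None or pd.isna(ka) or pd.isna(kb):
                continue
            if ka == kb:
                out.add(tuple(sorted((a, b))))
                break
    return out
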