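"""Jaro and Jaro-Winkler string similarity.

These comparators score partial agreement between name strings in [0, 1]
and drive the partial-agreement weighting of string fields during
probabilistic linkage.  Both are implemented from the standard
definitions: the Jaro similarity counts characters that match within a
sliding window of half the longer string, discounts transpositions at
half weight, and averages three ratios; the Winkler variant adds a bonus
proportional to the length of the common prefix.
"""

from __future__ import annotations

__all__ = ["jaro", "jaro_winkler"]


def jaro(a: str, b: str) -> float:
    """Jaro similarity between two strings.

    sim = (m/|a| + m/|b| + (m - t/2)/m) / 3 where ``m`` is the number of
    matching characters (equal characters no further apart than
    ``floor(max(|a|,|b|)/2) - 1``) and ``t/2`` is half the number of
    out-of-order matches.  Returns 0.0 when no characters match and 1.0
    when both strings are empty.
    """
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(max(la, lb) // 2 - 1, 0)
    a_flags = [False] * la
    b_flags = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_flags[j] and b[j] == ca:
                a_flags[i] = True
                b_flags[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters taken in order from each string
    transposed = 0
    j = 0
    for i in range(la):
        if a_flags[i]:
            while not b_flags[j]:
                j += 1
            if a[i] != b[j]:
                transposed += 1
            j += 1
    half_t = transposed / 2.0
    return (m / la + m / lb + (m - half_t) / m) / 3.0


def jaro_winkler(
    a: str,
    b: str,
    prefix_scale: float = 0.1,
    max_prefix: int = 4,
) -> float:
    """Jaro-Winkler similarity: Jaro plus a common-prefix bonus.

    jw = jaro + L * prefix_scale * (1 - jaro), with L the length of the
    common prefix capped at ``max_prefix``.  ``prefix_scale * max_prefix``
    must not exceed 1 so the result stays in [0, 1].
    """
    if prefix_scale * max_prefix > 1.0 + 1e-12:
        raise ValueError("prefix_scale * max_prefix must be <= 1")
    base = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= max_prefix:
            break
        prefix += 1
    return base + prefix * prefix_scale * (1.0 - base)
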