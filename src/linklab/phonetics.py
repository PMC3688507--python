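"""Phonetic encodings used for blocking and name cleaning.

Two classic encoders are provided:

* :func:`soundex` — American Soundex as specified for the US census:
  the initial letter is kept, remaining consonants map to the digit
  classes 1-6, adjacent letters with the same digit collapse, H and W
  are transparent for adjacency (a consonant separated from an
  equal-coded consonant only by H or W still collapses), vowels break
  runs, and the code is zero-padded to four characters.
* :func:`nysiis` — the New York State Identification and Intelligence
  System transformation, following the original rule set (head and tail
  substitutions, vowel flattening to A, and the terminal S/AY/A
  clean-up).  The code is not truncated.

Both return ``None`` for input with no alphabetic content, which callers
treat as a missing value.
"""

from __future__ import annotations

import re

__all__ = ["soundex", "nysiis"]

_SOUNDEX_CODES = {}
for _letters, _digit in [
    ("BFPV", "1"),
    ("CGJKQSXZ", "2"),
    ("DT", "3"),
    ("L", "4"),
    ("MN", "5"),
    ("R", "6"),
]:
    for _ch in _letters:
        _SOUNDEX_CODES[_ch] = _digit

_ALPHA = re.compile(r"[^A-Z]")


def _letters_only(name) -> str:
    if name is None:
        return ""
    return _ALPHA.sub("", str(name).upper())


def soundex(name) -> str | None:
    """Four-character American Soundex code, or None for non-alphabetic input."""
    s = _letters_only(name)
    if not s:
        return None
    first = s[0]
    digits = []
    last_code = _SOUNDEX_CODES.get(first)  # seed so a repeat of the initial collapses
    for ch in s[1:]:
        if ch in "HW":
            continue  # transparent: does not reset last_code
        code = _SOUNDEX_CODES.get(ch)
        if code is None:  # vowel or Y: breaks the run
            last_code = None
            continue
        if code != last_code:
            digits.append(code)
            last_code = code
        if len(digits) == 3:
            break
    return first + "".join(digits).ljust(3, "0")


_NYSIIS_VOWELS = set("AEIOU")


def nysiis(name) -> str | None:
    """NYSIIS phonetic key, or None for non-alphabetic input."""
    s = _letters_only(name)
    if not s:
        return None
    # head substitutions
    for src, dst in [("MAC", "MCC"), ("KN", "NN"), ("K", "C"),
                     ("PH", "FF"), ("PF", "FF"), ("SCH", "SSS")]:
        if s.startswith(src):
            s = dst + s[len(src):]
            break
    # tail substitutions
    for src, dst in [("EE", "Y"), ("IE", "Y"), ("DT", "D"), ("RT", "D"),
                     ("RD", "D"), ("NT", "D"), ("ND", "D")]:
        if s.endswith(src):
            s = s[: -len(src)] + dst
            break
    key = s[0]
    i = 1
    n = len(s)
    while i < n:
        ch = s[i]
        step = 1
        if s[i : i + 2] == "EV":
            repl = "AF"
            step = 2
        elif ch in _NYSIIS_VOWELS:
            repl = "A"
        elif ch == "Q":
            repl = "G"
        elif ch == "Z":
            repl = "S"
        elif ch == "M":
            repl = "N"
        elif s[i : i + 2] == "KN":
            repl = "N"
            step = 2
        elif ch == "K":
            repl = "C"
        elif s[i : i + 3] == "SCH":
            repl = "SSS"
            step = 3
        elif s[i : i + 2] == "PH":
            repl = "FF"
            step = 2
        elif ch == "H" and (
            s[i - 1] not in _NYSIIS_VOWELS
            or (i + 1 < n and s[i + 1] not in _NYSIIS_VOWELS)
        ):
            repl = s[i - 1]
        elif ch == "W" and s[i - 1] in _NYSIIS_VOWELS:
            repl = s[i - 1]
        else:
            repl = ch
        for rc in repl:
            if rc != key[-1]:
                key += rc
        i += step
    # terminal clean-up
    if key.endswith("S") and len(key) > 1:
        key = key[:-1]
    if key.endswith("AY"):
        key = key[:-2] + "Y"
    if key.endswith("A") and len(key) > 1:
        key = key[:-1]
    return key
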