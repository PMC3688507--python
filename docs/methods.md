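# Methods

## Problem

Administrative person datasets (hospital admissions, electoral rolls)
lack a unique person identifier, so records belonging to the same
individual must be linked probabilistically from noisy identifying
fields.  Data cleaning — reformatting, removing invalid values,
stripping punctuation, phonetic encoding, nickname canonicalisation,
sex imputation — is conventionally assumed to improve linkage quality.
This package implements the full experimental apparatus needed to test
that assumption: a synthetic-data generator with known truth, graded
cleaning plans, a Fellegi–Sunter deduplication engine, and pairwise and
per-variable quality statistics.

## Synthetic data generator

*Originals.* Each original record is an independent draw: sex from a
two-value table (M 49.2 / F 50.8), forename from a per-sex frequency
table, surname and postcode from their tables, date of birth uniform
over 1900–2005 (no published age distribution exists for the emulated
file, so uniformity is the neutral choice).  The packaged tables are
authored stand-ins (`data/*_synthetic.csv`): their top-5 entries match
the published marginals of the Western-Australian-roll-derived file the
generator emulates (e.g. SMITH 0.92 %, JOHN 3.44 % of males, postcode
6210 2.84 %), with Zipf-weighted tails of ~200–300 plausible values.
Tail cardinality is deliberately smaller than a real population
vocabulary so that value-collision rates at the package's reduced
analysis scale (n = 20,000) resemble those of the 400k original; the
generator accepts arbitrary user tables.  Baseline missingness in
originals (surname 0.8 %, forename 0.8 %, sex 1.5 %, DOB 0.3 %,
postcode 0.4 %) combines with duplicate-error missingness so the final
file shows roughly 2 % missing names and 1 % missing postcodes, the
profile of the emulated file.  A configurable share (40 %) of missing
postcodes is coded as the sentinel `9999` rather than blank, and 0.2 %
of DOBs are invalid strings, giving the invalid-value cleaning step
real work.

*Duplicates.* Each original spawns k duplicates, k drawn from a
truncated geometric distribution (P(k) ∝ 0.45^k, k ≤ 9); originals are
generated until the running total of originals plus duplicates reaches
the requested size exactly.  Each duplicate draws an error count from a
categorical distribution ({0: .08, 1: .38, 2: .30, 3: .16, 4: .08}),
then for each error a field (forename .26, surname .26, DOB .20,
postcode .18, sex .05; remaining mass is a no-op) and an operator from
the per-field weights.  Operators: keyboard-adjacency typos
(insert/delete/substitute/transpose), phonetic respelling from a small
grapheme list (PH↔F, Y↔I, EE↔EA, C↔K, S↔Z, OU→U, GH→∅, letter
doubling), nickname substitution (canonical→diminutive using the
shipped table in reverse, or diminutive→canonical), first/last name
reversal, surname change and postcode change (fresh table draw),
hyphenation toggling (append a hyphenated second name, or strip
existing punctuation), and outright missingness.  DOB typos mostly stay
valid calendar dates (random day 1–28 or month 1–12 or year ±1–3);
day/month transposition can produce an invalid month, as real keying
errors do.

*Calibration.* The emulated file's own error rates are not published
("user-specified parameters"), so the defaults above were fixed once so
that uncleaned internal linkage of a generated 20,000-record file
attains a best pairwise F-measure near 0.88 — the quality regime of the
original 400k experiment — and were not revisited.  Every rate is
recorded in the dataset's provenance, and all randomness flows through
a single `numpy` generator with a documented draw order (sex, forename,
surname, postcode, DOB, missingness masks, sentinel coding, then
duplicate draws), so a config plus seed reproduces a file byte for
byte.

*What the generator does not emulate:* family/household structure,
longitudinal address histories beyond a postcode change, free-text
address lines, and correlated errors across fields (each error is drawn
independently).  Passing tests on generated data therefore demonstrate
the mechanism of the cleaning effects, not their exact magnitudes on
any particular real dataset.

## Cleaning plans

Techniques are total, idempotent field transformations; plans are
ordered step lists applied to a copy.  The presets mirror a graded
regime: `minimal` removes invalid DOBs (parse-validated against an
ordered dialect list; two-digit years ≤ 30 pivot to the 2000s) and
invalid postcodes (`9999` etc., user-extensible lists shipped in
`data/`), and strips punctuation/spaces from name fields (upper-cased
A–Z only).  `high` adds nickname canonicalisation (shipped chain-free
table of ~160 English diminutives; content is a package default, and
experiments should record the table used) and sex imputation from the
dataset's own forename–sex frequencies (strict-majority rule, matching
most-common-value imputation; ties stay missing).  Punctuation removal
precedes nickname lookup, so lookups operate on normalised names.
Phonetic encoders (census-rule Soundex with H/W adjacency transparency;
original-rule NYSIIS, untruncated, with W-after-vowel replaced by the
preceding source letter — implementations disagree on these corners,
so the choices are pinned here and by test) are available as techniques
for per-variable analysis but are not part of the presets.

## Linkage engine

Internal deduplication in the Fellegi–Sunter frame:

- **Blocking.** Union of two keys: Soundex of surname concatenated with
  the forename initial, and the full DOB string.  Records missing a
  key component join no block for that key.  True pairs missed by
  blocking remain false negatives — recall is measured against all
  truth pairs.
- **Comparison.** Jaro–Winkler similarity for forename and surname
  (prefix scale 0.1, max prefix 4, bonus applied unconditionally per
  the stated formula); exact comparison for sex, postcode, and day,
  month and year of birth separately.
- **Weights.** m is estimated by truth counting over labelled true
  pairs (exact agreement; both values present), u as the
  value-frequency collision probability Σ p_v² over non-missing values
  — deterministic and O(n).  Agreement/disagreement weights are
  log2(m/u) and log2((1−m)/(1−u)), probabilities clamped to
  [1e−6, 1−1e−6].  A two-class EM over exact-agreement patterns of the
  candidate pairs is provided for unlabelled data (classes oriented so
  agreement argues for the match class).
- **Scoring.** Exact fields contribute the agreement or disagreement
  weight; string fields interpolate linearly between them from
  similarity 1 down to a floor of 0.7 (at or below the floor the full
  disagreement weight applies); missing values contribute exactly 0.
  Pair score is the sum; a pair matches when its score strictly
  exceeds the threshold.
- **Threshold sweep.** From a start threshold (default: half the
  summed agreement weights) the sweep walks ±0.5 weight units,
  stopping each direction after `patience` (default 10) consecutive
  evaluations that fail to improve the best F.  The incumbent is
  replaced only on strict improvement, so a flat curve returns the
  start threshold and ties resolve to the threshold evaluated first
  (nearest the start, upward direction first); the full trace is
  returned.  A dip longer than the patience can hide a farther peak;
  the trace makes this visible, and a test documents the behaviour.

Pairwise classification only: no transitive closure or one-to-one
assignment, since quality is measured at pair level.

## Quality statistics

Pairwise precision, recall and F (harmonic mean, 0/0 → 0 with an
explicit flag) against the truth labels.  Per-variable predictive
ability treats exact agreement on a single field as a match predictor
over all C(n,2) record pairs; counts come from frequency identities
(Σ C(n_v,2) for agreeing pairs, Σ C(n_{e,v},2) over entity×value cells
for agreeing true pairs) and are verified against brute-force
enumeration on small fixtures.  Technique effects are *relative*
percentage changes in F (not percentage points); per-technique averages
are unweighted means over the touched fields, with per-field values
reported alongside.  The per-variable universe is all within-dataset
pairs, independent of blocking.

## Problem sizes

The analysis scripts and acceptance checks run the overall-quality
experiment at n = 20,000 records, the mechanism checks at n = 5,000
over five seeds, and generator-fidelity checks at n = 100,000 originals
— sizes chosen as the package's desk-scale working points; the
generator itself handles 400,000 records in a few tens of seconds.

## Known limitations

- F-measure weighs a false positive and a false negative equally;
  applications that must minimise one error type should inspect the
  sweep trace rather than the single best-F row.
- u-probabilities from Σ p_v² describe random pairs, not blocked
  non-match pairs; within blocks, key-correlated fields (surname) agree
  more often than u suggests.  Truth counting sidesteps this for m but
  not u; the effect is shared by standard practice.
- The nickname table and invalid-value lists are package defaults, not
  the (unpublished) originals; experiments should treat them as part of
  the configuration.
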