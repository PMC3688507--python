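# linklab

**Does data cleaning actually improve record linkage?**  `linklab` is a
workbench for answering that question quantitatively.  It generates
synthetic person datasets with known truth and realistic injected
errors, applies graded data-cleaning plans, links the records with a
Fellegi–Sunter probabilistic engine, and measures linkage quality
pairwise and per variable — so the effect of every cleaning technique
can be isolated and explained.

It is aimed at data-linkage units and health researchers who maintain
cleaning pipelines in front of probabilistic linkage and want to know
which steps help, which hurt, and why.

## The model

Internal linkage (deduplication) follows the Fellegi–Sunter frame.  For
each candidate pair and field *i* with agreement probability among
matches *m_i* and among non-matches *u_i*, the field contributes

```
w_i = log2(m_i / u_i)              on agreement
w_i = log2((1 − m_i) / (1 − u_i))  on disagreement
```

with linear interpolation between the two for partial string agreement
(Jaro–Winkler similarity above a floor of 0.7) and contribution 0 when
either value is missing.  A pair is a match when Σ w_i strictly exceeds
a threshold; the threshold is swept in 0.5-weight steps to the best
pairwise F-measure,

```
F = 2 · precision · recall / (precision + recall)
```

with precision/recall measured against the generator's truth labels.
The same precision/recall/F applied to "two records agree exactly on
this field" measures a single variable's predictive ability, before and
after each cleaning technique.

## Worked example

```python
from linklab import GeneratorConfig, generate_dataset
from linklab.cleaning import preset_plan
from linklab.evaluation import overall_quality_experiment

ds = generate_dataset(GeneratorConfig(n_total=20_000, seed=1))
table = overall_quality_experiment(
    ds.records, [preset_plan(p) for p in ("none", "minimal", "high")]
)
print(table.to_string(index=False))
```

prints

```
   plan  candidate_pairs  best_threshold  precision   recall  f_measure
   none            74581       13.744757   0.979874 0.798787   0.880112
minimal            74083       13.748383   0.977019 0.792286   0.875009
   high            75056       13.578964   0.971074 0.793957   0.873629
```

Reading the table: on a 20,000-record file whose duplicates carry
realistic errors, linkage with **no cleaning** reaches the best
F-measure (0.880); minimal cleaning (invalid values removed,
punctuation stripped) and heavy cleaning (plus nickname
canonicalisation and sex imputation) both *reduce* quality slightly.
The per-variable view (`analysis/03_technique_effects.py`) shows why:
nickname lookup raises forename recall but costs a ~21 % relative drop
in the field's F, and Soundex-encoding surnames costs ~26 % — merging
transformations reduce variability, so correct pairs agree more often
but incorrect pairs agree much more often.

The same stages are scriptable from the shell:

```
linklab generate --n 20000 --seed 1 --out data.csv
linklab clean    --in data.csv --plan high --out cleaned.csv
linklab link     --in cleaned.csv --out pairs.csv
linklab evaluate --pairs pairs.csv --truth data.csv
linklab experiment --n 20000 --seed 1 --out report/
```

The numbered scripts under `analysis/` run the full study (simulate →
overall quality → technique effects) and write their tables under
`results/`.

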