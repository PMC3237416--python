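# adrcat — adverse drug reaction causality assessment toolkit

Deciding whether a clinical event was *caused* by a drug is the daily
business of pharmacovigilance: clinicians, regulators and trialists
place each suspected adverse drug reaction (ADR) on the ordinal scale
**Unlikely < Possible < Probable < Definite**. Two structured
instruments dominate this work, and `adrcat` makes both executable:

* the **Naranjo questionnaire** — ten fixed questions answered
  yes / no / don't-know, each answer carrying an integer weight; the
  total score is partitioned into the four categories
  (≤0 Unlikely, 1–4 Possible, 5–8 Probable, ≥9 Definite);
* the **Liverpool causality assessment tool** — a decision tree of
  mostly dichotomous prompts (temporal relationship, alternative cause
  with an "unsure" option, de-challenge, improvement, re-challenge or
  previous reaction to the same drug) whose leaves are the four
  categories. The tree is data (JSON), not code, and a validator checks
  the properties the instrument's development established — in
  particular that **Definite is unreachable without an affirmative
  re-challenge / previous-reaction answer**.

Because such instruments are judged by how well independent assessors
agree, the package also implements the standard inter-rater
reliability (IRR) battery for a cases × raters grid of categories:

* pairwise **exact agreement** %EA and **extreme disagreement** %ED
  (ratings more than one scale step apart);
* pairwise **linear weighted kappa**
  κ<sub>w</sub> = (p<sub>o</sub> − p<sub>e</sub>) / (1 − p<sub>e</sub>)
  with weights w<sub>ij</sub> = 1 − |i − j|/3, with the
  Fleiss–Cohen–Everitt (1969) large-sample SE and a 95% CI;
* the multi-rater **Fleiss kappa** with the Fleiss (1971) variance;
* **Altman verbal bands** (poor / fair / moderate / good / very good).

Finally, a seeded **rater-panel simulator** draws latent true
categories from a prevalence vector and corrupts each rater's report
with an ordinal spillover model (probability `fidelity` of reporting
the truth, geometric decay over ordinal distance otherwise), and can
realise every simulated rating as a concrete Liverpool answer sheet by
inverse path sampling — so the whole pipeline is testable end to end
with known ground truth.

## Worked example

```python
from adrcat import (SimulationConfig, simulate_study, default_tree,
                    agreement_report, collate_categories)

tree = default_tree()
panel = simulate_study(SimulationConfig(n_cases=40, n_raters=7,
                                        fidelity=0.8, seed=2011), tree)
report = agreement_report(panel.ratings)
g = report.global_
print(g.kappa_fleiss, g.ci95, g.band)
```

prints (rounded) `0.50 (0.45, 0.55) moderate`: forty cases assessed by
seven raters at fidelity 0.8 yield a global Fleiss kappa of 0.50 —
"moderate" agreement on the Altman scale. A single rater pair shows
`%EA = 70.0, %ED = 10.0, kappa_w = 0.60 (0.41, 0.79)`: the two raters
matched exactly on 70% of cases and were more than one category apart
on 10%. Collating the panel's assignments,

```python
print(collate_categories(panel.ratings).to_markdown())
```

ends in `| **Total (%)** | 17 (6.1) | 80 (28.6) | 87 (31.1) | 96 (34.3) |`
— the per-category utilisation across all 280 assessments. Every
simulated rating is backed by an answer sheet that reproduces it:
`assess(tree, panel.sheets[("case1", "rater1")])` returns exactly the
category in `panel.ratings`.

The per-assessor category counts published with the Liverpool tool's
validation study ship as package data:

```python
from adrcat import study_arm_table
table = study_arm_table("observational_original_liverpool")
print(table.count(4), table.percentage(4))   # -> 125 44.6
```

## Command line

```bash
adrcat simulate --n-cases 40 --n-raters 7 --seed 1 --out-dir run1/
adrcat agree --input run1/ratings.csv --output report.json --table report.md
adrcat assess-liverpool --input run1/sheets.csv --output assessed.csv --explain
adrcat score-naranjo --input naranjo_sheets.csv --output scores.csv
adrcat collate --input run1/ratings.csv --output collated.csv
adrcat compare --instrument naranjo=a.csv --instrument liverpool=b.csv --output cmp.json
adrcat validate-tree --tree src/adrcat/data/liverpool_tree.json
```

## Layout

* `src/adrcat/naranjo.py` — questionnaire scoring engine
* `src/adrcat/liverpool.py` — decision-tree loading, validation, traversal
* `src/adrcat/agreement.py` — %EA/%ED, weighted kappa, Fleiss kappa, bands
* `src/adrcat/simulate.py` — latent-truth panel simulator
* `src/adrcat/collate.py`, `src/adrcat/io.py`, `src/adrcat/cli.py` —
  collation, comparison, CSV/JSON interfaces, umbrella CLI
* `src/adrcat/data/` — default weight table, default tree document,
  published study counts
* `docs/methods.md` — models, formulas, numerical choices, limitations
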