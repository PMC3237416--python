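# Methods

## The two instruments

**Naranjo questionnaire.** Ten questions, each answered yes / no /
don't-know, with an integer weight per (question, answer) pair; the
case's score is the sum of the ten weights. The packaged default matrix
(achievable totals −4 … 13) and the score partition ≤0 → Unlikely,
1–4 → Possible, 5–8 → Probable, ≥9 → Definite follow the classical
1981 formulation; the lowest category's historical label "doubtful" is
normalised to "Unlikely" so both instruments share one scale. The
weight table and boundaries are configuration (JSON), since several
dialects of the questionnaire circulate; validation requires all 30
weights, strictly increasing boundaries, and a partition that covers
the achievable range. Nothing in this package attempts to justify the
weights — they are encoded, not endorsed.

**Liverpool decision tree.** A rooted directed tree of prompts. Each
node declares its admissible answers (binary, except the
alternative-cause node which adds "unsure") and a route per answer to
another node or to a leaf labelled with a causality category. The
engine is generic; the packaged document encodes the final published
instrument. The published flowchart circulates only as a figure, so the
shipped document reconstructs its logic from the development narrative
(question order: temporal relationship → alternative cause →
de-challenge → improvement → re-challenge/previous reaction); the
reconstruction choices are recorded in the document's
`transcription_notes`, and any variant transcription can be dropped in
as a replacement JSON without code changes.

Validation is split in two. Loading rejects structural defects
(duplicate ids, dangling routes, cycles, unparseable leaves), listing
every violation at once. Semantic diagnostics then report, without
raising: acyclicity, totality (≥2 routes per node), reachability,
coverage of all four categories, and the **Definite gate** — every
root-to-Definite path must traverse a node tagged `rechallenge_gate`
via that node's affirmative answer. The gate rule is data-driven (a
node tag, not prompt-text matching) because the instrument's first
prototype famously allowed Definite without re-challenge evidence and
the final version's defining fix was to close those paths.

## Agreement statistics

Ratings live on integer codes 1–4 in the fixed order
Unlikely < Possible < Probable < Definite; ordinal distance is the
absolute code difference.

* **%EA** = 100 × (identical pairs)/(jointly rated pairs);
  **%ED** = 100 × (pairs at distance ≥ 2)/(jointly rated pairs).
  %EA + %(distance 1) + %ED = 100 by construction.
* **Linear weighted kappa** from the 4×4 contingency table with
  agreement weights w_ij = 1 − |i−j|/3:
  κ_w = (p_o − p_e)/(1 − p_e) with p_o = Σ w_ij p_ij and
  p_e = Σ w_ij p_i· p_·j. The standard error is the
  Fleiss–Cohen–Everitt (1969) large-sample (non-null) form; the 95% CI
  is κ ± 1.96·SE truncated to [−1, 1]. The null-variance alternative
  would be appropriate for testing κ = 0; the non-null form is the
  right one for interval estimation and is what is implemented.
* **Fleiss kappa** for N cases each rated by the same n raters, from
  the cases × categories count matrix; its CI uses the Fleiss (1971)
  variance (derived under the chance null — the conventional choice,
  with the usual caveat that it is approximate away from the null).
* **Altman bands** are applied to the full-precision estimate as
  half-open intervals: ≤0.20 poor, ≤0.40 fair, ≤0.60 moderate,
  ≤0.80 good, ≤1.00 very good (negative values are "poor"). The printed
  band edges leave gaps such as (0.20, 0.21); banding before display
  rounding resolves them deterministically.

Missing ratings: pairwise statistics use complete pairs for that pair
of raters; Fleiss kappa uses complete cases only, and the number of
excluded cases is reported. Chance-corrected statistics are undefined
when the chance-expected agreement is 1 (e.g. a panel unanimous in a
single category); such results carry a `degenerate` flag and NaN rather
than raising, since they arise legitimately in small panels.

Both kappas are authored here (the battery is the package's
deliverable, and no installed library provides the Fleiss-kappa
variance); `statsmodels`' independent implementations serve as oracles
in the test suite, alongside hand-written direct-formula evaluations.

## The simulator

A panel is generated as: latent category per case i.i.d. from a
4-vector `prevalence`; each rater's report equals the latent category
with probability `fidelity`, otherwise lands on another category with
probability ∝ `spillover_decay`^d (d = ordinal distance, renormalised
over the three other categories). One `numpy` generator seeded from the
config is threaded through all sampling; no global state.

Defaults are the study design the instruments were validated under:
40 cases × 7 raters. Default prevalence (0.01, 0.22, 0.33, 0.44)
mirrors the category mix a panel produces when applying the Liverpool
tool to suspected-ADR admissions (cases pre-selected as suspected ADRs
almost never rate Unlikely). Fidelity 0.7 with decay 0.5 was chosen
once as a realistic operating point: it keeps most disagreements one
category apart — the dominant pattern in real panels — and yields
moderate kappas. With `fidelity = 0.25, spillover_decay = 1` and
uniform prevalence the reports are i.i.d. uniform, giving an exact
independence null for calibration tests.

Liverpool answer sheets are produced by **inverse path sampling**: all
root-to-leaf paths are enumerated once, and for a target category one
of its paths is drawn uniformly; the sheet is exactly the answers along
that path, so re-assessment reproduces the rating with equality, not
approximately. Sheets are drawn from a sub-stream spawned from the
config seed, so a panel's ratings are identical whether or not sheets
are requested. Naranjo sheets are not simulated: a category does not
identify a point in the 3^10 answer space, so simulated Naranjo input
stays at the ratings level.

**What the simulator does not model:** rater-specific leniency or
bias, case-difficulty random effects, learning over assessment rounds,
and missing ratings. Passing recovery tests therefore show the
statistics and engines are correct under ordinal, exchangeable noise —
not that any particular real panel satisfies those assumptions.

**A non-obvious property of the spillover model.** The population
Fleiss kappa is not monotone in fidelity near zero: when fidelity is
small but decay < 1, every rater's misreports still cluster around the
latent category, producing agreement that the chance correction does
not absorb (with the defaults, population kappa falls from ≈0.17 at
fidelity 0 to ≈0.02 at 0.3 before rising to 1). Parameter-recovery
checks therefore run on the monotone branch, fidelity 0.4–1.0; the
analytic kappa computed directly from the misclassification kernel is
pinned alongside the simulation-based check.

## Collation and comparison

Collation counts each assessor's category assignments, sums them, and
reports percentages of the grand total rounded to a configurable
number of digits (1 by default, 0 for prose-style integers). The
per-assessor counts published with the Liverpool tool's validation
study ship as package data (`study_counts.json`, assessors anonymised
A1–A7; development-iteration arms retain only the collated panel
counts, which is all that was published). Instrument comparison aligns
two instruments on one case × rater grid and reports side-by-side
collations, global kappas, and the per-cell category shift
distribution; assessment totals are given under both conventions
(unique case–rater pairs vs. per-instrument assessments), since a
case rated with two instruments counts once under the first and twice
under the second.

## Problem sizes and numerical choices

Simulation-based checks use 2000 cases × 7 raters for the independence
null (|κ| within 3 SE of 0) and 500 cases × 3 seeds per grid point for
fidelity recovery — sizes at which the Monte-Carlo error is far below
the effects being checked while the whole battery runs in seconds.
Oracle-equivalence comparisons are asserted to 1e-12; exact-by-
construction identities (perfect agreement κ = 1, sheet round-trips)
are asserted with equality. CI truncation to [−1, 1] happens after the
±1.96·SE computation. Category and answer tokens are normalised
case-insensitively with whitespace stripped; numeric codes 1–4 are
accepted for categories.

## Known limitations

* The packaged tree is a faithful reconstruction of the published
  instrument's logic, not a verbatim figure transcription; users
  needing the exact published wording should transcribe it into the
  JSON schema and re-run `validate-tree`.
* The published pairwise kappas of the validation study cannot be
  recomputed here because per-case ratings were never deposited; only
  the collation arithmetic is reproduced exactly.
* Weighted-kappa CIs assume the large-sample normal approximation;
  with very few cases (tens) coverage is approximate, which matches
  how such tables are conventionally reported.
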