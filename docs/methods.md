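# Methods notes

## Scope and model

`moodmarkers` implements a four-step blood transcriptomic biomarker
workflow for mood disorders. The object of study is a probeset × visit
expression matrix on the log2 scale, a visit/phenotype table (SMS-7 mood
score, HAMD, YMRS, gender, diagnosis), and per-subject hospitalization
follow-up. The pipeline's stages are deliberately modular: each step reads
the previous step's table and can be run, tested, and replaced on its own.

The statistical core is simple by design — per-comparison fold-change
points, capped evidence sums, a strict monotonicity check plus classical
one-way ANOVA, rank-based AUC, and a single-covariate proportional-hazards
fit — because the method's strength is the *stacking* of independent,
individually weak filters, not any one estimator.

## Scoring constants

All thresholds default to the published constants of this family of
designs and are collected in `PipelineConfig`:

| parameter | default | meaning |
|---|---|---|
| mood cutoffs | 40 / 60 | SMS-7 low / high mood (0–100 scale) |
| HAMD cutoffs | 22 / 7 | clinically severe / non-depressed reference |
| YMRS cutoff | 20 | clinically severe mania |
| fold-change steps | 1.2 / 1.1 | full (±1) / half (±0.5) DE points |
| internal-point tiers | 33.3 / 50 / 80 % | 2 / 4 / 6 discovery points |
| carry-forward | 6 | minimum discovery + CFG score |
| alpha | 0.05 | nominal significance everywhere |
| Cox first-year horizon | 365 d | censoring for the year-1 trait target |

Overrides are permitted and recorded in the run metadata together with the
configuration hash and seed.

## Design choices where the design was open

- **Detection (absent/present) calls.** Vendor detection algorithms are
  not reproducible offline, so present = intensity above a per-probeset
  threshold, defaulting to the probeset's cohort-wide 25th percentile.
  This is a deliberate, documented substitute rule, not a reconstruction
  of any vendor algorithm.
- **"Consecutive" visits.** A mood comparison pairs strictly adjacent
  visits; an intervening intermediate-mood visit breaks the pair. A
  relaxed any-low-vs-any-high mode exists for sensitivity analysis.
- **DE/AP duplicates.** A probeset's DE and AP results are separate
  candidate entries throughout; they are never merged.
- **CFG allocation.** Only the 12-point cap and the six evidence streams
  are fixed by the method; the equal 2-point per-stream cap is this
  package's allocation, chosen as the only symmetric one consistent with
  the cap. It is configurable via per-category caps.
- **Stepwise rule.** Strict monotonicity (ties break the chain), with a
  non-strict option. The validation point map {stepwise: 2, + nominal
  ANOVA: 4, + Bonferroni: 6} is reconstructed from the 6-point maximum and
  the nominal/stepwise annotations of the worked marker rows; a
  Bonferroni-surviving exemplar is not available, so the 6-point rule is an
  extrapolation of the stated maximum.
- **Testing points.** Per (marker, target), the best stratum level counts
  (3 all > 2 gender > 1 gender × diagnosis), never a sum across strata, and
  either mode (cross-sectional or longitudinal) may earn it. This is the
  only rule that reproduces the worked composite totals (26/30/24/20).
- **Longitudinal extremum for decreased-risk markers.** The minimum
  replaces the maximum for both the level *and* the slope component (the
  source design states the substitution only for levels); the combined
  score is then negated so higher always means riskier. This keeps the
  orientation-invariance property exact.
- **AUC p-value.** One-sided normal approximation to the Mann–Whitney
  statistic (with tie correction), the same construction that yields the
  AUC itself. Swappable if an exact test is preferred.
- **Report boundaries.** A z-value exactly equal to a reference-group mean
  digitizes toward the more severe bin; the percentile rank is inclusive
  (fraction of database scores ≤ patient score). Both conventions are
  documented here because the alternatives are equally defensible.
- **Follow-up anchoring.** The synthetic generator emits one follow-up
  record per subject and event type, anchored at the subject's final
  (testing) visit; trait analyses therefore predict from that visit. A
  per-visit anchoring would multiply correlated observations without
  changing the mechanics being tested.
- **CLI surface.** Two subcommands (`simulate`, `run`) cover the
  workflow; `run` writes every intermediate stage table, so per-stage
  subcommands would duplicate the library API, which is the intended
  programmatic interface for single stages.

## Numerical details

- Z-scoring uses the population standard deviation (n denominator) by
  default, configurable to the sample convention; strata of size one and
  zero-variance probesets within a stratum fall back to pooled-cohort
  statistics, and a probeset constant across the whole cohort z-scores to
  0. No code path divides by zero.
- Slopes are computed on linear-scale levels as (level_t / level_{t−1}) /
  Δdays, with the previous level floored at 2⁻¹⁰ and zero-day gaps
  skipped.
- Validation's Bonferroni factor is the number of probesets actually
  tested in ANOVA (the stepwise ones), matching the order of operations of
  the workflow it implements.
- Panel selection and drug/medication rankings break ties
  deterministically (score, then identifier), so outputs are bit-stable
  under a fixed seed.

## The synthetic cohort: what it emulates and what it does not

The generator produces the *structure* the pipeline assumes: a discovery
cohort in which every subject has ≥ 1 adjacent diametric SMS-7 pair; a
validation cohort of severely depressed (HAMD ≥ 22) and manic (YMRS ≥ 20)
single-visit subjects whose planted-marker shifts extend the low→high
gradient (±0.75 × effect vs ±0.5 × effect), giving the stepwise pattern;
and a test cohort with mixed mood states, stratum baseline offsets, subject
random intercepts, and exponential hospitalization times whose log-hazard
is `hazard_beta` × the subject's risk-directed planted-marker z at the
anchor visit. Planted markers split 50/50 increased/decreased in high mood
to exercise direction handling everywhere.

Defaults — 2,000 probesets, 20 planted markers, log2 effect 1.0, per-visit
noise SD 0.2, 40 discovery subjects with 2–6 visits, hazard beta 0.7 —
describe a desk-scale study in which the within-subject design has
realistic power; the 54,625-probeset array size is available as a config
option. Sample sizes and clinical-scale ranges mimic a mid-sized VA-style
psychiatric cohort.

What it does *not* emulate: probe-level noise and RMA itself, batch and
medication effects beyond stratum offsets, correlated gene modules,
non-exponential hazards, missing visits, or diagnosis-dependent effect
sizes. Passing tests therefore demonstrate that the machinery is correct
and well calibrated (null AUC ≈ 0.5, null hazard ratio ≈ 1, uniform null
ANOVA p-values, recovery of planted effects), not that any particular
marker generalizes to real patients.

## Known limitations

- The evidence database and drug tables are synthetic stand-ins with the
  real tables' schema; curation of a literature corpus is out of scope.
- The repurposing scorer is a sign-agreement anti-match over overlapping
  genes, interface-compatible with — but not a reimplementation of —
  rank-based connectivity scoring against perturbagen databases.
- Cox fits are univariate with no covariate adjustment, matching the
  workflow being implemented; small strata are skipped (and logged), never
  silently imputed.
- ANOVA is the classical equal-variance test; Welch or nonparametric
  alternatives are out of scope.
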