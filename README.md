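# moodmarkers

A tested, reusable implementation of a four-step blood gene-expression
biomarker pipeline for mood disorders — discovery, prioritization,
validation, and testing — with composite evidence scoring, clinician-report
generation, and drug matching. It is aimed at computational psychiatry and
translational bioinformatics groups who want to run, stress-test, or extend
this style of longitudinal biomarker analysis without access to the original
microarray data: a seeded synthetic-cohort generator reproduces the data
structure every stage assumes, so the whole pipeline runs end to end on a
laptop.

## The method

Subjects with psychiatric disorders are followed longitudinally; at each
visit they rate their mood on a 0–100 visual analog scale (SMS-7, ≤ 40 =
low mood, ≥ 60 = high mood), receive clinical scales (HAMD for depression,
YMRS for mania), and give blood for whole-genome expression profiling
(log2, RMA-like normalization).

1. **Discovery (up to 6 points).** Within each subject, consecutive visits
   with diametric mood states are compared. Per comparison, a probeset
   scores ±1 for a linear fold change ≥ 1.2 (sign = direction in high
   mood), ±0.5 for 1.1–1.2, 0 otherwise (DE method), or ±1 for a detection
   call turning on/off (AP method). Scores are summed over all comparisons
   and subjects; |raw score| as a fraction of the maximum converts to
   internal points: 2 at ≥ 33.3 %, 4 at ≥ 50 %, 6 at ≥ 80 %.
2. **Prioritization with convergent functional genomics (up to 12
   points).** Each candidate gene is scored against six independent
   literature-evidence streams (human/animal × genetic/brain/peripheral),
   each capped at 2 points. Candidates with discovery + CFG ≥ 6 are carried
   forward — which keeps maximal-discovery genes with no prior literature.
3. **Validation (up to 6 points).** On de-logged, gender-and-diagnosis
   z-scored values, markers are checked for a strictly stepwise change
   along clinical depression (HAMD ≥ 22) → low mood → high mood → clinical
   mania (YMRS ≥ 20): 2 points if stepwise, 4 if one-way ANOVA p < 0.05,
   6 if Bonferroni-significant over the ANOVA-tested probesets.
4. **Testing (up to 3 points × 8 phenotypes).** In independent cohorts,
   each marker predicts four depression-family targets (low-mood state,
   depression state, first-year and all-future hospitalization with
   depression) and four mirrored mania-family targets — cross-sectionally
   (ROC AUC via the Mann–Whitney rank construction) and longitudinally
   (level + slope + extremum level + extremum slope, z-scored and summed;
   all-future hospitalizations use a single-covariate Cox fit). Per target:
   3 points if significant in all subjects, else 2 in a gender stratum,
   else 1 in a gender × diagnosis stratum.

The **convergent functional evidence (CFE)** score adds everything up, to a
maximum of 48 = 6 + 12 + 6 + 8 × 3. Panels are chosen by a
reference-marker cutoff (every marker scoring at least as well as a de
facto positive control). Downstream, drugs are matched to patients when
they modulate panel genes opposite to the disease direction, a
sign-agreement anti-match score ranks repurposing candidates, and a
clinician report digitizes each marker against severely depressed
(HAMD ≥ 22) and non-depressed (HAMD ≤ 7) reference groups into {0, 0.5, 1},
averages them into a 0–100 polygenic score with percentile, risk tier, and
asterisk flags for future-hospitalization and bipolar-switching risk.

## Worked example

```python
import moodmarkers as mm

cfg = mm.PipelineConfig(sim=mm.SimConfig(n_probesets=400, n_markers_planted=12,
                                         n_subjects_test=80, seed=7))
art = mm.run_pipeline(cfg, "out/")
print(art["dossier_table"].sort_values("cfe_depression", ascending=False)
      [["probeset_id", "discovery_points", "cfg_points",
        "validation_points", "cfe_depression", "cfe_bipolar"]].head())
```

prints

```
probeset_id  discovery_points  cfg_points  validation_points  cfe_depression  cfe_bipolar
ps_00315_at                 6          10                  6              34           46
ps_00278_at                 6           9                  6              33           45
ps_00313_at                 6           9                  6              33           42
ps_00326_at                 6           9                  6              33           45
ps_00039_at                 6           7                  6              31           43
```

All 12 planted markers survive to the dossier stage on this configuration:
each row shows a marker's discovery, literature-prioritization, and
validation points, and the two family composites (the depression CFE sums
steps 1–3 with the four depression-family testing categories; the bipolar
CFE adds the four mania-family categories as well). The run also writes a
patient report, e.g.

```
report: subject=phtst000 score=75.0 tier=intermediate percentile=86 future=1 bipolarity=0
```

— this patient's digitized panel averages to a polygenic depression score
of 75/100, above 86 % of the database, in the intermediate risk tier, with
one of the future-risk trait markers at 1 and no bipolar-switching flag.

The same pipeline is available from a shell:

```bash
moodmarkers simulate --seed 4 --n-probesets 500 --out cohort/
moodmarkers run --seed 7 --out results/
```

## Layout

- `src/moodmarkers/synthetic_cohort.py` — seeded cohort/expression/evidence/drug generators
- `src/moodmarkers/preprocess.py` — scale-tagged matrices, de-log, stratified z-scoring, detection calls
- `src/moodmarkers/discovery.py` — step 1 within-subject scoring
- `src/moodmarkers/cfg_prioritization.py` — step 2 literature-evidence scoring and carry-forward
- `src/moodmarkers/validation.py` — step 3 stepwise + ANOVA scoring
- `src/moodmarkers/testing.py` — step 4 stratified state/trait prediction
- `src/moodmarkers/cfe_panel.py` — CFE aggregation, panel selection, enrichment arithmetic
- `src/moodmarkers/therapeutics.py` — drug matching and signature anti-match ranking
- `src/moodmarkers/report.py` — digitization, polygenic score, tiers, flags, medication ranking
- `src/moodmarkers/pipeline.py`, `cli.py` — end-to-end driver and command line

See `docs/methods.md` for the modelling choices, defaults, and limitations.
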