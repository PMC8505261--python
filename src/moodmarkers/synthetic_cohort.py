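"""Seeded synthetic cohorts with the structure the pipeline assumes.

The generator emulates the data layout of a longitudinal blood
transcriptomics study of mood: an Affymetrix-like probeset x visit matrix
on the log2 (RMA-like) scale; a discovery cohort in which every subject has
at least one pair of consecutive visits with diametric SMS-7 mood states;
an independent validation cohort with clinically severe depression
(HAMD >= 22) or mania (YMRS >= 20); and a test cohort with follow-up
hospitalization records.  A configurable number of "planted" marker
probesets shift by a known log2 fold change between mood states (half
increased in high mood, half decreased), clinical severity groups shift
further in the same direction (giving the stepwise pattern validation looks
for), and hospitalization times follow an exponential model whose log
hazard is linear in the risk-directed planted-marker signal.  Everything is
reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import DECREASED, INCREASED
from .preprocess import SCALE_LOG2, ExpressionMatrix

#: default (gender, diagnosis, baseline log2 offset) strata
DEFAULT_STRATA = (
    ("M", "BP", 0.00), ("M", "MDD", 0.08), ("M", "SZA", 0.16), ("M", "PTSD", 0.24),
    ("F", "BP", 0.12), ("F", "MDD", 0.20), ("F", "SZA", 0.28), ("F", "PTSD", 0.36),
)

_MOOD_SHIFT = {"low": -0.5, "intermediate": 0.0, "high": 0.5,
               "clinical_depression": -0.75, "clinical_mania": 0.75}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic cohort generator.

    The defaults describe the desk-scale study: 2,000 probesets with 20
    planted markers shifting by one log2 unit between high- and low-mood
    states under 0.2 log2 units of per-visit noise, 40 discovery subjects,
    and a log-hazard of 0.7 per unit of risk-directed marker z for
    hospitalization events.  The 54,625-probeset nominal array size is a
    config option, not the default.
    """

    n_probesets: int = 2000
    n_markers_planted: int = 20
    effect_log2fc: float = 1.0
    noise_sd: float = 0.2
    n_subjects_discovery: int = 40
    n_subjects_validation: int = 40
    n_subjects_test: int = 120
    visits_per_subject: tuple[int, int] = (2, 6)
    strata: Sequence[tuple[str, str, float]] = DEFAULT_STRATA
    hazard_beta: float = 0.7
    baseline_log2: float = 7.0
    subject_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_probesets, self.n_subjects_discovery,
               self.n_subjects_validation, self.n_subjects_test) < 1:
            raise ValueError("all cohort and probeset counts must be >= 1")
        if self.n_markers_planted > self.n_probesets:
            raise ValueError("cannot plant more markers than probesets")
        if self.n_markers_planted < 0 or self.effect_log2fc < 0:
            raise ValueError("planted count and effect size must be non-negative")
        lo, hi = self.visits_per_subject
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_subject must be a valid (min, max) range")


@dataclass
class SyntheticTruth:
    """Ground truth the generator planted, for oracle-style checks."""

    planted: list[str]
    directions: dict[str, str]          # probeset -> direction in high mood
    baseline: pd.Series                 # per-probeset baseline log2
    probeset_gene: dict[str, str]       # probeset -> gene symbol
    config: dict = field(default_factory=dict)


def _gene_of(i: int) -> str:
    return f"GENE{i:05d}"


def _probeset_of(i: int) -> str:
    return f"ps_{i:05d}_at"


def generate_cohort(config: SimConfig
                    ) -> tuple[pd.DataFrame, ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate visits, expression, follow-up records, and planted truth.

    Returns ``(visits, matrix, followup, truth)``: a visit table covering
    all three cohorts (``cohort`` column in {discovery, validation, test}),
    a log2-scale expression matrix over every visit sample, per-subject
    follow-up records for the test cohort (one per event type, anchored at
    each subject's final visit), and the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    probesets = [_probeset_of(i) for i in range(config.n_probesets)]
    genes = {p: _gene_of(i) for i, p in enumerate(probesets)}
    baseline = pd.Series(
        config.baseline_log2 + rng.normal(0.0, 1.0, config.n_probesets),
        index=probesets)
    planted_idx = np.sort(rng.choice(config.n_probesets,
                                     size=config.n_markers_planted, replace=False))
    planted = [probesets[i] for i in planted_idx]
    directions = {p: (INCREASED if k % 2 == 0 else DECREASED)
                  for k, p in enumerate(planted)}
    dir_sign = pd.Series(0.0, index=probesets)
    for p, d in directions.items():
        dir_sign[p] = 1.0 if d == INCREASED else -1.0

    strata = list(config.strata)
    offsets = {(g, d): off for g, d, off in strata}

    visit_rows: list[dict] = []
    expr_cols: dict[str, np.ndarray] = {}
    state_of: dict[str, str] = {}

    def add_visit(subject: str, cohort: str, visit: int, days: float,
                  gender: str, dx: str, state: str) -> None:
        sample = f"{subject}_v{visit}"
        if state == "low" or state == "clinical_depression":
            sms7 = float(rng.integers(5, 41))
            hamd = float(rng.integers(22, 36)) if state == "clinical_depression" \
                else float(rng.integers(8, 31))
            ymrs = float(rng.integers(0, 6))
        elif state == "high" or state == "clinical_mania":
            sms7 = float(rng.integers(60, 96))
            hamd = float(rng.integers(0, 8))
            ymrs = float(rng.integers(20, 41)) if state == "clinical_mania" \
                else float(rng.integers(3, 26))
        else:
            sms7 = float(rng.integers(41, 60))
            hamd = float(rng.integers(5, 16))
            ymrs = float(rng.integers(0, 10))
        visit_rows.append({
            "subject_id": subject, "visit_number": visit, "sample_id": sample,
            "days_since_first": days, "gender": gender, "diagnosis": dx,
            "sms7": sms7, "hamd": hamd, "ymrs": ymrs,
            "cfi_bp": int(rng.integers(1, 11)) if dx == "BP" else np.nan,
            "cohort": cohort,
        })
        state_of[sample] = state

    def subject_visits(subject: str, cohort: str, gender: str, dx: str,
                       states: Sequence[str]) -> None:
        days = 0.0
        for v, state in enumerate(states, start=1):
            add_visit(subject, cohort, v, days, gender, dx, state)
            days += float(rng.integers(60, 200))

    lo_v, hi_v = config.visits_per_subject
    for i in range(config.n_subjects_discovery):
        g, dx, _ = strata[i % len(strata)]
        n_visits = int(rng.integers(max(lo_v, 2), hi_v + 1))
        start_low = bool(rng.integers(0, 2))
        states = []
        for v in range(n_visits):
            base = "low" if (v % 2 == 0) == start_low else "high"
            # first two visits stay diametric so every subject keeps >= 1
            # consecutive low<->high pair; later visits may be intermediate
            if v >= 2 and rng.random() < 0.25:
                base = "intermediate"
            states.append(base)
        subject_visits(f"phchp{i:03d}", "discovery", g, dx, states)

    for i in range(config.n_subjects_validation):
        g, dx, _ = strata[i % len(strata)]
        state = "clinical_depression" if i % 2 == 0 else "clinical_mania"
        subject_visits(f"phval{i:03d}", "validation", g, dx, [state])

    for i in range(config.n_subjects_test):
        g, dx, _ = strata[i % len(strata)]
        n_visits = int(rng.integers(lo_v, hi_v + 1))
        states = [("low", "intermediate", "high")[rng.choice(3, p=(0.3, 0.4, 0.3))]
                  for _ in range(n_visits)]
        subject_visits(f"phtst{i:03d}", "test", g, dx, states)

    visits = pd.DataFrame(visit_rows)

    subject_ids = visits["subject_id"].unique()
    subject_intercept = pd.Series(
        rng.normal(0.0, config.subject_sd, len(subject_ids)), index=subject_ids)

    for row in visits.itertuples():
        mood = _MOOD_SHIFT[state_of[row.sample_id]]
        mean = (baseline.to_numpy()
                + offsets[(row.gender, row.diagnosis)]
                + subject_intercept[row.subject_id]
                + dir_sign.to_numpy() * config.effect_log2fc * mood)
        expr_cols[row.sample_id] = mean + rng.normal(0.0, config.noise_sd,
                                                     config.n_probesets)
    matrix = ExpressionMatrix(
        pd.DataFrame(expr_cols, index=probesets)[visits["sample_id"]], SCALE_LOG2)

    followup = _generate_followup(config, rng, visits, matrix, planted,
                                  dir_sign, baseline, offsets, subject_intercept)

    truth = SyntheticTruth(planted=planted, directions=directions,
                           baseline=baseline, probeset_gene=genes,
                           config=asdict(config))
    return visits, matrix, followup, truth


def _generate_followup(config, rng, visits, matrix, planted, dir_sign,
                       baseline, offsets, subject_intercept) -> pd.DataFrame:
    """Exponential time-to-hospitalization with log-linear hazard in marker z."""
    test = visits[visits["cohort"] == "test"]
    anchors = (test.sort_values("visit_number")
               .groupby("subject_id").tail(1).set_index("subject_id"))
    base_rate = 1.0 / 700.0  # baseline mean time to event, days

    # risk-directed marker signal at the anchor visit, standardized
    risk = {}
    for subj, row in anchors.iterrows():
        expected = (baseline[planted]
                    + offsets[(row["gender"], row["diagnosis"])]
                    + subject_intercept[subj])
        resid = matrix.values.loc[planted, row["sample_id"]] - expected
        risk[subj] = float((-dir_sign[planted] * resid).mean())  # depression risk
    risk = pd.Series(risk)
    scale = risk.std(ddof=0)
    z_dep = (risk - risk.mean()) / scale if scale > 0 else risk * 0.0

    rows = []
    for subj, row in anchors.iterrows():
        follow = float(rng.integers(365, 2501))
        for event_type, z in (("hosp_depression", z_dep[subj]),
                              ("hosp_mania", -z_dep[subj])):
            rate = base_rate * float(np.exp(config.hazard_beta * z))
            t = float(rng.exponential(1.0 / rate))
            event = t <= follow
            rows.append({
                "subject_id": subj, "anchor_visit": int(row["visit_number"]),
                "event_type": event_type,
                "time_to_first_event": round(t, 1) if event else np.nan,
                "followup_days": follow,
                "n_events": int(event),
            })
    return pd.DataFrame(rows)


def generate_evidence_db(genes: Sequence[str],
                         planted_genes: Sequence[str] = (),
                         planted_fraction_with_evidence: float = 1.0,
                         seed: int = 0) -> pd.DataFrame:
    """Six-category literature-evidence levels per gene, planted genes enriched.

    Background genes draw each category from {0, 1, 2} with probabilities
    (0.80, 0.15, 0.05); the chosen fraction of planted genes draw from
    (0.20, 0.30, 0.50), emulating well-studied mood genes.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    from .cfg_prioritization import EVIDENCE_CATEGORIES
    rng = np.random.default_rng(seed)
    genes = list(genes)
    enriched: set[str] = set()
    planted_genes = [g for g in planted_genes if g in set(genes)]
    if planted_genes and planted_fraction_with_evidence > 0:
        k = int(round(planted_fraction_with_evidence * len(planted_genes)))
        enriched = set(rng.choice(planted_genes, size=k, replace=False))
    rows = {}
    for g in genes:
        p = (0.20, 0.30, 0.50) if g in enriched else (0.80, 0.15, 0.05)
        rows[g] = rng.choice(3, size=len(EVIDENCE_CATEGORIES), p=p)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(EVIDENCE_CATEGORIES)).rename_axis("gene")


def generate_drug_tables(genes: Sequence[str], n_drugs: int = 12, seed: int = 0
                         ) -> tuple[dict[str, dict[str, str]],
                                    dict[str, dict[str, int]]]:
    """Random drug-gene modulation table and signed drug signatures.

    Each drug modulates a random subset of genes up or down; its signature
    is the signed version of the same set.  Deterministic under the seed.
    """
    if n_drugs < 1:
        raise ValueError("need at least one drug")
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    drug_gene: dict[str, dict[str, str]] = {}
    drug_sig: dict[str, dict[str, int]] = {}
    for i in range(n_drugs):
        drug = f"compound_{i:02d}"
        k = int(rng.integers(2, max(3, min(15, len(genes)) + 1)))
        chosen = rng.choice(genes, size=min(k, len(genes)), replace=False)
        signs = rng.choice([1, -1], size=len(chosen))
        drug_gene[drug] = {g: ("up" if s > 0 else "down")
                           for g, s in zip(chosen, signs)}
        drug_sig[drug] = {g: int(s) for g, s in zip(chosen, signs)}
    return drug_gene, drug_sig
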