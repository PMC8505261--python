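"""End-to-end pipeline driver: simulate -> discover -> prioritize ->
validate -> test -> CFE -> panel -> drugs -> report.

Every stage's output is written to the output directory, together with the
effective configuration, its hash, and the seed, so a rerun under the same
configuration is bit-identical and each intermediate is inspectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (cfe_panel, cfg_prioritization, discovery, preprocess, report,
               synthetic_cohort, testing, therapeutics, validation)
from .preprocess import ExpressionMatrix
from .synthetic_cohort import SimConfig


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, defaulting to the published values.

    Overriding any threshold is allowed (and recorded in the output
    metadata), but the defaults are the study's printed constants: mood
    cutoffs 40/60, HAMD 22 (severe) and 7 (non-depressed reference),
    YMRS 20, fold-change steps 1.2/1.1, internal-point percentages
    33.3/50/80, carry-forward 6, alpha 0.05, first-year Cox horizon 365 d.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    low_mood_cutoff: float = discovery.LOW_MOOD_CUTOFF
    high_mood_cutoff: float = discovery.HIGH_MOOD_CUTOFF
    hamd_severe: float = validation.HAMD_SEVERE
    hamd_nondepressed: float = report.HAMD_NON_DEPRESSED
    ymrs_severe: float = validation.YMRS_SEVERE
    alpha: float = testing.ALPHA
    carry_forward_threshold: int = cfg_prioritization.CARRY_FORWARD_THRESHOLD
    n_drugs: int = 12
    adjacency: str = "strict"

    def __post_init__(self) -> None:
        if self.low_mood_cutoff >= self.high_mood_cutoff:
            raise ValueError("low-mood cutoff must be below high-mood cutoff")
        if self.hamd_nondepressed >= self.hamd_severe:
            raise ValueError("HAMD reference cutoffs inverted")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline on a synthetic cohort; return the artifacts.

    Writes per-stage tables (TSV/CSV), the panel and drug rankings (JSON),
    at least one patient report, and a metadata file carrying the config
    hash and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate -------------------------------------------------------
    visits, matrix, followup, truth = synthetic_cohort.generate_cohort(config.sim)
    genes = truth.probeset_gene
    evidence = synthetic_cohort.generate_evidence_db(
        sorted(set(genes.values())),
        planted_genes=[genes[p] for p in truth.planted],
        seed=config.sim.seed + 1)
    drug_gene_db, drug_sig_db = synthetic_cohort.generate_drug_tables(
        sorted(set(genes.values())), n_drugs=config.n_drugs,
        seed=config.sim.seed + 2)

    visits.to_csv(outdir / "visits.csv", index=False)
    followup.to_csv(outdir / "followup.csv", index=False)
    matrix.to_tsv(outdir / "expression_log2.tsv")
    evidence.to_csv(outdir / "evidence_db.tsv", sep="\t")
    (outdir / "drug_gene_db.json").write_text(json.dumps(drug_gene_db, indent=1))
    (outdir / "drug_signature_db.json").write_text(json.dumps(drug_sig_db, indent=1))

    by_cohort = {c: visits[visits["cohort"] == c] for c in
                 ("discovery", "validation", "test")}

    # --- step 1: discovery ---------------------------------------------
    disc_visits = by_cohort["discovery"]
    disc_matrix = ExpressionMatrix(matrix.values[disc_visits["sample_id"]],
                                   matrix.scale_tag)
    calls = preprocess.ap_call(disc_matrix)
    disc = discovery.run_discovery(disc_matrix, disc_visits, calls,
                                   adjacency=config.adjacency)
    disc["gene"] = disc["probeset_id"].map(genes)
    disc.to_csv(outdir / "step1_discovery.tsv", sep="\t", index=False)

    # --- step 2: CFG prioritization ------------------------------------
    candidates = disc[disc["internal_points"] > 0].rename(
        columns={"internal_points": "discovery_points"})
    prioritized = cfg_prioritization.carry_forward(
        candidates, evidence, threshold=config.carry_forward_threshold)
    prioritized.to_csv(outdir / "step2_prioritized.tsv", sep="\t", index=False)
    carried = prioritized[prioritized["carried_forward"]]

    # --- step 3: validation --------------------------------------------
    val_samples = pd.concat([by_cohort["discovery"], by_cohort["validation"]])
    val_matrix = ExpressionMatrix(matrix.values[val_samples["sample_id"]],
                                  matrix.scale_tag)
    z_val = preprocess.zscore_by_stratum(
        preprocess.delog(val_matrix), val_samples)
    groups = validation.build_validation_groups(
        by_cohort["discovery"], by_cohort["validation"],
        hamd_cutoff=config.hamd_severe, ymrs_cutoff=config.ymrs_severe)
    carried_best = (carried.sort_values(["combined", "probeset_id"],
                                        ascending=[False, True])
                    .drop_duplicates("probeset_id"))
    directions = carried_best.set_index("probeset_id")["direction"]
    val = validation.anova_validation(z_val, groups, directions,
                                      alpha=config.alpha)
    val.to_csv(outdir / "step3_validation.tsv", sep="\t", index=False)

    # --- step 4: testing ------------------------------------------------
    test_visits = by_cohort["test"]
    test_matrix = ExpressionMatrix(matrix.values[test_visits["sample_id"]],
                                   matrix.scale_tag)
    lin_test = preprocess.delog(test_matrix)
    z_test = preprocess.zscore_by_stratum(lin_test, test_visits)
    top = val[val["points"] > 0]
    panel_in = top[["probeset_id", "direction"]].reset_index(drop=True)
    predictions = testing.stratified_testing(
        panel_in, z_test.values, lin_test.values, test_visits, followup,
        alpha=config.alpha)
    predictions.to_csv(outdir / "step4_predictions.tsv", sep="\t", index=False)
    points = testing.assign_testing_points(predictions, alpha=config.alpha) \
        if not predictions.empty else pd.DataFrame(
            columns=["probeset_id", "target", "points"])

    # --- CFE aggregation and panel selection ----------------------------
    pts_map = {(r.probeset_id, r.target): int(r.points)
               for r in points.itertuples()}
    dossiers = []
    for r in carried_best.itertuples():
        if r.probeset_id not in val.index:
            continue
        dossiers.append(cfe_panel.MarkerDossier(
            probeset_id=r.probeset_id, gene=r.gene,
            discovery_points=int(r.discovery_points),
            cfg_points=int(r.cfg_points),
            validation_points=int(val.loc[r.probeset_id, "points"]),
            testing_points={t: pts_map.get((r.probeset_id, t), 0)
                            for t in testing.ALL_TARGETS},
            direction=r.direction))
    dossier_df = cfe_panel.dossier_table(dossiers)
    dossier_df.to_csv(outdir / "cfe_dossiers.tsv", sep="\t", index=False)

    artifacts = {"visits": visits, "matrix": matrix, "followup": followup,
                 "truth": truth, "discovery": disc, "prioritized": prioritized,
                 "validation": val, "predictions": predictions,
                 "dossiers": dossiers, "dossier_table": dossier_df}

    if dossiers:
        ref = max(dossiers, key=lambda d: (cfe_total_safe(d), d.probeset_id))
        median_ref = sorted(dossiers, key=lambda d: (cfe_total_safe(d),
                                                     d.probeset_id))[len(dossiers) // 2]
        panel = cfe_panel.select_panel(dossiers, median_ref.probeset_id,
                                       "depression", name="depression_panel")
        panel.to_json(outdir / "panel_depression.json")
        artifacts["panel"] = panel

        # --- therapeutics ------------------------------------------------
        gene_dirs = {genes[p]: panel.directions[p] for p in panel.members}
        matches = therapeutics.pharmacogenomic_match(gene_dirs, drug_gene_db)
        panel_sig = {g: (1 if d == discovery.INCREASED else -1) * -1
                     for g, d in gene_dirs.items()}  # depression-direction signs
        repurposing = therapeutics.rank_drugs(panel_sig, drug_sig_db)
        repurposing.to_csv(outdir / "repurposing.tsv", sep="\t", index=False)
        artifacts["repurposing"] = repurposing

        # --- patient report ---------------------------------------------
        marker_dirs = {p: panel.directions[p] for p in panel.members}
        patient_visit = test_visits.loc[test_visits["hamd"].idxmax()]
        ref_profile = report.build_reference_profile(
            z_test.values, test_visits, marker_dirs,
            exclude_subject=patient_visit["subject_id"])
        z_patient = {p: float(z_test.values.at[p, patient_visit["sample_id"]])
                     for p in panel.members}
        digitized = report.digitize_panel(z_patient, ref_profile, marker_dirs)
        score = report.polygenic_score(digitized)
        tier, percentile = report.risk_tier(score, ref_profile)
        gene_digitized = {genes[p]: v for p, v in digitized.items()}
        meds = report.medication_ranking(gene_digitized, matches)
        trait_subset = panel.members[: min(3, len(panel.members))]
        bipolar_subset = panel.members[: min(6, len(panel.members))]
        future, bip = report.risk_flags(digitized, trait_subset, bipolar_subset,
                                        mania_marker=None)
        patient_report = report.PatientReport(
            subject_id=str(patient_visit["subject_id"]),
            sample_id=str(patient_visit["sample_id"]),
            digitized=digitized, polygenic_score=score, percentile=percentile,
            risk_tier=tier, future_risk_asterisks=future,
            bipolarity_asterisks=bip, medications=meds,
            repurposing=repurposing)
        patient_report.to_json(outdir / "patient_report.json")
        (outdir / "patient_report.md").write_text(patient_report.to_markdown())
        artifacts["report"] = patient_report

    meta = {"config": config.to_dict(), "config_hash": config.config_hash(),
            "seed": config.sim.seed}
    (outdir / "metadata.json").write_text(
        json.dumps(meta, indent=1, default=str))
    return artifacts


def cfe_total_safe(dossier) -> int:
    return cfe_panel.cfe_total(dossier, "depression")
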