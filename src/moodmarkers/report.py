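"""Clinician report: digitized panel, polygenic score, risk tiers, medications.

A new patient's stratum-z-scored marker values are digitized against two
reference groups drawn from the database of previously tested subjects: the
severely depressed (HAMD >= 22) and the non-depressed (HAMD <= 7).  For a
marker increased in depression, a value above the depressed-group mean
scores 1, below the non-depressed mean 0, in between 0.5; decreased markers
mirror the rule.  Digitized scores average into a 0-100 polygenic
depression score, ranked against the database distribution, with flags for
future hospitalization risk and bipolar switching, plus a ranked list of
medications matched to the elevated markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .discovery import INCREASED
from .therapeutics import disease_direction

HAMD_DEPRESSED = 22.0
HAMD_NON_DEPRESSED = 7.0

TIER_HIGH, TIER_INTERMEDIATE, TIER_LOW = "high", "intermediate", "low"
_TIER_COLORS = {TIER_HIGH: "red", TIER_INTERMEDIATE: "yellow", TIER_LOW: "green"}


@dataclass
class ReferenceProfile:
    """Frozen reference statistics against which new patients are scored.

    ``depressed_mean`` / ``nondepressed_mean`` hold the per-marker mean z
    values of the two reference groups; ``score_distribution`` the polygenic
    scores of every database subject (for percentile ranking), and the
    two group-average polygenic scores set the tier boundaries.
    """

    depressed_mean: pd.Series
    nondepressed_mean: pd.Series
    score_distribution: np.ndarray
    depressed_score_mean: float
    nondepressed_score_mean: float
    n_subjects: int


def digitize_marker(z_value: float, depressed_mean: float,
                    nondepressed_mean: float, direction_in_high_mood: str) -> float:
    """Digitize one marker z-value to 0, 0.5 or 1 against the reference means.

    Boundary ties resolve toward the more severe bin.  Inverted reference
    means (the non-depressed mean beyond the depressed mean in the risk
    direction) are flagged as an error.
    """
    increased_in_depression = disease_direction(direction_in_high_mood) == "up"
    if increased_in_depression:
        if nondepressed_mean > depressed_mean:
            raise ValueError("reference means inverted for increased marker")
        if z_value >= depressed_mean:
            return 1.0
        if z_value <= nondepressed_mean:
            return 0.0
    else:
        if nondepressed_mean < depressed_mean:
            raise ValueError("reference means inverted for decreased marker")
        if z_value <= depressed_mean:
            return 1.0
        if z_value >= nondepressed_mean:
            return 0.0
    return 0.5


def digitize_panel(z_values: Mapping[str, float], ref: ReferenceProfile,
                   directions: Mapping[str, str]) -> dict[str, float]:
    return {m: digitize_marker(z_values[m], ref.depressed_mean[m],
                               ref.nondepressed_mean[m], directions[m])
            for m in directions}


def polygenic_score(digitized: Mapping[str, float] | list[float]) -> float:
    """100 x the mean digitized score, to two decimals."""
    vals = list(digitized.values()) if isinstance(digitized, Mapping) else list(digitized)
    if not vals:
        raise ValueError("empty panel")
    return round(100.0 * float(np.mean(vals)), 2)


def build_reference_profile(z_matrix: pd.DataFrame, visits: pd.DataFrame,
                            directions: Mapping[str, str],
                            exclude_subject: str | None = None) -> ReferenceProfile:
    """Reference means and score distribution from the subject database.

    The scored patient must be excluded (``exclude_subject``) so the profile
    is independent of the report it feeds.  Digitization of the database
    subjects themselves uses the same rule applied to new patients.
    """
    vis = visits.set_index("sample_id") if "sample_id" in visits.columns else visits
    vis = vis.loc[vis.index.intersection(z_matrix.columns)]
    if exclude_subject is not None:
        vis = vis[vis["subject_id"] != exclude_subject]
    markers = list(directions)
    dep = vis.index[vis["hamd"] >= HAMD_DEPRESSED]
    non = vis.index[vis["hamd"] <= HAMD_NON_DEPRESSED]
    if len(dep) == 0 or len(non) == 0:
        raise ValueError("both reference groups must be nonempty")
    dep_mean = z_matrix.loc[markers, dep].mean(axis=1)
    non_mean = z_matrix.loc[markers, non].mean(axis=1)

    scores = {}
    for sample in vis.index:
        digitized = {m: digitize_marker(z_matrix.at[m, sample], dep_mean[m],
                                        non_mean[m], directions[m])
                     for m in markers}
        scores[sample] = polygenic_score(digitized)
    score_series = pd.Series(scores)
    return ReferenceProfile(
        depressed_mean=dep_mean, nondepressed_mean=non_mean,
        score_distribution=score_series.to_numpy(),
        depressed_score_mean=float(score_series[dep].mean()),
        nondepressed_score_mean=float(score_series[non].mean()),
        n_subjects=int(vis["subject_id"].nunique()))


def risk_tier(score: float, ref: ReferenceProfile) -> tuple[str, float]:
    """Risk tier and rank percentile of a polygenic score.

    High if at or above the depressed-group average score, low if at or
    below the non-depressed average, else intermediate; percentile is the
    inclusive fraction of database scores <= the patient's score, x 100.
    """
    if score >= ref.depressed_score_mean:
        tier = TIER_HIGH
    elif score <= ref.nondepressed_score_mean:
        tier = TIER_LOW
    else:
        tier = TIER_INTERMEDIATE
    percentile = 100.0 * float(np.mean(ref.score_distribution <= score))
    return tier, percentile


def risk_flags(digitized: Mapping[str, float],
               trait_risk_markers: list[str],
               bipolar_markers: list[str],
               mania_marker: str | None) -> tuple[int, int]:
    """Future-risk and bipolarity asterisk counts.

    Future risk: how many of the trait-risk subset scored 1 (0-3 asterisks).
    Bipolarity: one asterisk if strictly more than half the bipolar subset
    scored 1, plus one if the mania marker scored 1 (0-2 asterisks).
    """
    for m in trait_risk_markers + bipolar_markers + ([mania_marker] if mania_marker else []):
        if m not in digitized:
            raise ValueError(f"role-tagged marker {m!r} missing from panel")
    future = sum(1 for m in trait_risk_markers if digitized[m] == 1.0)
    n_bip_hit = sum(1 for m in bipolar_markers if digitized[m] == 1.0)
    bipolarity = int(n_bip_hit > len(bipolar_markers) / 2)
    if mania_marker is not None and digitized[mania_marker] == 1.0:
        bipolarity += 1
    return future, bipolarity


def medication_ranking(digitized: Mapping[str, float],
                       matches: Mapping[str, set[str]]) -> pd.DataFrame:
    """Score each medication by its coverage of the patient's elevated panel.

    Per medication: 100 x the mean over all panel markers of
    (1 if the drug matches the marker else 0) x the marker's digitized
    score.  Sorted descending with a deterministic name tie-break.
    """
    markers = list(digitized)
    rows = []
    for drug, matched in matches.items():
        hit = sum(digitized[m] for m in markers if m in matched)
        rows.append({"medication": drug, "score": 100.0 * hit / len(markers)})
    out = pd.DataFrame(rows, columns=["medication", "score"])
    return out.sort_values(["score", "medication"], ascending=[False, True],
                           ignore_index=True)


@dataclass
class PatientReport:
    """Everything the clinician-facing rendering needs."""

    subject_id: str
    sample_id: str
    digitized: dict[str, float]
    polygenic_score: float
    percentile: float
    risk_tier: str
    future_risk_asterisks: int
    bipolarity_asterisks: int
    medications: pd.DataFrame
    repurposing: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path) -> None:
        payload = {
            "subject_id": self.subject_id, "sample_id": self.sample_id,
            "digitized": self.digitized,
            "polygenic_score": self.polygenic_score,
            "percentile": self.percentile,
            "risk_tier": self.risk_tier,
            "risk_tier_color": _TIER_COLORS[self.risk_tier],
            "future_risk_asterisks": self.future_risk_asterisks,
            "bipolarity_asterisks": self.bipolarity_asterisks,
            "medications": self.medications.to_dict(orient="records"),
            "repurposing": self.repurposing.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_markdown(self) -> str:
        lines = [
            f"# Mood biomarker report — subject {self.subject_id}",
            "",
            f"**Polygenic depression score:** {self.polygenic_score:.2f} / 100",
            f"**Percentile in database:** {self.percentile:.0f}%",
            f"**Current depression severity tier:** {self.risk_tier}"
            f" ({_TIER_COLORS[self.risk_tier]})",
            f"**Future depression hospitalization risk:** "
            f"{'*' * self.future_risk_asterisks or 'none'}",
            f"**Bipolar switching risk:** "
            f"{'*' * self.bipolarity_asterisks or 'none'}",
            "",
            "## Digitized biomarkers",
        ]
        for marker, val in self.digitized.items():
            lines.append(f"- {marker}: {val:g}")
        lines += ["", "## Ranked existing medications"]
        for row in self.medications.itertuples():
            lines.append(f"- {row.medication}: {row.score:.1f}")
        if len(self.repurposing):
            lines += ["", "## Repurposing candidates"]
            for row in self.repurposing.itertuples():
                lines.append(f"- {row.drug}: {row.score:+.2f}")
        return "\n".join(lines) + "\n"
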