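"""Convergent Functional Evidence (CFE) aggregation and panel selection.

Per marker, the CFE score adds discovery internal points (up to 6), CFG
prioritization points (up to 12), validation points (up to 6), and testing
points (up to 3 per phenotype target).  The depression-family CFE sums the
four depression targets, the mania-family CFE the four mania targets, and
the bipolar CFE all eight, so the maximum is 6 + 12 + 6 + 8 x 3 = 48.
Panels are selected with a reference-marker cutoff: every marker scoring at
least as well as the reference (a de facto positive control) is a member.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .testing import ALL_TARGETS, DEPRESSION_FAMILY, MANIA_FAMILY

CFE_MAX = 48

_FAMILY_TARGETS = {
    "depression": DEPRESSION_FAMILY,
    "mania": MANIA_FAMILY,
    "bipolar": ALL_TARGETS,
}


@dataclass
class MarkerDossier:
    """Accumulated evidence for one (probeset, method) candidate."""

    probeset_id: str
    gene: str
    discovery_points: int
    cfg_points: int
    validation_points: int
    testing_points: dict[str, int] = field(default_factory=dict)
    direction: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.testing_points) - set(ALL_TARGETS)
        if unknown:
            raise ValueError(f"unknown testing targets: {sorted(unknown)}")

    @property
    def steps123(self) -> int:
        return self.discovery_points + self.cfg_points + self.validation_points


def cfe_total(dossier: MarkerDossier, family: str) -> int:
    """Family CFE score: steps 1-3 subtotal plus the family's testing points."""
    if family not in _FAMILY_TARGETS:
        raise ValueError(f"unknown family {family!r}")
    for component in ("discovery_points", "cfg_points", "validation_points"):
        if getattr(dossier, component) is None:
            raise ValueError(f"dossier missing {component}")
    testing = sum(dossier.testing_points.get(t, 0) for t in _FAMILY_TARGETS[family])
    return dossier.steps123 + testing


def dossier_table(dossiers: Sequence[MarkerDossier]) -> pd.DataFrame:
    """Tabulate dossiers with per-family CFE totals."""
    rows = []
    for d in dossiers:
        rows.append({
            "probeset_id": d.probeset_id, "gene": d.gene,
            "direction": d.direction,
            "discovery_points": d.discovery_points, "cfg_points": d.cfg_points,
            "validation_points": d.validation_points,
            **{f"testing_{t}": d.testing_points.get(t, 0) for t in ALL_TARGETS},
            "cfe_depression": cfe_total(d, "depression"),
            "cfe_mania": cfe_total(d, "mania"),
            "cfe_bipolar": cfe_total(d, "bipolar"),
        })
    return pd.DataFrame(rows)


@dataclass
class PanelDefinition:
    """A named biomarker panel with member directions and role tags."""

    name: str
    members: list[str]
    directions: dict[str, str]
    role_tags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        member_set = set(self.members)
        for tag, ids in self.role_tags.items():
            stray = set(ids) - member_set
            if stray:
                raise ValueError(f"role tag {tag!r} references non-members: {sorted(stray)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "name": self.name, "members": self.members,
            "directions": self.directions, "role_tags": self.role_tags,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        return cls(**json.loads(Path(path).read_text()))


def select_panel(dossiers: Sequence[MarkerDossier], reference_probeset: str,
                 family: str, name: str | None = None) -> PanelDefinition:
    """All markers with family CFE >= the reference marker's, sorted.

    Sorting is descending by score with a deterministic probeset-id
    tie-break, so the panel is reproducible regardless of input order.
    """
    by_id = {d.probeset_id: d for d in dossiers}
    if reference_probeset not in by_id:
        raise ValueError(f"reference marker {reference_probeset!r} not in dossiers")
    cutoff = cfe_total(by_id[reference_probeset], family)
    scored = [(cfe_total(d, family), d) for d in dossiers]
    members = sorted((d for s, d in scored if s >= cutoff),
                     key=lambda d: (-cfe_total(d, family), d.probeset_id))
    return PanelDefinition(
        name=name or f"{family}_panel",
        members=[d.probeset_id for d in members],
        directions={d.probeset_id: d.direction for d in members})


def enrichment_fold(n_total: int, n_retained: int) -> float:
    """Fold enrichment of a filtering step: total / retained."""
    if n_retained < 1:
        raise ValueError("at least one retained item is required")
    return n_total / n_retained


def category_enrichment(panel_genes: Iterable[str], category_genes: Iterable[str],
                        genome_size: int = 21000) -> float:
    """Fold over-representation of a gene category in a panel.

    (k/n) / (K/N) with k the panel genes in the category, n the panel size,
    K the category size, N the genome size (default 21,000 genes).
    """
    panel = set(panel_genes)
    category = set(category_genes)
    if not panel:
        raise ValueError("panel is empty")
    if not category:
        raise ValueError("category is empty")
    k = len(panel & category)
    return (k / len(panel)) / (len(category) / genome_size)


def read_gene_category(path: str | Path) -> pd.DataFrame:
    """Read a plain-text gene list, one gene per line, optional tier column."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows.append({"gene": parts[0],
                     "tier": parts[1] if len(parts) > 1 else None})
    return pd.DataFrame(rows)
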