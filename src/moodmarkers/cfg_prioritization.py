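"""Step 2 — Convergent Functional Genomics (CFG) prioritization.

Discovery candidates are scored against a structured literature-evidence
database with six streams: human genetic, human brain, human peripheral,
animal genetic, animal brain, animal peripheral.  Evidence within each
stream is graded none/modest/strong (0/1/2); the six capped stream scores
sum to a CFG score of at most 12.  Candidates whose combined discovery +
CFG score reaches 6 are carried forward — which deliberately retains a
maximal-discovery candidate (6 internal points) with no external evidence.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

EVIDENCE_CATEGORIES = (
    "human_genetic", "human_brain", "human_peripheral",
    "animal_genetic", "animal_brain", "animal_peripheral",
)
CATEGORY_CAP = 2
CFG_MAX = 12
CARRY_FORWARD_THRESHOLD = 6


def read_evidence_db(path: str | Path) -> pd.DataFrame:
    """Read a gene x six-category evidence table from TSV or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        db = pd.read_json(path, orient="index")
    else:
        db = pd.read_csv(path, sep="\t", index_col="gene")
    missing = set(EVIDENCE_CATEGORIES) - set(db.columns)
    if missing:
        raise ValueError(f"evidence table missing categories: {sorted(missing)}")
    return db[list(EVIDENCE_CATEGORIES)]


def cfg_score(gene: str, db: pd.DataFrame,
              category_caps: dict[str, int] | None = None) -> int:
    """CFG evidence score for one gene, 0-12.

    Each of the six streams contributes min(evidence level, cap) points with
    a default cap of 2 per stream; the sum is capped at 12.  A gene absent
    from the database scores 0.  ``category_caps`` overrides per-stream caps
    (the equal 2-point allocation is a package design choice, not a fact
    about any particular curation effort).
    """
    if gene not in db.index:
        return 0
    caps = dict.fromkeys(EVIDENCE_CATEGORIES, CATEGORY_CAP)
    if category_caps:
        caps.update(category_caps)
    row = db.loc[gene]
    total = sum(min(int(row[cat]), caps[cat]) for cat in EVIDENCE_CATEGORIES)
    return min(total, CFG_MAX)


def carry_forward(candidates: pd.DataFrame, db: pd.DataFrame,
                  threshold: int = CARRY_FORWARD_THRESHOLD) -> pd.DataFrame:
    """Score candidates with CFG and flag those carried to validation.

    ``candidates`` needs columns ``probeset_id``, ``gene`` and
    ``discovery_points``.  Returns a copy with ``cfg_points``, ``combined``
    (= discovery + CFG) and ``carried_forward`` (combined >= threshold).
    """
    required = {"probeset_id", "gene", "discovery_points"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    out = candidates.copy()
    out["cfg_points"] = [cfg_score(g, db) for g in out["gene"]]
    out["combined"] = out["discovery_points"] + out["cfg_points"]
    out["carried_forward"] = out["combined"] >= threshold
    return out
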