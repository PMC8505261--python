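"""Pharmacogenomic matching and signature-based drug repurposing.

A drug "matches" a panel marker when it modulates the gene opposite to the
gene's disease direction — i.e., toward the high-mood direction for a
depression panel.  Marker directions are stored as direction of change in
high mood (the discovery convention); a single conversion function owns the
sign flip to the depression-disease direction, to keep orientation bugs out.

The repurposing scorer ranks drugs by how opposite their induced signature
is to the panel's disease signature.  It is a simple sign-agreement score
with the same interface as rank-based connectivity scorers, so one of those
can be substituted.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .discovery import INCREASED

UP, DOWN = "up", "down"


def disease_direction(direction_in_high_mood: str) -> str:
    """Direction of change in depression: the negation of the high-mood direction."""
    return DOWN if direction_in_high_mood == INCREASED else UP


def pharmacogenomic_match(panel_directions: Mapping[str, str],
                          drug_db: Mapping[str, Mapping[str, str]],
                          ) -> dict[str, set[str]]:
    """Per drug, the panel genes it modulates opposite to their disease direction.

    ``panel_directions`` maps gene -> direction of change in high mood;
    ``drug_db`` maps drug -> {gene: "up"/"down"} modulation.  A drug matches
    a gene when its modulation equals the gene's high-mood direction, i.e.
    opposes the depression direction.
    """
    toward_high = {gene: (UP if d == INCREASED else DOWN)
                   for gene, d in panel_directions.items()}
    matches: dict[str, set[str]] = {}
    for drug, modulated in drug_db.items():
        matches[drug] = {gene for gene, mod in modulated.items()
                         if gene in toward_high and mod == toward_high[gene]}
    return matches


def signature_antimatch_score(panel_signature: Mapping[str, int],
                              drug_signature: Mapping[str, int]) -> float:
    """Opposite-match score in [-1, 1]; +1 means a perfect anti-signature.

    Over the genes shared by both signatures, sign agreement contributes -1
    and disagreement +1, averaged.  Signatures use +1 for up, -1 for down.
    """
    overlap = set(panel_signature) & set(drug_signature)
    if not overlap:
        raise ValueError("signatures share no genes")
    agreement = sum(1 if panel_signature[g] == drug_signature[g] else -1
                    for g in overlap)
    return -agreement / len(overlap)


def rank_drugs(panel_signature: Mapping[str, int],
               signature_db: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Rank every drug in a signature database by anti-match score.

    Drugs sharing no genes with the panel are omitted.  Ties break on the
    drug name for determinism.
    """
    rows = []
    for drug, sig in signature_db.items():
        overlap = set(panel_signature) & set(sig)
        if not overlap:
            continue
        rows.append({"drug": drug,
                     "score": signature_antimatch_score(panel_signature, sig),
                     "n_overlap": len(overlap)})
    out = pd.DataFrame(rows, columns=["drug", "score", "n_overlap"])
    return out.sort_values(["score", "drug"], ascending=[False, True],
                           ignore_index=True)
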