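"""Step 1 — within-subject discovery of mood-state-tracking probesets.

Each subject contributes comparisons between consecutive visits whose
self-reported mood (SMS-7, a 0-100 visual analog scale) is diametric:
low (<= 40) versus high (>= 60).  Per comparison, a probeset is scored by
fold change (DE) or by a detection-call transition (AP); per-comparison
scores are summed across all comparisons and subjects into a raw score,
expressed as a percentage of the maximum attainable, and converted to
internal points: 2 at >= 33.3%, 4 at >= 50%, 6 at >= 80%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .preprocess import SCALE_LINEAR, SCALE_LOG2, ExpressionMatrix, ScaleError

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"

LOW_MOOD_CUTOFF = 40.0
HIGH_MOOD_CUTOFF = 60.0
FOLD_CHANGE_FULL = 1.2
FOLD_CHANGE_HALF = 1.1
POINT_THRESHOLDS = ((80.0, 6), (50.0, 4), (100.0 / 3.0, 2))

INCREASED = "increased_in_high"
DECREASED = "decreased_in_high"


def label_mood_state(sms7: float, low_cutoff: float = LOW_MOOD_CUTOFF,
                     high_cutoff: float = HIGH_MOOD_CUTOFF) -> str:
    """Map an SMS-7 score to ``low`` (<=40), ``high`` (>=60) or ``intermediate``."""
    if not 0 <= sms7 <= 100:
        raise ValueError(f"SMS-7 score {sms7} outside [0, 100]")
    if sms7 <= low_cutoff:
        return LOW
    if sms7 >= high_cutoff:
        return HIGH
    return INTERMEDIATE


@dataclass(frozen=True)
class MoodComparison:
    """One within-subject low-vs-high mood visit pair.

    ``sample_low``/``sample_high`` identify the expression columns of the
    low- and high-mood visits; ``low_first`` records the temporal order.
    """

    subject_id: str
    sample_low: str
    sample_high: str
    visit_pair: tuple[int, int]
    low_first: bool


def enumerate_comparisons(visits: pd.DataFrame,
                          adjacency: Literal["strict", "any"] = "strict",
                          ) -> list[MoodComparison]:
    """List every diametric mood comparison in a visit table.

    ``strict`` (the default) pairs only adjacent visits, so an intervening
    intermediate-mood visit breaks the pair; ``any`` pairs every low-mood
    visit of a subject with every high-mood visit, for sensitivity analysis.
    """
    comparisons: list[MoodComparison] = []
    for subject, grp in visits.groupby("subject_id", sort=True):
        grp = grp.sort_values("visit_number")
        states = [label_mood_state(s) for s in grp["sms7"]]
        rows = list(grp.itertuples())
        if adjacency == "strict":
            pairs = [(rows[i], rows[i + 1]) for i in range(len(rows) - 1)
                     if {states[i], states[i + 1]} == {LOW, HIGH}]
        elif adjacency == "any":
            lows = [r for r, s in zip(rows, states) if s == LOW]
            highs = [r for r, s in zip(rows, states) if s == HIGH]
            pairs = [(lo, hi) for lo in lows for hi in highs]
        else:
            raise ValueError(f"unknown adjacency mode {adjacency!r}")
        for a, b in pairs:
            a_low = label_mood_state(a.sms7) == LOW
            lo, hi = (a, b) if a_low else (b, a)
            comparisons.append(MoodComparison(
                subject_id=str(subject),
                sample_low=lo.sample_id, sample_high=hi.sample_id,
                visit_pair=(int(a.visit_number), int(b.visit_number)),
                low_first=a_low))
    return comparisons


def score_de_comparison(fold_change: float) -> float:
    """Score a linear high/low fold change: +-1 at 1.2x, +-0.5 at 1.1x, else 0."""
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    if fold_change >= FOLD_CHANGE_FULL:
        return 1.0
    if fold_change >= FOLD_CHANGE_HALF:
        return 0.5
    if fold_change <= 1.0 / FOLD_CHANGE_FULL:
        return -1.0
    if fold_change <= 1.0 / FOLD_CHANGE_HALF:
        return -0.5
    return 0.0


def score_ap_comparison(call_low: bool, call_high: bool) -> int:
    """Score a detection-call transition low->high: turned on +1, off -1, else 0."""
    return int(call_high) - int(call_low)


def internal_points(pct_of_max: float) -> int:
    """Convert |raw score| as a percentage of maximum into 0/2/4/6 points."""
    for threshold, pts in POINT_THRESHOLDS:
        if pct_of_max >= threshold:
            return pts
    return 0


def _linear_values(matrix: ExpressionMatrix) -> pd.DataFrame:
    if matrix.scale_tag == SCALE_LINEAR:
        return matrix.values
    if matrix.scale_tag == SCALE_LOG2:
        return np.exp2(matrix.values)
    raise ScaleError("DE fold changes need log2 or linear intensities")


def discovery_scores(matrix: ExpressionMatrix,
                     comparisons: Sequence[MoodComparison],
                     method: Literal["DE", "AP"],
                     calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Raw scores, percentage of maximum, and internal points per probeset.

    For DE, per-comparison scores come from the linear high/low expression
    ratio; for AP, from detection-call transitions (``calls`` required).
    The denominator of ``pct_of_max`` is the number of comparisons — the
    maximum |raw score| attainable if every comparison scored +-1.
    """
    if not comparisons:
        raise ValueError("at least one mood comparison is required")
    n = len(comparisons)
    low_cols = [c.sample_low for c in comparisons]
    high_cols = [c.sample_high for c in comparisons]

    if method == "DE":
        lin = _linear_values(matrix)
        fc = lin[high_cols].to_numpy() / lin[low_cols].to_numpy()
        per_comp = np.select(
            [fc >= FOLD_CHANGE_FULL, fc >= FOLD_CHANGE_HALF,
             fc <= 1.0 / FOLD_CHANGE_FULL, fc <= 1.0 / FOLD_CHANGE_HALF],
            [1.0, 0.5, -1.0, -0.5], default=0.0)
    elif method == "AP":
        if calls is None:
            raise ValueError("AP scoring requires a detection-call matrix")
        per_comp = (calls[high_cols].to_numpy().astype(int)
                    - calls[low_cols].to_numpy().astype(int)).astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")

    raw = per_comp.sum(axis=1)
    pct = 100.0 * np.abs(raw) / n
    pts = np.array([internal_points(p) for p in pct], dtype=int)
    direction = np.where(raw >= 0, INCREASED, DECREASED)
    return pd.DataFrame({
        "probeset_id": matrix.probeset_ids,
        "method": method,
        "direction": direction,
        "raw_score": raw,
        "pct_of_max": pct,
        "internal_points": pts,
    }).set_index("probeset_id", drop=False)


def run_discovery(matrix: ExpressionMatrix, visits: pd.DataFrame,
                  calls: pd.DataFrame,
                  adjacency: Literal["strict", "any"] = "strict") -> pd.DataFrame:
    """Full step 1: enumerate comparisons and score both DE and AP.

    Each (probeset, method) pair is kept as a separate candidate entry;
    duplicates are not merged before prioritization.
    """
    comparisons = enumerate_comparisons(visits, adjacency=adjacency)
    de = discovery_scores(matrix, comparisons, "DE")
    ap = discovery_scores(matrix, comparisons, "AP", calls=calls)
    return pd.concat([de, ap], ignore_index=True)
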