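"""Step 3 — four-group stepwise validation with ANOVA.

Carried-forward markers are assessed for a stepwise change in expression
along clinical depression (HAMD >= 22, independent cohort) -> low-mood
discovery visits -> high-mood discovery visits -> clinical mania
(YMRS >= 20, independent cohort), on de-logged, stratum-z-scored values.
Stepwise markers get 2 points, 4 if one-way ANOVA across the four groups is
nominally significant, 6 if the Bonferroni-corrected p (over the number of
ANOVA-tested probesets) is significant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import (HIGH_MOOD_CUTOFF, INCREASED, LOW_MOOD_CUTOFF)
from .preprocess import SCALE_ZSCORED, ExpressionMatrix, ScaleError

GROUP_ORDER = ("clinical_depression", "low_mood", "high_mood", "clinical_mania")

HAMD_SEVERE = 22.0
YMRS_SEVERE = 20.0
ALPHA = 0.05


def build_validation_groups(discovery_visits: pd.DataFrame,
                            validation_visits: pd.DataFrame,
                            hamd_cutoff: float = HAMD_SEVERE,
                            ymrs_cutoff: float = YMRS_SEVERE,
                            ) -> dict[str, list[str]]:
    """Assemble the four sample groups for the stepwise assessment.

    Low/high mood groups come from the discovery cohort's SMS-7 labels;
    the clinically severe groups from the independent validation cohort.
    """
    groups = {
        "clinical_depression": list(
            validation_visits.loc[validation_visits["hamd"] >= hamd_cutoff, "sample_id"]),
        "low_mood": list(
            discovery_visits.loc[discovery_visits["sms7"] <= LOW_MOOD_CUTOFF, "sample_id"]),
        "high_mood": list(
            discovery_visits.loc[discovery_visits["sms7"] >= HIGH_MOOD_CUTOFF, "sample_id"]),
        "clinical_mania": list(
            validation_visits.loc[validation_visits["ymrs"] >= ymrs_cutoff, "sample_id"]),
    }
    return groups


def stepwise_check(group_means: Sequence[float], direction: str,
                   strict: bool = True) -> bool:
    """True iff the four group means are monotone in the marker's direction.

    Means are ordered depression -> low mood -> high mood -> mania; a marker
    increased in high mood must increase along that axis, a decreased one
    must decrease.  Ties break the chain under the default strict rule.
    """
    m = np.asarray(group_means, dtype=float)
    if m.shape != (4,):
        raise ValueError("exactly four group means are required")
    diffs = np.diff(m)
    if direction != INCREASED:
        diffs = -diffs
    return bool((diffs > 0).all()) if strict else bool((diffs >= 0).all())


def anova_validation(matrix: ExpressionMatrix,
                     groups: Mapping[str, Sequence[str]],
                     directions: Mapping[str, str] | pd.Series,
                     alpha: float = ALPHA,
                     strict: bool = True) -> pd.DataFrame:
    """Stepwise check plus one-way ANOVA and Bonferroni over tested probesets.

    ``directions`` maps probeset -> direction of change in high mood (from
    discovery).  Only probesets present in ``directions`` are assessed.
    ANOVA is the classical equal-variance one-way test, run for the
    stepwise-changed probesets; the Bonferroni factor is the number of
    probesets tested in ANOVA.
    """
    if matrix.scale_tag != SCALE_ZSCORED:
        raise ScaleError("validation expects stratum-z-scored values")
    for name in GROUP_ORDER:
        if len(groups[name]) < 2:
            raise ValueError(f"validation group {name!r} has fewer than 2 samples")

    probesets = [p for p in matrix.probeset_ids if p in directions]
    blocks = {name: matrix.values[list(groups[name])] for name in GROUP_ORDER}
    means = {name: blocks[name].mean(axis=1) for name in GROUP_ORDER}

    rows = []
    for p in probesets:
        gm = [means[name][p] for name in GROUP_ORDER]
        stepwise = stepwise_check(gm, directions[p], strict=strict)
        rows.append({"probeset_id": p, "direction": directions[p],
                     **{f"mean_{name}": m for name, m in zip(GROUP_ORDER, gm)},
                     "stepwise": stepwise})
    result = pd.DataFrame(rows).set_index("probeset_id", drop=False)

    tested = result.index[result["stepwise"]]
    n_tested = len(tested)
    anova_p = pd.Series(np.nan, index=result.index)
    for p in tested:
        samples = [blocks[name].loc[p].to_numpy() for name in GROUP_ORDER]
        anova_p[p] = stats.f_oneway(*samples).pvalue
    result["anova_p"] = anova_p
    result["bonferroni_p"] = np.minimum(1.0, result["anova_p"] * max(n_tested, 1))
    result["points"] = 0
    result.loc[result["stepwise"], "points"] = 2
    result.loc[result["stepwise"] & (result["anova_p"] < alpha), "points"] = 4
    result.loc[result["stepwise"] & (result["bonferroni_p"] < alpha), "points"] = 6
    return result
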