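"""Step 4 — testing markers for clinical utility in independent cohorts.

Eight phenotype targets are assessed per marker: four in the depression
family (state low mood, state clinical depression, first-year and all-future
hospitalizations with depression) and four mirrored in the mania family.
State targets and first-year hospitalization use ROC AUC via the
Mann-Whitney rank construction; all-future hospitalization uses a
single-covariate Cox proportional-hazards fit.  Each analysis runs both
cross-sectionally (stratum-z-scored level at one visit) and longitudinally
(level, slope, extremum level, extremum slope, each z-scored and summed),
in every stratum (all subjects, per gender, per gender x diagnosis).
Per (marker, target), points are 3 if significant in all subjects, else 2
if in a gender stratum, else 1 if in a gender x diagnosis stratum.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .discovery import HIGH_MOOD_CUTOFF, INCREASED, LOW_MOOD_CUTOFF
from .validation import HAMD_SEVERE, YMRS_SEVERE

logger = logging.getLogger(__name__)

DEPRESSION_FAMILY = ("low_mood", "depression_state",
                     "hosp_depression_year1", "hosp_depression_all")
MANIA_FAMILY = ("high_mood", "mania_state",
                "hosp_mania_year1", "hosp_mania_all")
ALL_TARGETS = DEPRESSION_FAMILY + MANIA_FAMILY
STATE_TARGETS = ("low_mood", "depression_state", "high_mood", "mania_state")
COX_TARGETS = ("hosp_depression_all", "hosp_mania_all")

YEAR1_HORIZON = 365.0
ALPHA = 0.05
LEVEL_FLOOR = 2.0 ** -10  # linear-scale floor guarding slope ratios

_STRATUM_POINTS = {"all": 3, "gender": 2, "gender_dx": 1}


class DegenerateLabels(ValueError):
    """A stratum lacked both positive and negative observations (or events)."""


def target_family(target: str) -> str:
    if target in DEPRESSION_FAMILY:
        return "depression"
    if target in MANIA_FAMILY:
        return "mania"
    raise ValueError(f"unknown phenotype target {target!r}")


def risk_sign(direction: str, family: str) -> int:
    """+1 if higher expression means higher risk for this target family.

    ``direction`` is the direction of change in high mood (discovery
    convention).  A marker increased in high mood is *decreased* in
    depression, so for depression-family targets its risk runs opposite to
    its expression; for mania-family targets it runs with it.
    """
    up_in_high = direction == INCREASED
    if family == "depression":
        return -1 if up_in_high else 1
    if family == "mania":
        return 1 if up_in_high else -1
    raise ValueError(f"unknown family {family!r}")


def cross_sectional_predictor(z_values: pd.Series, direction: str,
                              family: str) -> pd.Series:
    """Oriented per-visit risk score: z for increased-risk markers, -z otherwise."""
    return z_values * risk_sign(direction, family)


def panel_score(z_matrix: pd.DataFrame, directions: Mapping[str, str],
                family: str) -> pd.Series:
    """Panel risk score per visit: sum of increased-risk minus decreased-risk z."""
    total = pd.Series(0.0, index=z_matrix.columns)
    for probeset, direction in directions.items():
        total += z_matrix.loc[probeset] * risk_sign(direction, family)
    return total


def longitudinal_features(levels: pd.Series, visits: pd.DataFrame,
                          risk_increasing: bool,
                          floor: float = LEVEL_FLOOR) -> pd.DataFrame:
    """Per-visit longitudinal components of one marker, linear-scale levels.

    For every visit with at least one prior visit for that subject:
    the level, the slope into the visit (level ratio current/previous,
    divided by days between visits; previous level floored at ``floor``,
    zero-day gaps skipped), the extremum level over current and past visits
    (maximum for increased-risk markers, minimum for decreased-risk), and
    the extremum slope, same convention.
    """
    vis = visits.set_index("sample_id") if "sample_id" in visits.columns else visits
    rows = []
    for _, grp in vis.loc[vis.index.intersection(levels.index)].groupby("subject_id"):
        grp = grp.sort_values("visit_number")
        samples = list(grp.index)
        if len(samples) < 2:
            continue  # longitudinal sub-cohort: subjects with >= 2 visits
        lv = levels[samples].to_numpy(dtype=float)
        days = grp["days_since_first"].to_numpy(dtype=float)
        slopes: list[float] = []
        for t in range(1, len(samples)):
            dt = days[t] - days[t - 1]
            if dt <= 0:
                continue
            slopes.append((lv[t] / max(lv[t - 1], floor)) / dt)
            ext = np.max if risk_increasing else np.min
            rows.append({
                "sample_id": samples[t],
                "level": lv[t],
                "slope": slopes[-1],
                "ext_level": float(ext(lv[: t + 1])),
                "ext_slope": float(ext(slopes)),
            })
    if not rows:
        return pd.DataFrame(columns=["level", "slope", "ext_level", "ext_slope"])
    return pd.DataFrame(rows).set_index("sample_id")


def longitudinal_predictor(levels: pd.Series, visits: pd.DataFrame,
                           direction: str, family: str,
                           floor: float = LEVEL_FLOOR) -> pd.Series:
    """Combined longitudinal risk score per eligible visit.

    The four components are z-scored across the eligible test population
    (population sd) and summed; for decreased-risk markers the sum is
    negated so that a higher score always means higher risk.
    """
    sign = risk_sign(direction, family)
    feats = longitudinal_features(levels, visits, risk_increasing=sign > 0,
                                  floor=floor)
    if feats.empty:
        return pd.Series(dtype=float)
    sd = feats.std(axis=0, ddof=0).replace(0.0, np.nan)
    z = feats.sub(feats.mean(axis=0), axis=1).div(sd, axis=1).fillna(0.0)
    return sign * z.sum(axis=1)


def roc_predict(scores: pd.Series | np.ndarray,
                labels: pd.Series | np.ndarray) -> tuple[float, float]:
    """ROC AUC by the Mann-Whitney rank construction, with a one-sided p.

    AUC = U / (n_pos * n_neg), ties counting one half; the p-value is the
    one-sided normal approximation to the Mann-Whitney statistic for
    AUC > 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabels("ROC needs at least one positive and one negative")
    res = stats.mannwhitneyu(pos, neg, alternative="greater", method="asymptotic")
    auc = res.statistic / (len(pos) * len(neg))
    return float(auc), float(res.pvalue)


def followup_durations(followup: pd.DataFrame, event_type: str,
                       horizon: Literal["year1", "all_future"]) -> pd.DataFrame:
    """Durations and event flags for a Cox fit, per follow-up record.

    ``year1`` censors at 365 days (subjects without an event contribute 365
    censored days); ``all_future`` censors at the last observed day.
    """
    fu = followup[followup["event_type"] == event_type]
    had = fu["time_to_first_event"].notna()
    if horizon == "year1":
        event = had & (fu["time_to_first_event"] <= YEAR1_HORIZON)
        duration = np.where(event, fu["time_to_first_event"], YEAR1_HORIZON)
    elif horizon == "all_future":
        event = had
        duration = np.where(event, fu["time_to_first_event"], fu["followup_days"])
    else:
        raise ValueError(f"unknown horizon {horizon!r}")
    return pd.DataFrame({"subject_id": fu["subject_id"].to_numpy(),
                         "duration": duration.astype(float),
                         "event": event.to_numpy().astype(bool)})


def cox_trait(scores: pd.Series | np.ndarray, durations: pd.Series | np.ndarray,
              events: pd.Series | np.ndarray) -> tuple[float, float]:
    """Single-covariate proportional-hazards fit on an oriented risk score.

    Returns the hazard ratio per unit risk score (> 1 means increased risk
    by construction, since the score is pre-oriented) and its Wald p-value.
    """
    df = pd.DataFrame({"risk": np.asarray(scores, dtype=float),
                       "duration": np.asarray(durations, dtype=float),
                       "event": np.asarray(events).astype(bool)})
    if df["event"].sum() == 0:
        raise DegenerateLabels("Cox fit needs at least one event")
    if df.loc[df["event"], "duration"].nunique() == 1 and df["event"].sum() > 1 \
            and len(df) == df["event"].sum():
        raise DegenerateLabels("all events at identical times")
    fitter = CoxPHFitter()
    # small gender x diagnosis strata with near-perfect separation trip
    # lifelines' convergence warnings routinely in bulk scans
    import warnings
    from lifelines.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fitter.fit(df, duration_col="duration", event_col="event")
    return (float(np.exp(fitter.params_["risk"])),
            float(fitter.summary.loc["risk", "p"]))


def bonferroni_correct(p: float, n_candidates: int) -> float:
    """Multiplicity correction over a candidate panel: min(1, p x n)."""
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    return min(1.0, p * n_candidates)


def state_labels(visits: pd.DataFrame, target: str,
                 hamd_cutoff: float = HAMD_SEVERE,
                 ymrs_cutoff: float = YMRS_SEVERE) -> pd.Series:
    """Binary per-visit labels for a state target, indexed by sample id."""
    vis = visits.set_index("sample_id") if "sample_id" in visits.columns else visits
    if target == "low_mood":
        return vis["sms7"] <= LOW_MOOD_CUTOFF
    if target == "high_mood":
        return vis["sms7"] >= HIGH_MOOD_CUTOFF
    if target == "depression_state":
        return vis["hamd"] >= hamd_cutoff
    if target == "mania_state":
        return vis["ymrs"] >= ymrs_cutoff
    raise ValueError(f"{target!r} is not a state target")


def _strata(visits: pd.DataFrame) -> list[tuple[str, str, pd.Series]]:
    """(level, label, row mask) for all / per-gender / per-gender-x-diagnosis."""
    out = [("all", "all", pd.Series(True, index=visits.index))]
    for g in sorted(visits["gender"].unique()):
        out.append(("gender", str(g), visits["gender"] == g))
    for (g, d), _ in visits.groupby(["gender", "diagnosis"]):
        out.append(("gender_dx", f"{g}-{d}",
                    (visits["gender"] == g) & (visits["diagnosis"] == d)))
    return out


def stratified_testing(panel: pd.DataFrame, z_matrix: pd.DataFrame,
                       linear_matrix: pd.DataFrame, visits: pd.DataFrame,
                       followup: pd.DataFrame,
                       targets: Iterable[str] = ALL_TARGETS,
                       alpha: float = ALPHA) -> pd.DataFrame:
    """Run every (marker, target, stratum, mode) analysis of step 4.

    ``panel`` needs columns ``probeset_id`` and ``direction``; ``z_matrix``
    holds stratum-z-scored values and ``linear_matrix`` linear-scale levels
    (for slopes), both probesets x samples over the test cohort.  Follow-up
    records are anchored at each subject's final (testing) visit.  Strata
    failing preconditions (no positives, no events...) are skipped and
    logged.  Returns a long-form table of StratumPrediction rows.
    """
    vis = visits.set_index("sample_id") if "sample_id" in visits.columns else visits
    vis = vis[vis.index.isin(z_matrix.columns)].rename_axis("sample_id")
    anchors = (vis.reset_index().sort_values("visit_number")
               .groupby("subject_id").tail(1).set_index("subject_id")["sample_id"])
    rows = []
    for marker in panel.itertuples():
        probeset, direction = marker.probeset_id, marker.direction
        for target in targets:
            family = target_family(target)
            cs_scores = cross_sectional_predictor(
                z_matrix.loc[probeset], direction, family)
            lg_scores = longitudinal_predictor(
                linear_matrix.loc[probeset], vis, direction, family)
            for level, label, mask in _strata(vis):
                stratum_samples = vis.index[mask]
                for mode, scores in (("cross_sectional", cs_scores),
                                     ("longitudinal", lg_scores)):
                    row = {"probeset_id": probeset, "direction": direction,
                           "target": target, "stratum_level": level,
                           "stratum": label, "mode": mode}
                    try:
                        if target in STATE_TARGETS or target.endswith("year1"):
                            rows.append(row | _roc_cell(
                                scores, stratum_samples, vis, followup, target))
                        else:
                            rows.append(row | _cox_cell(
                                scores, stratum_samples, vis, followup,
                                anchors, target))
                    except DegenerateLabels as exc:
                        logger.debug("skipping %s/%s/%s/%s: %s",
                                     probeset, target, label, mode, exc)
    result = pd.DataFrame(rows)
    if not result.empty:
        result["significant"] = result["p"] < alpha
    return result


def _roc_cell(scores, stratum_samples, vis, followup, target):
    if target in STATE_TARGETS:
        labels = state_labels(vis, target)
        samples = scores.index.intersection(stratum_samples)
    else:  # first-year hospitalization, labelled at the anchor visit
        event_type = ("hosp_depression" if "depression" in target else "hosp_mania")
        dur = followup_durations(followup, event_type, "year1").set_index("subject_id")
        # subjects need either a first-year event or >= 1 year of follow-up
        fu = followup[followup["event_type"] == event_type].set_index("subject_id")
        eligible = dur.index[(dur["event"]) | (fu["followup_days"] >= YEAR1_HORIZON)]
        anchor_of = vis.reset_index().sort_values("visit_number") \
            .groupby("subject_id").tail(1).set_index("subject_id")["sample_id"]
        anchor_of = anchor_of.loc[anchor_of.index.intersection(eligible)]
        labels = pd.Series(dur.loc[anchor_of.index, "event"].to_numpy(),
                           index=anchor_of.to_numpy())
        samples = scores.index.intersection(stratum_samples).intersection(labels.index)
    if len(samples) == 0:
        raise DegenerateLabels("no eligible visits in stratum")
    y = labels[samples].astype(bool)
    auc, p = roc_predict(scores[samples], y)
    return {"n_pos": int(y.sum()), "n_total": int(len(y)),
            "statistic": auc, "p": p, "kind": "auc",
            "pearson_r": _pearson(scores[samples], y.astype(float))}


def _cox_cell(scores, stratum_samples, vis, followup, anchors, target):
    event_type = "hosp_depression" if "depression" in target else "hosp_mania"
    dur = followup_durations(followup, event_type, "all_future")
    dur = dur.set_index("subject_id")
    subjects = anchors.index[anchors.isin(stratum_samples)
                             & anchors.isin(scores.index)]
    subjects = subjects.intersection(dur.index)
    if len(subjects) < 3:
        raise DegenerateLabels("too few subjects with follow-up in stratum")
    s = scores[anchors[subjects]].to_numpy()
    hr, p = cox_trait(s, dur.loc[subjects, "duration"], dur.loc[subjects, "event"])
    return {"n_pos": int(dur.loc[subjects, "event"].sum()),
            "n_total": int(len(subjects)), "statistic": hr, "p": p,
            "kind": "cox_or",
            "pearson_r": _pearson(pd.Series(s),
                                  dur.loc[subjects, "event"].astype(float))}


def _pearson(x: pd.Series, y: pd.Series) -> float:
    """Auxiliary Pearson correlation; NaN on degenerate inputs.

    Reported alongside AUC/Cox results for completeness but never used for
    the point assignment."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def assign_testing_points(predictions: pd.DataFrame,
                          alpha: float = ALPHA) -> pd.DataFrame:
    """Per (marker, target) points from the 3/2/1 best-stratum rule.

    3 points if any mode is significant in the all-subjects stratum, else 2
    if in any gender stratum, else 1 if in any gender x diagnosis stratum,
    else 0.  Either mode (cross-sectional or longitudinal) may earn the
    category; the best stratum level counts, not a sum across strata.
    """
    required = {"probeset_id", "target", "stratum_level", "p"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    sig = predictions[predictions["p"] < alpha]
    best = (sig.assign(points=sig["stratum_level"].map(_STRATUM_POINTS))
            .groupby(["probeset_id", "target"])["points"].max())
    idx = pd.MultiIndex.from_product(
        [predictions["probeset_id"].unique(), list(ALL_TARGETS)],
        names=["probeset_id", "target"])
    return (best.reindex(idx, fill_value=0).astype(int)
            .rename("points").reset_index())
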