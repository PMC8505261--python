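"""Expression-matrix containers and stratified normalization.

The pipeline's order of operations is: RMA-like log2 intensities come in,
are de-logged where a stage needs linear-scale ratios, and are z-scored by
(gender, diagnosis) stratum before validation and testing so that different
demographic groups can be pooled.  Every matrix carries a ``scale_tag`` so
that stage preconditions can be checked rather than assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCALE_LOG2 = "log2"
SCALE_LINEAR = "linear"
SCALE_ZSCORED = "zscored"

#: column names expected in a visit table
VISIT_COLUMNS = ("subject_id", "visit_number", "days_since_first", "gender",
                 "diagnosis", "sms7", "hamd", "ymrs")


class ScaleError(ValueError):
    """A matrix arrived on the wrong scale for the requested transform."""


@dataclass
class ExpressionMatrix:
    """Probeset x visit-sample intensity matrix with an explicit scale.

    Parameters
    ----------
    values
        DataFrame with probeset ids as the index and visit-sample ids as
        columns.  No missing values are permitted.
    scale_tag
        One of ``log2``, ``linear`` or ``zscored``.
    """

    values: pd.DataFrame
    scale_tag: str

    def __post_init__(self) -> None:
        if self.scale_tag not in (SCALE_LOG2, SCALE_LINEAR, SCALE_ZSCORED):
            raise ScaleError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def probeset_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV with a sidecar ``<path>.meta.json``."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="probeset_id")
        meta = {"scale_tag": self.scale_tag,
                "n_probesets": int(self.values.shape[0]),
                "n_samples": int(self.values.shape[1])}
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path, scale_tag: str | None = None) -> "ExpressionMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="probeset_id")
        if scale_tag is None:
            meta_path = Path(str(path) + ".meta.json")
            if meta_path.exists():
                scale_tag = json.loads(meta_path.read_text())["scale_tag"]
            else:
                raise ScaleError("scale_tag not given and no sidecar metadata found")
        return cls(values, scale_tag)


def delog(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Take 2 to the power of every log2 value, yielding the linear scale."""
    if matrix.scale_tag != SCALE_LOG2:
        raise ScaleError(f"delog expects a log2 matrix, got {matrix.scale_tag!r}")
    return ExpressionMatrix(np.exp2(matrix.values), SCALE_LINEAR)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`delog`; requires strictly positive linear values."""
    if matrix.scale_tag != SCALE_LINEAR:
        raise ScaleError(f"log2_transform expects a linear matrix, got {matrix.scale_tag!r}")
    if (matrix.values <= 0).any().any():
        raise ValueError("non-positive values cannot be log2-transformed")
    return ExpressionMatrix(np.log2(matrix.values), SCALE_LOG2)


def _stratum_key(visits: pd.DataFrame) -> pd.Series:
    return visits["gender"].astype(str) + "|" + visits["diagnosis"].astype(str)


def zscore_by_stratum(matrix: ExpressionMatrix, visits: pd.DataFrame,
                      ddof: int = 0) -> ExpressionMatrix:
    """Z-score each probeset within each (gender, diagnosis) stratum.

    Strata of size one, and probesets with zero variance within a stratum,
    fall back to pooled-cohort statistics; a probeset constant across the
    whole cohort z-scores to 0.  ``ddof=0`` (population standard deviation)
    is the default; pass ``ddof=1`` for the sample convention.
    """
    vis = visits.set_index("sample_id") if "sample_id" in visits.columns else visits
    missing = matrix.sample_ids.difference(vis.index)
    if len(missing):
        raise ValueError(f"samples missing from visit table: {list(missing)[:5]}")
    strata = _stratum_key(vis.loc[matrix.sample_ids])

    vals = matrix.values
    pooled_mu = vals.mean(axis=1)
    pooled_sd = vals.std(axis=1, ddof=ddof)

    out = pd.DataFrame(index=vals.index, columns=vals.columns, dtype=float)
    for _, cols in matrix.sample_ids.groupby(strata).items():
        block = vals[cols]
        if len(cols) < 2:
            mu, sd = pooled_mu, pooled_sd
        else:
            mu = block.mean(axis=1)
            sd = block.std(axis=1, ddof=ddof)
            degenerate = sd == 0
            if degenerate.any():
                mu = mu.where(~degenerate, pooled_mu)
                sd = sd.where(~degenerate, pooled_sd)
        z = block.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
        out[cols] = z
    return ExpressionMatrix(out, SCALE_ZSCORED)


def ap_call(matrix: ExpressionMatrix, threshold: float | pd.Series | None = None
            ) -> pd.DataFrame:
    """Absent/present detection calls: present iff intensity above threshold.

    Vendor detection calls are not reproducible offline, so a transparent
    stand-in rule is used: by default each probeset's threshold is its own
    cohort-wide 25th percentile, so the bottom quartile of a probeset's
    intensities are "absent".  A scalar or per-probeset Series may be passed
    instead.  Returns a boolean DataFrame of the same shape.
    """
    if matrix.scale_tag == SCALE_ZSCORED:
        raise ScaleError("AP calls are made on log2 or linear intensities")
    vals = matrix.values
    if threshold is None:
        threshold = vals.quantile(0.25, axis=1)
    if np.isscalar(threshold):
        return vals.gt(float(threshold))
    return vals.gt(threshold, axis=0)
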