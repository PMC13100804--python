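"""Log2 transformation, outlier-sample QC and metabolite-class summaries.

QC follows the mean-z rule: per-feature z-scores across samples (computed on
the log2 scale), averaged within each sample; samples whose |mean z| exceeds
±3 are flagged as outliers and excluded from downstream model fits.  Class
values are sums of member-feature concentrations on the natural scale —
summing log-values would be dimensionally meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, LOG2, NATURAL

logger = logging.getLogger("rejumet")


def log2_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Elementwise log2; missing preserved; rejects non-positive values."""
    if matrix.scale != NATURAL:
        raise ValueError("matrix is already log2-scaled")
    values = matrix.data.to_numpy(dtype=float)
    bad = np.nonzero(values <= 0)
    if bad[0].size:
        cells = [(matrix.sample_ids[r], matrix.feature_ids[c])
                 for r, c in zip(bad[0][:10], bad[1][:10])]
        raise ValueError(f"non-positive values cannot be log2 transformed: {cells}")
    return FeatureMatrix(pd.DataFrame(np.log2(values), index=matrix.data.index,
                                      columns=matrix.data.columns), scale=LOG2)


@dataclass
class QCReport:
    """Per-sample QC verdicts; ``flagged`` ⇔ |mean_z| > threshold."""

    table: pd.DataFrame  # sample_id, mean_z, flagged
    threshold: float

    @property
    def flagged_samples(self) -> list:
        return list(self.table.loc[self.table["flagged"], "sample_id"])


def flag_outlier_samples(matrix: FeatureMatrix, threshold: float = 3.0) -> QCReport:
    """Flag samples whose mean feature z-score exceeds ±threshold.

    z-scores are computed per feature across samples (sample SD, n−1
    denominator), skipping missing cells; a zero-variance feature contributes
    z = 0 for every sample (logged, not an error).  Each sample's mean_z is
    the mean of its z-scores over non-missing features.
    """
    if matrix.scale != LOG2:
        raise ValueError("outlier QC expects a log2-scaled matrix")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier QC")
    values = matrix.data.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance feature(s) contribute z = 0 to QC",
                       int(zero_var.sum()))
    sd_safe = np.where(zero_var, 1.0, sd)
    z = (values - mean) / sd_safe
    z[:, zero_var] = 0.0
    mean_z = np.nanmean(z, axis=1)
    table = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "mean_z": mean_z,
        "flagged": np.abs(mean_z) > threshold,
    })
    return QCReport(table, threshold)


def drop_flagged_samples(matrix: FeatureMatrix, report: QCReport) -> FeatureMatrix:
    keep = [s for s in matrix.sample_ids if s not in set(report.flagged_samples)]
    return matrix.subset_samples(keep)


def class_sums(matrix: FeatureMatrix, annotation: pd.Series) -> pd.DataFrame:
    """Sum member-feature concentrations per class (natural scale).

    Missing member values are simply absent from the sum; a cell where every
    member is missing is itself missing.  Classes with zero members do not
    appear.  Returns a samples x classes DataFrame.
    """
    if matrix.scale != NATURAL:
        raise ValueError("class sums are defined on the natural concentration scale")
    ann = annotation.reindex(matrix.feature_ids)
    if ann.isna().any():
        missing = list(ann.index[ann.isna()])[:10]
        raise ValueError(f"features without class annotation: {missing}")
    out = {}
    for cls in dict.fromkeys(ann):
        members = ann.index[ann == cls]
        sub = matrix.data[members]
        summed = sub.sum(axis=1, min_count=1)  # all-missing -> NaN, not 0
        out[cls] = summed
    return pd.DataFrame(out, index=matrix.data.index)
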