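"""Shared data containers for the rejuvenation-analysis pipeline.

The common currency is the :class:`FeatureMatrix` (samples x metabolites or
proteins, concentrations in µM or relative abundance) together with a
feature-class annotation and per-sample metadata.  Effects of age or treatment
on every feature are carried as an :class:`EffectVector`; the headline
statistic of the analysis, a Spearman correlation between two such vectors, is
a :class:`SignatureScore`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Metabolite classes of the targeted panel: amino acids, acylcarnitines,
#: biogenic amines, lysophosphatidylcholines, phosphatidylcholines,
#: sphingomyelins and hexoses.  Features outside these map to "other".
METABOLITE_CLASSES = ("AA", "AC", "BA", "LysoPC", "PC", "SM", "H")

NATURAL = "natural"
LOG2 = "log2"


@dataclass
class FeatureMatrix:
    """Samples x features concentration/abundance table.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples (index = sample ids), columns are features.  Missing
        values (e.g. below the limit of detection) are ``NaN``.
    scale : str
        Either ``"natural"`` (concentrations, strictly positive where present)
        or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = NATURAL

    def __post_init__(self) -> None:
        if self.scale not in (NATURAL, LOG2):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate feature ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if self.scale == NATURAL and np.any(values <= 0):
            rows, colpos = np.nonzero(values <= 0)
            cells = [(idx[r], cols[c]) for r, c in zip(rows[:5], colpos[:5])]
            raise ValueError(
                f"natural-scale values must be positive; offending cells {cells}"
            )
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[list(sample_ids)], scale=self.scale)

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[:, list(feature_ids)], scale=self.scale)


def validate_annotation(annotation: pd.Series, matrix: Optional[FeatureMatrix] = None) -> pd.Series:
    """Validate a feature -> class-label annotation.

    Unknown class labels are mapped to ``"other"``.  When a matrix is given,
    every matrix feature must be annotated exactly once.
    """
    if annotation.index.duplicated().any():
        dupes = sorted(annotation.index[annotation.index.duplicated()].unique())
        raise ValueError(f"duplicate feature annotations: {dupes}")
    allowed = set(METABOLITE_CLASSES) | {"other"}
    cleaned = annotation.astype(str).where(annotation.astype(str).isin(allowed), "other")
    if matrix is not None:
        missing = set(matrix.feature_ids) - set(cleaned.index)
        if missing:
            raise ValueError(f"features without class annotation: {sorted(missing)[:10]}")
        cleaned = cleaned.loc[matrix.feature_ids]
    return cleaned


REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "species")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the per-sample metadata table.

    Requires ``sample_id``/``subject_id``/``species`` columns and unique
    sample ids; study-specific columns (age_group, genotype, treatment,
    dose_mg, visit_index, body_weight_g, bmi) are optional and validated by
    the stages that use them.
    """
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique())
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    bad_species = set(meta["species"].unique()) - {"mouse", "human"}
    if bad_species:
        raise ValueError(f"unknown species labels: {sorted(bad_species)}")
    return meta.reset_index(drop=True)


@dataclass
class EffectVector:
    """Per-feature effect estimates (log2 fold change or β-age per year).

    ``table`` is indexed by feature id with columns ``estimate``, ``se``,
    ``t``, ``p`` and ``q`` (BH-adjusted); ``label`` names the condition the
    effects describe (e.g. ``"mouse aging"`` or ``"Los WT"``).
    """

    table: pd.DataFrame
    label: str = ""
    n_used: int = 0

    COLUMNS = ("estimate", "se", "t", "p", "q")

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate feature ids in effect table")
        for col in ("estimate",):
            if col not in self.table.columns:
                raise ValueError(f"effect table missing column {col!r}")
        for col in self.COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        q = self.table["q"].to_numpy(dtype=float)
        finite_q = q[np.isfinite(q)]
        if finite_q.size and (np.any(finite_q <= 0) or np.any(finite_q > 1)):
            raise ValueError("q values must lie in (0, 1]")

    @property
    def feature_ids(self) -> list:
        return list(self.table.index)

    @property
    def estimate(self) -> pd.Series:
        return self.table["estimate"]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "feature", out.index)
        out["label"] = self.label
        return out.reset_index(drop=True)


@dataclass
class SignatureScore:
    """Spearman correlation between a signature and an effect vector."""

    rho: float
    p: float
    n_features: int
    label_x: str = ""
    label_y: str = ""
    q: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")


@dataclass
class ModerationParams:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0² prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior df must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")


@dataclass
class MixedModelFit:
    """Random-intercept linear mixed model fit (ML).

    ``fixed_effects`` is a table indexed by term with columns ``estimate``,
    ``se`` and ``p`` (Wald).  ``deviance`` is −2·log-likelihood.
    """

    fixed_effects: pd.DataFrame
    random_intercept_variance: float
    residual_variance: float
    log_likelihood: float
    n_obs: int
    n_subjects: int
    converged: bool = True
    outcome: str = ""

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    @property
    def n_params(self) -> int:
        # fixed effects + random-intercept variance + residual variance
        return len(self.fixed_effects) + 2

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.n_params

    @property
    def bic(self) -> float:
        return self.deviance + np.log(self.n_obs) * self.n_params


def validate_survival_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate (subject_id, group, time_days, event) survival records."""
    required = ("subject_id", "group", "time_days", "event")
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"survival cohort missing columns: {missing}")
    times = cohort["time_days"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)) or np.any(times < 0):
        raise ValueError("survival times must be finite and non-negative")
    events = set(np.unique(cohort["event"].to_numpy(dtype=int)))
    if not events <= {0, 1}:
        raise ValueError("event flags must be 0 or 1")
    return cohort.reset_index(drop=True)
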