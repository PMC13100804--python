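"""Per-feature linear models with empirical-Bayes variance moderation.

Each feature (metabolite or protein, log2 scale) is fitted by ordinary least
squares against a shared design matrix (group indicators + numeric covariates
+ optional subject-block indicators for longitudinal designs).  Residual
variances are then shrunk toward a prior estimated from the whole ensemble:
the log residual variances are matched in moments to a scaled-F distribution,
giving prior degrees of freedom d0 (possibly infinite) and prior variance
s0².  The moderated variance

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)

yields a moderated t-statistic on d0 + d_g degrees of freedom for any
contrast of the coefficients — the classic moderated-t framework for small-n
omics designs.  Multiplicity is controlled by Benjamini–Hochberg FDR, and
evidence across paired comparisons is pooled with Fisher's combined
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import EffectVector, FeatureMatrix, LOG2, ModerationParams

logger = logging.getLogger("rejumet")


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    """Model matrix with named columns and named contrast vectors."""

    frame: pd.DataFrame  # samples x columns
    group_column: Optional[str] = None
    group_levels: Sequence[str] = ()
    reference_level: Optional[str] = None
    contrasts: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def column_names(self) -> List[str]:
        return list(self.frame.columns)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.frame.index)

    def contrast(self, level_a: str, level_b: Optional[str] = None) -> np.ndarray:
        """Contrast estimating mean(level_a) − mean(level_b or reference)."""
        vec = np.zeros(len(self.frame.columns))

        def add(level, sign):
            if level == self.reference_level:
                return
            col = f"{self.group_column}[{level}]"
            if col not in self.frame.columns:
                raise KeyError(f"unknown group level {level!r}")
            vec[self.frame.columns.get_loc(col)] = sign

        add(level_a, 1.0)
        if level_b is not None:
            add(level_b, -1.0)
        return vec


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> List[str]:
    """Columns lying in the span of the columns before them."""
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        coef, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
        resid = X[:, j] - prev @ coef
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            bad.append(names[j])
    return bad


def build_design(meta: pd.DataFrame, group: Optional[str] = None,
                 covariates: Sequence[str] = (), block: Optional[str] = None,
                 reference: Optional[str] = None,
                 sample_id: str = "sample_id") -> DesignMatrix:
    """Build an intercept + treatment-coded design from sample metadata.

    ``group`` is coded with indicator columns for every non-reference level;
    ``covariates`` enter as numeric columns; ``block`` (e.g. subject id in a
    longitudinal design) adds fixed indicator columns implementing the
    blocking.  Raises on rank deficiency, naming the collinear columns.
    """
    for col in [c for c in [group, block, *covariates] if c is not None]:
        if col not in meta.columns:
            raise KeyError(f"metadata column {col!r} not found")
        if meta[col].isna().any():
            raise ValueError(f"metadata column {col!r} has missing values")

    index = meta[sample_id] if sample_id in meta.columns else meta.index
    cols = {"Intercept": np.ones(len(meta))}
    levels: List[str] = []
    if group is not None:
        levels = list(dict.fromkeys(meta[group]))
        if reference is None:
            reference = levels[0]
        elif reference not in levels:
            raise ValueError(f"reference level {reference!r} not present")
        for lev in levels:
            if lev != reference:
                cols[f"{group}[{lev}]"] = (meta[group] == lev).astype(float).to_numpy()
    for cov in covariates:
        cols[cov] = meta[cov].astype(float).to_numpy()
    if block is not None:
        block_levels = list(dict.fromkeys(meta[block]))
        for lev in block_levels[1:]:
            cols[f"{block}[{lev}]"] = (meta[block] == lev).astype(float).to_numpy()

    frame = pd.DataFrame(cols, index=index)
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, frame.columns)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame, group_column=group, group_levels=levels,
                        reference_level=reference)


# ---------------------------------------------------------------------------
# per-feature OLS + empirical Bayes


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-12:
            break
    return float(x)


def estimate_variance_prior(sigma2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Moment-match log residual variances to a scaled-F prior.

    Returns (d0, s0²).  With no excess spread in the variances beyond what
    their chi-square sampling noise explains, d0 = ∞ and s̃² collapses to s0²
    for every feature (logged, not an error).
    """
    ok = np.isfinite(sigma2) & (sigma2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 features with positive residual df")
    s2, d = sigma2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        logger.info("no excess variance spread: prior df is infinite")
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


class ModeratedLinearModel(BaseEstimator):
    """Feature-wise OLS with empirical-Bayes moderated contrasts.

    scikit-learn-style estimator: ``fit(X, Y)`` takes the design matrix
    (samples x p, :class:`DesignMatrix` or DataFrame) and the log2 response
    matrix (samples x features); missing responses are handled by per-feature
    row deletion.  Fitted attributes:

    - ``coef_`` : (n_features, p) OLS coefficients
    - ``sigma2_``, ``df_residual_`` : per-feature residual variance and df
    - ``cov_unscaled_`` : per-feature (X'X)⁻¹ on that feature's rows
    - ``prior_df_``, ``prior_var_`` : empirical-Bayes prior (d0, s0²)
    - ``skipped_`` : features with too few observations to fit

    ``contrast_effects`` then returns moderated (or ordinary) t-tests for any
    contrast vector as an :class:`EffectVector`.

    Parameters
    ----------
    moderated : bool
        Use the empirical-Bayes moderated t (default).  ``False`` gives the
        ordinary per-feature t-test on d_g df.
    """

    def __init__(self, moderated: bool = True):
        self.moderated = moderated

    def fit(self, X, Y):
        if isinstance(X, DesignMatrix):
            self.design_ = X
            Xmat = X.frame.to_numpy(dtype=float)
        else:
            self.design_ = None
            Xmat = np.asarray(pd.DataFrame(X), dtype=float)
        if isinstance(Y, FeatureMatrix):
            if Y.scale != LOG2:
                raise ValueError("responses must be log2 scaled")
            Ydf = Y.data
        else:
            Ydf = pd.DataFrame(Y)
        if Xmat.shape[0] != Ydf.shape[0]:
            raise ValueError("design and response row counts differ")

        n, p = Xmat.shape
        n_feat = Ydf.shape[1]
        yvals = Ydf.to_numpy(dtype=float)
        coef = np.full((n_feat, p), np.nan)
        sigma2 = np.full(n_feat, np.nan)
        dfres = np.zeros(n_feat)
        cov = np.full((n_feat, p, p), np.nan)
        skipped = []

        finite = np.isfinite(yvals)
        complete = finite.all(axis=0)
        if complete.any():
            # shared fast path for features with no missing values
            xtx_inv = np.linalg.inv(Xmat.T @ Xmat)
            beta = (xtx_inv @ Xmat.T @ yvals[:, complete]).T
            resid = yvals[:, complete] - Xmat @ beta.T
            d = n - p
            coef[complete] = beta
            dfres[complete] = d
            if d > 0:
                sigma2[complete] = (resid ** 2).sum(axis=0) / d
            cov[complete] = xtx_inv
        for j in np.nonzero(~complete)[0]:
            mask = finite[:, j]
            n_ok = int(mask.sum())
            if n_ok <= p:
                skipped.append(Ydf.columns[j])
                continue
            Xj = Xmat[mask]
            if np.linalg.matrix_rank(Xj) < p:
                skipped.append(Ydf.columns[j])
                continue
            xtx_inv = np.linalg.inv(Xj.T @ Xj)
            beta = xtx_inv @ Xj.T @ yvals[mask, j]
            resid = yvals[mask, j] - Xj @ beta
            coef[j] = beta
            dfres[j] = n_ok - p
            sigma2[j] = (resid ** 2).sum() / (n_ok - p)
            cov[j] = xtx_inv

        fitted = np.isfinite(coef).all(axis=1)
        if not fitted.any():
            raise ValueError("no feature could be fitted (all skipped)")
        if skipped:
            logger.warning("skipped %d feature(s) with insufficient observations",
                           len(skipped))

        self.feature_ids_ = list(Ydf.columns)
        self.coef_ = coef
        self.sigma2_ = sigma2
        self.df_residual_ = dfres
        self.cov_unscaled_ = cov
        self.skipped_ = skipped
        self.n_obs_ = finite.sum(axis=0)
        if self.moderated:
            prior = estimate_variance_prior(sigma2, dfres)
            self.prior_df_, self.prior_var_ = prior.d0, prior.s0_sq
        else:
            self.prior_df_, self.prior_var_ = 0.0, np.nan
        return self

    def _moderated_variance(self) -> np.ndarray:
        d0, s0 = self.prior_df_, self.prior_var_
        s2 = np.where(np.isfinite(self.sigma2_), self.sigma2_, 0.0)
        if not self.moderated or d0 == 0:
            return self.sigma2_
        if np.isinf(d0):
            return np.full_like(self.sigma2_, s0)
        return (d0 * s0 + self.df_residual_ * s2) / (d0 + self.df_residual_)

    def contrast_effects(self, contrast, label: str = "") -> EffectVector:
        """Moderated t-test of a contrast; returns estimate/SE/t/p/q per feature."""
        if isinstance(contrast, str):
            if self.design_ is None:
                raise ValueError("named contrasts require a DesignMatrix")
            contrast = self.design_.contrast(contrast)
        c = np.asarray(contrast, dtype=float)
        if c.shape != (self.coef_.shape[1],):
            raise ValueError("contrast length does not match design columns")

        estimate = self.coef_ @ c
        su = np.sqrt(np.einsum("i,nij,j->n", c, self.cov_unscaled_, c))
        s2_post = self._moderated_variance()
        se = np.sqrt(s2_post) * su
        with np.errstate(divide="ignore", invalid="ignore"):
            t = estimate / se
        df_total = self.df_residual_ + (self.prior_df_ if self.moderated else 0.0)
        p = np.full_like(estimate, np.nan)
        ok = np.isfinite(t) & (self.df_residual_ > 0)
        if np.isinf(df_total).any():
            p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
        else:
            p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total[ok])
        p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
        q = np.full_like(p, np.nan)
        q[ok] = bh_adjust(p[ok])
        table = pd.DataFrame(
            {"estimate": estimate, "se": se, "t": t, "p": p, "q": q},
            index=self.feature_ids_)
        return EffectVector(table, label=label, n_used=int(ok.sum()))


def fit_feature_models(matrix, design: DesignMatrix,
                       moderated: bool = True) -> ModeratedLinearModel:
    """Fit per-feature OLS models (thin wrapper over ModeratedLinearModel)."""
    return ModeratedLinearModel(moderated=moderated).fit(design, matrix)


def ebayes_moderate(model: ModeratedLinearModel, contrast, label: str = ""):
    """Moderated contrast test; returns (EffectVector, ModerationParams)."""
    effects = model.contrast_effects(contrast, label=label)
    params = ModerationParams(
        d0=model.prior_df_ if model.prior_df_ > 0 else np.inf,
        s0_sq=model.prior_var_ if np.isfinite(model.prior_var_) else 1.0,
    ) if model.moderated else None
    return effects, params


# ---------------------------------------------------------------------------
# multiplicity and evidence pooling


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (order preserving)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def fisher_combine(p1, p2) -> np.ndarray:
    """Fisher's combined probability across two comparisons per feature.

    X² = −2(ln p1 + ln p2) referred to a chi-square with 4 df.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("p-value vectors must have equal length")
    for arr in (a, b):
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
            raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * (np.log(a) + np.log(b))
    return stats.chi2.sf(x2, df=4)
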