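"""Random-intercept linear mixed models with polynomial dose terms.

The per-subject signature score, summed metabolite classes and clinical
outcomes (blood pressure, osmolality) are modelled as

    outcome ~ 1 + Dose + Dose² [+ BMI] + (1 | subject)

with maximum likelihood (not REML — polynomial orders are compared across
fixed-effect structures).  The model is fitted by profiling the likelihood
over the variance ratio λ = σ²_subject / σ²_residual: for fixed λ the GLS
fixed effects and the residual variance have closed forms, so a bounded
one-dimensional search over λ suffices.  λ = 0 (no between-subject variance)
is an allowed boundary at which the fit reduces exactly to OLS.

The mouse class-level model (class ~ Age + BW + Genotype*Treatment + (1|ID))
is fitted with the same machinery; each mouse contributes a single serum
sample there, so the random intercept is degenerate and the boundary
handling applies.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datatypes import MixedModelFit
from .differential import bh_adjust

logger = logging.getLogger("rejumet")

_LOG_LAMBDA_BOUNDS = (-15.0, 15.0)


class RandomInterceptLMM(BaseEstimator):
    """ML linear mixed model with a single random intercept per group.

    ``fit(X, y, groups)`` expects a full-rank fixed-effects design
    (DataFrame with named columns, or array), the outcome vector and a group
    label per observation.  Fitted attributes: ``coef_``, ``se_``,
    ``pvalues_`` (Wald, normal reference), ``sigma2_subject_``,
    ``sigma2_resid_``, ``loglik_``, ``deviance_``, ``aic_``, ``bic_``,
    ``converged_``.
    """

    def __init__(self, max_iter: int = 200):
        self.max_iter = max_iter

    # -- profiled likelihood machinery ------------------------------------

    @staticmethod
    def _group_sums(X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
        p = X.shape[1]
        sx = np.zeros((n_groups, p))
        sy = np.zeros(n_groups)
        np.add.at(sx, codes, X)
        np.add.at(sy, codes, y)
        return sx, sy

    def _profile(self, lam: float):
        """GLS fit at fixed λ; returns (−2 log L, β, XtWX, sigma2_resid)."""
        X, y = self._X, self._y
        n = len(y)
        shrink = lam / (1.0 + lam * self._group_n)  # per group
        xtwx = X.T @ X - (self._sx * shrink[:, None]).T @ self._sx
        xtwy = X.T @ y - self._sx.T @ (shrink * self._sy)
        ytwy = float(y @ y - shrink @ (self._sy ** 2))
        beta = np.linalg.solve(xtwx, xtwy)
        rss = ytwy - float(beta @ xtwy)
        rss = max(rss, np.finfo(float).tiny)
        sigma2 = rss / n
        logdet = float(np.sum(np.log1p(lam * self._group_n)))
        dev = n * np.log(2.0 * np.pi * sigma2) + logdet + n
        return dev, beta, xtwx, sigma2

    def fit(self, X, y, groups):
        if isinstance(X, pd.DataFrame):
            self.column_names_ = list(X.columns)
            Xmat = X.to_numpy(dtype=float)
        else:
            Xmat = np.asarray(X, dtype=float)
            self.column_names_ = [f"x{j}" for j in range(Xmat.shape[1])]
        yvec = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        ok = np.isfinite(yvec) & np.isfinite(Xmat).all(axis=1)
        Xmat, yvec, groups = Xmat[ok], yvec[ok], groups[ok]
        n, p = Xmat.shape
        if n <= p:
            raise ValueError("not enough observations for the fixed effects")
        if np.linalg.matrix_rank(Xmat) < p:
            raise ValueError("fixed-effects design is rank deficient")
        uniq, codes = np.unique(groups, return_inverse=True)
        if len(uniq) < 2:
            raise ValueError("need at least 2 subjects")

        self._X, self._y = Xmat, yvec
        self._group_n = np.bincount(codes).astype(float)
        self._sx, self._sy = self._group_sums(Xmat, yvec, codes, len(uniq))

        if np.max(self._group_n) == 1:
            # one observation per subject: the random intercept is
            # unidentifiable and the profile is flat, so take the boundary
            lam_hat = 0.0
            converged = True
        else:
            res = optimize.minimize_scalar(
                lambda s: self._profile(np.exp(s))[0],
                bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
                options={"xatol": 1e-12, "maxiter": self.max_iter})
            lam_hat = float(np.exp(res.x))
            dev0 = self._profile(0.0)[0]
            if dev0 <= float(res.fun) + 1e-10:  # boundary: no subject variance
                lam_hat = 0.0
            converged = bool(res.success or lam_hat == 0.0)
        dev, beta, xtwx, sigma2 = self._profile(lam_hat)

        cov_beta = sigma2 * np.linalg.inv(xtwx)
        se = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))

        self.coef_ = beta
        self.se_ = se
        self.pvalues_ = pvals
        self.lambda_ = lam_hat
        self.sigma2_resid_ = sigma2
        self.sigma2_subject_ = lam_hat * sigma2
        self.deviance_ = dev
        self.loglik_ = -0.5 * dev
        self.n_obs_ = n
        self.n_groups_ = len(uniq)
        self.converged_ = converged
        k = p + 2
        self.aic_ = dev + 2 * k
        self.bic_ = dev + np.log(n) * k
        del self._X, self._y, self._sx, self._sy, self._group_n
        return self

    def predict(self, X):
        Xmat = (X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame)
                else np.asarray(X, dtype=float))
        return Xmat @ self.coef_

    def to_fit(self, outcome: str = "") -> MixedModelFit:
        fixed = pd.DataFrame(
            {"estimate": self.coef_, "se": self.se_, "p": self.pvalues_},
            index=self.column_names_)
        return MixedModelFit(
            fixed_effects=fixed,
            random_intercept_variance=self.sigma2_subject_,
            residual_variance=self.sigma2_resid_,
            log_likelihood=self.loglik_,
            n_obs=self.n_obs_, n_subjects=self.n_groups_,
            converged=self.converged_, outcome=outcome)


# ---------------------------------------------------------------------------
# dose designs


def polynomial_dose_design(dose: Sequence[float], order: int,
                           covariates: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Intercept + raw dose powers (mg) + optional numeric covariates."""
    d = np.asarray(dose, dtype=float)
    if order < 1:
        raise ValueError("polynomial order must be >= 1")
    cols = {"Intercept": np.ones_like(d)}
    for k in range(1, order + 1):
        cols["dose" if k == 1 else f"dose^{k}"] = d ** k
    frame = pd.DataFrame(cols)
    if covariates is not None:
        for c in covariates.columns:
            frame[c] = covariates[c].to_numpy(dtype=float)
    return frame


def fit_random_intercept_lmm(outcome, dose, subject, order: int = 2,
                             covariates: Optional[pd.DataFrame] = None,
                             outcome_name: str = "") -> MixedModelFit:
    """Fit outcome ~ poly(dose, order) [+ covariates] + (1|subject) by ML."""
    distinct = len(np.unique(np.asarray(dose, dtype=float)))
    if order > distinct - 1:
        raise ValueError(
            f"order {order} exceeds distinct doses - 1 ({distinct - 1})")
    X = polynomial_dose_design(dose, order, covariates)
    model = RandomInterceptLMM().fit(X, outcome, subject)
    return model.to_fit(outcome=outcome_name)


def select_polynomial_order(outcome, dose, subject,
                            covariates: Optional[pd.DataFrame] = None,
                            orders: Iterable[int] = (1, 2, 3),
                            criterion: str = "bic",
                            ) -> Tuple[int, Dict[int, MixedModelFit]]:
    """Fit candidate polynomial orders by ML and select one.

    All candidates use the identical observation set; orders exceeding
    (distinct doses − 1) are excluded with a warning, as is any candidate
    that fails to fit.  Because ML deviance is non-increasing in nested
    order, selection uses an information criterion (``"bic"`` default,
    ``"aic"`` or raw ``"deviance"`` available); deviance/AIC/BIC are all
    reported on every fit.
    """
    if criterion not in ("bic", "aic", "deviance"):
        raise ValueError("criterion must be 'bic', 'aic' or 'deviance'")
    outcome = np.asarray(outcome, dtype=float)
    dose = np.asarray(dose, dtype=float)
    subject = np.asarray(subject)
    ok = np.isfinite(outcome)
    outcome, dose, subject = outcome[ok], dose[ok], subject[ok]
    cov = covariates.loc[ok].reset_index(drop=True) if covariates is not None else None
    distinct = len(np.unique(dose))

    fits: Dict[int, MixedModelFit] = {}
    for order in sorted(orders):
        if order > distinct - 1:
            logger.warning("order %d excluded: exceeds distinct doses - 1 (%d)",
                           order, distinct - 1)
            continue
        try:
            X = polynomial_dose_design(dose, order, cov)
            fits[order] = RandomInterceptLMM().fit(X, outcome, subject).to_fit()
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("order %d excluded: %s", order, exc)
    if not fits:
        raise ValueError("no polynomial order could be fitted")
    key = {"bic": lambda f: f.bic, "aic": lambda f: f.aic,
           "deviance": lambda f: f.deviance}[criterion]
    selected = min(fits, key=lambda o: key(fits[o]))
    return selected, fits


# ---------------------------------------------------------------------------
# class-level models


def fit_class_dose_models(class_matrix: pd.DataFrame, meta: pd.DataFrame,
                          covariate: str = "bmi", order: int = 2,
                          ) -> Tuple[pd.DataFrame, Dict[str, MixedModelFit]]:
    """Dose–response mixed model per metabolite class (human design).

    Outcome is log2 of the summed class concentration; fixed effects are the
    polynomial dose terms plus the body covariate; (1|subject) random
    intercept.  Dose-term p-values are BH-adjusted across the whole family
    (classes x dose terms).  Returns a tidy coefficient table and the fits.
    """
    meta_idx = meta.set_index("sample_id")
    rows, fits = [], {}
    for cls in class_matrix.columns:
        sums = class_matrix[cls]
        ok = np.isfinite(sums.to_numpy(dtype=float)) & (sums.to_numpy(dtype=float) > 0)
        if ok.sum() < 3:
            logger.warning("class %s skipped: fewer than 3 finite sums", cls)
            continue
        samples = class_matrix.index[ok]
        sub = meta_idx.loc[samples]
        outcome = np.log2(sums[ok].to_numpy(dtype=float))
        cov = pd.DataFrame({covariate: sub[covariate].to_numpy(dtype=float)})
        try:
            fit = fit_random_intercept_lmm(
                outcome, sub["dose_mg"].to_numpy(dtype=float),
                sub["subject_id"].to_numpy(), order=order, covariates=cov,
                outcome_name=f"log2 {cls} sum")
        except ValueError as exc:
            logger.warning("class %s skipped: %s", cls, exc)
            continue
        fits[cls] = fit
        for term, row in fit.fixed_effects.iterrows():
            rows.append({"class": cls, "term": term, "estimate": row["estimate"],
                         "se": row["se"], "p": row["p"]})
    table = pd.DataFrame(rows)
    if len(table):
        dose_terms = table["term"].str.startswith("dose")
        table["q"] = np.nan
        if dose_terms.any():
            table.loc[dose_terms, "q"] = bh_adjust(table.loc[dose_terms, "p"])
    return table, fits


def fit_mouse_class_model(class_matrix: pd.DataFrame, meta: pd.DataFrame,
                          ) -> Tuple[pd.DataFrame, Dict[str, MixedModelFit]]:
    """Per-class fixed effects of age, body weight, genotype and treatment.

    Implements class ~ 1 + Age + BW + Genotype*Treatment + (1|ID) on the
    log2 summed class concentration.  Each mouse contributes one serum
    sample, so the random intercept is degenerate and the fit reduces to OLS
    at the λ = 0 boundary.  Genotype or treatment columns (and interactions)
    are dropped with a warning when the corresponding factor has a single
    level.  Returns the heatmap-ready tidy table and per-class fits.
    """
    required = ["age_group", "genotype", "treatment", "body_weight_g", "subject_id"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"mouse metadata missing columns: {missing}")
    meta_idx = meta.set_index("sample_id").loc[class_matrix.index]

    cols = {"Intercept": np.ones(len(meta_idx))}
    cols["Age[old]"] = (meta_idx["age_group"] == "old").astype(float).to_numpy()
    cols["BW"] = meta_idx["body_weight_g"].to_numpy(dtype=float)
    genotypes = [g for g in dict.fromkeys(meta_idx["genotype"]) if g != "WT"]
    treatments = [t for t in dict.fromkeys(meta_idx["treatment"]) if t != "control"]
    if not genotypes:
        logger.warning("single genotype: genotype and interaction columns dropped")
    if not treatments:
        logger.warning("no treatment arm: treatment columns dropped")
    for g in genotypes:
        cols[f"Genotype[{g}]"] = (meta_idx["genotype"] == g).astype(float).to_numpy()
    for t in treatments:
        cols[f"Treatment[{t}]"] = (meta_idx["treatment"] == t).astype(float).to_numpy()
    for g in genotypes:
        for t in treatments:
            cols[f"Genotype[{g}]:Treatment[{t}]"] = (
                cols[f"Genotype[{g}]"] * cols[f"Treatment[{t}]"])

    X = pd.DataFrame(cols, index=class_matrix.index)
    rows, fits = [], {}
    for cls in class_matrix.columns:
        sums = class_matrix[cls].to_numpy(dtype=float)
        ok = np.isfinite(sums) & (sums > 0)
        if ok.sum() <= X.shape[1]:
            logger.warning("class %s skipped: too few observations", cls)
            continue
        model = RandomInterceptLMM().fit(
            X.loc[ok], np.log2(sums[ok]), meta_idx.loc[ok, "subject_id"].to_numpy())
        fits[cls] = model.to_fit(outcome=f"log2 {cls} sum")
        for term, row in fits[cls].fixed_effects.iterrows():
            rows.append({"class": cls, "term": term, "estimate": row["estimate"],
                         "se": row["se"], "p": row["p"]})
    return pd.DataFrame(rows), fits
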