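"""Kaplan–Meier survival estimation, log-rank testing and calculated osmolality.

The product-limit estimator and the (k-group) log-rank test are implemented
directly: at every distinct event time the observed events per group are
compared with their hypergeometric expectation given the risk sets, and the
chi-square statistic on k−1 df uses the summed covariance. Censored subjects
tied with an event time are processed after the events (standard convention),
so they count in the risk set at that time.

Calculated serum osmolality uses the standard clinical formula
2·Na + glucose/18 + BUN/2.8 (sodium in mmol/L, glucose and BUN in mg/dL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from scipy import stats

from .datatypes import validate_survival_cohort


@dataclass
class KMEstimate:
    """Per-group product-limit curves plus the log-rank test."""

    curves: Dict[str, pd.DataFrame]  # time, at_risk, events, survival
    chi_square: float
    df: int
    p: float


def kaplan_meier_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival for one group.

    Rows at every distinct event time: risk-set size, events, and the
    survival probability just after that time.  Survival starts at 1 (an
    implicit time-0 row is included).
    """
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = [{"time": 0.0, "at_risk": len(times), "events": 0, "survival": 1.0}]
    surv = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int(np.sum(times >= t))  # ties censored at t remain at risk
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d,
                     "survival": surv})
    return pd.DataFrame(rows)


def logrank_test(cohort: pd.DataFrame) -> Tuple[float, int, float]:
    """k-group log-rank test; returns (chi_square, df, p).

    Observed vs expected events per group at every event time, with the
    multivariate hypergeometric covariance of the event allocation; the
    statistic is (O−E)' V⁻ (O−E) over the first k−1 groups, chi-square with
    k−1 df (asymptotic).
    """
    cohort = validate_survival_cohort(cohort)
    groups = list(dict.fromkeys(cohort["group"]))
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    times = cohort["time_days"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    gidx = np.array([groups.index(g) for g in cohort["group"]])
    if events.sum() == 0:
        raise ValueError("no events")

    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int(((times == t) & (events == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(times == t) & (events == 1)], minlength=k).astype(float)
        e_g = n_g * d / n
        o_minus_e += d_g - e_g
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += v
    u = o_minus_e[:-1]
    v = cov[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(v) @ u) if np.any(v) else 0.0
    p = float(stats.chi2.sf(chi2, df=k - 1)) if chi2 > 0 else 1.0
    return chi2, k - 1, p


def kaplan_meier(cohort: pd.DataFrame) -> KMEstimate:
    """Per-group Kaplan–Meier curves with a log-rank comparison."""
    cohort = validate_survival_cohort(cohort)
    curves = {}
    for group, sub in cohort.groupby("group", sort=False):
        curves[str(group)] = kaplan_meier_curve(
            sub["time_days"].to_numpy(dtype=float),
            sub["event"].to_numpy(dtype=int))
    if cohort["group"].nunique() >= 2 and cohort["event"].sum() > 0:
        chi2, df, p = logrank_test(cohort)
    else:
        chi2, df, p = np.nan, 0, np.nan
    return KMEstimate(curves=curves, chi_square=chi2, df=df, p=p)


def calculated_osmolality(sodium_mmol_l, glucose_mg_dl, bun_mg_dl):
    """Calculated serum osmolality (mOsm/kg): 2·Na + glucose/18 + BUN/2.8."""
    na = np.asarray(sodium_mmol_l, dtype=float)
    glu = np.asarray(glucose_mg_dl, dtype=float)
    bun = np.asarray(bun_mg_dl, dtype=float)
    for name, arr in (("sodium", na), ("glucose", glu), ("BUN", bun)):
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} values must be positive")
    result = 2.0 * na + glu / 18.0 + bun / 2.8
    if result.ndim == 0:
        return float(result)
    return result
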