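"""Aging-signature construction and reversal scoring.

The aging signature is a per-feature vector of age effects (log2FC old vs
young, or external per-year β-age coefficients).  A treatment's reversal
score is the Spearman correlation between its per-feature effects and that
signature over the shared features: ρ < 0 means the treatment moves features
opposite to aging ("rejuvenation").  Families of scores (several treatment
arms against one signature) are BH-adjusted together; per-subject scores in
the longitudinal design correlate each subject-visit's change-from-baseline
vector against the β-age signature.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EffectVector, FeatureMatrix, LOG2, SignatureScore
from .differential import bh_adjust

logger = logging.getLogger("rejumet")


def _shared_finite(signature: EffectVector, effect: EffectVector):
    sig = signature.estimate
    eff = effect.estimate
    shared = [f for f in sig.index if f in set(eff.index)]
    x = sig.loc[shared].to_numpy(dtype=float)
    y = eff.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho (tiny n only)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= target
        total += 1
    return count / total


def reversal_score(signature: EffectVector, effect: EffectVector,
                   exact_below: int = 0) -> SignatureScore:
    """Spearman correlation of a treatment effect against an aging signature.

    Features are intersected by exact name; ties get average ranks; the
    two-sided p uses the t-approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df.
    With ``exact_below`` set, panels smaller than that use an exact
    permutation p instead (feasible for n < 10).
    """
    x, y = _shared_finite(signature, effect)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 shared finite features")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero rank variance: constant effect vector")
    rho, p = stats.spearmanr(x, y)
    if exact_below and n < exact_below:
        p = _exact_spearman_p(x, y, rho)
    p = min(max(float(p), np.finfo(float).tiny), 1.0)  # keep p in (0, 1] for BH
    return SignatureScore(rho=float(rho), p=float(p), n_features=n,
                          label_x=signature.label, label_y=effect.label)


def score_family(signature: EffectVector,
                 effects: Sequence[EffectVector]) -> List[SignatureScore]:
    """Score several effects against one signature; BH across the family."""
    scores = []
    for effect in effects:
        try:
            scores.append(reversal_score(signature, effect))
        except ValueError as exc:
            raise ValueError(f"scoring {effect.label!r} failed: {exc}") from exc
    q = bh_adjust([s.p for s in scores])
    for s, qi in zip(scores, q):
        s.q = float(qi)
    return scores


def scores_to_frame(scores: Sequence[SignatureScore]) -> pd.DataFrame:
    return pd.DataFrame([{
        "label_x": s.label_x, "label_y": s.label_y, "rho": s.rho,
        "p": s.p, "q": s.q, "n_features": s.n_features,
    } for s in scores])


@dataclass
class SubjectScoreSeries:
    """One subject's per-visit signature scores (baseline excluded)."""

    subject_id: str
    table: pd.DataFrame  # visit_index, dose_mg, rho, p, n_features, note
    baseline_visit: int


def subject_signature_scores(matrix: FeatureMatrix, meta: pd.DataFrame,
                             beta_age: EffectVector,
                             baseline_visit: Optional[int] = None,
                             ) -> List[SubjectScoreSeries]:
    """Per-subject, per-visit signature scores in the longitudinal design.

    For each subject, each follow-up visit's change from that subject's own
    baseline (log2 value difference per feature) is correlated against the
    β-age signature.  Missing features are dropped pairwise.  An all-zero
    change vector (follow-up identical to baseline) cannot be ranked and is
    recorded as a missing score with a reason, not an error.
    """
    if matrix.scale != LOG2:
        raise ValueError("subject scoring expects a log2-scaled matrix")
    if "visit_index" not in meta.columns:
        raise ValueError("metadata must carry visit_index")
    beta = beta_age.estimate
    shared = [f for f in matrix.feature_ids if f in set(beta.index)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 features shared with the age signature")
    bvec = beta.loc[shared].to_numpy(dtype=float)

    out = []
    for subject, sub in meta.groupby("subject_id", sort=False):
        sub = sub.sort_values("visit_index")
        visits = list(sub["visit_index"])
        base_visit = baseline_visit if baseline_visit is not None else min(visits)
        if base_visit not in visits:
            raise ValueError(f"subject {subject!r} has no baseline visit")
        base_sample = sub.loc[sub["visit_index"] == base_visit, "sample_id"].iloc[0]
        base_vals = matrix.data.loc[base_sample, shared].to_numpy(dtype=float)
        records = []
        for _, row in sub.iterrows():
            if row["visit_index"] == base_visit:
                continue
            vals = matrix.data.loc[row["sample_id"], shared].to_numpy(dtype=float)
            change = vals - base_vals
            ok = np.isfinite(change) & np.isfinite(bvec)
            rec = {"visit_index": int(row["visit_index"]),
                   "dose_mg": float(row.get("dose_mg", np.nan)),
                   "rho": np.nan, "p": np.nan, "n_features": int(ok.sum()),
                   "note": ""}
            if ok.sum() < 3:
                rec["note"] = "fewer than 3 shared features"
            elif np.all(change[ok] == change[ok][0]):
                rec["note"] = "constant change vector"
            else:
                rho, p = stats.spearmanr(change[ok], bvec[ok])
                rec["rho"], rec["p"] = float(rho), float(p)
            records.append(rec)
        out.append(SubjectScoreSeries(subject_id=str(subject),
                                      table=pd.DataFrame(records),
                                      baseline_visit=int(base_visit)))
    return out


def subject_scores_to_frame(series: Sequence[SubjectScoreSeries]) -> pd.DataFrame:
    frames = []
    for s in series:
        t = s.table.copy()
        t.insert(0, "subject_id", s.subject_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
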