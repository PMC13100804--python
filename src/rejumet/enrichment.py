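"""Preranked gene-set enrichment for cell-type marker sets.

Features are ranked by a signed statistic (moderated t by default) and each
marker set is scored with the weighted Kolmogorov–Smirnov running sum:
stepping down the ranking, the sum rises by |stat|^w / Σ_members|stat|^w at
members and falls by 1/(N−m) elsewhere; the enrichment score (ES) is the
extremum.  Significance comes from gene-label permutation (sets of equal
size drawn from the ranked universe), the appropriate null for a preranked
effect vector; p-values are two-sided on |ES| with the permutation floor
1/(1+n_perm), BH-adjusted across sets.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .differential import bh_adjust

logger = logging.getLogger("rejumet")


def build_ranked_list(statistic: pd.Series) -> pd.Series:
    """Order features by decreasing statistic; ties broken by feature id.

    Duplicate feature ids are rejected — the ranking must be a strict order.
    """
    if statistic.index.duplicated().any():
        raise ValueError("duplicate feature ids in ranking")
    values = statistic.astype(float)
    if values.isna().any():
        raise ValueError("ranking statistic contains missing values")
    order = sorted(values.index, key=lambda f: (-values[f], str(f)))
    return values.loc[order]


def _running_sum_extremum(in_set: np.ndarray, weights: np.ndarray) -> float:
    n = len(in_set)
    m = int(in_set.sum())
    hit = np.where(in_set, weights, 0.0)
    total = hit.sum()
    if total == 0:  # all member stats zero: equal weights
        hit = in_set / m
    else:
        hit = hit / total
    miss = np.where(~in_set, 1.0 / (n - m), 0.0) if n > m else np.zeros(n)
    running = np.cumsum(hit - miss)
    return float(running[np.argmax(np.abs(running))])


def enrichment_score(ranked: pd.Series, gene_set: Iterable[str],
                     weight_exponent: float = 1.0) -> float:
    """Weighted KS enrichment score of a feature set against a ranked list."""
    members = set(gene_set) & set(ranked.index)
    if not members:
        raise ValueError("gene set has no overlap with the ranked list")
    in_set = np.array([f in members for f in ranked.index])
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    return _running_sum_extremum(in_set, weights)


def permutation_pvalues(ranked: pd.Series, gene_sets: Dict[str, Sequence[str]],
                        n_perm: int = 1000, seed: int = 0,
                        weight_exponent: float = 1.0,
                        min_size: int = 2) -> pd.DataFrame:
    """Gene-label permutation p-values for a family of sets.

    For each set, ``n_perm`` random same-size member selections from the
    ranked universe form the null; p = (1 + #{|ES_perm| ≥ |ES_obs|}) /
    (1 + n_perm).  The normalised ES divides by the mean |ES| of the null.
    Results are BH-adjusted across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ranked = build_ranked_list(ranked)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    universe = np.array(ranked.index)

    rows = []
    for name, members in gene_sets.items():
        overlap = set(members) & set(universe)
        size = len(overlap)
        if size < min_size:
            logger.warning("set %s skipped: %d member(s) in ranking", name, size)
            continue
        in_set = np.isin(universe, list(overlap))
        es_obs = _running_sum_extremum(in_set, weights)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=size, replace=False)] = True
            null[b] = _running_sum_extremum(perm, weights)
        p = (1.0 + np.sum(np.abs(null) >= abs(es_obs))) / (1.0 + n_perm)
        denom = float(np.mean(np.abs(null)))
        nes = es_obs / denom if denom > 0 else np.nan
        rows.append({"set": name, "size": size, "es": es_obs, "nes": nes, "p": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["p"])
    return result


def read_gmt(path) -> Dict[str, Tuple[str, ...]]:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = tuple(parts[2:])
    return sets
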