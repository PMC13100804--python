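"""Cross-condition integration: correlation network and effect PCA.

Conditions (mouse aging, losartan arms, knockout arms, human aging β, human
losartan) are each summarised by a per-feature effect vector.  The network
has one node per condition and Spearman-correlation edges (BH-adjusted over
all pairs; q < 0.05 marks significant edges), laid out by classical
multidimensional scaling of the signed distance 1 − ρ so that anticorrelated
conditions sit far apart.  The PCA scales each condition's effect vector by
its own standard deviation *without centering* (equalising β-age and log2FC
scales while preserving the origin) and decomposes the result by SVD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import EffectVector
from .differential import bh_adjust

logger = logging.getLogger("rejumet")


def effects_to_matrix(effects: Sequence[EffectVector]) -> pd.DataFrame:
    """Features x conditions estimate matrix over the shared feature set."""
    if len(effects) < 2:
        raise ValueError("need at least 2 conditions")
    labels = [e.label or f"condition_{i}" for i, e in enumerate(effects)]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")
    shared = set(effects[0].feature_ids)
    for e in effects[1:]:
        shared &= set(e.feature_ids)
    ordered = [f for f in effects[0].feature_ids if f in shared]
    mat = pd.DataFrame(
        {lab: e.estimate.loc[ordered] for lab, e in zip(labels, effects)})
    return mat.dropna(axis=0)


@dataclass
class EffectNetwork:
    nodes: List[str]
    edges: pd.DataFrame  # node_a, node_b, rho, p, q, significant, n_features
    layout: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes:
            x, y = self.layout.get(node, (0.0, 0.0))
            g.add_node(node, x=float(x), y=float(y))
        for _, row in self.edges.iterrows():
            if np.isfinite(row["rho"]):
                g.add_edge(row["node_a"], row["node_b"], rho=float(row["rho"]),
                           p=float(row["p"]), q=float(row["q"]),
                           significant=bool(row["significant"]))
        return g


def _classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix to k dimensions."""
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    # deterministic sign: first non-zero coordinate of each axis positive
    for c in range(coords.shape[1]):
        col = coords[:, c]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, c] = -col
    return coords


def build_effect_network(effects: Sequence[EffectVector],
                         alpha: float = 0.05) -> EffectNetwork:
    """All-pairs Spearman correlation network of condition effects.

    Pairwise intersection of finite features; BH across all pairs; an edge is
    significant when q < alpha.  A condition with a constant effect vector
    has undefined correlations — its edges are kept with rho = NaN and
    flagged as undefined rather than dropped silently.
    """
    labels = [e.label or f"condition_{i}" for i, e in enumerate(effects)]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")
    series = {lab: e.estimate for lab, e in zip(labels, effects)}

    rows = []
    for a, b in combinations(labels, 2):
        x = series[a]
        y = series[b]
        shared = [f for f in x.index if f in set(y.index)]
        xv = x.loc[shared].to_numpy(dtype=float)
        yv = y.loc[shared].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        rec = {"node_a": a, "node_b": b, "rho": np.nan, "p": np.nan,
               "n_features": int(ok.sum()), "undefined": False}
        if ok.sum() < 3:
            rec["undefined"] = True
        elif np.all(xv[ok] == xv[ok][0]) or np.all(yv[ok] == yv[ok][0]):
            logger.warning("edge (%s, %s) undefined: constant effect vector", a, b)
            rec["undefined"] = True
        else:
            rho, p = stats.spearmanr(xv[ok], yv[ok])
            rec["rho"], rec["p"] = float(rho), float(p)
        rows.append(rec)
    edges = pd.DataFrame(rows)
    defined = ~edges["undefined"]
    edges["q"] = np.nan
    if defined.any():
        edges.loc[defined, "q"] = bh_adjust(np.clip(edges.loc[defined, "p"],
                                                    np.finfo(float).tiny, 1.0))
    edges["significant"] = defined & (edges["q"] < alpha)

    # layout: classical MDS of 1 - rho (signed), undefined pairs at distance 1
    n = len(labels)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for _, row in edges.iterrows():
        if np.isfinite(row["rho"]):
            i, j = labels.index(row["node_a"]), labels.index(row["node_b"])
            dist[i, j] = dist[j, i] = 1.0 - row["rho"]
    coords = _classical_mds(dist)
    layout = {lab: (float(coords[i, 0]), float(coords[i, 1]))
              for i, lab in enumerate(labels)}
    return EffectNetwork(nodes=labels, edges=edges, layout=layout)


class EffectPCA(BaseEstimator):
    """Uncentered PCA of condition effect vectors.

    Each condition column is divided by its own standard deviation (computed
    about its mean) with *no* mean subtraction, then the conditions x
    features matrix is decomposed by SVD.  Fitted attributes:

    - ``loadings_`` : features x components, orthonormal columns
    - ``scores_`` : conditions x components
    - ``variance_fraction_`` : squared singular values, normalised to 1
    - ``feature_ids_``, ``condition_labels_``
    """

    def __init__(self, scale_mode: str = "z-scale-no-center"):
        self.scale_mode = scale_mode

    def fit(self, effects):
        if isinstance(effects, pd.DataFrame):
            mat = effects.dropna(axis=0)
        else:
            mat = effects_to_matrix(effects)
        if mat.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        values = mat.to_numpy(dtype=float)
        if self.scale_mode == "z-scale-no-center":
            sd = values.std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = [mat.columns[i] for i in np.nonzero(sd == 0)[0]]
                raise ValueError(f"zero-variance condition(s): {bad}")
            scaled = values / sd
        elif self.scale_mode == "none":
            scaled = values
        else:
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")

        # conditions are the observations: decompose X (conditions x features)
        u, s, vt = np.linalg.svd(scaled.T, full_matrices=False)
        # deterministic sign: largest-magnitude loading positive per component
        for k in range(vt.shape[0]):
            j = np.argmax(np.abs(vt[k]))
            if vt[k, j] < 0:
                vt[k] = -vt[k]
                u[:, k] = -u[:, k]
        self.feature_ids_ = list(mat.index)
        self.condition_labels_ = list(mat.columns)
        self.loadings_ = vt.T  # features x components
        self.scores_ = u * s  # conditions x components
        self.singular_values_ = s
        total = float(np.sum(s ** 2))
        self.variance_fraction_ = (s ** 2) / total if total > 0 else s * 0.0
        self.scaled_ = pd.DataFrame(scaled, index=mat.index, columns=mat.columns)
        return self

    def fit_transform(self, effects):
        return self.fit(effects).scores_

    def reconstruct(self) -> np.ndarray:
        """Scaled input implied by all retained components (conditions x features)."""
        return self.scores_ @ self.loadings_.T


def effect_pca(effects, scale_mode: str = "z-scale-no-center") -> EffectPCA:
    """Functional wrapper over :class:`EffectPCA`."""
    return EffectPCA(scale_mode=scale_mode).fit(effects)
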