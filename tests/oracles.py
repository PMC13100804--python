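"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a published formula through a different code path
than the package (brute force, enumeration, closed form, or a different
root-finder), so agreement is evidence of correctness rather than
self-consistency.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats


def ebayes_oracle(sigma2, df, estimate, stdev_unscaled):
    """Direct-formula moderated-t computation.

    Moment-matches log s² to the scaled-F prior, solving the trigamma
    equation with bracketing bisection (brentq) rather than Newton, then
    applies the moderated-variance and t formulas literally.
    Returns (d0, s0_sq, t, p).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.asarray(df, dtype=float)
    z = np.log(sigma2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if e_var > 0:
        f = lambda x: special.polygamma(1, x) - e_var
        x = optimize.brentq(f, 1e-10, 1e12, xtol=1e-300, rtol=8.9e-16)
        d0 = 2.0 * x
        s0_sq = np.exp(e_mean + special.digamma(x) - np.log(x))
    else:
        d0, s0_sq = np.inf, float(np.exp(e_mean))
    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s0_sq)
        t = estimate / (np.sqrt(s2_post) * stdev_unscaled)
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s2_post = (d0 * s0_sq + df * sigma2) / (d0 + df)
        t = estimate / (np.sqrt(s2_post) * stdev_unscaled)
        p = 2.0 * stats.t.sf(np.abs(t), d0 + df)
    return d0, s0_sq, t, p


def bh_oracle(p):
    """Definition-following O(m²) Benjamini–Hochberg adjustment.

    q_i = min over thresholds p_j ≥ p_i of m·p_j / #{k : p_k ≤ p_j}, capped
    at 1 — the step-up rule applied literally, without sorting tricks.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = []
        for j in range(m):
            if p[j] >= p[i]:
                rank = int(np.sum(p <= p[j]))
                candidates.append(m * p[j] / rank)
        q[i] = min(1.0, min(candidates))
    return q


def chi2_4_tail(x):
    """Upper tail of chi-square with 4 df via its closed form (1 + x/2)e^(−x/2)."""
    return (1.0 + x / 2.0) * np.exp(-x / 2.0)


def chi2_4_tail_quad(x):
    """Same tail by numerical integration of the density (independent route)."""
    from scipy.integrate import quad

    dens = lambda u: u * np.exp(-u / 2.0) / 4.0
    val, _ = quad(dens, x, np.inf)
    return val


def manual_ranks(x):
    """Average ranks computed by explicit counting (no library rank call)."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y):
    """Rank-then-Pearson Spearman correlation."""
    rx, ry = manual_ranks(x), manual_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def balanced_lmm_closed_form(y, n_subjects, n_per_subject):
    """Textbook ML solution of the balanced one-way random-effects model.

    y is (a·m,) grouped by subject in blocks of m.  Returns
    (mu, sigma2_subject, sigma2_resid); the between-subject component is
    clipped at 0 (boundary).
    """
    a, m = n_subjects, n_per_subject
    y = np.asarray(y, dtype=float).reshape(a, m)
    subj_means = y.mean(axis=1)
    grand = y.mean()
    ssa = m * np.sum((subj_means - grand) ** 2)
    msa = ssa / (a - 1)
    mse = np.sum((y - subj_means[:, None]) ** 2) / (a * (m - 1))
    sigma_b = max(((1 - 1 / a) * msa - mse) / m, 0.0)
    return float(grand), float(sigma_b), float(mse)


def enrichment_score_oracle(ranked_ids, ranked_stats, gene_set, weight=1.0):
    """Brute-force weighted KS running sum, one position at a time."""
    members = set(gene_set)
    n = len(ranked_ids)
    m = sum(1 for f in ranked_ids if f in members)
    denom = sum(abs(s) ** weight for f, s in zip(ranked_ids, ranked_stats)
                if f in members)
    best = 0.0
    running = 0.0
    for f, s in zip(ranked_ids, ranked_stats):
        if f in members:
            running += (abs(s) ** weight / denom) if denom > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


def class_sum_oracle(values, classes):
    """Loop-based class sums: values (n x p), classes length-p labels."""
    out = {}
    for cls in dict.fromkeys(classes):
        idx = [j for j, c in enumerate(classes) if c == cls]
        col = []
        for i in range(values.shape[0]):
            cells = [values[i, j] for j in idx if np.isfinite(values[i, j])]
            col.append(sum(cells) if cells else np.nan)
        out[cls] = np.array(col)
    return out


def km_hand_table(times, events):
    """Product-limit survival computed row by row (for fixture checking)."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    rows = []
    surv = 1.0
    for t in sorted(set(times[events == 1])):
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= (n_risk - d) / n_risk
        rows.append((float(t), n_risk, d, surv))
    return rows
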