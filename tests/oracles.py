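"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately naive implementations — fixed-point iteration, explicit
step-up minima, explicit normal equations — kept free of any code from
the package under test.
"""

from __future__ import annotations

import numpy as np


def curate_oracle(annotations, rt_tolerance=0.10, intensity_fraction=0.25):
    """Exhaustive O(n^2) redundancy filter over (mode, key) groups.

    Iterates to a fixed point: an annotation is removed while there
    exists a surviving strictly-preferred annotation of the same identity
    and mode (higher abundance, ties by earlier RT then input order)
    within the RT tolerance, or while its abundance is below the fraction
    of its group's surviving maximum.  Cross-mode: for identities in both
    modes, every annotation of the mode with the lower per-identity
    maximum abundance is removed (positive wins exact ties).
    """
    items = list(enumerate(annotations))

    def prefer(a_idx, b_idx):  # is a preferred over b
        a, b = annotations[a_idx], annotations[b_idx]
        ka = (-a.abundance, a.retention_time, a_idx)
        kb = (-b.abundance, b.retention_time, b_idx)
        return ka < kb

    alive = {i for i, _ in items}
    changed = True
    while changed:
        changed = False
        for i, a in items:
            if i not in alive:
                continue
            group = [j for j, b in items
                     if j != i and j in alive and b.mode == a.mode and b.key == a.key]
            group_max = max([annotations[j].abundance for j in group] + [a.abundance])
            rt_hit = any(
                prefer(j, i)
                and abs(annotations[j].retention_time - a.retention_time) < rt_tolerance
                for j in group
            )
            weak = a.abundance < intensity_fraction * group_max
            if rt_hit or weak:
                alive.discard(i)
                changed = True

    pos_max, neg_max = {}, {}
    for i in alive:
        a = annotations[i]
        d = pos_max if a.mode == "positive" else neg_max
        d[a.key] = max(d.get(a.key, 0.0), a.abundance)
    survivors = []
    for i, a in items:
        if i not in alive:
            continue
        if a.key in pos_max and a.key in neg_max:
            if a.mode == "positive":
                keep = pos_max[a.key] >= neg_max[a.key]
            else:
                keep = neg_max[a.key] > pos_max[a.key]
            if not keep:
                continue
        survivors.append(a)
    return survivors


def bh_oracle(p_values):
    """Step-up BH as an explicit min-over-tail: q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(rank_i, m)), 1.0
        )
    return q


def ols_oracle(y, X):
    """Explicit normal-equations OLS: beta = (X'X)^-1 X'y, textbook SEs."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    from scipy import stats

    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p
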