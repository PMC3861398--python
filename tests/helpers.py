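"""Independent oracle implementations used by the tests.

Everything here is deliberately written as plain, slow, readable code with
no dependency on nestmorph internals, so that agreement between package and
oracle is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def boundary_scan_oracle(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour.

    Pixels outside the raster count as background.
    """
    mask = np.asarray(mask, bool)
    H, W = mask.shape
    out = np.zeros_like(mask)
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < H and 0 <= cc < W) or not mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def otsu_bruteforce(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance maximization over bin boundaries."""
    v = np.asarray(values, float).ravel()
    lo, hi = v.min(), v.max()
    hist, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_thr = -1.0, lo
    total = hist.sum()
    for t in range(1, nbins):
        w0 = hist[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t] * centers[:t]).sum() / w0
        mu1 = (hist[t:] * centers[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_thr = centers[t - 1]
    return best_thr


def logrank_chisq_oracle(times, events, groups) -> float:
    """k-group log-rank chi-square via a plain loop over event times.

    Standard hypergeometric mean/variance with the (N-d)/(N-1) tie factor;
    the quadratic form drops the last group.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = labels.size
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        N = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n_j = np.array([(at_risk & (groups == g)).sum() for g in labels], float)
        d_j = np.array([((times == t) & (events == 1) & (groups == g)).sum()
                        for g in labels], float)
        O += d_j
        E += d * n_j / N
        if N > 1:
            c = d * (N - d) / (N - 1)
            p = n_j / N
            V += c * (np.diag(p) - np.outer(p, p))
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    return float(z @ np.linalg.solve(Vsub, z))


def search_cutpoints_oracle(values, times, events, min_frac: float = 0.10):
    """Naive double-loop best-P two-cutpoint search.

    Enumerates every ordered pair of distinct observed values in
    lexicographic order and recomputes the 3-group log-rank statistic from
    scratch for each; strict improvement keeps the first (smallest) maximizer.
    Returns (cut1, cut2, chisq).
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = values.size
    distinct = np.sort(np.unique(values))
    best = (None, None, -np.inf)
    for i in range(distinct.size):
        for j in range(i + 1, distinct.size):
            c1, c2 = distinct[i], distinct[j]
            g = (values > c1).astype(int) + (values > c2).astype(int)
            sizes = np.bincount(g, minlength=3)
            if sizes.min() < min_frac * n:
                continue
            try:
                chi = logrank_chisq_oracle(times, events, g)
            except np.linalg.LinAlgError:
                continue
            if chi > best[2]:
                best = (float(c1), float(c2), chi)
    return best


def km_survival_oracle(times, events, t: float) -> float:
    """Product-limit estimate S(t) computed by the textbook formula."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    for tt in np.sort(np.unique(times[events == 1])):
        if tt > t:
            break
        n_at_risk = (times >= tt).sum()
        d = ((times == tt) & (events == 1)).sum()
        s *= 1.0 - d / n_at_risk
    return s


def cox_score_test_oracle(times, events, x) -> float:
    """Cox partial-likelihood score chi-square at beta = 0 (no ties)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    U = 0.0
    I = 0.0
    for t in times[events == 1]:
        at_risk = times >= t
        xbar = x[at_risk].mean()
        xi = x[(times == t) & (events == 1)]
        U += float(xi.sum() - xi.size * xbar)
        I += float(xi.size * (np.mean(x[at_risk] ** 2) - xbar**2))
    return U * U / I
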