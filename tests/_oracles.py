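"""Brute-force reference implementations used only by the test suite.

Each oracle evaluates the published definition literally — explicit
loops, Floyd-Warshall dynamic programming, exhaustive enumeration —
independently of the package's vectorized implementations.
"""

import itertools

import numpy as np


def degree_oracle(w):
    n = len(w)
    return np.array(
        [sum(1 for j in range(n) if w[i][j] > 0) for i in range(n)]
    )


def strength_oracle(w):
    n = len(w)
    return np.array([sum(w[i][j] for j in range(n)) for i in range(n)])


def clustering_oracle(w):
    """Geometric-mean triangle clustering on max-normalized weights."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    what = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if w[i][j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += (what[i][j] * what[i][h] * what[j][h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def floyd_warshall_oracle(lengths):
    """All-pairs shortest paths by dynamic programming."""
    n = len(lengths)
    d = np.array(lengths, dtype=float)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def distance_oracle(w):
    """Weighted distances with reciprocal lengths, via Floyd-Warshall."""
    n = len(w)
    lengths = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if w[i][j] > 0:
                lengths[i][j] = 1.0 / w[i][j]
    return floyd_warshall_oracle(lengths)


def global_efficiency_oracle(w):
    n = len(w)
    d = distance_oracle(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i][j]):
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def local_efficiency_oracle(w):
    """Literal loop evaluation of the weighted local-efficiency formula.

    For each node u: neighbor-neighbor distances on cube-root reciprocal
    lengths within the neighborhood subgraph; entry terms are cube roots
    of the connection weights to u.
    """
    w = np.asarray(w, dtype=float)
    n = len(w)
    out = np.zeros(n)
    for u in range(n):
        nbrs = [j for j in range(n) if w[u][j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        m = len(nbrs)
        sub_len = np.full((m, m), np.inf)
        for a in range(m):
            for b in range(m):
                if w[nbrs[a]][nbrs[b]] > 0:
                    sub_len[a][b] = (1.0 / w[nbrs[a]][nbrs[b]]) ** (1.0 / 3.0)
        d = floyd_warshall_oracle(sub_len)
        total = 0.0
        for a in range(m):
            for b in range(m):
                if a != b and np.isfinite(d[a][b]) and d[a][b] > 0:
                    total += (
                        (w[u][nbrs[a]] * w[u][nbrs[b]]) ** (1.0 / 3.0)
                        / d[a][b]
                    )
        out[u] = total / (k * (k - 1))
    return out


def wilcoxon_exact_oracle(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        rp = sum(r for r, s in zip(ranks, signs) if s)
        if min(rp, ranks.sum() - rp) <= w_obs:
            count += 1
    return w_obs, count / 2.0**n


def bh_stepup_oracle(pvals):
    """Independent Benjamini-Hochberg step-up, computed by definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, m * p[idx] / rank)
        q[idx] = min(prev, 1.0)
    return q


def ols_oracle(x, y):
    """Closed-form simple OLS with hat diagonal and Cook's distances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    beta = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - beta * xbar
    fitted = intercept + beta * x
    resid = y - fitted
    sse = (resid**2).sum()
    sst = ((y - ybar) ** 2).sum()
    r2 = 1.0 - sse / sst
    s2 = sse / (n - 2)
    f = r2 * (n - 2) / (1.0 - r2)
    h = 1.0 / n + (x - xbar) ** 2 / sxx
    cooks = resid**2 * h / (2 * s2 * (1 - h) ** 2)
    from scipy.stats import f as fdist

    p = fdist.sf(f, 1, n - 2)
    return {
        "beta": beta,
        "intercept": intercept,
        "r2": r2,
        "f": f,
        "p": p,
        "resid": resid,
        "h": h,
        "cooks": cooks,
        "slope_se": np.sqrt(s2 / sxx),
    }
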