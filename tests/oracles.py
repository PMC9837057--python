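"""Independent reference implementations used only to check the package.

Each oracle re-derives its quantity by the most literal route available
(explicit enumeration, hand-rolled step-up, textbook normal equations) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(pvals):
    """Literal Benjamini-Hochberg step-up adjusted p-values."""
    p = list(map(float, pvals))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = p[i] * n / rank_from_top
        running_min = min(running_min, value)
        adj[i] = min(running_min, 1.0)
    return adj


def coloc_enumerate(labf_a, labf_b, p1, p2, p12):
    """Posterior PPH0..PPH4 by explicit enumeration of causal configurations.

    Every single-causal-variant configuration pair is listed: the empty
    configuration (H0), each variant causal for one trait only (H1/H2), each
    ordered pair of distinct variants (H3), and each shared variant (H4).
    Weights are accumulated in plain floats after subtracting the max log
    Bayes factor for stability.
    """
    la = [float(x) for x in labf_a]
    lb = [float(x) for x in labf_b]
    m = len(la)
    assert len(lb) == m

    configs = [("h0", 0.0)]
    for j in range(m):
        configs.append(("h1", math.log(p1) + la[j]))
    for k in range(m):
        configs.append(("h2", math.log(p2) + lb[k]))
    for j in range(m):
        for k in range(m):
            if j != k:
                configs.append(("h3", math.log(p1) + math.log(p2) + la[j] + lb[k]))
    for j in range(m):
        configs.append(("h4", math.log(p12) + la[j] + lb[j]))

    top = max(w for _, w in configs)
    sums = {"h0": 0.0, "h1": 0.0, "h2": 0.0, "h3": 0.0, "h4": 0.0}
    for name, w in configs:
        sums[name] += math.exp(w - top)
    total = sum(sums.values())
    return np.array([sums[h] / total for h in ("h0", "h1", "h2", "h3", "h4")])


def wls_line(x, y, w):
    """Weighted least squares of y on [1, x] via textbook normal equations.

    Returns (intercept, slope, se_intercept_unit, se_slope_unit, sigma) where
    the unit SEs are sqrt(diag((X'WX)^-1)) and sigma^2 is the weighted
    residual mean square on n - 2 df.
    """
    x, y, w = (np.asarray(v, float) for v in (x, y, w))
    n = len(x)
    s_w = w.sum()
    s_wx = (w * x).sum()
    s_wxx = (w * x * x).sum()
    s_wy = (w * y).sum()
    s_wxy = (w * x * y).sum()
    det = s_w * s_wxx - s_wx**2
    intercept = (s_wxx * s_wy - s_wx * s_wxy) / det
    slope = (s_w * s_wxy - s_wx * s_wy) / det
    resid = y - intercept - slope * x
    sigma2 = float((w * resid**2).sum() / (n - 2))
    se_intercept_unit = math.sqrt(s_wxx / det)
    se_slope_unit = math.sqrt(s_w / det)
    return intercept, slope, se_intercept_unit, se_slope_unit, math.sqrt(sigma2)


def greedy_tag_bruteforce(r2, priority, positions, keys, threshold):
    """Literal re-execution of the stated tagging rule with explicit scans."""
    r2 = np.asarray(r2, float)
    m = r2.shape[0]
    unassigned = set(range(m))
    loci = {}
    while unassigned:
        tag = min(unassigned, key=lambda i: (priority[i], positions[i], keys[i]))
        members = {tag}
        for j in list(unassigned):
            if r2[tag, j] >= threshold:
                members.add(j)
        unassigned -= members
        loci[tag] = sorted(members)
    return loci


def allpairs_containment(chroms, positions, regions):
    """All-pairs closed-interval containment: list of region gene_ids per SNP."""
    out = []
    for c, p in zip(chroms, positions):
        hits = [r.gene_id for r in regions
                if r.chrom == str(c) and r.start <= p <= r.end]
        out.append(sorted(hits))
    return out


def ols_slope(g, y):
    """Simple-regression slope, intercept, SE by hand (normal equations)."""
    g, y = np.asarray(g, float), np.asarray(y, float)
    n = len(g)
    gbar, ybar = g.mean(), y.mean()
    sxx = ((g - gbar) ** 2).sum()
    sxy = ((g - gbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * gbar
    resid = y - intercept - slope * g
    sigma2 = (resid**2).sum() / (n - 2)
    return slope, intercept, math.sqrt(sigma2 / sxx)
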