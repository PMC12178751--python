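"""Independent brute-force reference implementations used only by tests.

Everything here is written from the textbook definitions — explicit rank
tables, reachability closures, exhaustive minima — deliberately avoiding
the code paths (scipy/sklearn/statsmodels and the package itself) that
they are used to check.
"""

from __future__ import annotations

import math
from itertools import combinations


def ranks_with_ties(values):
    """Average ranks (1-based), shared ranks averaged, via explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x, y):
    """Pearson correlation of the rank tables (handles ties by averaging)."""
    rx, ry = ranks_with_ties(list(x)), ranks_with_ties(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    denx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    deny = math.sqrt(sum((b - my) ** 2 for b in ry))
    if denx == 0 or deny == 0:
        return float("nan")
    return num / (denx * deny)


def kruskal_wallis_h(samples):
    """Tie-corrected Kruskal-Wallis H from the textbook formula."""
    pooled = [v for s in samples for v in s]
    n = len(pooled)
    ranks = ranks_with_ties(pooled)
    h = 0.0
    pos = 0
    for s in samples:
        r = ranks[pos:pos + len(s)]
        pos += len(s)
        h += (sum(r) ** 2) / len(s)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    correction = 1 - sum(t ** 3 - t for t in counts.values()) / (n ** 3 - n)
    if correction == 0:
        return 0.0
    return h / correction


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        candidate = pvals[i] * m / rank_from_top
        running_min = min(running_min, candidate)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def dbscan_labels(points, eps, min_pts):
    """DBSCAN by explicit reachability closure over core points.

    Core point: at least ``min_pts`` neighbours within eps including
    itself.  Border points join the first cluster (in index order of the
    seeding core point) that reaches them; unreachable points get -1.
    """
    n = len(points)

    def dist(i, j):
        return math.dist(points[i], points[j])

    neighbours = [[j for j in range(n) if dist(i, j) <= eps] for i in range(n)]
    core = [len(neighbours[i]) >= min_pts for i in range(n)]
    labels = [None] * n
    cluster = -1
    for i in range(n):
        if labels[i] is not None or not core[i]:
            continue
        cluster += 1
        frontier = [i]
        labels[i] = cluster
        while frontier:
            p = frontier.pop(0)
            if not core[p]:
                continue
            for q in neighbours[p]:
                if labels[q] is None:
                    labels[q] = cluster
                    frontier.append(q)
    return [l if l is not None else -1 for l in labels]


def nearest_other_cluster_km(dist_matrix, labels):
    """Per-site minimum distance to any site with a different label."""
    out = []
    for i, li in enumerate(labels):
        best = math.inf
        for j, lj in enumerate(labels):
            if lj != li:
                best = min(best, dist_matrix[i][j])
        out.append(best)
    return out


def altman_or_ci(a, b, c, d, z=1.959963984540054):
    """Log-scale Wald CI for a 2x2 odds ratio, 0.5 added if any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


def spearman_pairs(abundances, dist_matrix):
    """Decay rho for one MAG by explicit pair enumeration and rank tables."""
    idx = range(len(abundances))
    v1 = [abs(abundances[i] - abundances[j]) for i, j in combinations(idx, 2)]
    v2 = [dist_matrix[i][j] for i, j in combinations(idx, 2)]
    return spearman_rho(v1, v2)
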