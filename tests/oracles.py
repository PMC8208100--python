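"""Independent reference implementations used as test oracles.

These deliberately use the most transparent formulation available (full
enumeration, closed forms) and share no code with the package internals.
"""

import itertools
import math

import numpy as np


def brute_force_ward(x: np.ndarray) -> np.ndarray:
    """Greedy agglomeration by exhaustive SSE-increase enumeration.

    At each step every cluster pair's merge cost is computed from scratch
    via centroids (cost = sqrt(2 * delta-SSE), the convention in which a
    singleton pair's height equals its Euclidean distance); the cheapest
    pair merges.  Returns rows (id_a, id_b, height, size) with new clusters
    numbered n, n+1, ... as in the standard linkage encoding.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(members) > 1:
        best = None
        for a, b in itertools.combinations(sorted(members), 2):
            ca = x[members[a]].mean(axis=0)
            cb = x[members[b]].mean(axis=0)
            na, nb = len(members[a]), len(members[b])
            dsse = na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))
            h = math.sqrt(2.0 * dsse)
            if best is None or h < best[0] - 1e-12:
                best = (h, a, b)
        h, a, b = best
        merges.append((min(a, b), max(a, b), h, len(members[a]) + len(members[b])))
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return np.array(merges, dtype=float)


def pooled_t(a, b):
    """Two-sample pooled-variance t statistic, textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def oneway_f(groups):
    """One-way ANOVA F statistic as a variance ratio, textbook formula."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def pearson_chi2(table):
    """Pearson chi-square from first principles."""
    obs = np.asarray(table, float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def binary_henderson(lam_cation, lam_anion, c_pip, c_bath, rt_f_mv):
    """Closed-form junction potential of a single 1:1 salt dilution."""
    return (rt_f_mv * (lam_cation - lam_anion) / (lam_cation + lam_anion)
            * math.log(c_pip / c_bath))
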