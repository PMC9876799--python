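"""Brute-force reference implementations used only by the test suite.

Each oracle is written from the defining formula or by exhaustive
enumeration, independently of the package's production code paths.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


# ---------------------------------------------------------------- allelic

def allelic_status_oracle(mut_cns, total_cn, relations, minor_cn):
    """Transcription of the three-subgroup rules over integer inputs.

    ``mut_cns``: integer copy number per clonal non-synonymous mutation
    (indexed 0..k-1); ``relations``: {(i, j): 'cis'|'trans'|'unphaseable'};
    ``minor_cn``: minor allele copy number or None.
    Returns the biallelic class string.
    """
    k = len(mut_cns)
    loh = [cn >= total_cn or minor_cn == 0 for cn in mut_cns]

    if k == 1:
        return "biallelic" if loh[0] else "not_biallelic"

    # group mutations connected by cis relations (transitive closure)
    groups = [frozenset([i]) for i in range(k)]
    changed = True
    while changed:
        changed = False
        for ga, gb in combinations(groups, 2):
            if any(
                relations.get((min(i, j), max(i, j))) == "cis"
                for i in ga
                for j in gb
            ):
                groups.remove(ga)
                groups.remove(gb)
                groups.append(ga | gb)
                changed = True
                break
    # one representative per cis group: the largest copy number
    rep_cn = [max(mut_cns[i] for i in g) for g in groups]
    cn_sum = sum(rep_cn)

    # rule 1b: any mutation showing LOH
    if any(loh):
        return "biallelic"
    # rule 1a: representatives pairwise in trans and sum covers the gene
    cross_trans = []
    for ga, gb in combinations(groups, 2):
        cross_trans.append(
            any(
                relations.get((min(i, j), max(i, j))) == "trans"
                for i in ga
                for j in gb
            )
        )
    if len(groups) >= 2 and all(cross_trans) and cn_sum >= total_cn:
        return "biallelic"
    # rule 2: some pair unresolvable but the sum still covers the gene
    if cn_sum >= total_cn and not all(cross_trans):
        return "potentially_biallelic"
    # rule 3
    return "not_biallelic"


# ----------------------------------------------------------------- fisher

def fisher_two_sided_oracle(a, b, c, d):
    """Exact rational two-sided Fisher p by full hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 in (0, n) or col1 in (0, n):
        return Fraction(1)
    denom = comb(n, col1)
    probs = {}
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        probs[x] = Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)
    observed = probs[a]
    return min(Fraction(1), sum(p for p in probs.values() if p <= observed))


# --------------------------------------------------------------- wilcoxon

def wilcoxon_two_sided_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating every group assignment."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, n_x = len(pooled), len(x)
    sums = [
        sum(split) for split in combinations(range(1, n + 1), n_x)
    ]
    total = len(sums)
    lower = sum(1 for s in sums if s <= w_obs) / total
    upper = sum(1 for s in sums if s >= w_obs) / total
    return min(1.0, 2.0 * min(lower, upper))


# --------------------------------------------------------------------- BH

def benjamini_hochberg_oracle(p_values):
    """Direct-formula BH: q_i = min_{j: p_(j) >= p_(i)} min(1, p_(j)*m/j)."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        value = min(1.0, p[i] * m / (pos + 1))
        if pos < m - 1:
            value = min(value, q[order[pos + 1]])
        q[i] = value
    return q


# ----------------------------------------------------------------- logit

def irls_logistic_oracle(X, y, n_iter=100, tol=1e-12):
    """Plain Newton-Raphson/IRLS logistic fit; X includes the intercept."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ------------------------------------------------------------------ ward

def ward_merge_sequence_oracle(points):
    """Greedy Ward agglomeration by explicit ESS-increase minimization.

    Returns a list of (frozenset_of_leaves, height) in merge order, with
    heights on the same scale as scipy's ward linkage (sqrt(2 * dESS)).
    Ties break on the lexicographically smallest pair of cluster indices.
    """
    points = np.asarray(points, dtype=float)
    clusters = [
        {"leaves": frozenset([i]), "centroid": points[i].copy(), "size": 1}
        for i in range(len(points))
    ]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]
            d2 = float(np.sum((a["centroid"] - b["centroid"]) ** 2))
            d_ess = a["size"] * b["size"] / (a["size"] + b["size"]) * d2
            if best is None or d_ess < best[0] - 1e-12:
                best = (d_ess, i, j)
        d_ess, i, j = best
        a, b = clusters[i], clusters[j]
        size = a["size"] + b["size"]
        merged = {
            "leaves": a["leaves"] | b["leaves"],
            "centroid": (a["size"] * a["centroid"] + b["size"] * b["centroid"])
            / size,
            "size": size,
        }
        merges.append((merged["leaves"], float(np.sqrt(2.0 * d_ess))))
        clusters = [
            c for idx, c in enumerate(clusters) if idx not in (i, j)
        ] + [merged]
    return merges
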