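"""Independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import numpy as np


def ward_bruteforce_euclidean(X):
    """Greedy Ward agglomeration recomputing cluster variance sums explicitly.

    At each step every candidate pair's increase in within-cluster error sum
    of squares (ESS) is recomputed from the raw points; the pair with the
    smallest increase merges.  Heights are reported on the ward.D2 scale,
    ``h = sqrt(2 * dESS)``.  Returns a list of ``(frozenset(members), height)``
    in merge order.  O(N^4) — only for tiny N.
    """
    X = np.asarray(X, dtype=float)

    def ess(idx):
        P = X[list(idx)]
        return float(((P - P.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = ess(clusters[i] | clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, np.sqrt(2.0 * d)))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def ward_bruteforce_lw(D):
    """Greedy ward.D2 on an arbitrary dissimilarity matrix via the
    Lance-Williams recurrence applied to squared dissimilarities, heights
    reported unsquared.  Returns ``(frozenset(members), height)`` per merge."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    S = D.astype(float) ** 2
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                if best is None or S[a, b] < best[0]:
                    best = (S[a, b], a, b)
        s, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((merged, np.sqrt(s)))
        na, nb = sizes[a], sizes[b]
        Snew = np.full(S.shape[0] + 1, np.nan)
        S = np.pad(S, ((0, 1), (0, 1)), constant_values=np.nan)
        for w in active:
            if w in (a, b):
                continue
            nw = sizes[w]
            S[next_id, w] = S[w, next_id] = (
                (na + nw) * S[a, w] + (nb + nw) * S[b, w] - nw * S[a, b]
            ) / (na + nb + nw)
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return merges


def scipy_tree_to_merges(Z):
    """scipy linkage -> list of (frozenset(members), height) in merge order."""
    Z = np.asarray(Z)
    n = Z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, h, _) in enumerate(Z):
        m = members[int(a)] | members[int(b)]
        members[n + i] = m
        out.append((m, float(h)))
    return out


def bh_cutoff_by_hand(pvals, q):
    """Largest p(i) with p(i) <= i*q/m by direct scan."""
    ps = sorted(pvals)
    m = len(ps)
    cut = 0.0
    for i, p in enumerate(ps, start=1):
        if p <= i * q / m:
            cut = p
    return cut
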