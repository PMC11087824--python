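"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with ``cnvae``: the segmentation oracle
is an exhaustive dynamic program over all segmentations, and the sorting
and binning oracles are naive pairwise/group-by computations.
"""

import itertools

import numpy as np


def exhaustive_segmentation(track, penalty_cost, sigma):
    """Globally optimal changepoints by O(n^2) dynamic programming.

    Minimises  sum_seg SSE(seg) / sigma^2 + penalty_cost * n_breakpoints
    over all segmentations of the 1-D track.  Matches the likelihood-ratio
    acceptance rule of greedy binary segmentation when the greedy solution
    is globally optimal.
    """
    track = np.asarray(track, dtype=float)
    n = len(track)

    def sse(lo, hi):
        x = track[lo:hi]
        return float(((x - x.mean()) ** 2).sum()) / sigma ** 2

    best = np.full(n + 1, np.inf)
    back = np.zeros(n + 1, dtype=int)
    best[0] = -penalty_cost  # first segment carries no breakpoint cost
    for j in range(1, n + 1):
        for i in range(j):
            c = best[i] + penalty_cost + sse(i, j)
            if c < best[j]:
                best[j] = c
                back[j] = i
    bps = []
    j = n
    while j > 0:
        i = back[j]
        if i > 0:
            bps.append(i)
        j = i
    return sorted(bps)


def brute_force_sort(gene_ids, chroms, starts, chrom_order):
    """Expected gene order: lexicographic on (chromosome rank, start, id)."""
    rank = {c: i for i, c in enumerate(chrom_order)}
    rows = sorted(
        zip(gene_ids, chroms, starts),
        key=lambda r: (rank[r[1]], r[2], r[0]),
    )
    return [r[0] for r in rows]


def groupby_bin_means(X, bin_of_gene):
    """Naive per-bin mean over member genes for every cell."""
    X = np.asarray(X, dtype=float)
    bins = sorted(set(bin_of_gene))
    out = np.empty((X.shape[0], len(bins)))
    for j, b in enumerate(bins):
        cols = [g for g, bb in enumerate(bin_of_gene) if bb == b]
        out[:, j] = X[:, cols].mean(axis=1)
    return out


def single_changepoint_scan(track, sigma):
    """Best single split by exhaustive likelihood scan; returns (t, 2*delta_ll)."""
    track = np.asarray(track, dtype=float)
    n = len(track)

    def sse(x):
        return float(((x - x.mean()) ** 2).sum())

    base = sse(track)
    best_t, best_gain = None, -np.inf
    for t in range(1, n):
        gain = base - sse(track[:t]) - sse(track[t:])
        if gain > best_gain:
            best_t, best_gain = t, gain
    return best_t, best_gain / sigma ** 2


def all_segmentations_best(track, penalty_cost, sigma, max_bps=3):
    """Brute-force minimum over every breakpoint subset of size <= max_bps."""
    track = np.asarray(track, dtype=float)
    n = len(track)

    def cost(bps):
        bounds = [0] + list(bps) + [n]
        total = len(bps) * penalty_cost
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            x = track[lo:hi]
            total += float(((x - x.mean()) ** 2).sum()) / sigma ** 2
        return total

    best_bps, best_cost = (), cost(())
    for k in range(1, max_bps + 1):
        for bps in itertools.combinations(range(1, n), k):
            c = cost(bps)
            if c < best_cost:
                best_bps, best_cost = bps, c
    return list(best_bps)
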