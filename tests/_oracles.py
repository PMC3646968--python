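"""Brute-force oracles for the segmentation DP, independent of the package."""

import itertools


def all_segmentations(T, L_min):
    """Breakpoint tuples of every multi-segment partition of [1..T]."""
    out = []
    for r in range(1, T):
        for bps in itertools.combinations(range(1, T), r):
            edges = [0, *bps, T]
            if all(e1 - e0 >= L_min for e0, e1 in zip(edges, edges[1:])):
                out.append(bps)
    return out


def objective(weights, bps, T):
    edges = [0, *bps, T]
    segs = [(edges[j] + 1, edges[j + 1]) for j in range(len(edges) - 1)]
    return sum(
        weights[(segs[j][0], segs[j][1], segs[j + 1][1])]
        for j in range(len(segs) - 1)
    )


def penalty(bps, T, lam, criterion, K_max):
    k = len(bps) + 1
    if criterion == "count":
        return sum(lam * j / K_max for j in range(3, k + 1))
    if criterion == "length":
        edges = [0, *bps, T]
        lengths = [e1 - e0 for e0, e1 in zip(edges, edges[1:])]
        return sum(lam / length for length in lengths[2:])
    return 0.0


def best_segmentation(weights, T, L_min, lam=0.0, criterion="none", K_max=None):
    """Exhaustive optimum of F - penalty: (score, k, breakpoints, F)."""
    if K_max is None:
        K_max = T - 1
    best = None
    for bps in all_segmentations(T, L_min):
        if len(bps) > K_max:
            continue
        F = objective(weights, bps, T)
        cand = (F - penalty(bps, T, lam, criterion, K_max), len(bps) + 1, bps, F)
        if (
            best is None
            or cand[0] > best[0]
            or (cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2]))
        ):
            best = cand
    return best
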