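"""Independent oracles and small utilities shared across test modules.

Everything here is deliberately naive (enumeration / brute force) and
independent of the implementation paths it checks.
"""

import numpy as np

import spicoda as sp


def random_positive_table(rng, n, d):
    vals = np.exp(rng.normal(size=(n, d)))
    return sp.CompositionTable(
        [f"s{i}" for i in range(n)], [f"p{j}" for j in range(d)], vals
    )


def brute_force_ward_merges(points):
    """Greedy minimum-ESS-increase agglomeration, by exhaustive search.

    At every step evaluates the within-cluster sum-of-squares increase
    (nA*nB/(nA+nB)) * ||mean_A - mean_B||^2 for ALL cluster pairs and
    merges the cheapest. Returns the sequence of merged leaf sets.
    """
    points = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ia, ib = sorted(clusters[a]), sorted(clusters[b])
                ma = points[ia].mean(axis=0)
                mb = points[ib].mean(axis=0)
                na, nb = len(ia), len(ib)
                cost = na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], cost))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def merge_tree_leaf_sets(tree):
    """The sequence of (set_a, set_b) merged at each step of a MergeTree."""
    n = tree.n_leaves
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for t, (a, b, h, _) in enumerate(tree.merges):
        sa, sb = sets[int(a)], sets[int(b)]
        out.append((sa, sb, h))
        sets[n + t] = sa | sb
    return out


def quartiles_by_sorting(values):
    """Type-7 (linear interpolation) quartiles computed from first
    principles on the sorted sample."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return q(0.25), q(0.5), q(0.75)
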