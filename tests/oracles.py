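"""Independent test oracles.

Implemented separately from the package (different decompositions and
algorithms) so each dual-route check compares two genuinely distinct
computations: structure enumeration anchored at the RIGHTMOST position,
a memoized recursive forest-edit distance, and permutation-based Shapley
values with leaf-path expectations.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations

import numpy as np

_CANONICAL = {
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "U"): "GU", ("U", "G"): "GU",
}


def enumerate_structures(seq, model, constraint=None):
    """All valid (pair-set, energy) combos, built from the 3' end.

    Mirror decomposition of the package's 5'-anchored enumerator.
    """
    n = len(seq)
    c = constraint if constraint is not None else "." * n

    def pair_ok(i, j):
        t = _CANONICAL.get((seq[i], seq[j]))
        if t is None or j - i - 1 < model.min_hairpin:
            return False
        return c[i] in ".|<" and c[j] in ".|>"

    def unpaired_ok(i):
        return c[i] in ".x"

    def rec(i, j):
        if j < i:
            return [()]
        out = []
        if unpaired_ok(j):
            out.extend(rec(i, j - 1))
        for k in range(i, j):
            if pair_ok(k, j):
                for left in rec(i, k - 1):
                    for inner in rec(k + 1, j - 1):
                        out.append(left + inner + ((k, j),))
        return out

    results = []
    for pairs in rec(0, n - 1):
        energy = sum(
            model.pair_energies[_CANONICAL[(seq[i], seq[j])]] for i, j in pairs
        )
        results.append((frozenset(pairs), energy))
    return results


def boltzmann_summary(seq, model, constraint=None):
    """(Z, min energy, pair-probability dict, expected bp distance) by enumeration."""
    structures = enumerate_structures(seq, model, constraint)
    z = sum(math.exp(-e / model.kT) for _, e in structures)
    emin = min(e for _, e in structures)
    probs: dict = {}
    for pairs, e in structures:
        w = math.exp(-e / model.kT) / z
        for p in pairs:
            probs[p] = probs.get(p, 0.0) + w
    diversity = 2.0 * sum(p * (1.0 - p) for p in probs.values())
    return z, emin, probs, diversity


def _freeze(node):
    return (node.label, tuple(_freeze(c) for c in node.children))


def _size(t):
    return 1 + sum(_size(c) for c in t[1])


def forest_edit_distance(a, b):
    """Unit-cost ordered-forest edit distance, memoized recursion."""

    @lru_cache(maxsize=None)
    def fd(F, G):
        if not F and not G:
            return 0
        if not F:
            return sum(_size(g) for g in G)
        if not G:
            return sum(_size(f) for f in F)
        f, g = F[-1], G[-1]
        return min(
            fd(F[:-1] + f[1], G) + 1,
            fd(F, G[:-1] + g[1]) + 1,
            fd(f[1], g[1]) + fd(F[:-1], G[:-1]) + (f[0] != g[0]),
        )

    return fd((_freeze(a),), (_freeze(b),))


def leaf_path_expectation(tree, x, known):
    """E[tree | features in ``known`` fixed at x], by leaf-path enumeration."""
    cl, cr = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    value = tree.value[:, 0, 0]
    total = 0.0

    def walk(node, weight):
        nonlocal total
        if cl[node] == -1:
            total += weight * value[node]
            return
        f = feat[node]
        if f in known:
            nxt = cl[node] if x[f] <= thr[node] else cr[node]
            walk(nxt, weight)
        else:
            walk(cl[node], weight * cover[cl[node]] / cover[node])
            walk(cr[node], weight * cover[cr[node]] / cover[node])

    walk(0, 1.0)
    return total


def brute_shapley(tree, x):
    """Exact Shapley values of one tree by permutation averaging."""
    used = sorted(set(int(f) for f in tree.feature if f >= 0))
    phi = np.zeros(len(x))
    if not used:
        return phi
    perms = list(permutations(used))
    for perm in perms:
        known: set = set()
        before = leaf_path_expectation(tree, x, frozenset(known))
        for f in perm:
            known.add(f)
            after = leaf_path_expectation(tree, x, frozenset(known))
            phi[f] += after - before
            before = after
    return phi / len(perms)
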