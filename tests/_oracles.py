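"""Independent reference implementations used only to check the package.

These deliberately share no code with streampop: a quadratic pure-Python
Smith-Waterman, a path-metric random additive tree generator, and a
four-point-condition quartet oracle that derives tree topology directly
from a distance matrix.
"""

from __future__ import annotations

import itertools

import numpy as np


def sw_score(a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> float:
    """Exhaustive Smith-Waterman best local score, linear gap penalty."""
    best = 0.0
    prev = [0.0] * (len(b) + 1)
    for ca in a:
        cur = [0.0]
        for j, cb in enumerate(b):
            diag = prev[j] + (match if ca == cb else mismatch)
            v = max(0.0, diag, prev[j + 1] + gap, cur[j] + gap)
            cur.append(v)
            if v > best:
                best = v
        prev = cur
    return best


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree on t0..t{n-1} with uniform(0.1, 1.0) branch lengths.

    Returns (distance_matrix, taxa, true_splits) where true_splits is the
    set of non-trivial bipartitions, each canonicalized as the side NOT
    containing the lexicographically smallest taxon.
    """
    assert n_taxa in (4, 5)
    taxa = [f"t{i}" for i in range(n_taxa)]
    order = list(rng.permutation(n_taxa))
    a, b, c, d = (taxa[i] for i in order[:4])

    def bl():
        return float(rng.uniform(0.1, 1.0))

    # edge-weighted graph; internal vertices u, v (and w for 5 taxa)
    edges = {}

    def add(x, y):
        edges.setdefault(x, {})[y] = edges.setdefault(y, {})[x] = bl()

    if n_taxa == 4:
        add(a, "u"); add(b, "u"); add(c, "v"); add(d, "v"); add("u", "v")
        splits = [{a, b}]
    else:
        e = taxa[order[4]]
        add(a, "u"); add(b, "u"); add(c, "v"); add(d, "v")
        add("u", "w"); add("v", "w"); add(e, "w")
        splits = [{a, b}, {c, d}]

    def path_length(x, y):
        # DFS on the tiny tree
        stack = [(x, 0.0, None)]
        while stack:
            node, dist, parent = stack.pop()
            if node == y:
                return dist
            for nxt, w in edges[node].items():
                if nxt != parent:
                    stack.append((nxt, dist + w, node))
        raise AssertionError("disconnected tree")

    D = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        D[i, j] = D[j, i] = path_length(taxa[i], taxa[j])

    anchor = min(taxa)
    canonical = set()
    for s in splits:
        side = frozenset(s) if anchor not in s else frozenset(taxa) - frozenset(s)
        canonical.add(side)
    return D, taxa, canonical


def four_point_quartets(D: np.ndarray, taxa: list) -> dict:
    """Quartet topologies derived from the distance matrix alone.

    For each 4-subset the pairing with the smallest sum of opposite
    distances is the quartet's split (the four-point condition). Returns
    {frozenset(quartet): frozenset of one cherry pair}.
    """
    idx = {t: i for i, t in enumerate(taxa)}
    out = {}
    for quartet in itertools.combinations(taxa, 4):
        w, x, y, z = quartet
        sums = {
            frozenset((w, x)): D[idx[w], idx[x]] + D[idx[y], idx[z]],
            frozenset((w, y)): D[idx[w], idx[y]] + D[idx[x], idx[z]],
            frozenset((w, z)): D[idx[w], idx[z]] + D[idx[x], idx[y]],
        }
        pair = min(sums, key=lambda k: (sums[k], sorted(k)))
        out[frozenset(quartet)] = _canonical_pair(pair, frozenset(quartet))
    return out


def _canonical_pair(pair: frozenset, quartet: frozenset) -> frozenset:
    """The cherry side of a quartet split containing the smallest taxon."""
    return pair if min(quartet) in pair else quartet - pair


def quartets_from_splits(splits: set, taxa: list) -> dict:
    """Quartet topologies induced by a tree's bipartition set."""
    out = {}
    full = frozenset(taxa)
    for quartet in itertools.combinations(taxa, 4):
        q = frozenset(quartet)
        for side in splits:
            for half in (side, full - side):
                inside = q & half
                if len(inside) == 2:
                    out[q] = _canonical_pair(frozenset(inside), q)
                    break
            if q in out:
                break
    return out
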