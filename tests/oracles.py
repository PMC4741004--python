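"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's alignment path: plain-Python Gotoh
dynamic programming and naive counting.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def gotoh_global_score(
    a: str, b: str, score_fn, gap_open: float, gap_extend: float
) -> float:
    """Optimal global affine-gap score; a gap of length L costs
    gap_open + L * gap_extend."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - first, X[i - 1][j] - gap_extend, Y[i - 1][j] - first
            )
            Y[i][j] = max(
                M[i][j - 1] - first, Y[i][j - 1] - gap_extend, X[i][j - 1] - first
            )
    return float(max(M[n][m], X[n][m], Y[n][m]))


def dna_score_fn(match: float, mismatch: float):
    def fn(x, y):
        if x == "N" or y == "N":
            return mismatch
        return match if x == y else mismatch

    return fn


def blosum_score_fn(matrix):
    def fn(x, y):
        return float(matrix[x, y])

    return fn


def window_gc(seq: str) -> float:
    gc = sum(1 for c in seq if c in "GC")
    tot = sum(1 for c in seq if c in "ACGT")
    return gc / tot if tot else 0.0


def window_skew(seq: str) -> float:
    g = seq.count("G")
    c = seq.count("C")
    return (g - c) / (g + c) if g + c else 0.0


def pairwise_p_distance(row_a: str, row_b: str) -> float:
    """Mismatch fraction over columns where neither row has a gap."""
    total = mism = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        total += 1
        if x != y:
            mism += 1
    if total == 0:
        raise ValueError("no comparable sites")
    return mism / total


def random_additive_instance(rng, n_taxa, min_bl=0.05, max_bl=1.0):
    """Random binary tree with positive branch lengths.

    Returns (labels, D, true_bipartitions): the exact leaf-to-leaf distance
    matrix and the non-trivial bipartitions of the generating topology
    (canonicalized to the side not containing the smallest label).
    """
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    anchor = min(labels)

    def build(items):
        if len(items) == 1:
            return {"leaf": items[0]}
        k = int(rng.integers(1, len(items)))
        perm = [items[i] for i in rng.permutation(len(items))]
        return {"children": [build(perm[:k]), build(perm[k:])]}

    root = build(labels)
    D = {}
    bipartitions = set()

    def walk(node):
        """Returns {leaf: distance to this node}."""
        if "leaf" in node:
            return {node["leaf"]: 0.0}
        sub = []
        for child in node["children"]:
            dists = walk(child)
            bl = float(min_bl + (max_bl - min_bl) * rng.random())
            dists = {leaf: d + bl for leaf, d in dists.items()}
            side = frozenset(dists)
            if anchor in side:
                side = frozenset(set(labels) - side)
            if 2 <= len(side) <= n_taxa - 2:
                bipartitions.add(side)
            sub.append(dists)
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for la, da in sub[i].items():
                    for lb, db in sub[j].items():
                        D[(la, lb)] = D[(lb, la)] = da + db
        merged = {}
        for d in sub:
            merged.update(d)
        return merged

    walk(root)
    mat = np.zeros((n_taxa, n_taxa))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i != j:
                mat[i, j] = D[(la, lb)]
    return labels, mat, bipartitions


def tree_leaf_distances(tree):
    """Pairwise leaf distances induced by a genophys Tree (path lengths)."""
    idpaths = {}

    def walk(node, acc):
        path = acc + ((id(node), node.branch_length),)
        if node.is_leaf():
            idpaths[node.name] = path
        else:
            for child in node.children:
                walk(child, path)

    for child in tree.root.children:
        walk(child, ())
    out = {}
    leaves = sorted(idpaths)
    for i, la in enumerate(leaves):
        for j in range(i + 1, len(leaves)):
            lb = leaves[j]
            pa, pb = idpaths[la], idpaths[lb]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k][0] == pb[k][0]:
                k += 1
            dist = sum(x[1] for x in pa[k:]) + sum(x[1] for x in pb[k:])
            out[(la, lb)] = out[(lb, la)] = dist
    return out
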