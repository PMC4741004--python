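"""Distance matrices, neighbor-joining, bootstrap supports and marker
concatenation.

NJ follows the Saitou-Nei agglomeration with deterministic tie-breaking
(lexicographically smallest pair of cluster keys, where a cluster's key is its
smallest leaf label). Negative branch lengths are clamped to zero with the
deficit moved to the sister edge, so the pair's summed length is preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .align import align_dna, dna_aligner, run_alignment

GAP = "-"


@dataclass
class TreeNode:
    name: str = ""
    branch_length: float = 0.0
    support: Optional[int] = None
    children: List["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> Set[str]:
        if self.is_leaf():
            return {self.name}
        out: Set[str] = set()
        for c in self.children:
            out |= c.leaf_labels()
        return out


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]{},;:']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class Tree:
    """Unrooted tree stored as a trifurcating (or rooted) node structure."""

    root: TreeNode

    def leaves(self) -> Set[str]:
        return self.root.leaf_labels()

    def newick(self, with_supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{_quote(node.name)}:{node.branch_length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = str(int(node.support))
            return f"({inner}){label}:{node.branch_length:g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> Set[frozenset]:
        """Non-trivial bipartitions, canonicalized to the side not containing
        the lexicographically smallest leaf."""
        all_leaves = self.leaves()
        anchor = min(all_leaves)
        n = len(all_leaves)
        out: Set[frozenset] = set()

        def walk(node: TreeNode):
            for child in node.children:
                side = frozenset(child.leaf_labels())
                if anchor in side:
                    side = frozenset(all_leaves - side)
                if 2 <= len(side) <= n - 2:
                    out.add(side)
                walk(child)

        walk(self.root)
        return out

    def _internal_edges(self) -> List[Tuple[TreeNode, frozenset]]:
        all_leaves = self.leaves()
        anchor = min(all_leaves)
        n = len(all_leaves)
        edges = []

        def walk(node: TreeNode):
            for child in node.children:
                if not child.is_leaf():
                    side = frozenset(child.leaf_labels())
                    if anchor in side:
                        side = frozenset(all_leaves - side)
                    if 2 <= len(side) <= n - 2:
                        edges.append((child, side))
                walk(child)

        walk(self.root)
        return edges


@dataclass
class DistanceMatrix:
    labels: List[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal is not zero")


@dataclass
class MultipleAlignment:
    labels: List[str]
    rows: List[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]


def p_distance(
    aln: MultipleAlignment, gap_mode: str = "pairwise-delete"
) -> DistanceMatrix:
    """Mismatch fraction per pair; gap columns excluded per ``gap_mode``."""
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 rows")
    if gap_mode not in ("pairwise-delete", "complete-delete"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    gap_byte = ord(GAP)
    if gap_mode == "complete-delete":
        keep = np.ones(aln.n_columns, dtype=bool)
        for a in arrs:
            keep &= a != gap_byte
        arrs = [a[keep] for a in arrs]
    n = len(arrs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ai, aj = arrs[i], arrs[j]
            ok = (ai != gap_byte) & (aj != gap_byte)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable sites for pair ({aln.labels[i]}, {aln.labels[j]})"
                )
            mism = int(((ai != aj) & ok).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(list(aln.labels), d)


def jukes_cantor(D: DistanceMatrix) -> DistanceMatrix:
    p = D.matrix
    if np.any(p >= 0.75):
        raise ValueError("p-distance >= 0.75: Jukes-Cantor correction undefined")
    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(D.labels), d)


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices."""
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in D.labels]
    keys: List[str] = list(D.labels)  # smallest leaf label per cluster
    d = D.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break on the cluster keys
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                if q[ii, jj] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[active[ii]], keys[active[jj]])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining clusters
        new_row = np.zeros(d.shape[0] + 1)
        for kk in active:
            if kk in (i, j):
                continue
            new_row[kk] = 0.5 * (d[i, kk] + d[j, kk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # final 3-star: closed-form limb lengths
    i, j, k = active
    li = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    for idx, l in zip((i, j, k), (li, lj, lk)):
        nodes[idx].branch_length = l
    order = sorted((i, j, k), key=lambda x: keys[x])
    root = TreeNode(children=[nodes[x] for x in order])
    return Tree(root)


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise-delete",
) -> Tree:
    """NJ tree of the full alignment with bipartition supports (percent of
    column-resampled replicates containing each internal edge)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if aln.n_columns < 1:
        raise ValueError("alignment has no columns")
    full_tree = neighbor_joining(p_distance(aln, gap_mode))
    edges = full_tree._internal_edges()
    counts = {side: 0 for _, side in edges}
    rng = np.random.default_rng(seed)
    n_ok = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, aln.n_columns)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        try:
            rep_tree = neighbor_joining(
                p_distance(MultipleAlignment(list(aln.labels), rows), gap_mode)
            )
        except ValueError:
            continue
        n_ok += 1
        rep_biparts = rep_tree.bipartitions()
        for side in counts:
            if side in rep_biparts:
                counts[side] += 1
    if n_ok == 0:
        raise ValueError("all bootstrap replicates failed")
    for node, side in edges:
        node.support = int(round(100.0 * counts[side] / n_ok))
    return full_tree


def concatenate_alignments(
    blocks: Sequence[MultipleAlignment],
) -> Tuple[MultipleAlignment, List[Tuple[int, int]]]:
    """Row-wise concatenation matched by label; returns (alignment, block
    boundary list as half-open column intervals)."""
    if not blocks:
        raise ValueError("no alignment blocks")
    labels = sorted(blocks[0].labels)
    for bi, block in enumerate(blocks):
        missing = set(labels) ^ set(block.labels)
        if missing:
            raise ValueError(
                f"label(s) {sorted(missing)} missing or extra in block {bi}"
            )
    rows = []
    for lab in labels:
        rows.append("".join(block.row(lab) for block in blocks))
    boundaries = []
    pos = 0
    for block in blocks:
        boundaries.append((pos, pos + block.n_columns))
        pos += block.n_columns
    return MultipleAlignment(labels, rows), boundaries


def aai_dendrogram(dist: DistanceMatrix) -> Tree:
    """NJ dendrogram from an AAI distance matrix (100 - AAI)."""
    return neighbor_joining(dist)


def _kmer_set(seq: str, k: int) -> Set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def align_markers(
    labels: Sequence[str], sequences: Sequence[str], k: int = 6
) -> MultipleAlignment:
    """Center-star multiple alignment for small marker sets.

    The center sequence minimizes the summed k-mer distance to the others;
    every other sequence is pairwise-aligned to it and gap columns are merged.
    Not a ClustalO replacement; adequate for near-identical marker genes.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ksets = [_kmer_set(s, k) for s in sequences]
    n = len(sequences)
    dist_sum = []
    for i in range(n):
        tot = 0.0
        for j in range(n):
            if i == j:
                continue
            inter = len(ksets[i] & ksets[j])
            union = len(ksets[i] | ksets[j]) or 1
            tot += 1.0 - inter / union
        dist_sum.append(tot)
    center = int(np.argmin(dist_sum))
    aligner = dna_aligner(mode="global")

    def gapped_pair(blocks, seq_t: str, seq_q: str) -> Tuple[str, str]:
        """Expand aligned blocks into two gapped strings."""
        bt, bq = blocks
        gt, gq = [], []
        prev_t, prev_q = 0, 0
        for (ts, te), (qs, qe) in zip(bt, bq):
            gt.append(seq_t[prev_t:ts] + GAP * (qs - prev_q))
            gq.append(GAP * (ts - prev_t) + seq_q[prev_q:qs])
            gt.append(seq_t[ts:te])
            gq.append(seq_q[qs:qe])
            prev_t, prev_q = te, qe
        gt.append(seq_t[prev_t:] + GAP * (len(seq_q) - prev_q))
        gq.append(GAP * (len(seq_t) - prev_t) + seq_q[prev_q:])
        return "".join(gt), "".join(gq)

    # rows of the growing MSA, keyed by sequence index; the center row defines
    # the merge coordinate system
    msa: Dict[int, List[str]] = {center: list(sequences[center])}
    center_row = msa[center]

    for idx in range(n):
        if idx == center:
            continue
        _, blocks = run_alignment(aligner, sequences[center], sequences[idx], wildcard="N")
        pc, po = gapped_pair(blocks, sequences[center], sequences[idx])
        merged: Dict[int, List[str]] = {key: [] for key in msa}
        new_row: List[str] = []
        i = j = 0
        while i < len(center_row) or j < len(pc):
            if i < len(center_row) and center_row[i] == GAP:
                for key in msa:
                    merged[key].append(msa[key][i])
                new_row.append(GAP)
                i += 1
            elif j < len(pc) and pc[j] == GAP:
                for key in msa:
                    merged[key].append(GAP)
                new_row.append(po[j])
                j += 1
            else:
                for key in msa:
                    merged[key].append(msa[key][i])
                new_row.append(po[j])
                i += 1
                j += 1
        msa = merged
        msa[idx] = new_row
        center_row = msa[center]

    out_rows = ["".join(msa[i]) for i in range(n)]
    return MultipleAlignment(list(labels), out_rows)
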