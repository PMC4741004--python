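"""All-vs-all proteome comparison: filtered hits, reciprocal best hits, AAI,
single-linkage gene families, pan/core accumulation and exclusive genes.

Hits are kept only above the identity/coverage thresholds (defaults 30 % / 70 %,
coverage measured on the longer protein). "Best hit" means best alignment
score, with ties broken by higher identity and then lexicographic subject id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .align import protein_aligner, run_alignment
from .io import ProteinRecord


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    identity_pct: float
    coverage_longer_pct: float
    score: float


@dataclass(frozen=True)
class RbhPair:
    protein_a: str
    protein_b: str
    identity_pct: float


@dataclass(frozen=True)
class AaiResult:
    genome_a: str
    genome_b: str
    aai_pct: float  # nan when no RBH pair exists
    n_rbh: int


@dataclass(frozen=True)
class GeneFamily:
    family_id: int
    members: frozenset  # of (genome_id, protein_id)

    def genomes(self) -> Set[str]:
        return {g for g, _ in self.members}


@dataclass
class PanCoreCurve:
    genome_order: List[str]
    core_counts: List[int]
    pan_counts: List[int]


def _pair_stats(
    aligner, a: ProteinRecord, b: ProteinRecord
) -> Tuple[float, float, float]:
    """(identity, coverage-on-longer, score) for one unordered protein pair."""
    result, blocks = run_alignment(aligner, a.sequence, b.sequence)
    longer_cov = (
        result.subject_coverage_pct
        if a.length >= b.length
        else result.query_coverage_pct
    )
    return result.identity_pct, longer_cov, result.score


def filtered_hits(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    id_threshold_pct: float = 30.0,
    cov_threshold_pct: float = 70.0,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> List[HitRecord]:
    """A->B hit table after the identity and longer-protein coverage filters."""
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    aligner = protein_aligner(matrix, gap_open, gap_extend)
    hits = []
    for qa in proteome_a:
        for sb in proteome_b:
            identity, cov, score = _pair_stats(aligner, sb, qa)
            if identity >= id_threshold_pct and cov >= cov_threshold_pct:
                hits.append(HitRecord(qa.id, sb.id, identity, cov, score))
    return hits


def _best_by_query(hits: Iterable[HitRecord]) -> Dict[str, HitRecord]:
    best: Dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if (
            cur is None
            or h.score > cur.score
            or (h.score == cur.score and h.identity_pct > cur.identity_pct)
            or (
                h.score == cur.score
                and h.identity_pct == cur.identity_pct
                and h.subject_id < cur.subject_id
            )
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord], hits_ba: Sequence[HitRecord]
) -> List[RbhPair]:
    """Mutually-best pairs from the two directional hit tables."""
    best_ab = _best_by_query(hits_ab)
    best_ba = _best_by_query(hits_ba)
    pairs = []
    for a_id, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == a_id:
            pairs.append(RbhPair(a_id, hit.subject_id, hit.identity_pct))
    return pairs


def _all_pair_hits(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    id_threshold_pct: float,
    cov_threshold_pct: float,
    matrix: str = "BLOSUM62",
) -> Tuple[List[HitRecord], List[HitRecord]]:
    """Both directional tables from a single pass over unordered pairs
    (global alignment is symmetric, so identity/coverage/score are shared)."""
    aligner = protein_aligner(matrix)
    ab, ba = [], []
    for qa in proteome_a:
        for sb in proteome_b:
            identity, cov, score = _pair_stats(aligner, sb, qa)
            if identity >= id_threshold_pct and cov >= cov_threshold_pct:
                ab.append(HitRecord(qa.id, sb.id, identity, cov, score))
                ba.append(HitRecord(sb.id, qa.id, identity, cov, score))
    return ab, ba


def compute_aai(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    id_threshold_pct: float = 30.0,
    cov_threshold_pct: float = 70.0,
) -> AaiResult:
    """Mean reciprocal-best-hit identity between two proteomes."""
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    ga = proteome_a[0].genome_id
    gb = proteome_b[0].genome_id
    ab, ba = _all_pair_hits(proteome_a, proteome_b, id_threshold_pct, cov_threshold_pct)
    pairs = reciprocal_best_hits(ab, ba)
    aai = float(np.mean([p.identity_pct for p in pairs])) if pairs else math.nan
    return AaiResult(ga, gb, aai, len(pairs))


def aai_matrix_and_distance(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    id_threshold_pct: float = 30.0,
    cov_threshold_pct: float = 70.0,
) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Symmetric AAI matrix (diagonal 100) and distance matrix (100 - AAI)."""
    labels = list(proteomes)
    if len(labels) < 2:
        raise ValueError("need at least 2 proteomes")
    n = len(labels)
    aai = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = compute_aai(
                proteomes[labels[i]], proteomes[labels[j]],
                id_threshold_pct, cov_threshold_pct,
            )
            if math.isnan(res.aai_pct):
                raise ValueError(
                    f"AAI undefined for pair ({labels[i]}, {labels[j]}): no RBH"
                )
            aai[i, j] = aai[j, i] = res.aai_pct
    dist = 100.0 - aai
    np.fill_diagonal(dist, 0.0)
    return labels, aai, dist


class _UnionFind:
    def __init__(self):
        self.parent: Dict = {}

    def add(self, x):
        self.parent.setdefault(x, x)

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def build_gene_families(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    id_threshold_pct: float = 30.0,
    cov_threshold_pct: float = 70.0,
) -> List[GeneFamily]:
    """Single-linkage connected components of the passing-hit graph.

    Within-genome comparisons participate, so paralogs collapse into one
    family. Families partition the union of all proteomes; family ids are
    assigned deterministically by sorted smallest member.
    """
    if not proteomes:
        raise ValueError("need at least 1 proteome")
    uf = _UnionFind()
    for gid, prots in proteomes.items():
        for p in prots:
            uf.add((gid, p.id))
    genome_ids = list(proteomes)
    for i, ga in enumerate(genome_ids):
        for gb in genome_ids[i:]:
            pa, pb = proteomes[ga], proteomes[gb]
            if ga == gb:
                aligner = protein_aligner()
                for x in range(len(pa)):
                    for y in range(x + 1, len(pa)):
                        identity, cov, _ = _pair_stats(aligner, pa[x], pa[y])
                        if identity >= id_threshold_pct and cov >= cov_threshold_pct:
                            uf.union((ga, pa[x].id), (ga, pa[y].id))
            else:
                ab, _ = _all_pair_hits(pa, pb, id_threshold_pct, cov_threshold_pct)
                for h in ab:
                    uf.union((ga, h.query_id), (gb, h.subject_id))
    comps: Dict = {}
    for node in uf.parent:
        comps.setdefault(uf.find(node), set()).add(node)
    families = []
    for fid, members in enumerate(sorted(comps.values(), key=lambda s: min(s))):
        families.append(GeneFamily(fid, frozenset(members)))
    return families


def pan_core_curve(
    families: Sequence[GeneFamily], genome_order: Sequence[str]
) -> PanCoreCurve:
    """Core/pan family counts as genomes are added in the given order."""
    all_genomes = set()
    for f in families:
        all_genomes |= f.genomes()
    unknown = [g for g in genome_order if g not in all_genomes]
    if unknown:
        raise ValueError(f"unknown genome(s) in order: {unknown}")
    if len(set(genome_order)) != len(genome_order):
        raise ValueError("genome_order contains duplicates")
    core_counts, pan_counts = [], []
    seen: Set[str] = set()
    fam_genomes = [f.genomes() for f in families]
    for g in genome_order:
        seen.add(g)
        pan_counts.append(sum(1 for fg in fam_genomes if fg & seen))
        core_counts.append(sum(1 for fg in fam_genomes if seen <= fg))
    return PanCoreCurve(list(genome_order), core_counts, pan_counts)


def exclusive_genes(
    families: Sequence[GeneFamily], focal_genome: str
) -> Set[str]:
    """Protein ids of the focal genome whose family touches no other genome."""
    all_genomes = set()
    for f in families:
        all_genomes |= f.genomes()
    if focal_genome not in all_genomes:
        raise ValueError(f"unknown focal genome {focal_genome!r}")
    out: Set[str] = set()
    for f in families:
        if f.genomes() == {focal_genome}:
            out |= {pid for _, pid in f.members}
    return out
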