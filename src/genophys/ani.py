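"""Fragment-based average nucleotide identity with directional aligned fraction.

The query genome is cut into consecutive windows (default 1020 bp); each
fragment is located on the reference with a seeded k-mer prefilter and then
glocal-aligned (terminal gaps of the reference window free) on the better
strand. Fragments passing the identity/alignable filters contribute to the
ANI mean; the aligned fraction is the share of the query genome covered by
passing fragments and is therefore directional.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import dna_aligner, run_alignment
from .io import GenomeRecord

logger = logging.getLogger("genophys.ani")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class AniResult:
    query_id: str
    ref_id: str
    ani_pct: float  # nan when no fragment passes
    aligned_fraction_pct: float
    n_fragments_used: int
    n_fragments_total: int


@dataclass(frozen=True)
class SimilarRegion:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity_pct: float

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


@dataclass
class AniMatrix:
    labels: List[str]
    ani: np.ndarray      # row = query
    aligned: np.ndarray  # directional aligned fraction of the row genome


def fragment_genome(
    genome: GenomeRecord, frag_len: int = 1020, step: Optional[int] = None
) -> List[Fragment]:
    """Tile the genome into windows; the terminal remainder is discarded."""
    if frag_len < 100:
        raise ValueError("frag_len must be >= 100")
    step = frag_len if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    L = genome.length
    if L < frag_len:
        logger.warning(
            "genome %s (%d bp) shorter than fragment length %d: no fragments",
            genome.id, L, frag_len,
        )
        return []
    frags = []
    for start in range(0, L - frag_len + 1, step):
        frags.append(Fragment(start, start + frag_len, genome.sequence[start : start + frag_len]))
    return frags


class KmerIndex:
    """Exact k-mer position index over both the sequence as given."""

    def __init__(self, sequence: str, k: int = 12):
        self.k = k
        self.length = len(sequence)
        index: Dict[str, List[int]] = defaultdict(list)
        for i in range(len(sequence) - k + 1):
            kmer = sequence[i : i + k]
            if "N" not in kmer:
                index[kmer].append(i)
        self.index = dict(index)

    def candidate_offset(self, fragment: str, bucket: int = 100) -> Tuple[Optional[int], int]:
        """Most-voted diagonal offset (ref_pos - frag_pos) and its vote count."""
        votes: Counter = Counter()
        k = self.k
        for i in range(0, len(fragment) - k + 1):
            for pos in self.index.get(fragment[i : i + k], ()):
                votes[(pos - i) // bucket] += 1
        if not votes:
            return None, 0
        # deterministic: most votes, then lowest offset bucket
        best_bucket, n = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        return best_bucket * bucket, n


@dataclass(frozen=True)
class FragmentHit:
    identity_pct: float
    alignable_pct: float  # aligned span of the fragment / fragment length
    ref_start: int
    ref_end: int
    strand: str
    score: float


def _align_fragment_to_window(
    aligner, fragment: str, ref_seq: str, offset: int, margin: int
) -> Optional[Tuple[float, float, int, int, float]]:
    lo = max(0, offset - margin)
    hi = min(len(ref_seq), offset + len(fragment) + margin)
    window = ref_seq[lo:hi]
    if not window:
        return None
    result, blocks = run_alignment(aligner, window, fragment, wildcard="N")
    bt, _ = blocks
    if len(bt) == 0:
        return None
    ref_start = lo + int(bt[0][0])
    ref_end = lo + int(bt[-1][1])
    return result.identity_pct, result.query_coverage_pct, ref_start, ref_end, result.score


def best_fragment_hit(
    fragment: Fragment,
    ref_seq: str,
    index: KmerIndex,
    aligner,
    min_votes: int = 5,
    margin: int = 120,
) -> Optional[FragmentHit]:
    """Locate and glocal-align a fragment on the better strand of the reference.

    A minus-strand match means the reverse complement of the fragment matches
    the forward reference, so both searches run against the same index.
    """
    candidates = []
    off_f, votes_f = index.candidate_offset(fragment.sequence)
    if votes_f >= min_votes:
        candidates.append(("+", fragment.sequence, off_f))
    rc = revcomp(fragment.sequence)
    off_r, votes_r = index.candidate_offset(rc)
    if votes_r >= min_votes:
        candidates.append(("-", rc, off_r))
    best: Optional[FragmentHit] = None
    for strand, seq, offset in candidates:
        got = _align_fragment_to_window(aligner, seq, ref_seq, offset, margin)
        if got is None:
            continue
        identity, alignable, rs, re_, score = got
        hit = FragmentHit(identity, alignable, rs, re_, strand, score)
        if (
            best is None
            or hit.identity_pct > best.identity_pct
            or (hit.identity_pct == best.identity_pct and hit.ref_start < best.ref_start)
        ):
            best = hit
    return best


def _build_index(ref: GenomeRecord, k: int = 12) -> KmerIndex:
    return KmerIndex(ref.sequence, k)


def compute_ani(
    query: GenomeRecord,
    ref: GenomeRecord,
    frag_len: int = 1020,
    min_frag_identity_pct: float = 30.0,
    min_frag_alignable_pct: float = 70.0,
    k: int = 12,
    min_votes: int = 5,
    _index: Optional[KmerIndex] = None,
) -> AniResult:
    """Fragment-based ANI of ``query`` against ``ref`` (directional)."""
    if not query.sequence or not ref.sequence:
        raise ValueError("genomes must be non-empty")
    fragments = fragment_genome(query, frag_len)
    index = _index if _index is not None else _build_index(ref, k)
    aligner = dna_aligner(mode="glocal", free_end_side="target")
    identities = []
    used_bases = 0
    for frag in fragments:
        hit = best_fragment_hit(frag, ref.sequence, index, aligner, min_votes)
        if hit is None:
            continue
        if (
            hit.identity_pct >= min_frag_identity_pct
            and hit.alignable_pct >= min_frag_alignable_pct
        ):
            identities.append(hit.identity_pct)
            used_bases += frag.end - frag.start
    n_used = len(identities)
    ani = float(np.mean(identities)) if n_used else math.nan
    return AniResult(
        query_id=query.id,
        ref_id=ref.id,
        ani_pct=ani,
        aligned_fraction_pct=100.0 * used_bases / query.length,
        n_fragments_used=n_used,
        n_fragments_total=len(fragments),
    )


def ani_matrix(genomes: Sequence[GenomeRecord], **kwargs) -> AniMatrix:
    """All ordered pairs; diagonal left as nan."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    n = len(genomes)
    ani = np.full((n, n), np.nan)
    aligned = np.full((n, n), np.nan)
    for j, ref in enumerate(genomes):
        index = _build_index(ref, kwargs.get("k", 12))
        for i, query in enumerate(genomes):
            if i == j:
                continue
            res = compute_ani(query, ref, _index=index, **kwargs)
            ani[i, j] = res.ani_pct
            aligned[i, j] = res.aligned_fraction_pct
    return AniMatrix(ids, ani, aligned)


@dataclass(frozen=True)
class SpeciesCall:
    same_species: bool
    borderline: bool


def classify_species(
    ani_pct: float, low_pct: float = 95.0, high_pct: float = 96.0
) -> SpeciesCall:
    """Species-boundary call with a borderline band (default 95-96 %)."""
    if not (0.0 <= ani_pct <= 100.0):
        raise ValueError("ANI must be in [0, 100]")
    if ani_pct < low_pct:
        return SpeciesCall(same_species=False, borderline=False)
    if ani_pct > high_pct:
        return SpeciesCall(same_species=True, borderline=False)
    return SpeciesCall(same_species=False, borderline=True)


def find_high_identity_regions(
    a: GenomeRecord,
    b: GenomeRecord,
    min_identity_pct: float = 90.0,
    min_len: int = 2000,
    merge_gap: int = 0,
    frag_len: int = 1020,
    k: int = 12,
    min_votes: int = 5,
) -> List[SimilarRegion]:
    """Maximal runs of consecutive high-identity fragments of ``a`` on ``b``.

    Passing fragments separated by at most ``merge_gap`` bp on ``a`` are merged
    into one region; regions shorter than ``min_len`` are dropped.
    """
    if min_len < 500:
        raise ValueError("min_len must be >= 500")
    fragments = fragment_genome(a, frag_len)
    index = _build_index(b, k)
    aligner = dna_aligner(mode="glocal", free_end_side="target")
    passing: List[Tuple[Fragment, FragmentHit]] = []
    for frag in fragments:
        hit = best_fragment_hit(frag, b.sequence, index, aligner, min_votes)
        if hit is not None and hit.identity_pct >= min_identity_pct:
            passing.append((frag, hit))
    regions: List[SimilarRegion] = []
    run: List[Tuple[Fragment, FragmentHit]] = []

    def flush():
        if not run:
            return
        a_start = run[0][0].start
        a_end = run[-1][0].end
        b_start = min(h.ref_start for _, h in run)
        b_end = max(h.ref_end for _, h in run)
        identity = float(np.mean([h.identity_pct for _, h in run]))
        if a_end - a_start >= min_len:
            regions.append(SimilarRegion(a_start, a_end, b_start, b_end, identity))

    for frag, hit in passing:
        if run and frag.start - run[-1][0].end > merge_gap:
            flush()
            run = []
        run.append((frag, hit))
    flush()
    return regions
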