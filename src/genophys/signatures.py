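"""Window-based composition signatures and hemE-anchored oriC prediction.

GC content excludes N from numerator and denominator. Dinucleotide relative
abundances are counted on both strands (sequence plus reverse complement), so
the bias statistic is invariant to reverse complementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import protein_aligner, run_alignment
from .ani import revcomp
from .io import GenomeRecord, ProteinRecord

logger = logging.getLogger("genophys.signatures")

DNAA_BOX_CONSENSUS = "TTATCCACA"  # E. coli 9-mer

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

CODON_TABLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def translate(cds: str) -> str:
    """Translate a CDS, stopping at the first stop codon; unknowns become X."""
    out = []
    for i in range(0, len(cds) - 2, 3):
        aa = CODON_TABLE.get(cds[i : i + 3], "X")
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


@dataclass
class WindowProfile:
    genome_id: str
    window: int
    step: int
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    flags: Optional[np.ndarray] = None  # per-window boolean annotations


@dataclass(frozen=True)
class CompositionAnomaly:
    start: int
    end: int
    delta_star: float
    flagged: bool


@dataclass(frozen=True)
class DnaABoxHit:
    position: int
    strand: str
    mismatches: int
    matched_sequence: str


@dataclass(frozen=True)
class DuePrediction:
    start: int
    end: int
    at_fraction: float


@dataclass
class OriCPrediction:
    intergenic_start: int
    intergenic_end: int
    boxes: List[DnaABoxHit]
    due: Optional[DuePrediction]
    heme_start: int
    heme_end: int
    heme_strand: str
    heme_identity_pct: float


def _window_coords(L: int, window: int, step: int) -> Tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, L - window + 1, step)
    return starts, starts + window


def _base_arrays(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def gc_profile(genome: GenomeRecord, window: int, step: Optional[int] = None) -> WindowProfile:
    """(G+C)/(A+C+G+T) per window; windows with only N report 0 with a flag."""
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    L = genome.length
    if window > L:
        logger.warning("window %d > genome length %d: using one whole-genome window", window, L)
        window = L
    arr = _base_arrays(genome.sequence)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    is_acgt = (arr != ord("N")).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    ca = np.concatenate([[0], np.cumsum(is_acgt)])
    starts, ends = _window_coords(L, window, step)
    gc = cg[ends] - cg[starts]
    tot = ca[ends] - ca[starts]
    flags = tot == 0
    values = np.where(flags, 0.0, gc / np.where(tot == 0, 1, tot))
    return WindowProfile(genome.id, window, step, starts, ends, values, flags)


def gc_skew_profile(genome: GenomeRecord, window: int, step: Optional[int] = None) -> WindowProfile:
    """(G-C)/(G+C) per window; windows with G+C = 0 report 0 with a flag."""
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    L = genome.length
    if window > L:
        logger.warning("window %d > genome length %d: using one whole-genome window", window, L)
        window = L
    arr = _base_arrays(genome.sequence)
    cg = np.concatenate([[0], np.cumsum((arr == ord("G")).astype(np.int64))])
    cc = np.concatenate([[0], np.cumsum((arr == ord("C")).astype(np.int64))])
    starts, ends = _window_coords(L, window, step)
    g = cg[ends] - cg[starts]
    c = cc[ends] - cc[starts]
    tot = g + c
    flags = tot == 0
    values = np.where(flags, 0.0, (g - c) / np.where(tot == 0, 1, tot))
    return WindowProfile(genome.id, window, step, starts, ends, values, flags)


def _dinuc_rho(seq: str) -> np.ndarray:
    """16 dinucleotide relative abundances rho(xy) = f(xy) / (f(x) f(y)),
    counted on both strands; N-containing positions are skipped."""
    counts = np.zeros((4, 4))
    mono = np.zeros(4)
    for s in (seq, revcomp(seq)):
        arr = np.array([_CODE.get(ch, -1) for ch in s], dtype=np.int64)
        ok = arr >= 0
        mono += np.bincount(arr[ok], minlength=4)
        a, b = arr[:-1], arr[1:]
        good = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[good], b[good]), 1)
    if counts.sum() == 0 or mono.sum() == 0:
        return np.ones(16)
    f_xy = counts / counts.sum()
    f_x = mono / mono.sum()
    denom = np.outer(f_x, f_x)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, f_xy / denom, 1.0)
    return rho.ravel()


def dinucleotide_bias_scan(
    genome: GenomeRecord,
    window: int = 10000,
    step: int = 5000,
    threshold: float = 0.1,
) -> List[CompositionAnomaly]:
    """delta* = mean |rho_window - rho_genome| over the 16 dinucleotides;
    contiguous flagged windows are merged into anomalies."""
    if window < 1000:
        raise ValueError("window must be >= 1000")
    L = genome.length
    if window > L:
        window = L
    rho_genome = _dinuc_rho(genome.sequence)
    starts, ends = _window_coords(L, window, step)
    anomalies: List[CompositionAnomaly] = []
    run: List[Tuple[int, int, float]] = []

    def flush():
        if run:
            anomalies.append(
                CompositionAnomaly(
                    run[0][0], run[-1][1], float(np.mean([d for _, _, d in run])), True
                )
            )

    for s, e in zip(starts, ends):
        rho_w = _dinuc_rho(genome.sequence[s:e])
        delta = float(np.mean(np.abs(rho_w - rho_genome)))
        if delta > threshold:
            if run and s > run[-1][1]:
                flush()
                run = []
            run.append((int(s), int(e), delta))
        else:
            flush()
            run = []
    flush()
    return anomalies


def scan_dnaa_boxes(
    sequence: str,
    region_start: int = 0,
    consensus: str = DNAA_BOX_CONSENSUS,
    max_mismatches: int = 1,
) -> List[DnaABoxHit]:
    """Scan both strands for 9-mers within ``max_mismatches`` of the consensus.

    Positions are forward-strand coordinates of the 9-mer start, offset by
    ``region_start``.
    """
    k = len(consensus)
    hits: List[DnaABoxHit] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        if len(seq) < k:
            continue
        arr = _base_arrays(seq)
        cons = _base_arrays(consensus)
        n_pos = len(seq) - k + 1
        mism = np.zeros(n_pos, dtype=np.int64)
        for off in range(k):
            mism += arr[off : off + n_pos] != cons[off]
        for i in np.nonzero(mism <= max_mismatches)[0]:
            pos = int(i) if strand == "+" else len(sequence) - int(i) - k
            hits.append(
                DnaABoxHit(
                    position=region_start + pos,
                    strand=strand,
                    mismatches=int(mism[i]),
                    matched_sequence=seq[int(i) : int(i) + k],
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def find_due(
    sequence: str,
    region_start: int = 0,
    due_window: int = 50,
    due_at_min: float = 0.7,
) -> Optional[DuePrediction]:
    """First AT-rich stretch: the earliest window of ``due_window`` bp with AT
    fraction >= ``due_at_min``, extended right while the threshold holds."""
    arr = _base_arrays(sequence)
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
    if len(sequence) < due_window:
        return None
    c = np.concatenate([[0], np.cumsum(is_at)])
    for s in range(0, len(sequence) - due_window + 1):
        e = s + due_window
        if (c[e] - c[s]) / due_window >= due_at_min:
            while e < len(sequence) and (c[e + 1] - c[s]) / (e + 1 - s) >= due_at_min:
                e += 1
            frac = (c[e] - c[s]) / (e - s)
            return DuePrediction(region_start + s, region_start + e, float(frac))
    return None


def locate_protein_in_genome(
    genome: GenomeRecord,
    query: ProteinRecord,
    min_identity_pct: float = 40.0,
    seed_k: int = 5,
) -> Tuple[int, int, str, float]:
    """Six-frame scan for the best homolog of a protein query.

    Returns (start, end, strand, identity_pct) in genome coordinates. Seeding
    uses exact protein k-mers; the best-seeded frame region is then aligned
    glocally. Raises if nothing reaches ``min_identity_pct``.
    """
    qk = {query.sequence[i : i + seed_k]: i for i in range(len(query.sequence) - seed_k + 1)}
    aligner = protein_aligner(free_end_gaps=True)
    best = None  # (score, identity, start, end, strand)
    for strand, seq in (("+", genome.sequence), ("-", revcomp(genome.sequence))):
        for frame in range(3):
            prot = translate_through(seq[frame:])
            votes: Dict[int, int] = {}
            for i in range(len(prot) - seed_k + 1):
                j = qk.get(prot[i : i + seed_k])
                if j is not None:
                    off = (i - j) // 50
                    votes[off] = votes.get(off, 0) + 1
            if not votes or max(votes.values()) < 3:
                continue
            off = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0] * 50
            lo = max(0, off - 30)
            hi = min(len(prot), off + 50 + len(query.sequence) + 30)
            window = prot[lo:hi]
            if not window:
                continue
            result, blocks = run_alignment(aligner, window, query.sequence)
            bt, _ = blocks
            if len(bt) == 0:
                continue
            aa_start = lo + int(bt[0][0])
            aa_end = lo + int(bt[-1][1])
            nt_start = frame + 3 * aa_start
            nt_end = frame + 3 * aa_end
            if strand == "-":
                nt_start, nt_end = genome.length - nt_end, genome.length - nt_start
            cand = (result.score, result.identity_pct, nt_start, nt_end, strand)
            if best is None or cand[0] > best[0]:
                best = cand
    if best is None or best[1] < min_identity_pct:
        got = 0.0 if best is None else best[1]
        raise ValueError(
            f"no homolog of {query.id!r} found in {genome.id!r} "
            f"(best identity {got:.1f} % < {min_identity_pct} %)"
        )
    _, identity, start, end, strand = best
    return start, end, strand, identity


def translate_through(seq: str) -> str:
    """Frame translation that renders stop codons as '*' (for scanning)."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def find_oric(
    genome: GenomeRecord,
    heme_query: ProteinRecord,
    heme_location: Optional[Tuple[int, int, str]] = None,
    consensus: str = DNAA_BOX_CONSENSUS,
    max_mismatches: int = 1,
    flank: int = 1000,
    due_window: int = 50,
    due_at_min: float = 0.7,
    min_heme_identity_pct: float = 40.0,
) -> OriCPrediction:
    """Predict the replication origin as the intergenic interval upstream of
    the hemE homolog, reporting DnaA boxes and a duplex-unwinding element.

    ``heme_location`` (start, end, strand) skips the six-frame scan when gene
    coordinates are already known.
    """
    if heme_location is not None:
        h_start, h_end, h_strand = heme_location
        identity = 100.0
    else:
        h_start, h_end, h_strand, identity = locate_protein_in_genome(
            genome, heme_query, min_heme_identity_pct
        )
    if h_strand == "+":
        ig_start, ig_end = max(0, h_start - flank), h_start
    else:
        ig_start, ig_end = h_end, min(genome.length, h_end + flank)
    region = genome.sequence[ig_start:ig_end]
    boxes = scan_dnaa_boxes(region, ig_start, consensus, max_mismatches)
    if not boxes:
        logger.warning("no DnaA boxes found in intergenic region of %s", genome.id)
    due = find_due(region, ig_start, due_window, due_at_min)
    return OriCPrediction(
        intergenic_start=ig_start,
        intergenic_end=ig_end,
        boxes=boxes,
        due=due,
        heme_start=h_start,
        heme_end=h_end,
        heme_strand=h_strand,
        heme_identity_pct=identity,
    )
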