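"""Streptomycin-resistance residue calling in RpsL (ribosomal protein S12).

Positions are 1-based on the mature (Met-cleaved) E. coli K-12 RpsL sequence,
the numbering under which the K42R / K87R resistance substitutions are
described. Any replacement reference may be supplied as long as it carries
lysine at both positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .align import protein_aligner, run_alignment
from .io import ProteinRecord

# Mature E. coli K-12 RpsL (UniProt P0A7S3 minus the initiator Met).
RPSL_ECOLI_MATURE = (
    "ATVNQLVRKPRARKVAKSNVPALEACPQKRGVCTRVYTTTPKKPNSALRKVCRVRLTNGFEVTSYIGGEG"
    "HNLQEHSVILIRGGRVKDLPGVRYHTVRGALDCSGVKDRKQARSKYGVKRPKA"
)

RESISTANCE_POSITIONS = (42, 87)


def default_reference() -> ProteinRecord:
    return ProteinRecord("rpsL_Ecoli_K12", "Ecoli_K12", RPSL_ECOLI_MATURE)


@dataclass(frozen=True)
class MarkerCall:
    protein_id: str
    residue_42: Optional[str]
    residue_87: Optional[str]
    verdict: str  # resistant | sensitive | indeterminate
    aligned_positions: Dict[int, Optional[int]]  # 1-based ref pos -> 1-based query pos
    identity_pct: float
    note: str = ""


def _validate_reference(reference: ProteinRecord) -> None:
    for pos in RESISTANCE_POSITIONS:
        if len(reference.sequence) < pos or reference.sequence[pos - 1] != "K":
            raise ValueError(
                f"reference {reference.id!r} lacks lysine at position {pos}"
            )


def _map_position(blocks, ref_pos0: int) -> Optional[int]:
    """Map a 0-based reference position through aligned blocks to the query."""
    bt, bq = blocks
    for (ts, te), (qs, qe) in zip(bt, bq):
        if ts <= ref_pos0 < te:
            return qs + (ref_pos0 - ts)
    return None


def rpsl_call(
    query: ProteinRecord,
    reference: Optional[ProteinRecord] = None,
    min_identity_pct: float = 40.0,
) -> MarkerCall:
    """Call streptomycin resistance for one RpsL homolog.

    Resistant iff residue 42 or 87 (reference numbering, mapped through a
    global alignment) is arginine; indeterminate when either position maps to
    a gap.
    """
    reference = reference or default_reference()
    _validate_reference(reference)
    aligner = protein_aligner(free_end_gaps=True)
    result, blocks = run_alignment(aligner, reference.sequence, query.sequence)
    # free-end alignments of unrelated proteins can collapse to a short
    # high-identity sliver, so demand most of the reference be covered too
    if result.identity_pct < min_identity_pct or result.subject_coverage_pct < 60.0:
        raise ValueError(
            f"{query.id!r} is not an RpsL homolog "
            f"(identity {result.identity_pct:.1f} % < {min_identity_pct} % "
            f"or reference coverage {result.subject_coverage_pct:.1f} % < 60 %)"
        )
    residues: Dict[int, Optional[str]] = {}
    mapping: Dict[int, Optional[int]] = {}
    for pos in RESISTANCE_POSITIONS:
        qpos0 = _map_position(blocks, pos - 1)
        mapping[pos] = None if qpos0 is None else qpos0 + 1
        residues[pos] = None if qpos0 is None else query.sequence[qpos0]
    note = ""
    if any(r is None for r in residues.values()):
        verdict = "indeterminate"
    elif any(residues[p] == "R" for p in RESISTANCE_POSITIONS):
        verdict = "resistant"
    else:
        verdict = "sensitive"
        odd = [p for p in RESISTANCE_POSITIONS if residues[p] != "K"]
        if odd:
            note = "non-K/non-R residue at position(s) " + ",".join(map(str, odd))
    return MarkerCall(
        protein_id=query.id,
        residue_42=residues[42],
        residue_87=residues[87],
        verdict=verdict,
        aligned_positions=mapping,
        identity_pct=result.identity_pct,
        note=note,
    )


def scan_proteome_for_rpsl(
    proteome: Sequence[ProteinRecord],
    reference: Optional[ProteinRecord] = None,
    min_identity_pct: float = 40.0,
) -> MarkerCall:
    """Call the best RpsL homolog in a whole proteome (by alignment score)."""
    reference = reference or default_reference()
    _validate_reference(reference)
    aligner = protein_aligner(free_end_gaps=True)
    best: Optional[Tuple[float, ProteinRecord]] = None
    for prot in proteome:
        # skip proteins wildly different in length before aligning
        if not 0.3 <= prot.length / reference.length <= 3.0:
            continue
        result, _ = run_alignment(aligner, reference.sequence, prot.sequence)
        if best is None or result.score > best[0]:
            best = (result.score, prot)
    if best is None:
        raise ValueError("no RpsL-sized protein in proteome")
    return rpsl_call(best[1], reference, min_identity_pct)
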