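"""Readers and writers for the plain-text formats the pipeline touches.

Coordinates are 0-based half-open internally; report helpers print 1-based
starts so that end - start reproduces published region lengths.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger("genophys")

_DNA_OK = set("ACGTN")
_PROT_OK = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence (upper-case, alphabet ACGTN)."""

    id: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence tied to its source genome."""

    id: str
    genome_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A half-open genomic interval with a label and a score."""

    genome_id: str
    start: int
    end: int
    label: str
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region [{self.start}, {self.end}) for {self.label!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_sequence(seq: str, alphabet: str, rec_id: str) -> str:
    seq = seq.upper()
    ok = _DNA_OK if alphabet == "dna" else _PROT_OK
    for pos, ch in enumerate(seq):
        if ch not in ok:
            raise ValueError(
                f"illegal character {ch!r} at position {pos + 1} of record {rec_id!r}"
            )
    return seq


def read_fasta(
    path: Union[str, Path],
    alphabet: str = "dna",
    genome_id: Optional[str] = None,
) -> List[Union[GenomeRecord, ProteinRecord]]:
    """Parse a FASTA file into Genome/Protein records.

    Sequences are upper-cased; duplicate ids, illegal characters and empty
    files are errors. For proteins, ``genome_id`` defaults to the file stem.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    path = Path(path)
    records: List[Union[GenomeRecord, ProteinRecord]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _validate_sequence(str(rec.seq), alphabet, rec.id)
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        if alphabet == "dna":
            records.append(GenomeRecord(rec.id, rec.description, seq))
        else:
            records.append(
                ProteinRecord(rec.id, genome_id or path.stem, seq)
            )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Sequence[Union[GenomeRecord, ProteinRecord]],
    path: Union[str, Path],
    width: int = 70,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id} {desc}".rstrip() if desc and desc != rec.id else f">{rec.id}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_tsv_matrix(
    labels_rows: Sequence[str],
    labels_cols: Sequence[str],
    values: np.ndarray,
    path: Union[str, Path],
    companion: Optional[np.ndarray] = None,
) -> None:
    """Write a labelled matrix as TSV, "NN.NN [MM.MM]" when a companion
    (aligned-fraction) matrix is supplied; the diagonal of a square matrix
    with identical labels is written empty."""
    values = np.asarray(values, dtype=float)
    if len(set(labels_rows)) != len(labels_rows) or len(set(labels_cols)) != len(labels_cols):
        raise ValueError("row/column labels must be unique")
    if values.shape != (len(labels_rows), len(labels_cols)):
        raise ValueError("matrix shape does not match labels")
    if companion is not None:
        companion = np.asarray(companion, dtype=float)
        if companion.shape != values.shape:
            raise ValueError(
                f"companion matrix shape {companion.shape} != value shape {values.shape}"
            )
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(labels_cols)) + "\n")
        for i, rl in enumerate(labels_rows):
            cells = []
            for j, cl in enumerate(labels_cols):
                if rl == cl:
                    cells.append("")
                elif companion is not None:
                    cells.append(f"{values[i, j]:.2f} [{companion[i, j]:.2f}]")
                else:
                    cells.append(f"{values[i, j]:.2f}")
            fh.write("\t".join([rl] + cells) + "\n")


def read_tsv_matrix(
    path: Union[str, Path],
) -> Tuple[List[str], List[str], np.ndarray, Optional[np.ndarray]]:
    """Re-parse a matrix written by :func:`write_tsv_matrix` (nan diagonal)."""
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    cols = rows[0][1:]
    labels = [r[0] for r in rows[1:]]
    vals = np.full((len(labels), len(cols)), np.nan)
    comp = np.full((len(labels), len(cols)), np.nan)
    has_comp = False
    for i, r in enumerate(rows[1:]):
        for j, cell in enumerate(r[1:]):
            if not cell:
                continue
            if "[" in cell:
                has_comp = True
                v, c = cell.split("[")
                vals[i, j] = float(v)
                comp[i, j] = float(c.rstrip("]"))
            else:
                vals[i, j] = float(cell)
    return labels, cols, vals, (comp if has_comp else None)


def write_bed(regions: Sequence[RegionAnnotation], path: Union[str, Path]) -> None:
    """Write regions as standard 5-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            if r.start >= r.end:
                raise ValueError(f"start >= end in region {r.label!r}")
            fh.write(f"{r.genome_id}\t{r.start}\t{r.end}\t{r.label}\t{r.score:g}\n")


def read_bed(path: Union[str, Path]) -> List[RegionAnnotation]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 else 0.0
            regions.append(RegionAnnotation(chrom, start, end, label, score))
    return regions


def read_growth_csv(path: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray]:
    """Read `time_h,od600`; times must be strictly increasing and OD > 0."""
    times, ods = [], []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "time_h" not in reader.fieldnames or "od600" not in reader.fieldnames:
            raise ValueError(f"{path}: expected header 'time_h,od600'")
        for row in reader:
            t, od = float(row["time_h"]), float(row["od600"])
            if od <= 0:
                raise ValueError(f"{path}: OD must be positive (got {od} at t={t})")
            times.append(t)
            ods.append(od)
    t = np.array(times)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    return t, np.array(ods)


def read_chem_csv(path: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read `time_h,nitrate_mM,nitrite_mM`; concentrations must be >= 0."""
    times, no3, no2 = [], [], []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        required = {"time_h", "nitrate_mM", "nitrite_mM"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header 'time_h,nitrate_mM,nitrite_mM'")
        for row in reader:
            a, b = float(row["nitrate_mM"]), float(row["nitrite_mM"])
            if a < 0 or b < 0:
                raise ValueError(f"{path}: negative concentration")
            times.append(float(row["time_h"]))
            no3.append(a)
            no2.append(b)
    return np.array(times), np.array(no3), np.array(no2)


def write_growth_csv(path: Union[str, Path], time_h: np.ndarray, od600: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("time_h,od600\n")
        for t, od in zip(time_h, od600):
            fh.write(f"{t:g},{od:.6g}\n")


def write_chem_csv(
    path: Union[str, Path], time_h: np.ndarray, nitrate: np.ndarray, nitrite: np.ndarray
) -> None:
    with open(path, "w") as fh:
        fh.write("time_h,nitrate_mM,nitrite_mM\n")
        for t, a, b in zip(time_h, nitrate, nitrite):
            fh.write(f"{t:g},{a:.6g},{b:.6g}\n")


def load_config(path: Union[str, Path]) -> Dict:
    """Load a YAML config whose keys mirror CLI flags (dashes or underscores)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return {str(k).replace("-", "_"): v for k, v in cfg.items()}


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
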