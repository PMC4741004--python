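"""Synthetic genome sets and growth/chemistry series with known ground truth.

Genome sets are built from a random ancestor carrying planted gene families,
marker genes, an origin-of-replication block (hemE gene plus an upstream
intergenic interval with DnaA boxes and an AT-rich unwinding element) and
composition-shifted island segments. Descendants receive an exact substitution
count (round(d * L), substitutions only), so planted identities are
deterministic. The origin intergenic is scrubbed of accidental box-like
9-mers and AT-rich stretches, and is excluded from substitutions, so planted
coordinates are recovered exactly and null scans stay clean.

The growth simulator integrates Monod kinetics on nitrate with strict 1:1
nitrate-to-nitrite conversion and growth arrest at a nitrite toxicity
threshold; pre-noise chemistry obeys exact conservation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .align import align_protein
from .ani import revcomp
from .growth import ChemSeries, GrowthSeries
from .io import GenomeRecord, ProteinRecord
from .markers import RPSL_ECOLI_MATURE
from .signatures import (
    DNAA_BOX_CONSENSUS,
    find_due,
    scan_dnaa_boxes,
    translate,
)

BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOPS = {"TAA", "TAG", "TGA"}

MARKER_LENGTHS = {"rrs16s": 1200, "atpd": 900, "rpob": 1500}


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimParams:
    n_genomes: int = 4
    genome_len: int = 100_000
    n_core_families: int = 20
    n_accessory_families: int = 10
    mean_gene_len: int = 300
    nucleotide_divergence: Union[float, Sequence[float]] = 0.02
    protein_divergence: Union[float, Sequence[float]] = 0.02
    plant_oric: bool = True
    n_dnaa_boxes: int = 5
    plant_due: bool = True
    island_specs: Sequence[Tuple[int, float]] = ()  # (length, same-base transition excess)
    rpsl_variants: Optional[Sequence[str]] = None  # per genome, e.g. "KK", "KR"
    plant_rpsl: bool = True
    plant_markers: bool = True
    seed: int = 0

    def divergences(self) -> List[float]:
        d = self.nucleotide_divergence
        out = [float(d)] * self.n_genomes if np.isscalar(d) else [float(x) for x in d]
        if len(out) != self.n_genomes:
            raise ValueError("one nucleotide divergence per genome required")
        if any(not 0 <= x < 0.5 for x in out):
            raise ValueError("nucleotide divergence must be in [0, 0.5)")
        return out

    def protein_divergences(self) -> List[float]:
        d = self.protein_divergence
        out = [float(d)] * self.n_genomes if np.isscalar(d) else [float(x) for x in d]
        if len(out) != self.n_genomes:
            raise ValueError("one protein divergence per genome required")
        return out

    def variants(self) -> List[str]:
        if self.rpsl_variants is None:
            return ["KK"] * self.n_genomes
        v = [str(x).upper() for x in self.rpsl_variants]
        if len(v) != self.n_genomes or any(len(x) != 2 or set(x) - set("KR") for x in v):
            raise ValueError("rpsl_variants must be n_genomes two-letter K/R strings")
        return v


@dataclass
class GenomeFeatures:
    genes: Dict[str, Tuple[int, int, str]] = field(default_factory=dict)  # pid -> (s, e, family)
    markers: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    islands: List[Tuple[int, int]] = field(default_factory=list)
    heme: Optional[Tuple[int, int, str]] = None  # (s, e, strand)
    intergenic: Optional[Tuple[int, int]] = None
    boxes: List[int] = field(default_factory=list)
    due: Optional[Tuple[int, int]] = None
    rpsl_protein: Optional[str] = None
    rpsl_variant: Optional[str] = None


@dataclass
class TruthTables:
    families: Dict[str, List[Tuple[str, str]]]
    features: Dict[str, GenomeFeatures]
    identity_pct: Dict[Tuple[str, str], float]
    nucleotide_divergence: Dict[str, float]
    protein_divergence: Dict[str, float]

    def family_partition(self, genome_ids: Sequence[str]) -> List[frozenset]:
        """Planted family partition restricted to a genome subset."""
        keep = set(genome_ids)
        out = []
        for members in self.families.values():
            sub = frozenset((g, p) for g, p in members if g in keep)
            if sub:
                out.append(sub)
        return sorted(out, key=min)

    def pan_core_truth(
        self, genome_order: Sequence[str]
    ) -> Tuple[List[int], List[int]]:
        fams = [
            {g for g, _ in members if g in set(genome_order)}
            for members in self.families.values()
        ]
        fams = [f for f in fams if f]
        core, pan = [], []
        seen = set()
        for g in genome_order:
            seen.add(g)
            pan.append(sum(1 for f in fams if f & seen))
            core.append(sum(1 for f in fams if seen <= f))
        return core, pan

    def to_json(self) -> str:
        payload = {
            "families": self.families,
            "features": {g: asdict(f) for g, f in self.features.items()},
            "identity_pct": {f"{a}|{b}": v for (a, b), v in self.identity_pct.items()},
            "nucleotide_divergence": self.nucleotide_divergence,
            "protein_divergence": self.protein_divergence,
        }
        return json.dumps(payload, indent=1)


@dataclass
class SimulatedGenomeSet:
    ancestor: GenomeRecord
    genomes: List[GenomeRecord]
    proteomes: Dict[str, List[ProteinRecord]]
    truth: TruthTables

    def genome(self, gid: str) -> GenomeRecord:
        if gid == "ancestor":
            return self.ancestor
        return next(g for g in self.genomes if g.id == gid)


# ---------------------------------------------------------------------------
# sequence builders
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, length)])


def random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random stop-free codons + TAA; length rounded to a codon multiple."""
    length = max(30, 3 * round(length / 3))
    n_mid = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_mid + 1:
        c = random_dna(rng, 3)
        if c not in STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def biased_island(rng: np.random.Generator, length: int, shift: float) -> str:
    """First-order Markov sequence where repeating the previous base has
    probability 0.25 + shift (elevating the four XX dinucleotides)."""
    if not 0 <= shift <= 0.7:
        raise ValueError("island composition shift must be in [0, 0.7]")
    seq = [BASES[rng.integers(0, 4)]]
    p_same = 0.25 + shift
    for _ in range(length - 1):
        if rng.random() < p_same:
            seq.append(seq[-1])
        else:
            others = [b for b in BASES if b != seq[-1]]
            seq.append(others[rng.integers(0, 3)])
    return "".join(seq)


def substitute(
    seq: str,
    rng: np.random.Generator,
    n_subs: int,
    forbidden: Sequence[Tuple[int, int]] = (),
    alphabet: str = BASES,
) -> Tuple[str, Dict[int, str]]:
    """Apply exactly ``n_subs`` substitutions at distinct allowed positions."""
    allowed = np.ones(len(seq), dtype=bool)
    for s, e in forbidden:
        allowed[s:e] = False
    pool = np.nonzero(allowed)[0]
    if n_subs > len(pool):
        raise ValueError("more substitutions requested than allowed positions")
    positions = rng.choice(pool, size=n_subs, replace=False)
    chars = list(seq)
    changes: Dict[int, str] = {}
    for pos in sorted(int(p) for p in positions):
        alternatives = [b for b in alphabet if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, len(alternatives))]
        changes[pos] = chars[pos]
    return "".join(chars), changes


def _scrub_intergenic(
    region: List[str],
    rng: np.random.Generator,
    protected: List[Tuple[int, int]],
    consensus: str,
    max_mismatches: int,
    due_window: int,
    due_at_min: float,
    max_rounds: int = 200,
) -> None:
    """Remove accidental DnaA-box-like 9-mers and AT-rich stretches from an
    intergenic region (in place), leaving planted features untouched."""

    def is_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    planted_box_starts = {s for s, e in protected if e - s == len(consensus)}
    for _ in range(max_rounds):
        seq = "".join(region)
        dirty = False
        for hit in scan_dnaa_boxes(seq, 0, consensus, max_mismatches):
            if hit.position in planted_box_starts:
                continue
            spots = [p for p in range(hit.position, hit.position + len(consensus)) if not is_protected(p)]
            if not spots:
                continue
            pos = spots[rng.integers(0, len(spots))]
            region[pos] = BASES[rng.integers(0, 4)]
            dirty = True
        seq = "".join(region)
        due = find_due(seq, 0, due_window, due_at_min)
        planted_due = [(s, e) for s, e in protected if e - s >= due_window]
        while due is not None:
            if planted_due and due.start >= planted_due[0][0]:
                break
            spots = [
                p
                for p in range(due.start, due.end)
                if not is_protected(p) and region[p] in "AT"
            ]
            if not spots:
                break
            pos = spots[rng.integers(0, len(spots))]
            region[pos] = "GC"[rng.integers(0, 2)]
            dirty = True
            seq = "".join(region)
            due = find_due(seq, 0, due_window, due_at_min)
        if not dirty:
            return
    raise RuntimeError("could not scrub intergenic region")


def _build_oric_block(
    rng: np.random.Generator,
    n_boxes: int,
    plant_due: bool,
    intergenic_len: int = 1000,
    box_spacing: int = 80,
    due_len: int = 60,
    due_at: float = 0.85,
) -> Tuple[str, List[int], Optional[Tuple[int, int]]]:
    """Scrubbed intergenic region with planted boxes and (optionally) a DUE."""
    region = list(random_dna(rng, intergenic_len))
    box_starts = [100 + i * box_spacing for i in range(n_boxes)]
    consensus = DNAA_BOX_CONSENSUS
    for s in box_starts:
        region[s : s + len(consensus)] = list(consensus)
    due_coords = None
    protected = [(s, s + len(consensus)) for s in box_starts]
    if plant_due:
        due_start = intergenic_len - 150
        n_at = round(due_at * due_len)
        at_positions = rng.permutation(due_len)[:n_at]
        chars = ["GC"[rng.integers(0, 2)] for _ in range(due_len)]
        for p in at_positions:
            chars[p] = "AT"[rng.integers(0, 2)]
        region[due_start : due_start + due_len] = chars
        due_coords = (due_start, due_start + due_len)
        protected.append(due_coords)
    _scrub_intergenic(region, rng, protected, consensus, 1, 50, 0.7)
    return "".join(region), box_starts, due_coords


# ---------------------------------------------------------------------------
# genome-set simulation
# ---------------------------------------------------------------------------

def _guarded_family_proteins(
    rng: np.random.Generator,
    cds_list: List[str],
    fixed_proteins: List[str],
    mean_gene_len: int,
    guard_identity_pct: float = 26.0,
    max_rounds: int = 20,
) -> List[str]:
    """Regenerate ancestor CDSs until no cross-family protein pair comes close
    to the clustering identity threshold (keeps planted families separable)."""
    proteins = [translate(c) for c in cds_list]
    for _ in range(max_rounds):
        conflict = None
        pool = proteins + fixed_proteins
        for i in range(len(proteins)):
            for j in range(i + 1, len(pool)):
                if align_protein(proteins[i], pool[j]).identity_pct >= guard_identity_pct:
                    conflict = i
                    break
            if conflict is not None:
                break
        if conflict is None:
            return proteins
        cds_list[conflict] = random_cds(rng, mean_gene_len)
        proteins[conflict] = translate(cds_list[conflict])
    raise RuntimeError("could not generate separable gene families")


def simulate_genome_set(params: GenomeSimParams) -> SimulatedGenomeSet:
    rng = np.random.default_rng(params.seed)
    n = params.n_genomes
    gids = [f"G{i}" for i in range(n)]
    divs = params.divergences()
    pdivs = params.protein_divergences()
    variants = params.variants()

    # --- ancestor content blocks -------------------------------------------
    n_fam = params.n_core_families + params.n_accessory_families
    fam_names = [f"F{i:04d}" for i in range(n_fam)]
    cds_list = [random_cds(rng, params.mean_gene_len) for _ in range(n_fam)]
    heme_cds = random_cds(rng, 600)
    heme_protein = translate(heme_cds)
    fam_proteins = _guarded_family_proteins(
        rng, cds_list, [heme_protein, RPSL_ECOLI_MATURE], params.mean_gene_len
    )

    blocks: List[Tuple[str, object]] = []  # (kind, payload)
    if params.plant_oric:
        intergenic, box_offsets, due_offsets = _build_oric_block(
            rng, params.n_dnaa_boxes, params.plant_due
        )
        # one block so the intergenic abuts the hemE start with no spacer
        blocks.append(("oric", (intergenic, box_offsets, due_offsets, heme_cds)))
    if params.plant_markers:
        for mname, mlen in MARKER_LENGTHS.items():
            blocks.append(("marker", (mname, random_dna(rng, mlen))))
    for fam, cds in zip(fam_names, cds_list):
        blocks.append(("gene", (fam, cds)))
    for length, shift in params.island_specs:
        blocks.append(("island", biased_island(rng, int(length), float(shift))))

    def block_len(kind, payload):
        if kind == "oric":
            return len(payload[0]) + len(payload[3])
        if kind == "island":
            return len(payload)
        return len(payload[1])

    content_len = sum(block_len(k, p) for k, p in blocks)
    n_spacers = len(blocks) + 1
    remaining = params.genome_len - content_len
    if remaining < 20 * n_spacers:
        raise ValueError(
            f"cannot pack {content_len} bp of content plus spacers into "
            f"{params.genome_len} bp"
        )
    cuts = np.sort(rng.choice(remaining - 20 * n_spacers + 1, n_spacers - 1, replace=True))
    spacer_lens = np.diff(np.concatenate([[0], cuts, [remaining - 20 * n_spacers]])) + 20
    spacers = [random_dna(rng, int(l)) for l in spacer_lens]

    # --- accessory presence -------------------------------------------------
    presence: Dict[str, np.ndarray] = {}
    for i, fam in enumerate(fam_names):
        if i < params.n_core_families:
            presence[fam] = np.ones(n, dtype=bool)
        else:
            mask = rng.random(n) < 0.5
            if not mask.any():
                mask[rng.integers(0, n)] = True
            presence[fam] = mask

    # --- assemble genomes ---------------------------------------------------
    def assemble(gid_index: Optional[int]) -> Tuple[str, GenomeFeatures, List[Tuple[int, int, int]]]:
        """gid_index None = ancestor. Returns sequence, features and a list of
        (genome_start, genome_end, ancestor_start) block maps."""
        feats = GenomeFeatures()
        parts: List[str] = []
        block_map: List[Tuple[int, int, int]] = []
        pos = 0
        anc_pos = 0

        def push(seq: str, in_genome: bool) -> int:
            nonlocal pos, anc_pos
            start = pos
            if in_genome:
                parts.append(seq)
                block_map.append((pos, pos + len(seq), anc_pos))
                pos += len(seq)
            anc_pos += len(seq)
            return start

        gid = None if gid_index is None else gids[gid_index]
        push(spacers[0], True)
        for bi, (kind, payload) in enumerate(blocks):
            if kind == "oric":
                intergenic, box_offsets, due_offsets, cds = payload
                start = push(intergenic + cds, True)
                feats.intergenic = (start, start + len(intergenic))
                feats.boxes = [start + b for b in box_offsets]
                if due_offsets is not None:
                    feats.due = (start + due_offsets[0], start + due_offsets[1])
                feats.heme = (start + len(intergenic), start + len(intergenic) + len(cds), "+")
            elif kind == "marker":
                mname, seq = payload
                start = push(seq, True)
                feats.markers[mname] = (start, start + len(seq))
            elif kind == "gene":
                fam, cds = payload
                present = gid_index is None or presence[fam][gid_index]
                start = push(cds, present)
                if present:
                    pid = f"{'anc' if gid is None else gid}_{fam}"
                    feats.genes[pid] = (start, start + len(cds), fam)
            elif kind == "island":
                start = push(payload, True)
                feats.islands.append((start, start + len(payload)))
            push(spacers[bi + 1], True)
        return "".join(parts), feats, block_map

    anc_seq, anc_feats, _ = assemble(None)
    ancestor = GenomeRecord("ancestor", "simulated ancestor", anc_seq)

    genomes: List[GenomeRecord] = []
    features: Dict[str, GenomeFeatures] = {"ancestor": anc_feats}
    sub_maps: Dict[str, Dict[int, str]] = {"ancestor": {}}
    presence_by_gid: Dict[str, set] = {"ancestor": set(fam_names)}

    for i, gid in enumerate(gids):
        seq, feats, block_map = assemble(i)
        protected = []
        if feats.intergenic is not None:
            protected.append(feats.intergenic)
        if feats.heme is not None:
            protected.append(feats.heme[:2])
        n_subs = round(divs[i] * len(seq))
        mutated, changes = substitute(seq, rng, n_subs, protected)
        # record substitutions in ancestor coordinates for exact pair identity
        anc_changes: Dict[int, str] = {}
        for pos, base in changes.items():
            for gs, ge, ancs in block_map:
                if gs <= pos < ge:
                    anc_changes[ancs + (pos - gs)] = base
                    break
        genomes.append(GenomeRecord(gid, f"descendant d={divs[i]}", mutated))
        features[gid] = feats
        sub_maps[gid] = anc_changes
        presence_by_gid[gid] = {f for f in fam_names if presence[f][i]}

    # --- exact pairwise identities over shared blocks -----------------------
    identity: Dict[Tuple[str, str], float] = {}
    all_ids = ["ancestor"] + gids
    gene_len = {f: len(c) for f, c in zip(fam_names, cds_list)}
    gene_spans = {f: (s, e) for pid, (s, e, f) in anc_feats.genes.items()}

    for x in range(len(all_ids)):
        for y in range(x + 1, len(all_ids)):
            a, b = all_ids[x], all_ids[y]
            shared_fams = presence_by_gid[a] & presence_by_gid[b]
            shared_len = len(anc_seq) - sum(
                gene_len[f] for f in fam_names if f not in shared_fams
            )
            sa, sb = sub_maps[a], sub_maps[b]

            def in_shared(p: int) -> bool:
                for f, (s, e) in gene_spans.items():
                    if s <= p < e:
                        return f in shared_fams
                return True

            diff = 0
            for p in set(sa) | set(sb):
                if not in_shared(p):
                    continue
                if sa.get(p, anc_seq[p]) != sb.get(p, anc_seq[p]):
                    diff += 1
            identity[(a, b)] = identity[(b, a)] = 100.0 * (1.0 - diff / shared_len)

    # --- proteomes ----------------------------------------------------------
    proteomes: Dict[str, List[ProteinRecord]] = {}
    fam_members: Dict[str, List[Tuple[str, str]]] = {f: [] for f in fam_names}
    fam_members["hemE"] = []
    fam_members["rpsL"] = []

    def make_proteome(gid: str, idx: Optional[int]) -> List[ProteinRecord]:
        prots = []
        pdiv = 0.0 if idx is None else pdivs[idx]
        prefix = "anc" if idx is None else gid
        for fam, base_prot in zip(fam_names, fam_proteins):
            if idx is not None and not presence[fam][idx]:
                continue
            n_sub = round(pdiv * len(base_prot))
            mutated, _ = substitute(base_prot, rng, n_sub, alphabet=AA20)
            pid = f"{prefix}_{fam}"
            prots.append(ProteinRecord(pid, gid, mutated))
            fam_members[fam].append((gid, pid))
        if params.plant_oric:
            pid = f"{prefix}_hemE"
            prots.append(ProteinRecord(pid, gid, heme_protein))
            fam_members["hemE"].append((gid, pid))
        if params.plant_rpsl:
            variant = "KK" if idx is None else variants[idx]
            rpsl_seq = list(RPSL_ECOLI_MATURE)
            rpsl_seq[41] = variant[0]
            rpsl_seq[86] = variant[1]
            pid = f"{prefix}_rpsL"
            prots.append(ProteinRecord(pid, gid, "".join(rpsl_seq)))
            fam_members["rpsL"].append((gid, pid))
            features[gid].rpsl_protein = pid
            features[gid].rpsl_variant = variant
        return prots

    proteomes["ancestor"] = make_proteome("ancestor", None)
    for i, gid in enumerate(gids):
        proteomes[gid] = make_proteome(gid, i)

    truth = TruthTables(
        families={f: m for f, m in fam_members.items() if m},
        features=features,
        identity_pct=identity,
        nucleotide_divergence={g: d for g, d in zip(gids, divs)},
        protein_divergence={g: d for g, d in zip(gids, pdivs)},
    )
    return SimulatedGenomeSet(ancestor, genomes, proteomes, truth)


def extract_markers(sim: SimulatedGenomeSet) -> Dict[str, Dict[str, str]]:
    """marker name -> {genome id -> sequence} from planted coordinates."""
    out: Dict[str, Dict[str, str]] = {}
    for gid, feats in sim.truth.features.items():
        genome = sim.genome(gid)
        for mname, (s, e) in feats.markers.items():
            out.setdefault(mname, {})[gid] = genome.sequence[s:e]
    return out


def simulate_sequences_on_tree(
    tree_spec, seq_len: int, seed: int = 0
) -> Dict[str, str]:
    """Evolve a random sequence along a nested-tuple topology.

    ``tree_spec`` is either ("LEAFNAME", branch_frac) or ([children], branch_frac);
    each branch applies exactly round(branch_frac * seq_len) substitutions.
    Returns {leaf name: sequence}.
    """
    rng = np.random.default_rng(seed)
    root_seq = random_dna(rng, seq_len)
    out: Dict[str, str] = {}

    def walk(node, seq: str) -> None:
        payload, frac = node
        seq, _ = substitute(seq, rng, round(float(frac) * seq_len))
        if isinstance(payload, str):
            out[payload] = seq
        else:
            for child in payload:
                walk(child, seq)

    walk(tree_spec, root_seq)
    return out


# ---------------------------------------------------------------------------
# growth simulation
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimParams:
    mu_max: float = math.log(2) / 4.06  # per h; rich-medium-like default
    k_no3: float = 0.5  # mM
    yield_od_per_mM: float = 0.025
    od_0: float = 0.1
    nitrate_0: float = 20.0
    nitrite_0: float = 0.0
    nitrite_toxic: float = 20.0
    inhibition: str = "threshold"  # or "linear"
    noise_sd_od: float = 0.0
    noise_sd_chem: float = 0.0
    dt: float = 0.25
    t_end: float = 48.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("mu_max", "k_no3", "yield_od_per_mM", "od_0", "nitrate_0",
                     "nitrite_0", "nitrite_toxic", "noise_sd_od", "noise_sd_chem"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.inhibition not in ("threshold", "linear"):
            raise ValueError("inhibition must be 'threshold' or 'linear'")


def simulate_growth(
    params: GrowthSimParams, return_pre_noise: bool = False
):
    """Integrate anaerobic growth on nitrate; returns (GrowthSeries, ChemSeries).

    Growth rate is mu_max * NO3/(K + NO3), gated by nitrite: zero at or above
    the toxicity threshold ("threshold" mode) or scaled by (1 - NO2/toxic)
    ("linear" mode). Nitrate consumed equals OD gained / yield and converts
    1:1 to nitrite, so NO3 + NO2 is conserved exactly before noise.
    """
    p = params
    steps = int(round(p.t_end / p.dt))
    t = np.arange(steps + 1) * p.dt
    od = np.empty(steps + 1)
    no3 = np.empty(steps + 1)
    no2 = np.empty(steps + 1)
    od[0], no3[0], no2[0] = p.od_0, p.nitrate_0, p.nitrite_0
    for i in range(steps):
        if p.inhibition == "threshold":
            gate = 1.0 if no2[i] < p.nitrite_toxic else 0.0
        else:
            gate = max(0.0, 1.0 - no2[i] / p.nitrite_toxic) if p.nitrite_toxic > 0 else 0.0
        rate = p.mu_max * gate * (no3[i] / (p.k_no3 + no3[i]) if no3[i] > 0 else 0.0)
        d_od = rate * od[i] * p.dt
        need = d_od / p.yield_od_per_mM if p.yield_od_per_mM > 0 else 0.0
        if need > no3[i]:
            need = no3[i]
            d_od = need * p.yield_od_per_mM
        od[i + 1] = od[i] + d_od
        no3[i + 1] = no3[i] - need
        no2[i + 1] = no2[i] + need
    pre = (
        GrowthSeries(t.copy(), od.copy(), "pre-noise"),
        ChemSeries(t.copy(), no3.copy(), no2.copy()),
    )
    rng = np.random.default_rng(p.seed)
    if p.noise_sd_od > 0:
        od = od * np.exp(rng.normal(0.0, p.noise_sd_od, od.shape))
    if p.noise_sd_chem > 0:
        no3 = np.clip(no3 + rng.normal(0.0, p.noise_sd_chem, no3.shape), 0.0, None)
        no2 = np.clip(no2 + rng.normal(0.0, p.noise_sd_chem, no2.shape), 0.0, None)
    growth = GrowthSeries(t, od, "simulated")
    chem = ChemSeries(t, no3, no2)
    if return_pre_noise:
        return growth, chem, pre
    return growth, chem
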