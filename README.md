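# genophys

Genome-based taxonomy and physiology toolkit for bacterial isolates, built
around the analyses used to place a strain within a genus and species and to
characterize its growth on nitrate:

- **ANI** — fragment-based average nucleotide identity with per-direction
  aligned fraction, species-boundary classification (95–96 % band), and
  cross-genome high-identity region detection.
- **AAI / pan-core** — all-vs-all proteome comparison at 30 % identity / 70 %
  coverage (on the longer protein), reciprocal-best-hit AAI with an NJ
  dendrogram, single-linkage gene families, pan/core accumulation curves and
  exclusive-gene extraction.
- **Phylogeny** — p-distances (optional Jukes–Cantor), neighbor joining
  (exact on additive matrices), bootstrap supports, marker concatenation and
  a small center-star aligner for near-identical marker genes.
- **Signatures / oriC** — windowed GC content and GC skew, dinucleotide
  relative-abundance anomaly scan, and hemE-anchored oriC prediction with
  DnaA-box (default consensus `TTATCCACA`) and AT-rich DUE detection.
- **RpsL** — streptomycin-resistance calling at residues 42/87 (mature
  E. coli numbering) via alignment-based position mapping.
- **Growth kinetics** — exponential-window detection, log2 doubling-time
  fits, nitrate→nitrite stoichiometry regression and yield-ratio comparison.
- **Simulators** — synthetic genome sets with planted gene families, markers,
  oriC features, composition-shifted islands and RpsL variants (all with
  exact truth tables), plus a Monod nitrate-respiration growth simulator with
  strict 1:1 nitrate→nitrite conversion and nitrite-toxicity arrest.

All alignment statistics share one convention: identity = matches / alignment
columns excluding terminal-gap columns; coverage = aligned span / sequence
length. Internally all coordinates are 0-based half-open.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes independent dynamic-programming oracles for the alignment
kernel, planted-truth recovery tests for every simulator feature, and
`tests/test_acceptance.py` with one test class per acceptance criterion.

## Command line

```sh
genophys simulate-genomes --n-genomes 4 --genome-len 100000 --seed 1 --out-dir sim/
genophys ani --genomes sim/G0.fasta --genomes sim/G1.fasta --out ani.tsv
genophys aai --proteomes sim/G0.faa --proteomes sim/G1.faa --out aai.tsv --tree-out aai.nwk
genophys pancore --proteomes sim/*.faa --focal G0 --out-prefix pancore
genophys tree --markers m16s.fasta --markers atpd.fasta --bootstrap 1000 --seed 1 --out tree.nwk
genophys signatures --genome sim/G0.fasta --out-prefix sig
genophys oric --genome sim/G0.fasta --heme heme.faa --out oric.bed
genophys rpsl --query sim/G1.faa --out calls.tsv
genophys simulate-growth --nitrate 20 --nitrite 6 --out-prefix growth
genophys growth --od growth.od.csv --chem growth.chem.csv --out fit.json
```

Every subcommand also accepts `--config cfg.yaml` whose keys mirror its flags.

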