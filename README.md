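# editscan

Tooling for studying A-to-I RNA editing imposed on an editing-naïve genome,
from simulated (or real, pre-aligned) sequencing data:

- **`editscan.simulate`** — synthetic genomes, truth tables of planted
  editing sites (with optional upstream-G motif depletion and
  hairpin-embedded sites), and truth-aligned unstranded RNA-seq plus
  matched DNA-seq reads (FASTA/FASTQ/SAM, fully seed-deterministic).
- **`editscan.detect`** — de novo editing-site calling from RNA pileups
  against the reference with DNA-based genomic-variant exclusion, an exact
  upper-tail binomial error test per candidate and Benjamini–Hochberg FDR
  control with a conservative genome-sized test count; mismatches collapse
  into the 6 unstranded classes.
- **`editscan.metrics`** — genome-wide editing index (read-weighted
  percentage of adenosine-derived nucleotides observed as guanosine),
  per-site level histograms, replicate recurrence, and the
  neighbour-nucleotide motif matrix in edited-A orientation.
- **`editscan.fold`** — temperature-dependent RNA secondary-structure
  thermodynamics: a minimum-free-energy dynamic program over a compact
  nearest-neighbour ΔH/ΔS model, windows around sites (±400 bp by
  default), extraction of the site-containing duplex substructure, 7-N
  linker joining of discontiguous arms, ΔG recompute (ΔG = 0 for sites not
  in a duplex), and rank-based stability comparisons. The embedded energy
  model is a simplified stand-in for full Turner parameter sets: only
  orderings and distribution shifts are meaningful, not absolute values.
- **`editscan.growth`** — OD600 growth-curve AUC (trapezoid), spot-assay
  relative pixel-density ratios, and pairwise Welch t-tests with
  significance-star labels (`ns`/`*`/`**`/`***`/`****`).
- **`editscan.pipeline`** — one-command simulate → detect → index →
  motif → structure runs with a checksummed manifest for reproducibility.

## CLI

```sh
editscan simulate --config examples/pipeline.cfg --outdir sim/
editscan detect --rna sim/rna.sam --dna sim/dna.sam --genome sim/genome.fa \
    --out sites.tsv --min-depth 5 --fdr 0.05
editscan index --rna sim/rna.sam --genome sim/genome.fa
editscan motif --sites sites.tsv --genome sim/genome.fa --out motif.tsv
editscan recur rep1.tsv rep2.tsv rep3.tsv
editscan structure --genome sim/genome.fa --sites sites.tsv --flank 400 \
    --temp-c 30 --max-window 121 --out structure.tsv
editscan growth auc --curves curves.tsv --out auc.tsv
editscan growth compare --values values.tsv
editscan pipeline run --config examples/pipeline.cfg
```

The config format is flat `key = value` (see `examples/pipeline.cfg`).
Coordinates are 0-based half-open internally; TSV/SAM outputs use each
format's native 1-based convention. All randomness flows from the single
`seed` key.

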