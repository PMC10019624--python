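"""Synthetic genomes, planted editing sites, and truth-aligned reads.

Everything is driven by one integer seed; each stage draws from its own
child stream so outputs are byte-identical across reruns and stages stay
reproducible independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from editscan.genome import BASES, Genome, revcomp

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

# stream tags for per-stage child RNGs
_STREAM_GENOME = 0
_STREAM_SITES = 1
_STREAM_RNA = 2
_STREAM_DNA = 3


class InvalidConfigError(ValueError):
    """Raised for configurations that violate their invariants."""


class InfeasibleConfigError(ValueError):
    """Raised when a config is valid but cannot be satisfied by the genome."""


@dataclass
class SimulationConfig:
    """Parameters for one synthetic dataset.

    ``level_distribution`` is a mapping with a ``name`` key:
    ``{"name": "uniform", "low": .., "high": ..}``,
    ``{"name": "fixed", "value": ..}``, or
    ``{"name": "two_point", "values": [a, b], "probs": [p, 1-p]}``.
    """

    seed: int = 0
    contig_lengths: Sequence[int] = (100_000,)
    gc_content: float = 0.40
    n_sites: int = 0
    level_distribution: Mapping = field(
        default_factory=lambda: {"name": "uniform", "low": 0.2, "high": 0.9}
    )
    motif_bias: float = 0.0
    hairpin_fraction: float = 0.0
    coverage: float = 50.0
    read_length: int = 100
    error_rate: float = 0.0
    dna_coverage: float = 50.0
    hairpin_arm: int = 30
    hairpin_loop: int = 10
    base_quality: int = 30

    def __post_init__(self) -> None:
        if not self.contig_lengths:
            raise InvalidConfigError("contig_lengths must be non-empty")
        if any(length <= 0 for length in self.contig_lengths):
            raise InvalidConfigError("zero-length contig")
        if not 0.0 <= self.gc_content <= 1.0:
            raise InvalidConfigError("gc_content must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise InvalidConfigError("error_rate must be in [0, 1)")
        if self.read_length > min(self.contig_lengths):
            raise InvalidConfigError("read_length exceeds shortest contig")
        if self.n_sites < 0:
            raise InvalidConfigError("n_sites must be non-negative")
        for frac, name in ((self.motif_bias, "motif_bias"), (self.hairpin_fraction, "hairpin_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthTable:
    """Planted editing sites with per-site true editing levels.

    Positions are 0-based; ``strand`` records the strand carrying the
    edited adenosine (A on '+', i.e. reference T for '-' sites).
    """

    records: pd.DataFrame  # columns: contig, position, strand, true_level[, origin]

    COLUMNS = ("contig", "position", "strand", "true_level")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.records.columns:
                self.records[col] = pd.Series(dtype=object)
        dup = self.records.duplicated(subset=["contig", "position", "strand"])
        if dup.any():
            raise InvalidConfigError("duplicate truth positions")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def empty(cls) -> "TruthTable":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))

    def validate_against(self, genome: Genome) -> None:
        """Check that every site carries an A on its recorded strand."""
        for row in self.records.itertuples(index=False):
            base = genome.base(row.contig, row.position)
            expected = "A" if row.strand == "+" else "T"
            if base != expected:
                raise InvalidConfigError(
                    f"truth site {row.contig}:{row.position} ref={base}, "
                    f"expected {expected} for strand {row.strand}"
                )

    def to_tsv(self, path: str) -> None:
        """BED-like 6-column TSV: contig, start, end, name, level, strand."""
        df = self.records
        origins = (
            df["origin"].tolist() if "origin" in df.columns else ["site"] * len(df)
        )
        out = pd.DataFrame(
            {
                "contig": df["contig"],
                "start": df["position"],
                "end": df["position"] + 1,
                "name": [f"{o}_{i}" for i, o in enumerate(origins)],
                "level": df["true_level"],
                "strand": df["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "TruthTable":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "start", "end", "name", "level", "strand"],
        )
        return cls(
            pd.DataFrame(
                {
                    "contig": bed["contig"],
                    "position": bed["start"],
                    "strand": bed["strand"],
                    "true_level": bed["level"],
                    "origin": bed["name"].str.rsplit("_", n=1).str[0],
                }
            )
        )


@dataclass
class ReadSet:
    """Aligned single-end reads for one simulated library.

    ``seq`` rows are reference-oriented; ``reverse`` marks reads whose
    physical template was the minus strand (SAM FLAG 16, FASTQ revcomp).
    """

    names: List[str]
    contigs: List[str]
    starts: np.ndarray
    seqs: List[str]
    reverse: np.ndarray
    quality_char: str

    def __len__(self) -> int:
        return len(self.names)


def _draw_levels(rng: np.random.Generator, dist: Mapping, n: int) -> np.ndarray:
    name = dist.get("name", "uniform")
    if name == "uniform":
        lo, hi = float(dist["low"]), float(dist["high"])
        if not (0.0 < lo <= hi <= 1.0):
            raise InvalidConfigError("uniform level bounds must satisfy 0 < lo <= hi <= 1")
        return rng.uniform(lo, hi, size=n)
    if name == "fixed":
        value = float(dist["value"])
        if not 0.0 < value <= 1.0:
            raise InvalidConfigError("fixed level must be in (0, 1]")
        return np.full(n, value)
    if name == "two_point":
        values = np.asarray(dist["values"], dtype=float)
        probs = np.asarray(dist["probs"], dtype=float)
        return rng.choice(values, size=n, p=probs)
    raise InvalidConfigError(f"unknown level distribution {name!r}")


def generate_genome(config: SimulationConfig) -> Genome:
    """I.i.d. random genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    rng = config.rng(_STREAM_GENOME)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    genome = Genome()
    for i, length in enumerate(config.contig_lengths):
        bases = rng.choice(_BASE_ARR, size=length, p=probs)
        genome.add_contig(f"chr{i + 1}", bases.tobytes().decode("ascii"))
    return genome


def _plant_hairpins(
    genome: Genome, config: SimulationConfig, rng: np.random.Generator, n_hairpins: int
) -> List[Tuple[str, int, str]]:
    """Write inverted repeats into the genome; return mid-arm A site coords.

    Each hairpin is arm + loop + revcomp(arm); the site is an A at the
    middle of the 5' arm (site strand '+'), with a non-G base immediately
    upstream so motif statistics are not diluted by hairpin sites.
    """
    arm, loop = config.hairpin_arm, config.hairpin_loop
    span = 2 * arm + loop
    sites: List[Tuple[str, int, str]] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome.contigs}
    contigs = genome.contigs
    weights = np.array([genome.length(c) for c in contigs], dtype=float)
    weights /= weights.sum()
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for _ in range(n_hairpins):
        for _attempt in range(1000):
            contig = contigs[rng.choice(len(contigs), p=weights)]
            limit = genome.length(contig) - span
            if limit <= 1:
                continue
            start = int(rng.integers(1, limit))
            if any(start < e and start + span > s for s, e in occupied[contig]):
                continue
            arm_seq = list(rng.choice(_BASE_ARR, size=arm, p=probs).tobytes().decode())
            mid = arm // 2
            arm_seq[mid] = "A"
            if mid > 0 and arm_seq[mid - 1] == "G":
                arm_seq[mid - 1] = "C"
            arm5 = "".join(arm_seq)
            loop_seq = rng.choice(_BASE_ARR, size=loop, p=probs).tobytes().decode()
            genome.set_slice(contig, start, arm5 + loop_seq + revcomp(arm5))
            occupied[contig].append((start, start + span))
            sites.append((contig, start + mid, "+"))
            break
        else:
            raise InfeasibleConfigError("could not place hairpin without overlap")
    return sites


def plant_editing_sites(genome: Genome, config: SimulationConfig) -> TruthTable:
    """Sample ``n_sites`` adenosine positions (both strands) as truth sites.

    With probability ``motif_bias`` a candidate whose 5' neighbour (on the
    site strand) is G is rejected and resampled. ``hairpin_fraction`` of
    sites are embedded mid-arm in inverted repeats written into the genome
    (the genome is modified in place before the remaining sites are drawn).
    """
    rng = config.rng(_STREAM_SITES)
    n_hairpin = int(round(config.hairpin_fraction * config.n_sites))
    chosen: List[Tuple[str, int, str]] = []
    if n_hairpin:
        chosen.extend(_plant_hairpins(genome, config, rng, n_hairpin))
    taken = {(c, p) for c, p, _ in chosen}

    # candidate pool: reference A (site strand +) and reference T (site strand -)
    pool: List[Tuple[str, int, str]] = []
    for contig in genome.contigs:
        idx = genome.as_index_array(contig)
        for base_idx, strand in ((0, "+"), (3, "-")):
            for pos in np.flatnonzero(idx == base_idx):
                pool.append((contig, int(pos), strand))
    n_rest = config.n_sites - n_hairpin
    if n_rest > len(pool):
        raise InfeasibleConfigError(
            f"requested {config.n_sites} sites but only {len(pool)} adenosines available"
        )

    order = rng.permutation(len(pool))
    cursor = 0

    def next_candidate() -> Optional[Tuple[str, int, str]]:
        nonlocal cursor
        while cursor < len(order):
            cand = pool[order[cursor]]
            cursor += 1
            if (cand[0], cand[1]) not in taken:
                return cand
        return None

    while len(chosen) < config.n_sites:
        cand = next_candidate()
        if cand is None:
            raise InfeasibleConfigError("ran out of candidate adenosines")
        contig, pos, strand = cand
        if config.motif_bias > 0.0:
            # 5' neighbour on the site strand: pos-1 on '+', complement of pos+1 on '-'
            if strand == "+":
                up = genome.base(contig, pos - 1) if pos > 0 else "N"
            else:
                up = (
                    revcomp(genome.base(contig, pos + 1))
                    if pos + 1 < genome.length(contig)
                    else "N"
                )
            if up == "G" and rng.random() < config.motif_bias:
                continue
        taken.add((contig, pos))
        chosen.append(cand)

    if not chosen:
        return TruthTable.empty()
    levels = _draw_levels(rng, config.level_distribution, len(chosen))
    origins = ["hairpin"] * n_hairpin + ["background"] * (len(chosen) - n_hairpin)
    df = pd.DataFrame(
        {
            "contig": [c for c, _, _ in chosen],
            "position": [p for _, p, _ in chosen],
            "strand": [s for _, _, s in chosen],
            "true_level": levels,
            "origin": origins,
        }
    ).sort_values(["contig", "position"], kind="stable", ignore_index=True)
    truth = TruthTable(df)
    truth.validate_against(genome)
    return truth


def _simulate_library(
    genome: Genome,
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator,
    coverage: float,
    name_prefix: str,
) -> ReadSet:
    rl = config.read_length
    e = config.error_rate
    names: List[str] = []
    contigs_out: List[str] = []
    starts_out: List[np.ndarray] = []
    seqs: List[str] = []
    reverse_out: List[np.ndarray] = []
    read_id = 0
    for contig in genome.contigs:
        length = genome.length(contig)
        n_reads = int(round(coverage * length / rl))
        if n_reads == 0:
            continue
        starts = np.sort(rng.integers(0, length - rl + 1, size=n_reads))
        ref = np.frombuffer(genome[contig].encode("ascii"), dtype=np.uint8)
        matrix = ref[starts[:, None] + np.arange(rl)[None, :]].copy()
        # base-to-index for editing/error arithmetic; N stays out of the edit path
        idx_matrix = np.full(matrix.shape, -1, dtype=np.int8)
        for i, base in enumerate(BASES):
            idx_matrix[matrix == ord(base)] = i

        # plant edited alleles: G on '+' sites, C (revcomp of G) on '-' sites
        if len(truth):
            site_rows = truth.records[truth.records["contig"] == contig]
            for row in site_rows.itertuples(index=False):
                pos, strand, level = row.position, row.strand, row.true_level
                covering = np.flatnonzero((starts <= pos) & (starts > pos - rl))
                if covering.size == 0:
                    continue
                edited = covering[rng.random(covering.size) < level]
                alt = ord("G") if strand == "+" else ord("C")
                matrix[edited, pos - starts[edited]] = alt

        # uniform substitution errors, probability e, e/3 per alternative
        if e > 0.0:
            err_mask = rng.random(matrix.shape) < e
            err_mask &= idx_matrix >= 0
            n_err = int(err_mask.sum())
            if n_err:
                cur = np.full(matrix.shape, -1, dtype=np.int8)
                for i, base in enumerate(BASES):
                    cur[matrix == ord(base)] = i
                shift = rng.integers(1, 4, size=n_err)
                new_idx = (cur[err_mask] + shift) % 4
                matrix[err_mask] = _BASE_ARR[new_idx]

        reverse = rng.integers(0, 2, size=n_reads).astype(bool)
        names.extend(f"{name_prefix}_{contig}_{read_id + i}" for i in range(n_reads))
        read_id += n_reads
        contigs_out.extend([contig] * n_reads)
        starts_out.append(starts)
        seqs.extend(row.tobytes().decode("ascii") for row in matrix)
        reverse_out.append(reverse)
    return ReadSet(
        names=names,
        contigs=contigs_out,
        starts=np.concatenate(starts_out) if starts_out else np.array([], dtype=int),
        seqs=seqs,
        reverse=np.concatenate(reverse_out) if reverse_out else np.array([], dtype=bool),
        quality_char=chr(config.base_quality + 33),
    )


def simulate_reads(genome: Genome, truth: TruthTable, config: SimulationConfig) -> ReadSet:
    """Unstranded RNA-seq reads carrying A->G conversions at truth sites."""
    return _simulate_library(
        genome, truth, config, config.rng(_STREAM_RNA), config.coverage, "rna"
    )


def simulate_dna_reads(genome: Genome, config: SimulationConfig) -> ReadSet:
    """Matched DNA reads: same error model, no editing."""
    return _simulate_library(
        genome, TruthTable.empty(), config, config.rng(_STREAM_DNA), config.dna_coverage, "dna"
    )


# ------------------------------------------------------------------ writers

def write_sam(reads: ReadSet, genome: Genome, path: str) -> None:
    """Plain-text SAM with @SQ header; ungapped records, FLAG 16 on reverse."""
    rl = None
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig in genome.contigs:
            fh.write(f"@SQ\tSN:{contig}\tLN:{genome.length(contig)}\n")
        for i in range(len(reads)):
            seq = reads.seqs[i]
            if rl != len(seq):
                rl = len(seq)
                qual = reads.quality_char * rl
                cigar = f"{rl}M"
            flag = 16 if reads.reverse[i] else 0
            fh.write(
                f"{reads.names[i]}\t{flag}\t{reads.contigs[i]}\t{reads.starts[i] + 1}"
                f"\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )


def write_fastq(reads: ReadSet, path: str) -> None:
    """FASTQ (Sanger Phred+33); reverse-flagged reads are reverse-complemented."""
    with open(path, "w") as fh:
        for i in range(len(reads)):
            seq = reads.seqs[i]
            if reads.reverse[i]:
                seq = revcomp(seq)
            fh.write(f"@{reads.names[i]}\n{seq}\n+\n{reads.quality_char * len(seq)}\n")


def simulate_dataset(config: SimulationConfig, outdir: str) -> Dict[str, str]:
    """Run genome -> sites -> RNA/DNA reads and write all artifacts.

    Returns a dict of artifact paths (genome.fa, truth.tsv, rna.sam,
    rna.fastq, dna.sam).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(config)
    truth = plant_editing_sites(genome, config)
    rna = simulate_reads(genome, truth, config)
    dna = simulate_dna_reads(genome, config)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "rna_sam": os.path.join(outdir, "rna.sam"),
        "rna_fastq": os.path.join(outdir, "rna.fastq"),
        "dna_sam": os.path.join(outdir, "dna.sam"),
    }
    genome.to_fasta(paths["genome"])
    truth.to_tsv(paths["truth"])
    write_sam(rna, genome, paths["rna_sam"])
    write_fastq(rna, paths["rna_fastq"])
    write_sam(dna, genome, paths["dna_sam"])
    return paths
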