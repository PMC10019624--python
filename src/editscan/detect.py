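"""De novo editing-site detection from RNA/DNA pileups.

Candidate positions are RNA mismatches against the reference that pass
depth/level/support filters and are homozygous-reference in DNA; each
candidate is tested against the sequencing-error null with an exact
upper-tail binomial test and the battery is FDR-controlled with a
Benjamini-Hochberg step-up using a conservative genome-sized test count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binom

from editscan.genome import BASE_INDEX, BASES, Genome, complement

logger = logging.getLogger(__name__)


class InvalidCallError(ValueError):
    pass


class FormatError(ValueError):
    pass


# --------------------------------------------------------------- mismatches

def _canonical(ref: str, alt: str) -> Tuple[str, str]:
    rc = (complement(ref), complement(alt))
    return min((ref, alt), rc)


def classify_mismatch(ref: str, alt: str) -> str:
    """Collapse an ordered substitution into its unstranded class label.

    A substitution and its joint reverse-complement are indistinguishable
    in a non-strand-specific library, so the 12 ordered pairs collapse
    into 6 classes, labelled e.g. ``"A>G/T>C"``.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise InvalidCallError(f"ref and alt are both {ref!r}")
    if ref not in BASES or alt not in BASES:
        raise InvalidCallError(f"invalid bases {ref!r}->{alt!r}")
    r, a = _canonical(ref, alt)
    return f"{r}>{a}/{complement(r)}>{complement(a)}"


MISMATCH_CLASSES: Tuple[str, ...] = tuple(
    sorted({classify_mismatch(r, a) for r in BASES for a in BASES if r != a})
)

AG_CLASS = classify_mismatch("A", "G")  # "A>G/T>C"


# ------------------------------------------------------------------ pileup

@dataclass
class Pileup:
    """Per-contig (L, 4) arrays of base counts in A,C,G,T order."""

    counts: Dict[str, np.ndarray]

    def depth(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=1)

    def column(self, contig: str, position: int) -> np.ndarray:
        return self.counts[contig][position]

    @property
    def contigs(self) -> List[str]:
        return list(self.counts)


def build_pileup(
    alignments: str | Iterable, genome: Genome, base_quality_min: int = 20
) -> Pileup:
    """Count aligned bases per position, dropping bases below the quality cut.

    ``alignments`` is a SAM path (read with pysam) or an iterable of
    pysam AlignedSegment. Reverse-strand reads contribute their stored,
    already reference-oriented bases.
    """
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, "r", check_sq=False) as fh:
            return _pileup_from_records(fh, genome, base_quality_min)
    return _pileup_from_records(alignments, genome, base_quality_min)


def _pileup_from_records(records, genome: Genome, base_quality_min: int) -> Pileup:
    pos_acc: Dict[str, List[np.ndarray]] = {c: [] for c in genome.contigs}
    base_acc: Dict[str, List[np.ndarray]] = {c: [] for c in genome.contigs}
    for aln in records:
        if aln.is_unmapped:
            continue
        contig = aln.reference_name
        if contig not in pos_acc:
            raise FormatError(f"read {aln.query_name!r} references unknown contig {contig!r}")
        seq = aln.query_alignment_sequence
        quals = aln.query_alignment_qualities
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        base_idx = np.full(raw.shape, -1, dtype=np.int8)
        for base, idx in BASE_INDEX.items():
            base_idx[raw == ord(base)] = idx
        keep = base_idx >= 0
        if quals is not None:
            keep &= np.asarray(quals, dtype=np.int16) >= base_quality_min
        if aln.cigartuples and len(aln.cigartuples) == 1 and aln.cigartuples[0][0] in (0, 7, 8):
            ref_pos = aln.reference_start + np.arange(len(seq))
        else:  # general path: per-base reference positions from the CIGAR
            pairs = aln.get_aligned_pairs(matches_only=True)
            offset = aln.query_alignment_start
            qmap = np.full(len(seq), -1, dtype=np.int64)
            for q, r in pairs:
                qi = q - offset
                if 0 <= qi < len(seq):
                    qmap[qi] = r
            ref_pos = qmap
            keep &= qmap >= 0
        pos_acc[contig].append(ref_pos[keep])
        base_acc[contig].append(base_idx[keep])
    counts: Dict[str, np.ndarray] = {}
    for contig in genome.contigs:
        length = genome.length(contig)
        arr = np.zeros((length, 4), dtype=np.int64)
        if pos_acc[contig]:
            pos = np.concatenate(pos_acc[contig]).astype(np.int64)
            bidx = np.concatenate(base_acc[contig]).astype(np.int64)
            flat = np.bincount(pos * 4 + bidx, minlength=length * 4)
            arr = flat.reshape(length, 4)
        counts[contig] = arr
    return Pileup(counts)


# ----------------------------------------------------------------- testing

def site_pvalue(n: int, k: int, e: float):
    """Upper tail P(X >= k) for X ~ Binomial(n, e/3).

    The null is that all k alt reads of one specific alternative allele
    arose from uniform sequencing error at per-base rate ``e``.
    Accepts scalars or arrays.
    """
    n_arr = np.asarray(n)
    k_arr = np.asarray(k)
    if np.any(k_arr > n_arr) or np.any(k_arr < 0):
        raise InvalidCallError("require 0 <= k <= n")
    if not 0.0 <= e < 1.0:
        raise InvalidCallError("require 0 <= e < 1")
    p = binom.sf(k_arr - 1, n_arr, e / 3.0)
    if np.isscalar(n) and np.isscalar(k):
        return float(p)
    return p


def bh_adjust(p_values: Sequence[float], m_tests: int) -> np.ndarray:
    """Benjamini-Hochberg step-up with an external (conservative) test count.

    q_(i) = min_{j >= i} p_(j) * m_tests / j over the ascending-sorted
    list, capped at 1; input order is restored on return.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() <= 0.0 or p.max() > 1.0):
        raise InvalidCallError("p-values must lie in (0, 1]")
    if m_tests < p.size:
        raise InvalidConfig("m_tests smaller than number of candidates")
    if p.size == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_tests / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


class InvalidConfig(ValueError):
    pass


@dataclass
class DetectionParams:
    """Filters and test configuration for :func:`detect_sites`.

    ``error_rate`` defaults to the Phred-implied error at the base-quality
    cutoff (10^(-Q/10)); ``m_tests`` defaults to the genome length.
    """

    min_depth: int = 5
    min_level: float = 0.0
    min_alt_reads: int = 2
    base_quality_min: int = 20
    error_rate: Optional[float] = None
    m_tests: Optional[int] = None
    fdr_level: float = 0.05
    dna_min_depth: int = 5
    dna_max_alt: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise InvalidConfig("fdr_level must be in (0, 1)")

    @property
    def effective_error_rate(self) -> float:
        if self.error_rate is not None:
            return self.error_rate
        return 10.0 ** (-self.base_quality_min / 10.0)


SITE_COLUMNS = [
    "contig",
    "position",
    "ref",
    "mismatch_class",
    "depth",
    "alt_count",
    "level",
    "p",
    "q",
    "dna_depth",
    "dna_alt",
    "ambiguous",
]


def detect_sites(
    rna_pileup: Pileup,
    dna_pileup: Pileup,
    genome: Genome,
    params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Call editing sites; returns a site table sorted by (contig, position).

    A position is a candidate iff RNA depth >= min_depth, the single most
    frequent non-reference allele has >= min_alt_reads reads and level >=
    min_level, and the DNA pileup is homozygous reference there (depth >=
    dna_min_depth, non-reference reads <= dna_max_alt). Candidates without
    adequate DNA coverage are dropped and counted. Reported sites satisfy
    q <= fdr_level after BH adjustment over all candidates.
    """
    params = params or DetectionParams()
    m_tests = params.m_tests if params.m_tests is not None else genome.total_length
    e = params.effective_error_rate

    frames: List[pd.DataFrame] = []
    n_dna_uncovered = 0
    for contig in genome.contigs:
        counts = rna_pileup.counts[contig]
        depth = counts.sum(axis=1)
        ref_idx = genome.as_index_array(contig)
        valid_ref = ref_idx >= 0
        safe_ref = np.where(valid_ref, ref_idx, 0)
        alt_counts = counts.copy()
        alt_counts[np.arange(len(counts)), safe_ref] = 0
        best_alt = alt_counts.argmax(axis=1)  # first max = alphabetical tie-break
        k = alt_counts[np.arange(len(counts)), best_alt]
        n_ties = (alt_counts == k[:, None]).sum(axis=1)
        ambiguous = (n_ties > 1) & (k > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(depth > 0, k / np.maximum(depth, 1), 0.0)

        cand = (
            valid_ref
            & (depth >= params.min_depth)
            & (k >= params.min_alt_reads)
            & (level >= params.min_level)
        )
        if not cand.any():
            continue
        pos = np.flatnonzero(cand)

        dna_counts = dna_pileup.counts[contig][pos]
        dna_depth = dna_counts.sum(axis=1)
        # homozygosity is judged against the candidate's own alt allele
        dna_alt = dna_counts[np.arange(len(pos)), best_alt[pos]]
        covered = dna_depth >= params.dna_min_depth
        n_dna_uncovered += int((~covered).sum())
        homozygous = covered & (dna_alt <= params.dna_max_alt)
        pos = pos[homozygous]
        if pos.size == 0:
            continue
        dna_depth = dna_depth[homozygous]
        dna_alt = dna_alt[homozygous]

        refs = [BASES[i] for i in ref_idx[pos]]
        alts = [BASES[i] for i in best_alt[pos]]
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "position": pos,
                    "ref": refs,
                    "mismatch_class": [
                        classify_mismatch(r, a) for r, a in zip(refs, alts)
                    ],
                    "depth": depth[pos],
                    "alt_count": k[pos],
                    "level": level[pos],
                    "dna_depth": dna_depth,
                    "dna_alt": dna_alt,
                    "ambiguous": ambiguous[pos],
                }
            )
        )
    if n_dna_uncovered:
        logger.info("dropped %d candidate(s) without adequate DNA coverage", n_dna_uncovered)
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    table["p"] = site_pvalue(table["depth"].to_numpy(), table["alt_count"].to_numpy(), e)
    table["p"] = np.clip(table["p"].to_numpy(), np.finfo(float).tiny, 1.0)
    table["q"] = bh_adjust(table["p"].to_numpy(), m_tests)
    table = table[table["q"] <= params.fdr_level]
    table = table.sort_values(["contig", "position"], kind="stable", ignore_index=True)
    return table.reindex(columns=SITE_COLUMNS)


def mismatch_spectrum(sites: pd.DataFrame) -> Tuple[Dict[str, int], float]:
    """Counts per mismatch class plus the A>G/T>C fraction (0 if empty)."""
    spectrum = {label: 0 for label in MISMATCH_CLASSES}
    for label, count in sites["mismatch_class"].value_counts().items():
        spectrum[label] = int(count)
    total = sum(spectrum.values())
    fraction = spectrum[AG_CLASS] / total if total else 0.0
    return spectrum, fraction


# ----------------------------------------------------------------- site IO

def write_site_table(sites: pd.DataFrame, path: str) -> None:
    """TSV with 1-based positions at the format boundary."""
    out = sites.copy()
    out.insert(1, "pos_1based", out.pop("position") + 1)
    out.to_csv(path, sep="\t", index=False)


def read_site_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.insert(1, "position", df.pop("pos_1based") - 1)
    return df
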