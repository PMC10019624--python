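"""Genome-wide editing quantification: index, level histogram,
replicate recurrence, and the neighbour-nucleotide motif."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from editscan.detect import AG_CLASS, MISMATCH_CLASSES, Pileup, classify_mismatch
from editscan.genome import BASE_INDEX, BASES, Genome, complement

_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space


class UndefinedIndexError(ValueError):
    """No informative reads: the editing index is undefined."""


@dataclass
class ClassIndex:
    numerator: int
    denominator: int

    @property
    def index(self) -> float:
        """Edited-allele read percentage."""
        if self.denominator == 0:
            raise UndefinedIndexError("zero denominator")
        return 100.0 * self.numerator / self.denominator


@dataclass
class EditingIndexResult:
    """Read-weighted editing percentages, overall (A>G/T>C) and per class."""

    per_class: Dict[str, ClassIndex]

    @property
    def numerator(self) -> int:
        return self.per_class[AG_CLASS].numerator

    @property
    def denominator(self) -> int:
        return self.per_class[AG_CLASS].denominator

    @property
    def index(self) -> float:
        return self.per_class[AG_CLASS].index

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        return {
            label: {
                "numerator": ci.numerator,
                "denominator": ci.denominator,
                "index_percent": (ci.index if ci.denominator else float("nan")),
            }
            for label, ci in self.per_class.items()
        }


def _class_pairs() -> Dict[str, Tuple[Tuple[str, str], Tuple[str, str]]]:
    """Map each class label to its two (ref, alt) orientations."""
    out = {}
    for ref in BASES:
        for alt in BASES:
            if ref == alt:
                continue
            label = classify_mismatch(ref, alt)
            if label not in out:
                out[label] = ((ref, alt), (complement(ref), complement(alt)))
    return out


def editing_index(
    rna_pileup: Pileup,
    genome: Genome,
    dna_pileup: Optional[Pileup] = None,
    exclude_dna_variants: bool = False,
) -> EditingIndexResult:
    """Pooled unstranded editing index over the whole genome, per class.

    For the A>G/T>C class: numerator = G reads at reference-A positions
    plus C reads at reference-T positions; denominator = (A+G) reads at
    reference-A positions plus (T+C) reads at reference-T positions; the
    index is 100*numerator/denominator. Other classes are built the same
    way from their own base pairs. With ``exclude_dna_variants`` any
    position carrying a DNA-supported non-reference read is excluded.
    """
    totals = {label: [0, 0] for label in MISMATCH_CLASSES}
    any_reads = False
    for contig in rna_pileup.contigs:
        counts = rna_pileup.counts[contig]
        ref_idx = genome.as_index_array(contig)
        keep = ref_idx >= 0
        if exclude_dna_variants and dna_pileup is not None:
            dna = dna_pileup.counts[contig]
            dna_ref = dna[np.arange(len(dna)), np.where(keep, ref_idx, 0)]
            keep &= (dna.sum(axis=1) - dna_ref) == 0
        if counts.sum():
            any_reads = True
        for label, ((r1, a1), (r2, a2)) in _class_pairs().items():
            num = 0
            den = 0
            for r, a in ((r1, a1), (r2, a2)):
                mask = keep & (ref_idx == BASE_INDEX[r])
                num += int(counts[mask, BASE_INDEX[a]].sum())
                den += int(
                    counts[mask, BASE_INDEX[a]].sum() + counts[mask, BASE_INDEX[r]].sum()
                )
            totals[label][0] += num
            totals[label][1] += den
    if not any_reads:
        raise UndefinedIndexError("pileup contains no reads")
    return EditingIndexResult(
        per_class={label: ClassIndex(num, den) for label, (num, den) in totals.items()}
    )


def level_histogram(
    sites: pd.DataFrame, bin_width: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Histogram of per-site editing levels over [0, 1].

    Returns (bin_edges, counts); level 1.0 falls in the top bin.
    """
    levels = sites["level"].to_numpy(dtype=float) if len(sites) else np.array([])
    if len(levels) and (levels.min() < 0 or levels.max() > 1):
        raise ValueError("levels must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(levels, bins=n_bins, range=(0.0, 1.0))
    return edges, counts


@dataclass
class RecurrenceResult:
    exactly_k: Dict[int, int]
    at_least_k: Dict[int, int]
    union_size: int
    intersection_size: int

    @property
    def recurrent_fraction(self) -> float:
        """Fraction of distinct sites present in every replicate."""
        n = max(self.exactly_k) if self.exactly_k else 0
        if self.union_size == 0:
            return 0.0
        return self.exactly_k.get(n, 0) / self.union_size


def replicate_recurrence(site_tables: Sequence[pd.DataFrame]) -> RecurrenceResult:
    """Recurrence of sites across replicate tables.

    Site identity is (contig, position, mismatch_class); strand is not
    observable from an unstranded library.
    """
    if len(site_tables) < 2:
        raise ValueError("need at least two replicate tables")
    n_rep = len(site_tables)
    tally: Dict[Tuple, int] = {}
    for table in site_tables:
        keys = set(
            zip(table["contig"], table["position"], table["mismatch_class"])
        )
        for key in keys:
            tally[key] = tally.get(key, 0) + 1
    counts = np.array(list(tally.values()), dtype=int) if tally else np.array([], dtype=int)
    exactly = {k: int((counts == k).sum()) for k in range(1, n_rep + 1)}
    at_least = {k: int((counts >= k).sum()) for k in range(1, n_rep + 1)}
    return RecurrenceResult(
        exactly_k=exactly,
        at_least_k=at_least,
        union_size=len(tally),
        intersection_size=exactly.get(n_rep, 0) if tally else 0,
    )


def recurrence_percent(recurrent: int, total: int) -> int:
    """Percentage of recurrent sites, rounded to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * recurrent / total))


@dataclass
class MotifMatrix:
    """Per-offset nucleotide frequencies around edited adenosines.

    Offsets run -k..-1, +1..+k relative to the site (edited-A orientation);
    ``background`` holds the same frequencies over all genomic adenosines.
    """

    offsets: List[int]
    frequencies: pd.DataFrame  # index: offset, columns: A C G T
    background: pd.DataFrame
    n_sites: int
    n_skipped: int = 0


def _context_counts(
    genome: Genome, positions: Dict[str, Tuple[np.ndarray, np.ndarray]], k: int
) -> Tuple[np.ndarray, int]:
    """Accumulate base counts at each offset for (fwd, rev) position sets.

    Forward positions are read as-is; reverse positions (reference T,
    adenosine on the minus strand) contribute the complement at the
    mirrored offset. Returns (counts[2k, 4], n_skipped_at_edges).
    """
    offsets = [o for o in range(-k, k + 1) if o != 0]
    counts = np.zeros((len(offsets), 4), dtype=np.int64)
    skipped = 0
    for contig, (fwd, rev) in positions.items():
        idx = genome.as_index_array(contig)
        length = len(idx)
        for pos_set, is_rev in ((fwd, False), (rev, True)):
            if pos_set.size == 0:
                continue
            ok = (pos_set >= k) & (pos_set < length - k)
            skipped += int((~ok).sum())
            pos_set = pos_set[ok]
            for oi, off in enumerate(offsets):
                genome_off = -off if is_rev else off
                bases = idx[pos_set + genome_off]
                valid = bases >= 0
                bases = bases[valid]
                if is_rev:
                    bases = _COMP_IDX[bases]
                counts[oi] += np.bincount(bases, minlength=4)
    return counts, skipped


def neighbor_motif(sites: pd.DataFrame, genome: Genome, k: int = 1) -> MotifMatrix:
    """Nucleotide frequencies at offsets around sites, edited-A oriented.

    A>G/T>C sites whose reference base is T sit on the minus strand and
    are reverse-complemented before accumulation. Background frequencies
    come from every genomic adenosine (both strands, same orientation
    convention). Sites too close to a contig edge are skipped and counted.
    """
    offsets = [o for o in range(-k, k + 1) if o != 0]
    site_pos: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for contig, group in sites.groupby("contig", sort=False):
        fwd = group.loc[group["ref"].isin(["A", "C"]), "position"].to_numpy(dtype=int)
        rev = group.loc[~group["ref"].isin(["A", "C"]), "position"].to_numpy(dtype=int)
        site_pos[contig] = (fwd, rev)
    site_counts, skipped = _context_counts(genome, site_pos, k)

    bg_pos: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for contig in genome.contigs:
        idx = genome.as_index_array(contig)
        bg_pos[contig] = (np.flatnonzero(idx == 0), np.flatnonzero(idx == 3))
    bg_counts, _ = _context_counts(genome, bg_pos, k)

    def _freq(counts: np.ndarray) -> pd.DataFrame:
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freq = np.where(totals > 0, counts / np.maximum(totals, 1), np.nan)
        return pd.DataFrame(freq, index=offsets, columns=list(BASES))

    return MotifMatrix(
        offsets=offsets,
        frequencies=_freq(site_counts),
        background=_freq(bg_counts),
        n_sites=len(sites),
        n_skipped=skipped,
    )
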