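"""Reference genome container and FASTA round-trip.

Coordinates are 0-based, half-open throughout; 1-based appears only at
format boundaries (SAM, BED-derived TSVs).
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

#: canonical base order used for all count arrays
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U treated as T; N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class Genome:
    """Named contigs of A/C/G/T(/N) sequence, mutable in place.

    Sequences are stored as bytearrays so simulation code can plant
    structure (inverted repeats) without copying whole contigs.
    """

    def __init__(self, contigs: Dict[str, str] | None = None):
        self._seqs: Dict[str, bytearray] = {}
        if contigs:
            for name, seq in contigs.items():
                self.add_contig(name, seq)

    def add_contig(self, name: str, seq: str) -> None:
        if len(seq) == 0:
            raise ValueError(f"contig {name!r} has zero length")
        if name in self._seqs:
            raise ValueError(f"duplicate contig name {name!r}")
        self._seqs[name] = bytearray(seq.upper().encode("ascii"))

    @property
    def contigs(self) -> List[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name].decode("ascii")

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def base(self, name: str, pos: int) -> str:
        return chr(self._seqs[name][pos])

    def fetch(self, name: str, start: int, end: int) -> str:
        """Sequence of [start, end) clamped to contig bounds."""
        start = max(start, 0)
        end = min(end, len(self._seqs[name]))
        return self._seqs[name][start:end].decode("ascii")

    def set_slice(self, name: str, start: int, seq: str) -> None:
        """Overwrite contig bases in [start, start+len(seq))."""
        if start < 0 or start + len(seq) > len(self._seqs[name]):
            raise ValueError("slice outside contig bounds")
        self._seqs[name][start : start + len(seq)] = seq.upper().encode("ascii")

    def as_index_array(self, name: str) -> np.ndarray:
        """Contig as int8 array: A,C,G,T -> 0..3, anything else -> -1."""
        raw = np.frombuffer(bytes(self._seqs[name]), dtype=np.uint8)
        out = np.full(raw.shape, -1, dtype=np.int8)
        for base, idx in BASE_INDEX.items():
            out[raw == ord(base)] = idx
        return out

    def items(self) -> Iterator[Tuple[str, str]]:
        for name in self._seqs:
            yield name, self[name]

    # ---------------------------------------------------------------- FASTA
    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(self[name]), id=name, description="") for name in self._seqs
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        genome = cls()
        for rec in SeqIO.parse(path, "fasta"):
            genome.add_contig(rec.id, str(rec.seq))
        return genome
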