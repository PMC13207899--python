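"""Genome containers and base-level utilities.

Sequences are held as ``uint8`` code arrays (A=0, C=1, G=2, T=3) so that
base-composition queries, reverse complementation and trinucleotide counting
stay vectorised.  Coordinates follow the conventions of the formats they feed:
BED/bedGraph are 0-based half-open, GFF3/VCF/cytosine reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import IntervalSet

BASES = "ACGT"
A, C, G, T = range(4)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: complement of each base code (A<->T, C<->G)
COMP = np.array([T, G, C, A], dtype=np.uint8)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string into a uint8 code array.

    Raises ``ValueError`` on any character outside ACGT (case-insensitive);
    ambiguity codes are not supported in the synthetic pipeline.
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({ch for ch in seq if ch.upper() not in BASES})
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an ACGT string."""
    return _CHAR[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array."""
    return COMP[np.asarray(codes, dtype=np.uint8)[::-1]]


def gc_fraction(codes: np.ndarray) -> float:
    """Fraction of G+C bases."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("empty sequence")
    return float(((codes == C) | (codes == G)).mean())


@dataclass
class Transcript:
    """A protein-coding gene model: ordered CDS parts on one strand.

    ``parts`` are 0-based half-open genomic intervals sorted by start; the
    coding order is 5'->3' on the annotated strand.  The concatenated coding
    length must be a multiple of 3.
    """

    name: str
    chrom: str
    strand: str  # '+' or '-'
    parts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.parts = sorted((int(s), int(e)) for s, e in self.parts)
        for s, e in self.parts:
            if e <= s:
                raise ValueError(f"empty CDS part [{s},{e}) in {self.name}")

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def coding_positions(self) -> np.ndarray:
        """Genomic 0-based positions in coding (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.parts])
        return pos[::-1].copy() if self.strand == "-" else pos

    def coding_codes(self, sequences: dict[str, np.ndarray]) -> np.ndarray:
        """Sense-strand base codes of the concatenated CDS."""
        codes = sequences[self.chrom][self.coding_positions()]
        return COMP[codes] if self.strand == "-" else codes

    def contains(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.parts)


@dataclass
class GenomeBundle:
    """A genome with its chromatin annotation and gene models.

    ``pr`` (pericentromeric regions) is required to be a subset of the
    ``h3k9me3`` domains, mirroring the biology this pipeline targets: the
    pericentromere is the H3K9me3-richest stratum of the genome.
    """

    sequences: dict[str, np.ndarray]
    pr: IntervalSet
    h3k9me3: IntervalSet
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        leftover = self.pr.subtract(self.h3k9me3)
        if leftover.total_bp > 0:
            raise ValueError("PR intervals must lie inside H3K9me3 domains")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def seq_str(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        return decode_seq(self.sequences[chrom][slice(start, end)])

    def base_at(self, chrom: str, pos1: int) -> str:
        """Reference base (plus strand) at a 1-based position."""
        return BASES[int(self.sequences[chrom][pos1 - 1])]
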