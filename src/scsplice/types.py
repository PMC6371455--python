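"""Domain types shared across the pipeline.

Coordinates are 0-based half-open throughout; GTF input (1-based inclusive)
is converted on read.  A cassette exon is an internal exon ``A`` flanked by
two constitutive exons ``C1`` (5' in transcript orientation) and ``C2`` (3'),
separated by introns ``I1`` and ``I2``.  On the minus strand C1 therefore has
the *larger* genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

Interval = Tuple[int, int]

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Keys of the seven analysis contexts, in transcript order.
CONTEXT_KEYS = ("C1", "I1_5p", "I1_3p", "A", "I2_5p", "I2_3p", "C2")

#: The five region keys used for length features.
REGION_KEYS = ("C1", "I1", "A", "I2", "C2")

#: Five-way splicing category labels.
CATEGORIES = ("excluded", "included", "overdispersed", "underdispersed", "multimodal")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class CassetteExon:
    """One cassette-exon event: alternative exon A with flanks C1/C2.

    ``c1``, ``a``, ``c2`` are genomic intervals ordered by *transcript*
    position; ``i1``/``i2`` are the derived intronic gaps between them.
    ``distance_to_tss``/``distance_to_tts`` are genomic base-pair distances
    from A to the most extreme transcript start/end of the host gene.
    """

    exon_id: str
    chrom: str
    strand: str
    c1: Interval
    a: Interval
    c2: Interval
    gene_id: str = ""
    distance_to_tss: int = 0
    distance_to_tts: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        order = (self.c1, self.a, self.c2)
        genomic = order if self.strand == "+" else order[::-1]
        if not (genomic[0][1] <= genomic[1][0] and genomic[1][1] <= genomic[2][0]):
            raise ValueError(
                f"{self.exon_id}: exons not ordered/non-adjacent along the genome"
            )

    @property
    def i1(self) -> Interval:
        """Upstream intron (between C1 and A), genomic coordinates."""
        if self.strand == "+":
            return (self.c1[1], self.a[0])
        return (self.a[1], self.c1[0])

    @property
    def i2(self) -> Interval:
        """Downstream intron (between A and C2), genomic coordinates."""
        if self.strand == "+":
            return (self.a[1], self.c2[0])
        return (self.c2[1], self.a[0])

    @property
    def span(self) -> Interval:
        """Genomic interval from C1 start to C2 end (strand-agnostic)."""
        lo = min(self.c1[0], self.c2[0])
        hi = max(self.c1[1], self.c2[1])
        return (lo, hi)

    @property
    def region_lengths(self) -> dict:
        return {
            "C1": interval_len(self.c1),
            "I1": interval_len(self.i1),
            "A": interval_len(self.a),
            "I2": interval_len(self.i2),
            "C2": interval_len(self.c2),
        }


@dataclass
class ExonContexts:
    """The seven context sequences of a cassette exon, transcript-oriented.

    Intron-end contexts are truncated to at most 300 bp and anchored at their
    own end; for introns shorter than 600 bp the 5' and 3' contexts overlap.
    ``positions`` maps each context to the genomic (plus-strand) coordinate of
    every base of the oriented sequence, used to align methylation calls.
    """

    exon_id: str
    sequences: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]


@dataclass(frozen=True)
class CellQcStats:
    """Per-cell expression QC statistics."""

    endogenous_counts: float
    genes_nonzero: int
    top100_fraction: float
    ercc_fraction: float
    mapping_rate: float

    def __post_init__(self) -> None:
        for name in ("top100_fraction", "ercc_fraction", "mapping_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.endogenous_counts < 0 or self.genes_nonzero < 0:
            raise ValueError("counts must be non-negative")
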