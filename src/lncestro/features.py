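"""Genomic feature containers shared by the annotation-facing modules.

All coordinates are 0-based, half-open, on the forward strand of the genome;
``strand`` records which strand the feature is transcribed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CatalogueFormatError

__all__ = ["GenomicInterval", "TranscriptModel", "revcomp"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CatalogueFormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript isoform.

    ``support_count`` is the number of cDNA/EST records behind the isoform;
    isoforms supported by a single record (singletons) are excluded from the
    structure-element analysis.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    support_count: int = 2

    def __post_init__(self):
        if self.strand not in "+-":
            raise CatalogueFormatError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise CatalogueFormatError("transcript without exons")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e) or s < prev_end:
                raise CatalogueFormatError(
                    f"exons must be sorted, non-overlapping: {self.exons}"
                )
            prev_end = e
        if self.support_count < 1:
            raise CatalogueFormatError("support_count must be >= 1")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intervals between consecutive exons (forward-strand order)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Transcript (mRNA-sense) sequence from the genome."""
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq
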