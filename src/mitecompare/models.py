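"""Core coordinate and annotation model shared by every pipeline stage.

All genomic coordinates in this package are 1-based inclusive (the GFF3
convention); conversion to BED's 0-based half-open system happens only at
the export boundary in :mod:`mitecompare.readwrite`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

VALID_BASES = frozenset("ACGTN")

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when loaded data violates a model invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chromosome: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )
        if self.strand not in (STRAND_PLUS, STRAND_MINUS, STRAND_NONE):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between the nearest ends; 0 when the intervals overlap."""
        if self.chromosome != other.chromosome:
            raise ValueError("distance between intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass
class GenomeAccession:
    """One accession's genome: a name plus chromosome-name -> sequence map.

    Sequences are uppercase strings over the A, C, G, T, N alphabet.
    """

    accession_name: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValidationError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains invalid symbols: "
                    + ",".join(sorted(bad))
                )

    def sequence(self, interval: GenomicInterval) -> str:
        """Extract the (forward-strand) sequence of a 1-based interval."""
        chrom = self.chromosomes[interval.chromosome]
        if interval.end > len(chrom):
            raise ValidationError(
                f"interval {interval} exceeds chromosome length {len(chrom)}"
            )
        return chrom[interval.start - 1 : interval.end]


@dataclass
class GeneModel:
    """Strand-aware gene with ordered sub-regions.

    ``gene_id`` is the cross-accession homolog identifier: the same gene in
    different accessions carries the same ID.  Sub-region interval lists are
    ordered 5'->3' in transcription direction; ``introns`` are derived as the
    genomic gaps between consecutive CDS exons.
    """

    gene_id: str
    locus: GenomicInterval
    five_prime_utr: list[GenomicInterval] = field(default_factory=list)
    cds_exons: list[GenomicInterval] = field(default_factory=list)
    three_prime_utr: list[GenomicInterval] = field(default_factory=list)
    is_novel: bool = False

    def __post_init__(self) -> None:
        for iv in self.five_prime_utr + self.cds_exons + self.three_prime_utr:
            if iv.chromosome != self.locus.chromosome:
                raise ValidationError(
                    f"{self.gene_id}: sub-region on wrong chromosome"
                )
            if iv.start < self.locus.start or iv.end > self.locus.end:
                raise ValidationError(
                    f"{self.gene_id}: sub-region {iv.start}-{iv.end} outside "
                    f"gene bounds {self.locus.start}-{self.locus.end}"
                )
        self._order_subregions()

    def _order_subregions(self) -> None:
        forward = self.strand != STRAND_MINUS
        for lst in (self.five_prime_utr, self.cds_exons, self.three_prime_utr):
            lst.sort(key=lambda iv: iv.start, reverse=not forward)

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive CDS exons, 5'->3' in transcription order."""
        exons = sorted(self.cds_exons, key=lambda iv: iv.start)
        gaps = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end + 1:
                gaps.append(
                    GenomicInterval(self.locus.chromosome, a.end + 1, b.start - 1,
                                    self.strand)
                )
        if self.strand == STRAND_MINUS:
            gaps.reverse()
        return gaps

    @property
    def last_exon(self) -> GenomicInterval | None:
        """The 3'-most CDS exon in transcription direction."""
        if not self.cds_exons:
            return None
        exons = sorted(self.cds_exons, key=lambda iv: iv.start)
        return exons[0] if self.strand == STRAND_MINUS else exons[-1]

    def subregions(self) -> list[tuple[str, GenomicInterval]]:
        """(label, interval) pairs, ordered 5'->3' in transcription direction."""
        out: list[tuple[str, GenomicInterval]] = []
        out += [("5'UTR", iv) for iv in self.five_prime_utr]
        out += [("CDS-exon", iv) for iv in self.cds_exons]
        out += [("intron", iv) for iv in self.introns]
        out += [("3'UTR", iv) for iv in self.three_prime_utr]
        reverse = self.strand == STRAND_MINUS
        out.sort(key=lambda pair: pair[1].start, reverse=reverse)
        return out


class ExpressionTable:
    """Gene x accession RPKM matrix.

    Wraps a :class:`pandas.DataFrame` indexed by gene ID with one column per
    accession.  Missing values (``NaN``) are allowed and are distinct from
    zero; negative values are rejected.
    """

    def __init__(self, frame: pd.DataFrame):
        if (frame.to_numpy() < 0).any():
            raise ValidationError("expression table contains negative RPKM values")
        self.frame = frame.copy()
        self.frame.index.name = "gene_id"

    @classmethod
    def from_records(
        cls, values: Mapping[tuple[str, str], float]
    ) -> "ExpressionTable":
        ser = pd.Series(dict(values))
        frame = ser.unstack()
        return cls(frame)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.frame.columns)

    def value(self, gene_id: str, accession: str) -> float:
        return float(self.frame.at[gene_id, accession])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionTable) and self.frame.equals(other.frame)


def as_interval_table(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chromosome": iv.chromosome, "start": iv.start, "end": iv.end,
             "strand": iv.strand}
            for iv in intervals
        ],
        columns=["chromosome", "start", "end", "strand"],
    )
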