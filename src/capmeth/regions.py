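"""Core genomic interval types.

All coordinates are 0-based, half-open (BED convention). One-based input
formats are converted at the I/O boundary, never here.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if they touch or overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class TargetRegion:
    """A capture target region: the unit of methylation quantification."""

    interval: GenomicInterval
    region_id: str

    def __post_init__(self) -> None:
        if not self.region_id:
            raise ValueError("region_id must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def check_unique_ids(regions: list[TargetRegion]) -> None:
    seen: set[str] = set()
    for r in regions:
        if r.region_id in seen:
            raise ValueError(f"duplicate region_id: {r.region_id}")
        seen.add(r.region_id)


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model.

    ``cds`` empty means a noncoding gene. Exons must be sorted,
    non-overlapping and contained in the transcript; every CDS segment
    must lie inside an exon.
    """

    gene_id: str
    strand: str
    transcript: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.transcript.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.transcript.start or ex.end > self.transcript.end:
                raise ValueError(f"gene {self.gene_id}: exon outside transcript")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = ex.end
        for c in self.cds:
            if not any(c.start >= ex.start and c.end <= ex.end for ex in self.exons):
                raise ValueError(f"gene {self.gene_id}: CDS segment outside exons")

    @property
    def coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def chrom(self) -> str:
        return self.transcript.chrom

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (strand-aware)."""
        return self.transcript.start if self.strand == "+" else self.transcript.end - 1
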