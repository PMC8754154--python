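"""Genomic intervals and gene annotations.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based closed, is converted on read by :mod:`ttkinetics.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def five_prime(self) -> int:
        """5' end position in the interval's own orientation."""
        return self.start if self.strand != "-" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand != "-" else self.start


@dataclass
class Gene:
    """A gene with its exon structure.

    ``tss``/``tes`` are strand-aware: for a minus-strand gene the TSS is the
    interval end and the TES the interval start.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.strand != self.interval.strand or ex.chrom != self.interval.chrom:
                raise ValueError(f"exon of {self.gene_id} off-strand or off-chrom")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon of {self.gene_id} outside gene interval")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.five_prime

    @property
    def tes(self) -> int:
        return self.interval.three_prime

    @property
    def last_exon_end(self) -> int:
        """3'-most exon boundary in gene orientation (falls back to the TES)."""
        if not self.exons:
            return self.tes
        if self.strand == "-":
            return min(ex.start for ex in self.exons)
        return max(ex.end for ex in self.exons)

    def body(self, offset: int = 0) -> GenomicInterval:
        """Gene body from TSS+offset to TES, in gene orientation."""
        if self.strand == "-":
            start, end = self.interval.start, self.interval.end - offset
        else:
            start, end = self.interval.start + offset, self.interval.end
        if start >= end:
            raise ValueError(f"offset {offset} exceeds gene {self.gene_id} length")
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class GenomeAnnotation:
    """A set of genes plus chromosome sizes; the coordinate frame for the pipeline."""

    genes: list[Gene]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_ids must be unique")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def on_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def next_downstream_tss(self, gene: Gene, same_strand_only: bool = False):
        """Nearest TSS of another gene strictly downstream of ``gene``'s 3' end.

        Distance is measured in ``gene``'s orientation; returns None if no such
        gene exists on the chromosome.
        """
        best = None
        for other in self.on_chrom(gene.chrom):
            if other.gene_id == gene.gene_id:
                continue
            if same_strand_only and other.strand != gene.strand:
                continue
            d = (other.tss - gene.tes) if gene.strand != "-" else (gene.tes - other.tss)
            if d > 0 and (best is None or d < best[1]):
                best = (other, d)
        return best
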