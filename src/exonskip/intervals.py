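"""Core genomic coordinate types.

All internal coordinates are 0-based, half-open ``[start, end)``. The
1-based conventions of GTF and VCF are converted at the file boundary
(see :mod:`exonskip.io_formats`) so that only one conversion site exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Whether a 0-based position falls inside the interval."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene's ordered, disjoint exon counting bins.

    Overlapping exon records from annotation are flattened into disjoint
    bins by breakpoint union before a model is built, so reads over each
    bin can be counted unambiguously.

    Parameters
    ----------
    gene_id
        Gene identifier.
    intervals
        Exon bins sorted by start, pairwise non-overlapping, all on one
        chromosome and strand.
    exon_ids
        One identifier per bin, ``"<gene_id>:E001"``-style, unique within
        the gene.
    cds_flags
        Per-bin flag marking bins that are (partly) coding.
    phase
        Per-bin CDS phase in {0, 1, 2} for coding bins, ``None`` otherwise.
    cds_lengths
        Nucleotides of each bin that lie within the CDS (equals the bin
        length for fully coding bins, 0 for non-coding ones).
    """

    gene_id: str
    intervals: list[GenomicInterval]
    exon_ids: list[str]
    cds_flags: list[bool] = field(default_factory=list)
    phase: list[int | None] = field(default_factory=list)
    cds_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if len(self.exon_ids) != n:
            raise ValueError("exon_ids and intervals must have equal length")
        if len(set(self.exon_ids)) != n:
            raise ValueError(f"duplicate exon ids in gene {self.gene_id}")
        starts = [iv.start for iv in self.intervals]
        if starts != sorted(starts):
            raise ValueError(f"exon bins of {self.gene_id} are not sorted")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping bins in {self.gene_id}: {a} vs {b}"
                )
        if not self.cds_flags:
            self.cds_flags = [False] * n
        if not self.cds_lengths:
            self.cds_lengths = [
                len(iv) if f else 0 for iv, f in zip(self.intervals, self.cds_flags)
            ]
        if not self.phase:
            # phase = bases to the next codon start, accumulated in
            # translation order (genomic order on +, reversed on -)
            self.phase = [None] * n
            idx = range(n) if self.strand == "+" else range(n - 1, -1, -1)
            cum = 0
            for i in idx:
                if self.cds_lengths[i] > 0:
                    self.phase[i] = (3 - cum % 3) % 3
                    cum += self.cds_lengths[i]

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def span(self) -> GenomicInterval:
        """The genomic interval from the first to the last exon bin."""
        return GenomicInterval(
            self.chrom, self.intervals[0].start, self.intervals[-1].end, self.strand
        )

    def n_exons(self) -> int:
        return len(self.intervals)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exon bins, in genomic order."""
        out = []
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def exon_index(self, exon_id: str) -> int:
        return self.exon_ids.index(exon_id)


def flatten_exons(records: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Split possibly-overlapping exon records into disjoint counting bins.

    Takes 0-based half-open ``(start, end)`` pairs and returns the disjoint
    bins obtained from the union of all interval breakpoints, restricted to
    regions covered by at least one record.

    >>> flatten_exons([(99, 200), (149, 250)])
    [(99, 149), (149, 200), (200, 250)]
    """
    if not records:
        return []
    points = sorted({p for s, e in records for p in (s, e)})
    bins = []
    for lo, hi in zip(points, points[1:]):
        if any(s <= lo and hi <= e for s, e in records):
            bins.append((lo, hi))
    return bins


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV, VCF 1-based position convention."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float | None = None

    def __post_init__(self) -> None:
        bases = {"A", "C", "G", "T"}
        if self.ref not in bases or self.alt not in bases:
            raise ValueError(f"ref/alt must be single ACGT bases: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt for {self.id}")
        if self.maf is not None and not (0 < self.maf <= 0.5):
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1
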