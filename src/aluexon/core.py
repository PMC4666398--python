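"""Coordinate conventions, interval algebra and strand-aware ordering.

All coordinates in this package are 0-based, half-open (BED convention);
GTF readers/writers convert from/to 1-based closed at the boundary.  A
polyadenylation "site" is a single cleavage position (the strand-wise
3'-most base when the input track gives an interval).

Strand-aware ordering: "downstream" means further along the direction of
transcription, i.e. larger genomic coordinates on the plus strand and
smaller ones on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with a mandatory strand.

    The coordinate atom for exons, Alu elements and polyA sites.
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the first base in transcription direction."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Position of the last base in transcription direction."""
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SpliceJunction:
    """A splice junction seen as an exact intron gap in split reads.

    ``donor`` is the first intronic base at the 5' splice site and
    ``acceptor`` the last intronic base at the 3' splice site, both in
    transcription direction: on the plus strand donor < acceptor, on the
    minus strand donor > acceptor in genomic coordinates.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor positions must differ")
        if self.strand == "+" and not self.donor < self.acceptor:
            raise ValueError("plus-strand junction requires donor < acceptor")
        if self.strand == "-" and not self.donor > self.acceptor:
            raise ValueError("minus-strand junction requires donor > acceptor")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")

    @classmethod
    def from_gap(
        cls, chrom: str, gap_start: int, gap_end: int, strand: str, read_count: int = 0
    ) -> "SpliceJunction":
        """Build from a genomic intron gap [gap_start, gap_end)."""
        if strand == "+":
            return cls(chrom, gap_start, gap_end - 1, strand, read_count)
        return cls(chrom, gap_end - 1, gap_start, strand, read_count)

    @property
    def gap(self) -> tuple[int, int]:
        """The intron as a half-open genomic interval (gap_start, gap_end)."""
        if self.strand == "+":
            return (self.donor, self.acceptor + 1)
        return (self.acceptor, self.donor + 1)


@dataclass(frozen=True)
class AlignedRead:
    """A split-aligned read as ordered aligned blocks on one chrom/strand.

    A gap between consecutive blocks is a splice junction.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if len(self.blocks) < 1:
            raise ValueError("a read needs at least one aligned block")
        for b in self.blocks:
            if b.chrom != self.chrom or b.strand != self.strand:
                raise ValueError("all blocks must share the read's chrom and strand")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start - a.end < 1:
                raise ValueError("consecutive blocks must be sorted with gap >= 1")

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Intron gaps [gap_start, gap_end) between consecutive blocks."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])
        )

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass
class Transcript:
    """A transcript as a sorted tuple of exon intervals on one strand."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise ValueError("transcript needs at least one exon")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def terminal_exon(self) -> GenomicInterval:
        """Strand-wise last exon (contains the 3' UTR)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def three_prime_end(self) -> int:
        """Position of the transcript's last transcribed base."""
        return self.terminal_exon.three_prime

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """Gene with transcripts and the set of genuine polyA cleavage positions."""

    gene_id: str
    transcripts: list[Transcript] = field(default_factory=list)
    polya_sites: list[int] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand, self.gene_id)

    @property
    def exons(self) -> list[GenomicInterval]:
        out, seen = [], set()
        for t in self.transcripts:
            for e in t.exons:
                key = (e.start, e.end)
                if key not in seen:
                    seen.add(key)
                    out.append(e)
        return sorted(out, key=lambda e: e.start)

    def last_polya(self) -> int:
        """Strand-wise most downstream genuine polyA site of the gene.

        Falls back to the strand-wise gene 3' end when no site is annotated
        (callers log a warning in that case).
        """
        if self.polya_sites:
            return (
                max(self.polya_sites) if self.strand == "+" else min(self.polya_sites)
            )
        return self.span.three_prime


def overlaps(
    a: GenomicInterval, b: GenomicInterval, require_same_strand: bool = False
) -> bool:
    """True iff the two half-open intervals share >= 1 bp on one chromosome.

    Adjacent intervals ([10,20) vs [20,30)) never overlap.
    """
    if a.chrom != b.chrom:
        return False
    if require_same_strand and a.strand != b.strand:
        return False
    return max(a.start, b.start) < min(a.end, b.end)


def is_downstream(point: int, reference: int, strand: str) -> bool:
    """True iff ``point`` lies downstream of ``reference`` in transcription direction.

    Equality is not downstream.  Both positions are assumed to be on one
    chromosome.
    """
    if strand not in STRANDS:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return point > reference if strand == "+" else point < reference


def transcription_distance(from_pos: int, to_pos: int, strand: str) -> int:
    """Genomic separation in bp from ``from_pos`` to a downstream ``to_pos``.

    Measured from a polyA cleavage position to the gene-proximal boundary
    of a downstream exon; raises if ``to_pos`` is not strictly downstream.
    """
    if not is_downstream(to_pos, from_pos, strand):
        raise ValueError(
            f"position {to_pos} is not downstream of {from_pos} on strand {strand}"
        )
    return abs(to_pos - from_pos)


def interval_downstream_of(iv: GenomicInterval, reference: int) -> bool:
    """True iff the entire interval lies strictly downstream of ``reference``."""
    if iv.strand == "+":
        return iv.start > reference
    return iv.end - 1 < reference


def gene_proximal_boundary(iv: GenomicInterval) -> int:
    """Boundary of a downstream exon nearest the upstream gene.

    For an interval downstream of a plus-strand gene this is its start;
    for a minus-strand gene its (exclusive) end, matching gap-length
    semantics of the distance between polyA site and exon.
    """
    return iv.start if iv.strand == "+" else iv.end


def acceptor_boundary(exon: GenomicInterval) -> int:
    """Genomic boundary of the exon's 3' splice site (first exonic base edge).

    An intron gap [gs, ge) supports this acceptor iff ge == boundary on the
    plus strand, or gs == boundary on the minus strand.
    """
    return exon.start if exon.strand == "+" else exon.end


def donor_boundary(exon: GenomicInterval) -> int:
    """Genomic boundary of the exon's 5' splice site (last exonic base edge).

    An intron gap [gs, ge) starts at this donor iff gs == boundary on the
    plus strand, or ge == boundary on the minus strand.
    """
    return exon.end if exon.strand == "+" else exon.start


def gap_supports_acceptor(gap: tuple[int, int], exon: GenomicInterval) -> bool:
    gs, ge = gap
    return ge == exon.start if exon.strand == "+" else gs == exon.end


def gap_leaves_donor(gap: tuple[int, int], exon: GenomicInterval) -> bool:
    gs, ge = gap
    return gs == exon.end if exon.strand == "+" else ge == exon.start


def acceptor_position(exon: GenomicInterval) -> int:
    """0-based position of the first exonic base in transcription direction."""
    return exon.five_prime
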