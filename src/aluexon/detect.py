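"""Post-processing of predicted exons into candidate Alu exons.

A predicted exon becomes a candidate when (i) at least one of its splice
sites lies inside an Alu element annotated antisense to the exon's strand
and that splice site is supported by junction-spanning reads, and (ii) no
other predicted exon overlaps it (the prediction is unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    AlignedRead,
    GenomicInterval,
    acceptor_boundary,
    donor_boundary,
    overlaps,
)

#: junction key: (chrom, gap_start, gap_end) of the intron gap
JunctionKey = tuple[str, int, int]


@dataclass
class CandidateAluExon:
    """A predicted exon with at least one Alu-resident, read-supported splice site."""

    exon: GenomicInterval
    alu_element: GenomicInterval
    #: subset of {"acceptor_in_alu", "donor_in_alu"} -> supporting junction read count
    supported_splice_sites: dict[str, int] = field(default_factory=dict)
    ambiguous: bool = False

    @property
    def passed(self) -> bool:
        return bool(self.supported_splice_sites) and not self.ambiguous


@dataclass
class RejectedExon:
    """A predicted exon that failed the candidate criteria, with the reason."""

    exon: GenomicInterval
    reason: str  # "no_alu_splice_site" | "no_junction_support" | "ambiguous"


def aggregate_junctions(reads: Iterable[AlignedRead]) -> dict[JunctionKey, int]:
    """Collapse the intron gaps of split reads into junction read counts.

    One junction per distinct (chrom, gap_start, gap_end); a read with two
    gaps contributes to two junctions.
    """
    counts: dict[JunctionKey, int] = {}
    for read in reads:
        for gs, ge in read.gaps:
            key = (read.chrom, gs, ge)
            counts[key] = counts.get(key, 0) + 1
    return counts


def _alu_trees(alu_elements: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for alu in alu_elements:
        trees.setdefault(alu.chrom, IntervalTree()).addi(alu.start, alu.end, alu)
    return trees


def _acceptor_support(
    exon: GenomicInterval, junctions: Mapping[JunctionKey, int]
) -> int:
    """Total reads of junctions whose gap ends exactly at the exon's acceptor."""
    b = acceptor_boundary(exon)
    if exon.strand == "+":
        return sum(n for (c, gs, ge), n in junctions.items() if c == exon.chrom and ge == b)
    return sum(n for (c, gs, ge), n in junctions.items() if c == exon.chrom and gs == b)


def _donor_support(exon: GenomicInterval, junctions: Mapping[JunctionKey, int]) -> int:
    b = donor_boundary(exon)
    if exon.strand == "+":
        return sum(n for (c, gs, ge), n in junctions.items() if c == exon.chrom and gs == b)
    return sum(n for (c, gs, ge), n in junctions.items() if c == exon.chrom and ge == b)


def call_alu_exons(
    predicted_exons: Sequence[GenomicInterval],
    alu_elements: Sequence[GenomicInterval],
    junctions: Mapping[JunctionKey, int],
    min_junction_reads: int = 1,
) -> tuple[list[CandidateAluExon], list[RejectedExon]]:
    """Apply the two candidate criteria to every predicted exon.

    The Alu element must be annotated antisense to the exon's strand
    (exonised Alu elements contribute splice sites only in antisense
    orientation); splice-site-to-junction matching is exact coordinate
    equality; identical-coordinate duplicate predictions collapse before
    the overlap (ambiguity) test.  Output order is deterministic and
    independent of input ordering.
    """
    # collapse identical predictions
    uniq: dict[tuple[str, int, int, str], GenomicInterval] = {}
    for exon in predicted_exons:
        uniq.setdefault((exon.chrom, exon.start, exon.end, exon.strand), exon)
    exons = sorted(uniq.values(), key=lambda e: (e.chrom, e.start, e.end, e.strand))

    exon_trees: dict[str, IntervalTree] = {}
    for exon in exons:
        exon_trees.setdefault(exon.chrom, IntervalTree()).addi(exon.start, exon.end, exon)
    alu_trees = _alu_trees(alu_elements)

    candidates: list[CandidateAluExon] = []
    rejected: list[RejectedExon] = []
    for exon in exons:
        antisense = "-" if exon.strand == "+" else "+"
        tree = alu_trees.get(exon.chrom, IntervalTree())
        acc_pos = exon.five_prime
        don_pos = exon.three_prime
        acc_alu = [
            hit.data
            for hit in tree.at(acc_pos)
            if hit.data.strand == antisense
        ]
        don_alu = [
            hit.data
            for hit in tree.at(don_pos)
            if hit.data.strand == antisense
        ]
        if not acc_alu and not don_alu:
            rejected.append(RejectedExon(exon, "no_alu_splice_site"))
            continue
        supported: dict[str, int] = {}
        host: Optional[GenomicInterval] = None
        if acc_alu:
            n = _acceptor_support(exon, junctions)
            if n >= min_junction_reads:
                supported["acceptor_in_alu"] = n
                host = acc_alu[0]
        if don_alu:
            n = _donor_support(exon, junctions)
            if n >= min_junction_reads:
                supported["donor_in_alu"] = n
                host = host or don_alu[0]
        if not supported:
            rejected.append(RejectedExon(exon, "no_junction_support"))
            continue
        others = [
            hit.data
            for hit in exon_trees[exon.chrom].overlap(exon.start, exon.end)
            if hit.data is not exon and overlaps(hit.data, exon, require_same_strand=True)
        ]
        if others:
            rejected.append(RejectedExon(exon, "ambiguous"))
            continue
        candidates.append(CandidateAluExon(exon, host, supported, ambiguous=False))
    return candidates, rejected
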