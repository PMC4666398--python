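"""Gene linkage, locus and mechanism classification of candidate Alu exons.

Candidates are linked to genes through the splice-junction graph, split
into intergenic (entirely downstream of the gene's last genuine polyA
site) versus intronic, assigned one of the two exonisation mechanisms —
skipping of the complete terminal exon, or activation of a cryptic 5'
splice site inside the terminal exon (or both) — and annotated with the
polyA-to-exon distance, the splicing contribution at the Alu exon 3'
splice site, downstream cryptic exon chains, and per-condition inclusion
estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    AlignedRead,
    GeneModel,
    GenomicInterval,
    Transcript,
    acceptor_boundary,
    donor_boundary,
    gene_proximal_boundary,
    is_downstream,
    transcription_distance,
)
from .detect import CandidateAluExon, JunctionKey

log = logging.getLogger(__name__)

SCENARIOS = ("terminal_exon_skipping", "cryptic_5ss", "both", "not_applicable")

#: half-width of the continuous-read window around a splice-site boundary:
#: a continuously aligning read must cover >= FLANK nt on each side.
FLANK = 10


@dataclass
class AluExonCall:
    """A detected Alu exon with full classification."""

    call_id: str
    candidate: CandidateAluExon
    gene_id: Optional[str]
    locus_class: str  # intergenic | intronic | unlinked
    scenario: str = "not_applicable"
    distance_bp: Optional[int] = None
    splicing_contribution: Optional[float] = None
    downstream_cryptic_exon_count: int = 0
    inclusion: dict[str, Optional[float]] = field(default_factory=dict)


class ReadEvidence:
    """Indexed view of one condition's reads for junction and coverage queries."""

    def __init__(self, reads: Iterable[AlignedRead]):
        self.junctions: dict[JunctionKey, int] = {}
        self._by_end: dict[tuple[str, int], dict[int, int]] = {}
        self._by_start: dict[tuple[str, int], dict[int, int]] = {}
        self._block_trees: dict[str, IntervalTree] = {}
        self._block_counts: dict[tuple[str, int, int], int] = {}
        self.read_length = 0
        n = 0
        for read in reads:
            n += 1
            self.read_length = max(self.read_length, read.aligned_length)
            for gs, ge in read.gaps:
                key = (read.chrom, gs, ge)
                self.junctions[key] = self.junctions.get(key, 0) + 1
                self._by_end.setdefault((read.chrom, ge), {}).setdefault(gs, 0)
                self._by_end[(read.chrom, ge)][gs] += 1
                self._by_start.setdefault((read.chrom, gs), {}).setdefault(ge, 0)
                self._by_start[(read.chrom, gs)][ge] += 1
            for b in read.blocks:
                key = (read.chrom, b.start, b.end)
                self._block_counts[key] = self._block_counts.get(key, 0) + 1
        for (chrom, bs, be), count in self._block_counts.items():
            self._block_trees.setdefault(chrom, IntervalTree()).addi(bs, be, count)
        self.n_reads = n

    def junctions_ending_at(self, chrom: str, ge: int) -> dict[int, int]:
        """gap_start -> read count for gaps ending at ``ge``."""
        return dict(self._by_end.get((chrom, ge), {}))

    def junctions_starting_at(self, chrom: str, gs: int) -> dict[int, int]:
        """gap_end -> read count for gaps starting at ``gs``."""
        return dict(self._by_start.get((chrom, gs), {}))

    def acceptor_junction_donors(self, exon: GenomicInterval) -> dict[int, int]:
        """Donor-side gap endpoints of junctions supporting the exon's acceptor."""
        if exon.strand == "+":
            return self.junctions_ending_at(exon.chrom, exon.start)
        return self.junctions_starting_at(exon.chrom, exon.end)

    def reads_covering(self, chrom: str, lo: int, hi: int) -> int:
        """Reads with one aligned block fully covering [lo, hi)."""
        tree = self._block_trees.get(chrom)
        if tree is None:
            return 0
        return sum(
            hit.data for hit in tree.overlap(lo, hi) if hit.begin <= lo and hit.end >= hi
        )


def merge_junctions(*junction_dicts: Mapping[JunctionKey, int]) -> dict[JunctionKey, int]:
    out: dict[JunctionKey, int] = {}
    for d in junction_dicts:
        for key, n in d.items():
            out[key] = out.get(key, 0) + n
    return out


# ---------------------------------------------------------------------------
# gene linkage


def link_gene(
    candidate: CandidateAluExon,
    genes: Mapping[str, GeneModel],
    junctions: Mapping[JunctionKey, int],
    predicted_exons: Sequence[GenomicInterval] = (),
    max_hops: int = 3,
) -> Optional[str]:
    """Link a candidate to a gene through the splice-junction graph.

    Breadth-first traversal from the candidate's splice sites: a junction
    hop moves from one exon boundary to the far gap endpoint; chained hops
    pass through predicted or annotated exons whose boundaries coincide
    with gap endpoints.  The candidate links to the gene whose annotated
    span (matching strand) contains a reached position within
    ``max_hops`` hops; at equal hop count the gene nearest upstream of
    the candidate in transcription direction wins.
    """
    exon = candidate.exon
    chrom, strand = exon.chrom, exon.strand

    # map exon boundaries -> exons to continue the traversal through
    by_left: dict[int, list[GenomicInterval]] = {}
    by_right: dict[int, list[GenomicInterval]] = {}
    universe = list(predicted_exons)
    for gene in genes.values():
        if gene.chrom == chrom:
            universe.extend(gene.exons)
    for e in universe:
        if e.chrom != chrom:
            continue
        by_left.setdefault(e.start, []).append(e)
        by_right.setdefault(e.end, []).append(e)

    junc_by_start: dict[int, list[int]] = {}
    junc_by_end: dict[int, list[int]] = {}
    for (c, gs, ge) in junctions:
        if c != chrom:
            continue
        junc_by_start.setdefault(gs, []).append(ge)
        junc_by_end.setdefault(ge, []).append(gs)

    span_hits: dict[str, int] = {}  # gene_id -> minimal hop count

    def genes_at(pos: int, hops: int) -> None:
        for gid, gene in genes.items():
            if gene.chrom != chrom or gene.strand != strand:
                continue
            if gene.span.contains(pos):
                if gid not in span_hits or hops < span_hits[gid]:
                    span_hits[gid] = hops

    frontier: list[tuple[int, int]] = [(exon.start, exon.end)]
    seen: set[tuple[int, int]] = {(exon.start, exon.end)}
    for hop in range(1, max_hops + 1):
        nxt: list[tuple[int, int]] = []
        for left, right in frontier:
            # leave through the left boundary: gaps ending at `left`
            for gs in junc_by_end.get(left, []):
                genes_at(gs - 1, hop)  # gs-1 is the last exonic base of the far exon
                for e in by_right.get(gs, []):
                    key = (e.start, e.end)
                    if key not in seen:
                        seen.add(key)
                        nxt.append(key)
            # leave through the right boundary: gaps starting at `right`
            for ge in junc_by_start.get(right, []):
                genes_at(ge, hop)
                for e in by_left.get(ge, []):
                    key = (e.start, e.end)
                    if key not in seen:
                        seen.add(key)
                        nxt.append(key)
        if span_hits:
            break
        frontier = nxt
        if not frontier:
            break

    if not span_hits:
        return None
    best_hops = min(span_hits.values())
    tied = sorted(gid for gid, h in span_hits.items() if h == best_hops)
    if len(tied) == 1:
        return tied[0]

    # tie-break: nearest gene upstream of the candidate in transcription direction
    def upstream_gap(gid: str) -> tuple[int, str]:
        span = genes[gid].span
        if strand == "+":
            gap = exon.start - span.end
        else:
            gap = span.start - exon.end
        return (gap if gap >= 0 else 10**12, gid)

    return min(tied, key=upstream_gap)


# ---------------------------------------------------------------------------
# locus classification


def classify_locus(
    candidate: CandidateAluExon, gene: GeneModel
) -> tuple[str, Optional[int]]:
    """Intergenic iff the Alu exon lies entirely downstream of the gene's
    last genuine polyA site; returns the polyA-to-exon distance for
    intergenic calls (gap to the gene-proximal exon boundary)."""
    if not gene.polya_sites:
        log.warning(
            "gene %s has no annotated polyA site; using gene 3' end", gene.gene_id
        )
    last = gene.last_polya()
    boundary = gene_proximal_boundary(candidate.exon)
    if is_downstream(boundary, last, gene.strand):
        return "intergenic", transcription_distance(last, boundary, gene.strand)
    return "intronic", None


# ---------------------------------------------------------------------------
# mechanism scenario


def primary_transcript(gene: GeneModel) -> Transcript:
    """The transcript with the strand-wise most downstream 3' end."""
    if gene.strand == "+":
        return max(
            gene.transcripts,
            key=lambda t: (t.three_prime_end, t.exonic_length, t.transcript_id),
        )
    return max(
        gene.transcripts,
        key=lambda t: (-t.three_prime_end, t.exonic_length, t.transcript_id),
    )


def upstream_donors(gene: GeneModel) -> set[int]:
    """Donor boundaries of all annotated exons upstream of each transcript's
    terminal exon."""
    donors: set[int] = set()
    for tx in gene.transcripts:
        body = tx.exons[:-1] if gene.strand == "+" else tx.exons[1:]
        for e in body:
            donors.add(donor_boundary(e))
    return donors


@dataclass
class ScenarioEvidence:
    scenario: str
    skip_reads: int
    cryptic_reads: int
    cryptic_donors: dict[int, int]  # in-terminal donor gap endpoint -> reads


def classify_scenario(
    candidate: CandidateAluExon,
    gene: GeneModel,
    junctions: Mapping[JunctionKey, int],
    min_reads: int = 1,
    warn: bool = True,
) -> ScenarioEvidence:
    """Assign the exonisation mechanism from junction donors.

    Terminal-exon skipping: junctions from an annotated donor upstream of
    the terminal exon directly to the Alu exon acceptor.  Cryptic 5'
    splice site: junctions whose donor lies strictly inside the terminal
    exon body.  Both classes reaching ``min_reads`` -> "both"; neither ->
    "not_applicable" (the call survives with a warning).
    """
    exon = candidate.exon
    term = primary_transcript(gene).terminal_exon
    donors_up = upstream_donors(gene)

    if exon.strand == "+":
        donor_map = {
            gs: n
            for (c, gs, ge), n in junctions.items()
            if c == exon.chrom and ge == exon.start
        }
    else:
        donor_map = {
            ge: n
            for (c, gs, ge), n in junctions.items()
            if c == exon.chrom and gs == exon.end
        }

    skip = sum(n for d, n in donor_map.items() if d in donors_up)
    cryptic_donors = {
        d: n for d, n in donor_map.items() if term.start < d < term.end
    }
    cryp = sum(cryptic_donors.values())

    if skip >= min_reads and cryp >= min_reads:
        scenario = "both"
    elif skip >= min_reads:
        scenario = "terminal_exon_skipping"
    elif cryp >= min_reads:
        scenario = "cryptic_5ss"
    else:
        scenario = "not_applicable"
        if warn:
            log.warning(
                "call at %s:%d-%d: no junction evidence for either scenario",
                exon.chrom,
                exon.start,
                exon.end,
            )
    return ScenarioEvidence(scenario, skip, cryp, cryptic_donors)


# ---------------------------------------------------------------------------
# splicing contribution


def splicing_contribution(
    candidate: CandidateAluExon, evidence: ReadEvidence, flank: int = FLANK
) -> Optional[float]:
    """Fraction of junction-spanning among all reads overlapping the 3'SS.

    A read counts as continuously aligning when one block covers the
    acceptor boundary with >= ``flank`` nt aligned on each side; as
    junction-spanning when it contains the exact intron gap ending at the
    acceptor.  Returns junction / (junction + continuous), or None when
    no read overlaps (flagged upstream).
    """
    exon = candidate.exon
    b = acceptor_boundary(exon)
    junction = sum(evidence.acceptor_junction_donors(exon).values())
    continuous = evidence.reads_covering(exon.chrom, b - flank, b + flank)
    total = junction + continuous
    if total == 0:
        return None
    return junction / total


# ---------------------------------------------------------------------------
# downstream cryptic exons


def downstream_cryptic_exons(
    candidate: CandidateAluExon,
    predicted_exons: Sequence[GenomicInterval],
    junctions: Mapping[JunctionKey, int],
    max_chain: int = 10,
) -> int:
    """Count predicted exons strictly downstream of the Alu exon reachable
    by a junction chain starting at the Alu exon's donor."""
    return len(downstream_chain_exons(candidate, predicted_exons, junctions, max_chain))


def downstream_chain_exons(
    candidate: CandidateAluExon,
    predicted_exons: Sequence[GenomicInterval],
    junctions: Mapping[JunctionKey, int],
    max_chain: int = 10,
) -> list[GenomicInterval]:
    """The reachable downstream cryptic exons themselves (for isoform lengths)."""
    exon = candidate.exon
    chrom, strand = exon.chrom, exon.strand
    by_acceptor: dict[int, list[GenomicInterval]] = {}
    for e in predicted_exons:
        if e.chrom != chrom or e.strand != strand:
            continue
        by_acceptor.setdefault(acceptor_boundary(e), []).append(e)
    junc_from: dict[int, list[int]] = {}
    for (c, gs, ge) in junctions:
        if c != chrom:
            continue
        if strand == "+":
            junc_from.setdefault(gs, []).append(ge)
        else:
            junc_from.setdefault(ge, []).append(gs)
    out: list[GenomicInterval] = []
    seen: set[tuple[int, int]] = set()
    frontier = [donor_boundary(exon)]
    alu_3p = exon.three_prime
    for _ in range(max_chain):
        nxt: list[int] = []
        for donor in frontier:
            for far in junc_from.get(donor, []):
                for e in by_acceptor.get(far, []):
                    key = (e.start, e.end)
                    if key not in seen and is_downstream(e.five_prime, alu_3p, strand):
                        seen.add(key)
                        out.append(e)
                        nxt.append(donor_boundary(e))
        if not nxt:
            break
        frontier = nxt
    return out


# ---------------------------------------------------------------------------
# inclusion estimation


@dataclass
class InclusionEstimate:
    """Inclusion estimate with its discriminating read counts."""

    value: Optional[float]
    alu_reads: int
    canonical_reads: int

    @property
    def n_discriminating(self) -> int:
        return self.alu_reads + self.canonical_reads


def inclusion_components(
    candidate: CandidateAluExon,
    gene: GeneModel,
    scenario_ev: ScenarioEvidence,
    chain_exons: Sequence[GenomicInterval],
    evidence: ReadEvidence,
    flank: int = FLANK,
) -> InclusionEstimate:
    """Estimate the fraction of the gene's transcripts carrying the Alu exon.

    Discriminating reads are junction reads into the Alu exon acceptor
    (Alu isoforms) versus, depending on scenario, reads of the canonical
    terminal-exon acceptor junction (skipping) or reads aligning
    continuously across the cryptic donor boundary (cryptic 5'SS / both).
    Counts are normalised by the effective length of the isoform that can
    emit them (isoform length − read length + 1) and by the width of the
    start-position window that yields the diagnostic alignment, so the
    estimate is unbiased regardless of isoform length differences.
    Returns None on a zero denominator.
    """
    exon = candidate.exon
    L = evidence.read_length
    if L == 0:
        return InclusionEstimate(None, 0, 0)
    tx = primary_transcript(gene)
    term = tx.terminal_exon
    upstream_exons = tx.exons[:-1] if gene.strand == "+" else tx.exons[1:]
    upstream_len = sum(len(e) for e in upstream_exons)
    chain_len = sum(len(e) for e in chain_exons)
    canonical_len = tx.exonic_length
    skip_len = upstream_len + len(exon) + chain_len

    def eff(length: int) -> float:
        return max(length - L + 1, 1)

    w_junction = L - 1  # start positions that put >=1 nt on each side of a junction
    w_continuous = L - 2 * flank + 1

    donors_up = upstream_donors(gene)
    donor_map = evidence.acceptor_junction_donors(exon)
    n_alu = sum(donor_map.values())
    r_alu = 0.0
    for donor, count in donor_map.items():
        if term.start < donor < term.end:
            trunc = donor - term.start if gene.strand == "+" else term.end - donor
            iso_len = upstream_len + trunc + len(exon) + chain_len
        elif donor in donors_up:
            iso_len = skip_len
        else:
            iso_len = skip_len
        r_alu += count * eff(iso_len) / w_junction

    if scenario_ev.scenario == "terminal_exon_skipping":
        canonical_count = sum(evidence.acceptor_junction_donors(term).values())
        r_can = canonical_count * eff(canonical_len) / w_junction
    elif scenario_ev.scenario in ("cryptic_5ss", "both") and scenario_ev.cryptic_donors:
        c_star = max(
            scenario_ev.cryptic_donors, key=lambda d: (scenario_ev.cryptic_donors[d], d)
        )
        canonical_count = evidence.reads_covering(exon.chrom, c_star - flank, c_star + flank)
        r_can = canonical_count * eff(canonical_len) / w_continuous
    else:
        canonical_count = sum(evidence.acceptor_junction_donors(term).values())
        r_can = canonical_count * eff(canonical_len) / w_junction

    total = r_alu + r_can
    if total == 0:
        return InclusionEstimate(None, n_alu, canonical_count)
    return InclusionEstimate(
        min(max(r_alu / total, 0.0), 1.0), n_alu, canonical_count
    )


def estimate_inclusion(
    candidate: CandidateAluExon,
    gene: GeneModel,
    scenario_ev: ScenarioEvidence,
    chain_exons: Sequence[GenomicInterval],
    evidence: ReadEvidence,
    flank: int = FLANK,
) -> Optional[float]:
    """Estimated fraction of the gene's transcripts carrying the Alu exon
    (see :func:`inclusion_components` for the full account)."""
    return inclusion_components(
        candidate, gene, scenario_ev, chain_exons, evidence, flank=flank
    ).value


# ---------------------------------------------------------------------------
# orchestration


def classify_calls(
    candidates: Sequence[CandidateAluExon],
    genes: Mapping[str, GeneModel],
    predicted_exons: Sequence[GenomicInterval],
    evidence_by_condition: Mapping[str, ReadEvidence],
    detect_condition: str = "kd",
    max_hops: int = 3,
    min_reads: int = 1,
    flank: int = FLANK,
) -> list[AluExonCall]:
    """Run the full classification over all passing candidates.

    Junctions for linkage/scenario are merged over conditions; the
    splicing contribution is computed on the detection condition;
    inclusion is estimated per condition.  Output order is deterministic
    and independent of input ordering.
    """
    merged = merge_junctions(
        *(ev.junctions for ev in evidence_by_condition.values())
    )
    detect_ev = evidence_by_condition[detect_condition]
    calls: list[AluExonCall] = []
    for cand in sorted(
        candidates, key=lambda c: (c.exon.chrom, c.exon.start, c.exon.end, c.exon.strand)
    ):
        if not cand.passed:
            continue
        exon = cand.exon
        gid = link_gene(cand, genes, merged, predicted_exons, max_hops=max_hops)
        call_id = f"{gid or 'unlinked'}:{exon.chrom}:{exon.start}-{exon.end}"
        if gid is None:
            calls.append(
                AluExonCall(call_id, cand, None, "unlinked")
            )
            continue
        gene = genes[gid]
        locus, distance = classify_locus(cand, gene)
        call = AluExonCall(call_id, cand, gid, locus, distance_bp=distance)
        call.splicing_contribution = splicing_contribution(cand, detect_ev, flank=flank)
        if locus == "intergenic":
            scen = classify_scenario(cand, gene, merged, min_reads=min_reads)
            call.scenario = scen.scenario
            chain = downstream_chain_exons(cand, predicted_exons, merged)
            call.downstream_cryptic_exon_count = len(chain)
            for cond, ev in evidence_by_condition.items():
                cond_scen = classify_scenario(
                    cand, gene, ev.junctions, min_reads=min_reads, warn=False
                )
                use = cond_scen if cond_scen.scenario != "not_applicable" else scen
                call.inclusion[cond] = estimate_inclusion(
                    cand, gene, use, chain, ev, flank=flank
                )
        calls.append(call)
    return calls
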