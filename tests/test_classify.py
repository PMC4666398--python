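"""Gene linkage, locus/mechanism classification and quantification."""

import random

import pytest

from aluexon.core import AlignedRead, GeneModel, GenomicInterval, Transcript
from aluexon.classify import (
    ReadEvidence,
    classify_locus,
    classify_scenario,
    downstream_cryptic_exons,
    estimate_inclusion,
    link_gene,
    splicing_contribution,
)
from aluexon.detect import CandidateAluExon


def iv(start, end, strand="+", chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, strand, name=name)


def read(blocks, name="r", strand="+", chrom="chr1"):
    return AlignedRead(
        name, chrom, strand, tuple(iv(s, e, strand, chrom) for s, e in blocks)
    )


def make_gene(gid="g1", strand="+", polya=None):
    """Plus layout: e1 [1000,1200), e2 [1800,2000), terminal [2600,3200)."""
    g = GeneModel(gene_id=gid)
    g.transcripts.append(
        Transcript(
            f"{gid}.t1",
            (iv(1000, 1200, strand), iv(1800, 2000, strand), iv(2600, 3200, strand)),
        )
    )
    g.polya_sites.extend([3199] if polya is None else polya)
    return g


ALU = iv(3390, 3620, "-", name="AluSx")
ALU_EXON = iv(3430, 3580)


def cand(exon=ALU_EXON, alu=ALU, support=None):
    return CandidateAluExon(exon, alu, support or {"acceptor_in_alu": 5})


class TestLinkGene:
    def test_direct_junction_links_in_one_hop(self):
        genes = {"g1": make_gene()}
        junctions = {("chr1", 2000, 3430): 5}
        assert link_gene(cand(), genes, junctions) == "g1"

    def test_no_junction_to_any_gene_is_unlinked(self):
        genes = {"g1": make_gene()}
        assert link_gene(cand(), genes, {("chr1", 9000, 9500): 3}) is None

    def test_tie_break_prefers_nearest_upstream_gene(self):
        near = make_gene("g_near")
        far = GeneModel(gene_id="g_far")
        far.transcripts.append(Transcript("g_far.t1", (iv(100, 300), iv(500, 2000))))
        far.polya_sites.append(1999)
        junctions = {("chr1", 2000, 3430): 5}  # both genes share the donor at 2000
        got = link_gene(cand(), {"g_far": far, "g_near": near}, junctions)
        assert got == "g_near"

    def test_multi_hop_through_cryptic_exon_chain(self):
        """Alu exon reachable from the gene only via an intermediate exon."""
        genes = {"g1": make_gene()}
        mid = iv(3430, 3580)
        far_alu_exon = iv(4000, 4150)
        junctions = {("chr1", 2000, 3430): 5, ("chr1", 3580, 4000): 4}
        got = link_gene(
            cand(exon=far_alu_exon), genes, junctions, predicted_exons=[mid]
        )
        assert got == "g1"

    def test_max_hops_limits_traversal(self):
        genes = {"g1": make_gene()}
        mid = iv(3430, 3580)
        far_alu_exon = iv(4000, 4150)
        junctions = {("chr1", 2000, 3430): 5, ("chr1", 3580, 4000): 4}
        assert (
            link_gene(
                cand(exon=far_alu_exon),
                genes,
                junctions,
                predicted_exons=[mid],
                max_hops=1,
            )
            is None
        )


class TestClassifyLocus:
    def test_plus_strand_intergenic_distance(self):
        gene = make_gene(polya=[5000])
        locus, dist = classify_locus(cand(exon=iv(8200, 8400)), gene)
        assert (locus, dist) == ("intergenic", 3200)

    def test_minus_strand_intergenic_distance(self):
        gene = make_gene(strand="-", polya=[5000])
        locus, dist = classify_locus(cand(exon=iv(4800, 4959, "-")), gene)
        assert (locus, dist) == ("intergenic", 41)

    def test_exon_upstream_of_last_polya_is_intronic(self):
        gene = make_gene(polya=[5000])
        locus, dist = classify_locus(cand(exon=iv(4000, 4200)), gene)
        assert (locus, dist) == ("intronic", None)

    def test_last_polya_is_strand_wise_most_downstream(self):
        gene = make_gene(polya=[3000, 3199])
        locus, dist = classify_locus(cand(exon=iv(3100, 3150)), gene)
        assert locus == "intronic"  # downstream of 3000 but not of 3199

    def test_missing_polya_falls_back_to_gene_end(self, caplog):
        gene = make_gene(polya=[])
        with caplog.at_level("WARNING"):
            locus, dist = classify_locus(cand(exon=iv(3430, 3580)), gene)
        assert (locus, dist) == ("intergenic", 3430 - 3199)
        assert "polyA" in caplog.text


class TestClassifyScenario:
    def test_upstream_donor_junction_is_terminal_exon_skipping(self):
        gene = make_gene()
        ev = classify_scenario(cand(), gene, {("chr1", 2000, 3430): 7})
        assert ev.scenario == "terminal_exon_skipping"
        assert ev.skip_reads == 7

    def test_donor_inside_terminal_exon_is_cryptic_5ss(self):
        gene = make_gene()
        ev = classify_scenario(cand(), gene, {("chr1", 2900, 3430): 4})
        assert ev.scenario == "cryptic_5ss"
        assert ev.cryptic_donors == {2900: 4}

    def test_one_read_of_each_is_both(self):
        gene = make_gene()
        junctions = {("chr1", 2000, 3430): 1, ("chr1", 2900, 3430): 1}
        assert classify_scenario(cand(), gene, junctions).scenario == "both"

    def test_terminal_exon_boundaries_do_not_count_as_cryptic(self):
        # a donor exactly at the terminal exon start is not strictly inside
        gene = make_gene()
        ev = classify_scenario(cand(), gene, {("chr1", 2600, 3430): 3})
        assert ev.scenario == "not_applicable"

    def test_minus_strand_symmetric(self):
        # on the minus strand the terminal exon is the genomically first one
        gene = make_gene(strand="-")
        alu_exon = iv(300, 450, "-")
        c = cand(exon=alu_exon, alu=iv(260, 490, "+"))
        # skipping: donor of the next upstream exon [1800,2000) is its start
        ev = classify_scenario(c, gene, {("chr1", 450, 1800): 6})
        assert ev.scenario == "terminal_exon_skipping"
        # cryptic: donor boundary strictly inside the terminal exon [1000,1200)
        ev = classify_scenario(c, gene, {("chr1", 450, 1100): 6})
        assert ev.scenario == "cryptic_5ss"


class TestSplicingContribution:
    def brute_force(self, exon, reads, flank=10):
        """Independent per-read classifier straight from the definitions."""
        b = exon.start if exon.strand == "+" else exon.end
        junction = continuous = 0
        for r in reads:
            if r.chrom != exon.chrom:
                continue
            gaps = [(a.end, bl.start) for a, bl in zip(r.blocks, r.blocks[1:])]
            if any(
                (exon.strand == "+" and ge == b) or (exon.strand == "-" and gs == b)
                for gs, ge in gaps
            ):
                junction += 1
            elif any(bl.start <= b - flank and bl.end >= b + flank for bl in r.blocks):
                continuous += 1
        total = junction + continuous
        return None if total == 0 else junction / total

    def test_three_junction_one_continuous(self):
        reads = [
            read([(1990, 2000), (3430, 3495)], name=f"j{i}") for i in range(3)
        ] + [read([(3410, 3485)], name="c")]
        got = splicing_contribution(cand(), ReadEvidence(reads))
        assert got == 0.75
        assert got == self.brute_force(ALU_EXON, reads)

    def test_all_continuous_is_zero(self):
        reads = [read([(3400, 3475)], name=f"c{i}") for i in range(5)]
        assert splicing_contribution(cand(), ReadEvidence(reads)) == 0.0

    def test_all_junction_is_one(self):
        reads = [read([(1995, 2000), (3430, 3500)], name=f"j{i}") for i in range(4)]
        assert splicing_contribution(cand(), ReadEvidence(reads)) == 1.0

    def test_nine_nt_anchor_does_not_count_as_continuous(self):
        reads = [read([(3421, 3496)])]  # only 9 nt upstream of the acceptor at 3430
        assert splicing_contribution(cand(), ReadEvidence(reads)) is None

    def test_no_overlapping_reads_returns_absent(self):
        reads = [read([(100, 175)])]
        assert splicing_contribution(cand(), ReadEvidence(reads)) is None

    def test_matches_brute_force_on_random_reads(self):
        rng = random.Random(42)
        reads = []
        for i in range(500):
            if rng.random() < 0.5:
                anchor = rng.randint(1, 74)
                reads.append(
                    read([(2000 - anchor, 2000), (3430, 3430 + 75 - anchor)], name=f"j{i}")
                )
            else:
                start = rng.randint(3340, 3440)
                reads.append(read([(start, start + 75)], name=f"c{i}"))
        ev = ReadEvidence(reads)
        assert splicing_contribution(cand(), ev) == self.brute_force(ALU_EXON, reads)


class TestDownstreamCrypticExons:
    def test_no_junction_leaving_donor(self):
        assert downstream_cryptic_exons(cand(), [], {("chr1", 2000, 3430): 5}) == 0

    def test_single_downstream_exon(self):
        c1 = iv(3880, 4000)
        junctions = {("chr1", 3580, 3880): 3}
        assert downstream_cryptic_exons(cand(), [c1], junctions) == 1

    def test_chain_of_two(self):
        c1, c2 = iv(3880, 4000), iv(4300, 4420)
        junctions = {("chr1", 3580, 3880): 3, ("chr1", 4000, 4300): 2}
        assert downstream_cryptic_exons(cand(), [c1, c2], junctions) == 2

    def test_upstream_exons_never_counted(self):
        up = iv(1000, 1200)
        junctions = {("chr1", 3580, 3880): 3}
        assert downstream_cryptic_exons(cand(), [up], junctions) == 0


class TestEstimateInclusion:
    def equal_length_setup(self):
        """Canonical and Alu-skip isoforms of identical exonic length (1000 nt),
        so the count ratio is the inclusion estimate with no length correction."""
        gene = make_gene()
        alu_exon = iv(3430, 4030)  # 600 nt, same as the terminal exon
        c = cand(exon=alu_exon, alu=iv(3390, 4070, "-"))
        return gene, c

    def reads_for(self, n_alu, n_canonical):
        reads = [
            read([(1950, 2000), (3430, 3455)], name=f"a{i}") for i in range(n_alu)
        ]
        reads += [
            read([(1950, 2000), (2600, 2625)], name=f"k{i}") for i in range(n_canonical)
        ]
        return reads

    def test_thirty_alu_seventy_canonical(self):
        gene, c = self.equal_length_setup()
        ev = ReadEvidence(self.reads_for(30, 70))
        scen = classify_scenario(c, gene, ev.junctions)
        got = estimate_inclusion(c, gene, scen, [], ev)
        assert got == pytest.approx(0.30)

    def test_all_canonical_is_zero(self):
        gene, c = self.equal_length_setup()
        ev = ReadEvidence(self.reads_for(0, 50))
        scen = classify_scenario(c, gene, {("chr1", 2000, 3430): 1})
        assert estimate_inclusion(c, gene, scen, [], ev) == 0.0

    def test_zero_denominator_is_absent(self):
        gene, c = self.equal_length_setup()
        ev = ReadEvidence([read([(100, 175)])])
        scen = classify_scenario(c, gene, {("chr1", 2000, 3430): 1})
        assert estimate_inclusion(c, gene, scen, [], ev) is None


class TestReadOrderInvariance:
    def test_evidence_is_order_independent(self):
        rng = random.Random(7)
        reads = [
            read([(1990, 2000), (3430, 3495)], name=f"j{i}") for i in range(10)
        ] + [read([(3400 + i, 3475 + i)], name=f"c{i}") for i in range(10)]
        baseline = ReadEvidence(reads)
        base_contrib = splicing_contribution(cand(), baseline)
        for _ in range(3):
            shuffled = reads[:]
            rng.shuffle(shuffled)
            ev = ReadEvidence(shuffled)
            assert ev.junctions == baseline.junctions
            assert splicing_contribution(cand(), ev) == base_contrib
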