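"""Three-criterion human/mouse ortholog filter."""

import itertools

import pandas as pd
import pytest

from aluexon.core import GeneModel, GenomicInterval, Transcript
from aluexon.orthologs import (
    OrthologPair,
    filter_pair,
    load_ortholog_pairs,
    summarize_filter,
)
from aluexon.simulate import toy_ortholog_pair


class TestFilterPair:
    def test_identical_structure_fails_extension_and_alu(self):
        v = filter_pair(toy_ortholog_pair(False, False, False))
        assert not v.extends_beyond_mouse
        assert not v.alu_exon_downstream
        assert not v.passed

    def test_alu_extension_without_conserved_tail_passes(self):
        v = filter_pair(toy_ortholog_pair(True, True, False))
        assert v.extends_beyond_mouse
        assert v.alu_exon_downstream
        assert v.no_conserved_after_alu
        assert v.passed

    def test_conserved_exon_after_alu_fails_third_criterion(self):
        v = filter_pair(toy_ortholog_pair(True, True, True))
        assert v.extends_beyond_mouse and v.alu_exon_downstream
        assert not v.no_conserved_after_alu
        assert not v.passed

    def test_internal_alu_exon_does_not_satisfy_downstream_criterion(self):
        v = filter_pair(toy_ortholog_pair(False, True, False))
        assert not v.alu_exon_downstream
        assert not v.passed

    def test_exhaustive_toy_classes_pass_only_full_pattern(self):
        """Of the 8 structure classes (extension x Alu exon x post-Alu
        conserved exon) exactly the (+, +, -) class passes."""
        for ext, alu, post in itertools.product([True, False], repeat=3):
            verdict = filter_pair(toy_ortholog_pair(ext, alu, post))
            assert verdict.passed == (ext and alu and not post), (ext, alu, post)

    def test_strand_reflection_invariance(self):
        for ext, alu, post in itertools.product([True, False], repeat=3):
            plus = filter_pair(toy_ortholog_pair(ext, alu, post, strand="+"))
            minus = filter_pair(toy_ortholog_pair(ext, alu, post, strand="-"))
            assert (
                plus.extends_beyond_mouse,
                plus.alu_exon_downstream,
                plus.no_conserved_after_alu,
                plus.passed,
            ) == (
                minus.extends_beyond_mouse,
                minus.alu_exon_downstream,
                minus.no_conserved_after_alu,
                minus.passed,
            )

    def test_pass_implies_every_criterion(self):
        for ext, alu, post in itertools.product([True, False], repeat=3):
            v = filter_pair(toy_ortholog_pair(ext, alu, post))
            if v.passed:
                assert (
                    v.extends_beyond_mouse
                    and v.alu_exon_downstream
                    and v.no_conserved_after_alu
                )

    def test_correspondence_must_include_mouse_terminal(self):
        pair = toy_ortholog_pair(True, True, False)
        with pytest.raises(ValueError):
            OrthologPair(
                human_gene=pair.human_gene,
                mouse_gene=pair.mouse_gene,
                exon_correspondence={},
                mouse_terminal_in_human=pair.mouse_terminal_in_human,
            )


class TestSummarize:
    def test_empty_input(self):
        s = summarize_filter([])
        assert s["n_pairs"] == 0 and s["n_passing"] == 0 and s["passing_genes"] == []

    def test_counts_and_sorted_passing_list(self):
        pairs = [
            toy_ortholog_pair(True, True, False, gene_id="HB"),
            toy_ortholog_pair(True, True, False, gene_id="HA"),
            toy_ortholog_pair(True, True, False, gene_id="HC"),
            toy_ortholog_pair(True, False, False, gene_id="HX"),
            toy_ortholog_pair(False, False, False, gene_id="HY"),
        ]
        s = summarize_filter(pairs)
        assert s["n_pairs"] == 5
        assert s["n_passing"] == 3
        assert s["passing_genes"] == ["HA", "HB", "HC"]

    def test_idempotent(self):
        pairs = [toy_ortholog_pair(True, True, False)]
        assert summarize_filter(pairs) == summarize_filter(pairs)


class TestLoadPairs:
    def _gene(self, gid, exon_coords, strand="+", chrom="c1"):
        g = GeneModel(gene_id=gid)
        g.transcripts.append(
            Transcript(
                f"{gid}.t",
                tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords),
            )
        )
        return g

    def test_assembles_pair_from_table(self):
        human = {"hg": self._gene("hg", [(100, 200), (300, 400), (700, 760)])}
        mouse = {"mg": self._gene("mg", [(100, 200), (300, 400)])}
        corr = pd.DataFrame(
            [
                ["hg", 100, 200, "mg", 100, 200, 0],
                ["hg", 300, 400, "mg", 300, 400, 1],
            ],
            columns=[
                "human_gene", "human_exon_start", "human_exon_end",
                "mouse_gene", "mouse_exon_start", "mouse_exon_end",
                "is_mouse_terminal",
            ],
        )
        (pair,) = load_ortholog_pairs(human, mouse, corr, {"hg": {(700, 760)}})
        v = filter_pair(pair)
        assert v.passed

    def test_requires_exactly_one_terminal_marker(self):
        human = {"hg": self._gene("hg", [(100, 200)])}
        mouse = {"mg": self._gene("mg", [(100, 200)])}
        corr = pd.DataFrame(
            [["hg", 100, 200, "mg", 100, 200, 0]],
            columns=[
                "human_gene", "human_exon_start", "human_exon_end",
                "mouse_gene", "mouse_exon_start", "mouse_exon_end",
                "is_mouse_terminal",
            ],
        )
        with pytest.raises(ValueError):
            load_ortholog_pairs(human, mouse, corr, {})
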