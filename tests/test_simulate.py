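"""Synthetic-data generator: planted structure, determinism, sampling laws."""

import math

import numpy as np
import pytest

from aluexon.core import acceptor_boundary
from aluexon.simulate import (
    PlantedEvent,
    SimulationConfig,
    generate_annotation,
    generate_fpkm_matrix,
    simulate_reads,
)


def small_config(**kw):
    defaults = dict(n_genes=20, seed=123)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_scenario_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario_mix=(0.5, 0.5, 0.5))

    def test_event_with_zero_inclusion_only_for_none(self):
        with pytest.raises(ValueError):
            PlantedEvent(gene_id="g", scenario="none", inclusion_kd=0.2)


class TestGenerateAnnotation:
    def test_no_events_when_fraction_zero(self):
        bundle, events = generate_annotation(small_config(n_genes=1, fraction_with_events=0))
        assert len(bundle.genes) == 1
        assert all(ev.scenario == "none" for ev in events)

    def test_fixed_seed_reproducible(self):
        cfg = small_config()
        b1, e1 = generate_annotation(cfg)
        b2, e2 = generate_annotation(cfg)
        assert e1 == e2
        assert b1.alu_elements == b2.alu_elements
        assert b1.predicted_exons == b2.predicted_exons

    def test_pure_scenario_mix(self):
        cfg = small_config(fraction_with_events=1.0, scenario_mix=(1.0, 0.0, 0.0))
        _, events = generate_annotation(cfg)
        assert {ev.scenario for ev in events} == {"terminal_exon_skipping"}

    def test_planted_geometry_invariants(self):
        cfg = small_config(n_genes=60, fraction_with_events=0.7, seed=9)
        bundle, events = generate_annotation(cfg)
        lo, hi = cfg.distance_bounds
        for ev in events:
            if ev.scenario == "none":
                continue
            gene = bundle.genes[ev.gene_id]
            # antisense element containing the exon's splice sites
            assert ev.alu_interval.strand != gene.strand
            assert ev.alu_interval.start <= ev.alu_exon.start
            assert ev.alu_exon.end <= ev.alu_interval.end
            assert lo <= ev.distance_bp <= hi
            # planted distance equals the strand-aware polyA-to-boundary gap
            polya = gene.last_polya()
            if gene.strand == "+":
                assert ev.alu_exon.start - polya == ev.distance_bp
            else:
                assert polya - ev.alu_exon.end == ev.distance_bp

    def test_every_gene_has_genuine_polya(self):
        bundle, _ = generate_annotation(small_config())
        assert all(g.polya_sites for g in bundle.genes.values())


class TestSimulateReads:
    def test_zero_inclusion_means_no_alu_junctions(self):
        cfg = small_config(
            n_genes=10,
            fraction_with_events=1.0,
            inclusion_kd=(0.0, 0.0),
            inclusion_control=(0.0, 0.0),
        )
        bundle, events = generate_annotation(cfg)
        reads = simulate_reads(bundle, events, cfg, "kd")
        acceptors = {
            (ev.alu_exon.chrom, acceptor_boundary(ev.alu_exon)) for ev in events
        }
        for r in reads:
            for gs, ge in r.gaps:
                assert (r.chrom, ge) not in acceptors
                assert (r.chrom, gs) not in acceptors

    def test_full_inclusion_skipping_leaves_no_terminal_acceptor_reads(self):
        cfg = small_config(
            n_genes=6,
            fraction_with_events=1.0,
            scenario_mix=(1.0, 0.0, 0.0),
            inclusion_kd=(1.0, 1.0),
        )
        bundle, events = generate_annotation(cfg)
        reads = simulate_reads(bundle, events, cfg, "kd")
        term_acceptors = set()
        for gene in bundle.genes.values():
            tx = gene.transcripts[0]
            term = tx.terminal_exon
            term_acceptors.add(
                (gene.chrom, term.start if gene.strand == "+" else term.end)
            )
        for r in reads:
            for gs, ge in r.gaps:
                assert (r.chrom, ge) not in term_acceptors
                assert (r.chrom, gs) not in term_acceptors

    def test_alu_read_fraction_obeys_binomial_law(self):
        cfg = small_config(
            n_genes=1,
            fraction_with_events=1.0,
            scenario_mix=(1.0, 0.0, 0.0),
            read_depth=1000,
            inclusion_kd=(0.3, 0.3),
        )
        bundle, events = generate_annotation(cfg)
        reads = simulate_reads(bundle, events, cfg, "kd")
        n_alu = sum("alu" in r.read_id for r in reads)
        p, n = 0.3, 1000
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(n_alu / n - p) <= 3 * sd

    def test_read_lengths_exact_and_blocks_sorted(self):
        cfg = small_config(n_genes=8, fraction_with_events=1.0)
        bundle, events = generate_annotation(cfg)
        for r in simulate_reads(bundle, events, cfg, "kd"):
            assert r.aligned_length == cfg.read_length
            starts = [b.start for b in r.blocks]
            assert starts == sorted(starts)

    def test_fixed_seed_reproducible(self):
        cfg = small_config(n_genes=5, fraction_with_events=1.0)
        bundle, events = generate_annotation(cfg)
        r1 = simulate_reads(bundle, events, cfg, "control")
        r2 = simulate_reads(bundle, events, cfg, "control")
        assert r1 == r2


class TestFpkmMatrix:
    def test_planted_relative_abundance_consistent(self):
        cfg = small_config(n_genes=10, fraction_with_events=1.0)
        _, events = generate_annotation(cfg)
        fpkm, truth = generate_fpkm_matrix(events, cfg)
        for row in truth.itertuples():
            gene_rows = fpkm[fpkm["gene_id"] == row.gene_id]
            total = gene_rows[row.tissue].sum()
            alu = gene_rows.loc[gene_rows["contains_alu_exon"], row.tissue].sum()
            if math.isnan(row.relative_abundance):
                assert total == 0
            else:
                assert alu / total == pytest.approx(row.relative_abundance)

    def test_fixed_seed_reproducible(self):
        cfg = small_config(n_genes=6, fraction_with_events=1.0)
        _, events = generate_annotation(cfg)
        f1, t1 = generate_fpkm_matrix(events, cfg)
        f2, t2 = generate_fpkm_matrix(events, cfg)
        assert f1.equals(f2) and t1.equals(t2)
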