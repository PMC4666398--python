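"""Pipeline orchestration: simulate -> detect -> classify -> abundance -> orthologs.

Stages communicate through files in one output directory so CLI runs and
library runs behave identically.  Every output file carries a header
naming the tool version, the configuration hash and the seed; identical
config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import IsoformAbundanceMatrix
from .classify import ReadEvidence, classify_calls
from .detect import aggregate_junctions, call_alu_exons
from .io import (
    AnnotationBundle,
    assign_polya_to_genes,
    calls_to_frame,
    read_bed,
    read_calls,
    read_fpkm,
    read_gtf,
    read_sam,
    write_bed,
    write_calls,
    write_gtf,
    write_sam,
)
from .orthologs import load_ortholog_pairs, verdicts_frame
from .report import summarize_calls
from .simulate import (
    PlantedEvent,
    SimulationConfig,
    chrom_lengths,
    generate_annotation,
    generate_fpkm_matrix,
    simulate_reads,
    truth_frame,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "detect", "classify", "abundance", "orthologs")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Effective parameters of a pipeline run.

    The config hash covers every analysis parameter (not paths or log
    level), so it changes iff an effective parameter changes.
    """

    outdir: str = "aluexon_out"
    stages: tuple[str, ...] = ("simulate", "detect", "classify", "abundance")
    seed: int = 0
    # analysis thresholds, with documented defaults
    min_junction_reads: int = 1
    min_reads: int = 1
    flank: int = 10
    max_hops: int = 3
    tissue_threshold: float = 0.10
    polya_window: int = 10_000
    detect_condition: str = "kd"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # inputs for non-simulated runs / ortholog stage
    human_gtf: Optional[str] = None
    mouse_gtf: Optional[str] = None
    correspondence_tsv: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def effective_params(self) -> dict:
        d = dataclasses.asdict(self)
        for skip in ("outdir", "log_level", "human_gtf", "mouse_gtf", "correspondence_tsv"):
            d.pop(skip)
        d["stages"] = list(d["stages"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.effective_params(), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.pop("sim", {}).items()
        })
        d["stages"] = tuple(d.get("stages", ALL_STAGES[:4]))
        return cls(sim=sim, **{k: v for k, v in d.items() if k != "sim"})

    def header_comments(self) -> list[str]:
        return [f"aluexon v{__version__} config={self.config_hash()} seed={self.seed}"]


def _paths(outdir: Path) -> dict[str, Path]:
    return {
        "genome_gtf": outdir / "genome.gtf",
        "alu_bed": outdir / "alu.bed",
        "polya_bed": outdir / "polya.bed",
        "predicted_bed": outdir / "predicted_exons.bed",
        "control_sam": outdir / "control.sam",
        "kd_sam": outdir / "kd.sam",
        "fpkm_tsv": outdir / "fpkm.tsv",
        "fpkm_truth_tsv": outdir / "fpkm_truth.tsv",
        "truth_tsv": outdir / "truth.tsv",
        "candidates_tsv": outdir / "candidates.tsv",
        "calls_tsv": outdir / "calls.tsv",
        "calls_bed": outdir / "calls.bed",
        "summary_tsv": outdir / "summary.tsv",
        "relabund_tsv": outdir / "relabund.tsv",
        "ortholog_tsv": outdir / "ortholog_filter.tsv",
    }


def _write_tsv(df: pd.DataFrame, path: Path, comments: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"#{c}\n")
        df.to_csv(fh, sep="\t", index=False)


def stage_simulate(config: RunConfig, paths: dict[str, Path]) -> None:
    bundle, events = generate_annotation(config.sim)
    comments = config.header_comments()
    write_gtf(bundle.genes.values(), paths["genome_gtf"], comments=comments)
    write_bed(bundle.alu_elements, paths["alu_bed"], comments=comments)
    polya_iv = []
    from .core import GenomicInterval

    for gid, gene in bundle.genes.items():
        for pos in sorted(gene.polya_sites):
            polya_iv.append(GenomicInterval(gene.chrom, pos, pos + 1, gene.strand, name=gid))
    write_bed(polya_iv, paths["polya_bed"], comments=comments)
    named_exons = [
        dataclasses.replace(e, name=f"pe{k}")
        for k, e in enumerate(bundle.predicted_exons)
    ]
    write_bed(named_exons, paths["predicted_bed"], comments=comments)
    lengths = chrom_lengths(config.sim)
    for condition, path_key in (("control", "control_sam"), ("kd", "kd_sam")):
        reads = simulate_reads(bundle, events, config.sim, condition)
        write_sam(reads, paths[path_key], lengths, comments=comments)
    fpkm, fpkm_truth = generate_fpkm_matrix(events, config.sim)
    _write_tsv(fpkm, paths["fpkm_tsv"], comments)
    _write_tsv(fpkm_truth, paths["fpkm_truth_tsv"], comments)
    _write_tsv(truth_frame(events), paths["truth_tsv"], comments)


def _load_bundle(config: RunConfig, paths: dict[str, Path]) -> AnnotationBundle:
    bundle = AnnotationBundle()
    bundle.genes = read_gtf(paths["genome_gtf"])
    bundle.alu_elements = read_bed(paths["alu_bed"], kind="alu")
    bundle.predicted_exons = read_bed(paths["predicted_bed"], kind="exon")
    polya = read_bed(paths["polya_bed"], kind="polya")
    assign_polya_to_genes(polya, bundle.genes, window=config.polya_window)
    return bundle


def stage_detect(config: RunConfig, paths: dict[str, Path]) -> None:
    bundle = _load_bundle(config, paths)
    sam = paths["kd_sam"] if config.detect_condition == "kd" else paths["control_sam"]
    reads = read_sam(sam)
    junctions = aggregate_junctions(reads)
    candidates, rejected = call_alu_exons(
        bundle.predicted_exons,
        bundle.alu_elements,
        junctions,
        min_junction_reads=config.min_junction_reads,
    )
    rows = [
        {
            "chrom": c.exon.chrom,
            "start": c.exon.start,
            "end": c.exon.end,
            "strand": c.exon.strand,
            "alu_element": c.alu_element.name or ".",
            "supported_splice_sites": ",".join(sorted(c.supported_splice_sites)),
            "junction_reads": max(c.supported_splice_sites.values()),
        }
        for c in candidates
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand", "alu_element",
            "supported_splice_sites", "junction_reads",
        ],
    )
    _write_tsv(df, paths["candidates_tsv"], config.header_comments())
    log.info("detect: %d candidates, %d rejected", len(candidates), len(rejected))


def stage_classify(config: RunConfig, paths: dict[str, Path]) -> None:
    bundle = _load_bundle(config, paths)
    evidence = {
        "control": ReadEvidence(read_sam(paths["control_sam"])),
        "kd": ReadEvidence(read_sam(paths["kd_sam"])),
    }
    detect_ev = evidence[config.detect_condition]
    candidates, _ = call_alu_exons(
        bundle.predicted_exons,
        bundle.alu_elements,
        detect_ev.junctions,
        min_junction_reads=config.min_junction_reads,
    )
    calls = classify_calls(
        candidates,
        bundle.genes,
        bundle.predicted_exons,
        evidence,
        detect_condition=config.detect_condition,
        max_hops=config.max_hops,
        min_reads=config.min_reads,
        flank=config.flank,
    )
    comments = config.header_comments()
    write_calls(calls, paths["calls_tsv"], paths["calls_bed"], comments=comments)
    summary = summarize_calls(calls_to_frame(calls))
    df = pd.DataFrame(
        {"metric": list(summary.keys()), "value": [str(v) for v in summary.values()]}
    )
    _write_tsv(df, paths["summary_tsv"], comments)


def stage_abundance(config: RunConfig, paths: dict[str, Path]) -> None:
    matrix = IsoformAbundanceMatrix(read_fpkm(paths["fpkm_tsv"]))
    table = matrix.relative_abundance_table(threshold=config.tissue_threshold)
    _write_tsv(table, paths["relabund_tsv"], config.header_comments())


def stage_orthologs(config: RunConfig, paths: dict[str, Path]) -> None:
    if not (config.human_gtf and config.mouse_gtf and config.correspondence_tsv):
        raise StageError("orthologs", "human_gtf, mouse_gtf and correspondence_tsv required")
    human = read_gtf(config.human_gtf)
    mouse = read_gtf(config.mouse_gtf)
    corr = pd.read_csv(config.correspondence_tsv, sep="\t", comment="#")
    alu_flags: dict[str, set] = {}
    if paths["calls_tsv"].exists():
        calls = read_calls(paths["calls_tsv"])
        for row in calls.itertuples():
            if row.gene_id in human:
                alu_flags.setdefault(row.gene_id, set()).add(
                    (int(row.start), int(row.end))
                )
    pairs = load_ortholog_pairs(human, mouse, corr, alu_flags)
    _write_tsv(verdicts_frame(pairs), paths["ortholog_tsv"], config.header_comments())


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "classify": stage_classify,
    "abundance": stage_abundance,
    "orthologs": stage_orthologs,
}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the enabled stages in canonical order; returns output paths.

    A stage failure raises StageError naming the stage (the CLI maps this
    to a non-zero exit status).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = _paths(outdir)
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.monotonic()
        try:
            STAGE_FUNCS[stage](config, paths)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named error contract
            raise StageError(stage, str(exc)) from exc
        log.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)
    return paths


# ---------------------------------------------------------------------------
# truth comparison


def compare_to_truth(calls_df: pd.DataFrame, truth_df: pd.DataFrame) -> dict:
    """Per-event recovery of planted truth plus aggregate sensitivity/specificity.

    Sensitivity counts planted events recovered with exact locus class,
    scenario, distance and downstream-cryptic-exon count; specificity is
    the fraction of event-free genes with no call.  Raises when the call
    table references genes outside the truth universe.
    """
    truth_genes = set(truth_df["gene_id"])
    call_genes = set(calls_df["gene_id"]) - {".", ""}
    unknown = call_genes - truth_genes
    if unknown:
        raise ValueError(f"calls reference genes not in truth: {sorted(unknown)[:5]}")

    calls_by_gene = {g: grp for g, grp in calls_df.groupby("gene_id")}
    rows = []
    for ev in truth_df.itertuples():
        planted = ev.scenario != "none"
        grp = calls_by_gene.get(ev.gene_id)
        if not planted:
            rows.append(
                {
                    "gene_id": ev.gene_id,
                    "planted": False,
                    "called": grp is not None,
                    "matched": grp is None,
                }
            )
            continue
        matched = False
        if grp is not None:
            for call in grp.itertuples():
                if (
                    call.locus_class == "intergenic"
                    and call.scenario == ev.scenario
                    and int(call.distance_bp) == int(ev.distance_bp)
                    and int(call.downstream_cryptic_exons)
                    == int(ev.n_downstream_cryptic_exons)
                ):
                    matched = True
                    break
        rows.append(
            {
                "gene_id": ev.gene_id,
                "planted": True,
                "called": grp is not None,
                "matched": matched,
            }
        )
    table = pd.DataFrame(rows)
    planted = table[table["planted"]]
    clean = table[~table["planted"]]
    sensitivity = float(planted["matched"].mean()) if len(planted) else None
    specificity = float(clean["matched"].mean()) if len(clean) else None
    return {
        "per_event": table,
        "n_planted": int(len(planted)),
        "n_event_free": int(len(clean)),
        "sensitivity": sensitivity,
        "specificity": specificity,
    }
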