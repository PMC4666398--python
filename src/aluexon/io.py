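"""Readers and writers for the formats the pipeline touches.

SAM (single-end text subset: M/N/S CIGAR ops, FLAG 0x10 for strand), BED6,
GTF2.2 exon annotation, and the TSV tables the stages exchange.  Parsing is
backed by pysam (SAM) and gffutils (GTF); everything is converted to the
package's internal 0-based half-open convention at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
import pandas as pd
import pysam

from .core import AlignedRead, GeneModel, GenomicInterval, Transcript

log = logging.getLogger(__name__)

BED_KINDS = ("alu", "polya", "exon")

#: columns of calls.tsv, in stable order
CALL_COLUMNS = [
    "call_id",
    "chrom",
    "start",
    "end",
    "strand",
    "alu_element",
    "gene_id",
    "locus_class",
    "scenario",
    "distance_bp",
    "splicing_contribution",
    "downstream_cryptic_exons",
    "inclusion_control",
    "inclusion_kd",
    "supported_splice_sites",
]


@dataclass
class AnnotationBundle:
    """Everything the detection and classification stages consume."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    alu_elements: list[GenomicInterval] = field(default_factory=list)
    predicted_exons: list[GenomicInterval] = field(default_factory=list)


class SamFormatError(ValueError):
    pass


def _blocks_from_cigar(
    chrom: str, strand: str, pos: int, cigartuples: Sequence[tuple[int, int]]
) -> list[GenomicInterval]:
    """Apply M/N/S CIGAR semantics; any other op rejects the record."""
    blocks: list[GenomicInterval] = []
    cur_start: Optional[int] = None
    cursor = pos
    for op, length in cigartuples:
        if op == 0:  # M: consumes read and reference
            if cur_start is None:
                cur_start = cursor
            cursor += length
        elif op == 3:  # N: splice gap, closes the current block
            if cur_start is None:
                raise SamFormatError("CIGAR starts with N")
            blocks.append(GenomicInterval(chrom, cur_start, cursor, strand))
            cursor += length
            cur_start = None
        elif op == 4:  # S: consumes read only
            continue
        else:
            raise SamFormatError(f"unsupported CIGAR op code {op}")
    if cur_start is None:
        raise SamFormatError("CIGAR ends in a gap / aligns nothing")
    blocks.append(GenomicInterval(chrom, cur_start, cursor, strand))
    return blocks


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read single-end SAM into AlignedReads.

    M runs become aligned blocks, N runs become gaps, S runs are trimmed;
    unmapped records are skipped and records with other CIGAR ops are
    rejected with a warning.  Raises if more than half of the mapped
    records fail to parse.
    """
    reads: list[AlignedRead] = []
    n_bad = 0

    def add(name: str, chrom: str, strand: str, pos: int, cigartuples) -> None:
        nonlocal n_bad
        try:
            blocks = _blocks_from_cigar(chrom, strand, pos, cigartuples)
            reads.append(AlignedRead(name, chrom, strand, tuple(blocks)))
        except (SamFormatError, ValueError) as exc:
            n_bad += 1
            log.warning("skipping SAM record %s: %s", name, exc)

    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                strand = "-" if rec.is_reverse else "+"
                add(
                    rec.query_name,
                    rec.reference_name,
                    strand,
                    rec.reference_start,
                    rec.cigartuples or [],
                )
    except NotImplementedError:
        # headerless SAM text: pysam cannot iterate without @SQ lines
        for name, chrom, strand, pos, cig in _iter_headerless_sam(path):
            add(name, chrom, strand, pos, cig)
    total = len(reads) + n_bad
    if total and n_bad > total / 2:
        raise SamFormatError(f"{n_bad}/{total} SAM records failed to parse")
    return reads


_CIGAR_OPS = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}


def _iter_headerless_sam(path: str | Path):
    import re

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise SamFormatError(f"SAM record with {len(fields)} fields")
            name, flag_s, chrom, pos_s, _mapq, cigar = fields[:6]
            flag, pos = int(flag_s), int(pos_s)
            if flag & 0x4 or chrom == "*":
                continue
            cig = [
                (_CIGAR_OPS[op], int(n)) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
            ]
            yield name, chrom, "-" if flag & 0x10 else "+", pos - 1, cig


def write_sam(
    reads: Iterable[AlignedRead],
    path: str | Path,
    chrom_lengths: dict[str, int],
    comments: Sequence[str] = (),
) -> None:
    """Write reads as a headered SAM file (deterministic byte output)."""
    header: dict = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_lengths.items())],
    }
    if comments:
        header["CO"] = list(comments)
    with pysam.AlignmentFile(str(path), "w", header=pysam.AlignmentHeader.from_dict(header)) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.flag = 16 if read.strand == "-" else 0
            rec.reference_name = read.chrom
            rec.reference_start = read.blocks[0].start
            rec.mapping_quality = 255
            cig: list[tuple[int, int]] = []
            for i, b in enumerate(read.blocks):
                if i:
                    cig.append((3, b.start - read.blocks[i - 1].end))
                cig.append((0, len(b)))
            rec.cigartuples = cig
            out.write(rec)


class BedFormatError(ValueError):
    pass


def read_bed(path: str | Path, kind: str) -> list[GenomicInterval]:
    """Read a BED6 file into labelled intervals.

    ``kind`` selects the label namespace (alu element name, polyA site
    name / gene link, or predicted-exon id).  Malformed lines raise with
    their line number.
    """
    if kind not in BED_KINDS:
        raise ValueError(f"kind must be one of {BED_KINDS}, got {kind!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedFormatError(f"{path}:{lineno}: expected >= 6 BED columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                out.append(GenomicInterval(chrom, start, end, strand, name=name))
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"#{c}\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def polya_cleavage_position(site: GenomicInterval) -> int:
    """Collapse a polyA track interval to its strand-wise 3'-most base."""
    return site.three_prime


def assign_polya_to_genes(
    sites: Sequence[GenomicInterval],
    genes: dict[str, GeneModel],
    window: int = 10_000,
) -> None:
    """Assign each polyA site to exactly one gene, in place.

    A site whose name column matches a gene id goes to that gene;
    otherwise to the nearest same-strand gene whose span lies within
    ``window`` bp.  Unassignable sites are dropped with a warning.
    """
    for site in sites:
        pos = polya_cleavage_position(site)
        if site.name in genes:
            genes[site.name].polya_sites.append(pos)
            continue
        best: tuple[int, str] | None = None
        for gid, gene in genes.items():
            if gene.strand != site.strand or gene.chrom != site.chrom:
                continue
            span = gene.span
            dist = 0 if span.contains(pos) else min(
                abs(pos - span.start), abs(pos - (span.end - 1))
            )
            if dist <= window and (best is None or dist < best[0]):
                best = (dist, gid)
        if best is None:
            log.warning("polyA site %s:%d unassigned to any gene", site.chrom, pos)
        else:
            genes[best[1]].polya_sites.append(pos)


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Read exon features from a GTF file into GeneModels.

    1-based closed GTF coordinates are converted to 0-based half-open;
    exons are grouped into transcripts by transcript_id and transcripts
    by gene_id; exon order within transcripts is sorted genomically.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[tuple[str, str], list[GenomicInterval]] = {}
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes:
            raise ValueError(f"exon at {feat.seqid}:{feat.start} lacks transcript_id")
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes["transcript_id"][0]
        per_tx.setdefault((gid, tid), []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    genes: dict[str, GeneModel] = {}
    for (gid, tid), exons in per_tx.items():
        gene = genes.setdefault(gid, GeneModel(gene_id=gid))
        gene.transcripts.append(Transcript(tid, tuple(exons)))
    return genes


def write_gtf(
    genes: Iterable[GeneModel], path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write GeneModels as exon features (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"#{c}\n")
        for gene in genes:
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        f"{exon.chrom}\taluexon\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{exon.strand}\t.\t{attrs}\n"
                    )


def calls_to_frame(calls: Sequence) -> pd.DataFrame:
    """Flatten AluExonCall objects into the stable calls.tsv layout."""
    rows = []
    for call in calls:
        exon = call.candidate.exon
        rows.append(
            {
                "call_id": call.call_id,
                "chrom": exon.chrom,
                "start": exon.start,
                "end": exon.end,
                "strand": exon.strand,
                "alu_element": call.candidate.alu_element.name or ".",
                "gene_id": call.gene_id or ".",
                "locus_class": call.locus_class,
                "scenario": call.scenario,
                "distance_bp": "" if call.distance_bp is None else call.distance_bp,
                "splicing_contribution": ""
                if call.splicing_contribution is None
                else f"{call.splicing_contribution:.6g}",
                "downstream_cryptic_exons": call.downstream_cryptic_exon_count,
                "inclusion_control": ""
                if call.inclusion.get("control") is None
                else f"{call.inclusion['control']:.6g}",
                "inclusion_kd": ""
                if call.inclusion.get("kd") is None
                else f"{call.inclusion['kd']:.6g}",
                "supported_splice_sites": ",".join(
                    sorted(call.candidate.supported_splice_sites)
                ),
            }
        )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.sort_values(["chrom", "start", "call_id"]).reset_index(drop=True)


def write_calls(
    calls: Sequence,
    tsv_path: str | Path,
    bed_path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    """Write finalized calls as a TSV plus a BED6 of the exon intervals.

    Row order is deterministic (chrom, start, call id); re-running on
    identical input yields byte-identical files.
    """
    df = calls_to_frame(calls)
    with open(tsv_path, "w") as fh:
        for c in comments:
            fh.write(f"#{c}\n")
        df.to_csv(fh, sep="\t", index=False)
    by_id = {c.call_id: c for c in calls}
    ordered = [by_id[cid] for cid in df["call_id"]]
    write_bed(
        [
            GenomicInterval(
                c.candidate.exon.chrom,
                c.candidate.exon.start,
                c.candidate.exon.end,
                c.candidate.exon.strand,
                name=c.call_id,
            )
            for c in ordered
        ],
        bed_path,
        comments=comments,
    )


def read_calls(tsv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", comment="#")


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Read an isoform FPKM table (gene_id, isoform_id, contains_alu_exon, tissues...)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "isoform_id", "contains_alu_exon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FPKM table missing columns: {sorted(missing)}")
    return df
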