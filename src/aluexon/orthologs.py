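"""Human/mouse ortholog filter for Alu-derived 3' transcript extensions.

A human gene passes when, relative to its mouse orthologue, (i) a human
transcript's 3' end extends beyond the human exon corresponding to the
mouse terminal exon, (ii) at least one Alu-derived exon lies downstream
of that conserved terminal exon, and (iii) no human exon downstream of
the Alu exon is itself conserved (present in the exon correspondence).

The exon correspondence is input data (conserved exon pairs, e.g. from a
whole-genome orthology resource), never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import GeneModel, GenomicInterval, is_downstream

ExonKey = tuple[int, int]  # (start, end) of an exon on the gene's chromosome


@dataclass
class OrthologPair:
    """One human gene paired with its mouse orthologue.

    ``exon_correspondence`` maps conserved human exons to mouse exons by
    coordinates (one-to-one over the exons it covers);
    ``mouse_terminal_in_human`` is the human exon corresponding to the
    mouse terminal exon and must be part of the correspondence;
    ``alu_exon_keys`` flags the human exons that are Alu-derived.
    """

    human_gene: GeneModel
    mouse_gene: GeneModel
    exon_correspondence: dict[ExonKey, ExonKey]
    mouse_terminal_in_human: GenomicInterval
    alu_exon_keys: frozenset[ExonKey] = frozenset()

    def __post_init__(self) -> None:
        values = list(self.exon_correspondence.values())
        if len(set(values)) != len(values):
            raise ValueError("exon correspondence must be one-to-one")
        key = (self.mouse_terminal_in_human.start, self.mouse_terminal_in_human.end)
        if key not in self.exon_correspondence:
            raise ValueError("mouse_terminal_in_human must be in the correspondence")


@dataclass
class FilterVerdict:
    gene_id: str
    extends_beyond_mouse: bool
    alu_exon_downstream: bool
    no_conserved_after_alu: bool

    @property
    def passed(self) -> bool:
        return (
            self.extends_beyond_mouse
            and self.alu_exon_downstream
            and self.no_conserved_after_alu
        )


def filter_pair(pair: OrthologPair) -> FilterVerdict:
    """Evaluate the three criteria on one ortholog pair.

    Criterion (iii) is evaluated relative to the 5'-most qualifying Alu
    exon; it is vacuously true when no Alu exon qualifies (the pair then
    already fails criterion ii).
    """
    human = pair.human_gene
    strand = human.strand
    mt = pair.mouse_terminal_in_human
    mt_3p = mt.three_prime

    extends = any(
        is_downstream(tx.three_prime_end, mt_3p, strand) for tx in human.transcripts
    )

    alu_downstream = [
        e
        for e in human.exons
        if (e.start, e.end) in pair.alu_exon_keys
        and is_downstream(e.five_prime, mt_3p, strand)
    ]

    no_conserved_after = True
    if alu_downstream:
        # 5'-most qualifying Alu exon in transcription direction
        first_alu = min(
            alu_downstream,
            key=lambda e: e.start if strand == "+" else -e.end,
        )
        for e in human.exons:
            if (e.start, e.end) in pair.exon_correspondence and is_downstream(
                e.five_prime, first_alu.three_prime, strand
            ):
                no_conserved_after = False
                break

    return FilterVerdict(
        gene_id=human.gene_id,
        extends_beyond_mouse=extends,
        alu_exon_downstream=bool(alu_downstream),
        no_conserved_after_alu=no_conserved_after,
    )


def summarize_filter(pairs: Sequence[OrthologPair]) -> dict:
    """Deterministic tallies per criterion and the sorted passing gene list."""
    verdicts = [filter_pair(p) for p in pairs]
    return {
        "n_pairs": len(verdicts),
        "n_extends_beyond_mouse": sum(v.extends_beyond_mouse for v in verdicts),
        "n_alu_exon_downstream": sum(v.alu_exon_downstream for v in verdicts),
        "n_no_conserved_after_alu": sum(v.no_conserved_after_alu for v in verdicts),
        "n_passing": sum(v.passed for v in verdicts),
        "passing_genes": sorted(v.gene_id for v in verdicts if v.passed),
    }


def verdicts_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": v.gene_id,
            "extends_beyond_mouse": v.extends_beyond_mouse,
            "alu_exon_downstream": v.alu_exon_downstream,
            "no_conserved_after_alu": v.no_conserved_after_alu,
            "passed": v.passed,
        }
        for v in (filter_pair(p) for p in pairs)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "extends_beyond_mouse",
            "alu_exon_downstream",
            "no_conserved_after_alu",
            "passed",
        ],
    ).sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# correspondence table I/O

CORRESPONDENCE_COLUMNS = [
    "human_gene",
    "human_exon_start",
    "human_exon_end",
    "mouse_gene",
    "mouse_exon_start",
    "mouse_exon_end",
    "is_mouse_terminal",
]


def load_ortholog_pairs(
    human_genes: dict[str, GeneModel],
    mouse_genes: dict[str, GeneModel],
    correspondence: pd.DataFrame,
    alu_flags: dict[str, set[ExonKey]],
) -> list[OrthologPair]:
    """Assemble OrthologPairs from annotation plus a correspondence table.

    The table has one row per conserved exon pair (columns as in
    ``CORRESPONDENCE_COLUMNS``); ``is_mouse_terminal`` marks the human
    exon corresponding to the mouse terminal exon, exactly once per gene
    pair.  ``alu_flags`` carries the Alu-exon coordinates per human gene
    (typically from the classification stage's calls).
    """
    missing = set(CORRESPONDENCE_COLUMNS) - set(correspondence.columns)
    if missing:
        raise ValueError(f"correspondence table missing columns: {sorted(missing)}")
    pairs = []
    for (hgid, mgid), grp in correspondence.groupby(["human_gene", "mouse_gene"], sort=True):
        if hgid not in human_genes:
            raise KeyError(f"unknown human gene {hgid!r}")
        if mgid not in mouse_genes:
            raise KeyError(f"unknown mouse gene {mgid!r}")
        human = human_genes[hgid]
        corr = {
            (int(r.human_exon_start), int(r.human_exon_end)): (
                int(r.mouse_exon_start),
                int(r.mouse_exon_end),
            )
            for r in grp.itertuples()
        }
        term_rows = grp[grp["is_mouse_terminal"].astype(bool)]
        if len(term_rows) != 1:
            raise ValueError(
                f"pair {hgid}/{mgid}: need exactly one is_mouse_terminal row"
            )
        ts, te = int(term_rows.iloc[0]["human_exon_start"]), int(
            term_rows.iloc[0]["human_exon_end"]
        )
        mt = GenomicInterval(human.chrom, ts, te, human.strand)
        pairs.append(
            OrthologPair(
                human_gene=human,
                mouse_gene=mouse_genes[mgid],
                exon_correspondence=corr,
                mouse_terminal_in_human=mt,
                alu_exon_keys=frozenset(alu_flags.get(hgid, set())),
            )
        )
    return pairs
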