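"""Tissue-wise relative abundance of Alu-exon-containing isoforms.

Relative abundance of the Alu group in a tissue is the sum of FPKM over
the gene's Alu-exon-containing isoforms divided by the sum over all of
the gene's isoforms; it is undefined (None/NaN) where the gene's total
FPKM is zero.  Expression is displayed as log2(FPKM + 1).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("gene_id", "isoform_id", "contains_alu_exon")


class IsoformAbundanceMatrix:
    """Per-isoform, per-tissue FPKM with Alu-containing grouping."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(META_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self.tissues = [c for c in frame.columns if c not in META_COLUMNS]
        if not self.tissues:
            raise ValueError("no tissue columns")
        vals = self.frame[self.tissues].to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("FPKM values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene_id"].unique())

    def _gene_rows(self, gene_id: str) -> pd.DataFrame:
        rows = self.frame[self.frame["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(f"unknown gene {gene_id!r}")
        return rows

    def relative_abundance(self, gene_id: str, tissue: str) -> Optional[float]:
        """Alu-group FPKM over total gene FPKM in one tissue; None when the
        denominator is zero."""
        if tissue not in self.tissues:
            raise KeyError(f"unknown tissue {tissue!r}")
        rows = self._gene_rows(gene_id)
        total = float(rows[tissue].sum())
        if total == 0:
            return None
        alu = float(rows.loc[rows["contains_alu_exon"].astype(bool), tissue].sum())
        return alu / total

    def group_isoforms(self, gene_id: str) -> pd.DataFrame:
        """Per-tissue (alu_fraction, other_fraction) pair; NaN where undefined.

        Wherever defined the two fractions sum to 1 exactly.
        """
        rows = self._gene_rows(gene_id)
        out = []
        for tissue in self.tissues:
            r = self.relative_abundance(gene_id, tissue)
            out.append(
                {
                    "tissue": tissue,
                    "alu_fraction": math.nan if r is None else r,
                    "other_fraction": math.nan if r is None else 1.0 - r,
                }
            )
        return pd.DataFrame(out)

    def tissue_specific(self, gene_id: str, threshold: float = 0.10) -> bool:
        """True when the max-min spread of relative abundance across tissues
        (undefined tissues excluded) exceeds ``threshold``."""
        values = [
            r
            for tissue in self.tissues
            if (r := self.relative_abundance(gene_id, tissue)) is not None
        ]
        if len(values) < 2:
            return False
        return (max(values) - min(values)) > threshold

    def relative_abundance_table(self, threshold: float = 0.10) -> pd.DataFrame:
        """Long-form table of relative abundances plus the tissue-specific flag."""
        rows = []
        for gene in self.genes:
            flag = self.tissue_specific(gene, threshold)
            for tissue in self.tissues:
                r = self.relative_abundance(gene, tissue)
                rows.append(
                    {
                        "gene_id": gene,
                        "tissue": tissue,
                        "relative_abundance": math.nan if r is None else r,
                        "tissue_specific": flag,
                    }
                )
        return pd.DataFrame(rows)


def log_expression(fpkm) -> float:
    """log2(FPKM + 1); raises on negative input."""
    arr = np.asarray(fpkm, dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM must be >= 0")
    out = np.log2(arr + 1.0)
    return float(out) if out.ndim == 0 else out


def relative_abundance(
    matrix: IsoformAbundanceMatrix, gene_id: str, tissue: str
) -> Optional[float]:
    return matrix.relative_abundance(gene_id, tissue)


def group_isoforms(matrix: IsoformAbundanceMatrix, gene_id: str) -> pd.DataFrame:
    return matrix.group_isoforms(gene_id)
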