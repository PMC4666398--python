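"""Summary statistics and small arithmetic helpers for reports.

The same helpers that build summary.tsv are used to recompute headline
fractions (scenario totals, downstream-cryptic-exon fraction, tissue
inclusion fraction) from printed per-class counts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage of numerator over denominator, rounded for display."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round(100.0 * numerator / denominator, digits)


def scenario_total(counts: Sequence[int]) -> int:
    """Total event count as the sum over mechanism classes."""
    return int(sum(counts))


def contribution_histogram(values: Sequence[float], n_bins: int = 10) -> pd.DataFrame:
    """Equal-width histogram of splicing contributions on [0, 1].

    The right edge of the last bin is inclusive, so a contribution of
    exactly 1 is counted.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def distance_histogram(values: Sequence[int], bin_width: int = 1000) -> pd.DataFrame:
    """Distance histogram in fixed-width (default 1 kb) bins."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return pd.DataFrame({"bin_low": [], "bin_high": [], "count": []})
    top = int(np.ceil(vals.max() / bin_width)) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1].astype(int), "bin_high": edges[1:].astype(int), "count": counts}
    )


def summarize_calls(calls_df: pd.DataFrame) -> dict:
    """Headline numbers for summary.tsv from a calls table."""
    inter = calls_df[calls_df["locus_class"] == "intergenic"]
    distances = pd.to_numeric(inter["distance_bp"], errors="coerce").dropna()
    contributions = pd.to_numeric(
        calls_df["splicing_contribution"], errors="coerce"
    ).dropna()
    n_with_cryptic = int(
        (pd.to_numeric(inter["downstream_cryptic_exons"], errors="coerce") > 0).sum()
    )
    summary: dict = {
        "total_alu_exons": int(len(calls_df)),
        "intergenic": int(len(inter)),
        "intronic": int((calls_df["locus_class"] == "intronic").sum()),
        "unlinked": int((calls_df["locus_class"] == "unlinked").sum()),
    }
    for scen in ("terminal_exon_skipping", "cryptic_5ss", "both", "not_applicable"):
        summary[f"scenario_{scen}"] = int((inter["scenario"] == scen).sum())
    summary["distance_min_bp"] = int(distances.min()) if len(distances) else ""
    summary["distance_median_bp"] = (
        float(distances.median()) if len(distances) else ""
    )
    summary["distance_max_bp"] = int(distances.max()) if len(distances) else ""
    summary["downstream_cryptic_fraction_pct"] = (
        percent(n_with_cryptic, len(inter)) if len(inter) else ""
    )
    hist = contribution_histogram(contributions)
    for row in hist.itertuples():
        summary[f"contribution_{row.bin_low:.1f}_{row.bin_high:.1f}"] = int(row.count)
    return summary
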