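"""Sequencing-level QC and neighborhood co-regulation analysis.

4sU incorporated into nascent RNA mispairs during reverse transcription,
producing T>C conversions; their enrichment in the labeled over the total
library verifies the metabolic labeling. The spliced-read fraction (reads
with an alignment gap) verifies that labeled RNA is co-transcriptionally
spliced. Neighborhood correlation quantifies co-regulation of genes with
nearby (intergenic) transcription units as a function of distance and
relative strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


def conversion_enrichment(
    lrna_stats: pd.DataFrame, frna_stats: pd.DataFrame, min_positions: int = 1000
) -> float:
    """T>C conversion rate of the labeled over the total library.

    Rates are aggregated position-level per library: sum of conversions over
    the sum of T positions. NaN when the FRNA rate is zero (flag case).
    """
    for name, df in (("LRNA", lrna_stats), ("FRNA", frna_stats)):
        if df["n_t_positions"].sum() < min_positions:
            raise ValueError(f"{name}: fewer than {min_positions} T positions")
    rate_l = lrna_stats["n_t_to_c"].sum() / lrna_stats["n_t_positions"].sum()
    rate_f = frna_stats["n_t_to_c"].sum() / frna_stats["n_t_positions"].sum()
    if rate_f == 0:
        return float("nan")
    return float(rate_l / rate_f)


def spliced_fraction(stats: pd.DataFrame, gene_ids=None) -> pd.Series:
    """Percent of reads with a splice gap, per gene; genes with 0 reads dropped.

    ``stats`` needs columns ``gene_id`` and ``has_splice_gap``. Summarize
    with ``.median()`` / ``.quantile([0.25, 0.75])``.
    """
    if gene_ids is not None:
        stats = stats[stats["gene_id"].isin(gene_ids)]
    counts = stats.groupby("gene_id")["has_splice_gap"].agg(["sum", "count"])
    counts = counts[counts["count"] > 0]
    return 100.0 * counts["sum"] / counts["count"]


def neighborhood_correlation(
    pairs: pd.DataFrame,
    distance_bins,
    stratify_by: str | None = None,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Pearson r of (gene log2FC, neighbor log2FC) per distance bin.

    ``pairs`` needs ``gene_log2fc``, ``neighbor_log2fc`` and ``distance``
    (bp, signed, gene-oriented); ``stratify_by`` may name an extra grouping
    column (e.g. ``relative_strand``). Bins with fewer than ``min_pairs``
    pairs, or zero variance, are reported with r = NaN.
    """
    df = pairs.copy()
    df["distance_bin"] = pd.cut(df["distance"], distance_bins)
    group_cols = ["distance_bin"] + ([stratify_by] if stratify_by else [])
    rows = []
    for keys, grp in df.groupby(group_cols, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(grp)
        if (
            n < min_pairs
            or grp["gene_log2fc"].std() == 0
            or grp["neighbor_log2fc"].std() == 0
        ):
            r = float("nan")
        else:
            r = float(pearsonr(grp["gene_log2fc"], grp["neighbor_log2fc"])[0])
        rows.append((*keys, n, r))
    return pd.DataFrame(rows, columns=group_cols + ["n_pairs", "pearson_r"])
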