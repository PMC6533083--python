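"""Median-scaled outlier statistics for an expression compendium.

The procedure flags (gene, sample) pairs whose expression is extreme both
relative to the gene's own median across samples (``row_fold``) and relative
to the transcriptome-wide median within the sample (``col_fold``). A pair is
an outlier only when both folds strictly exceed their cutoffs (defaults
32 and 64). Folds with a zero median denominator are undefined (NaN) and are
never outliers; an optional pseudocount added to all values before the
medians is available for sensitivity analysis.

Median convention: the mean of the two central order statistics for
even-length vectors (numpy's default), stated so independent re-computations
agree bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionCompendium, OutlierCalls


def row_fold(
    compendium: ExpressionCompendium, pseudocount: float = 0.0
) -> np.ndarray:
    """Each value divided by its gene's median across samples.

    Returns a genes x samples array; rows whose across-sample median is zero
    are NaN (undefined).
    """
    x = compendium.values + pseudocount
    med = np.median(x, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x / med
    out[np.broadcast_to(med == 0, out.shape)] = np.nan
    return out


def col_fold(
    compendium: ExpressionCompendium, pseudocount: float = 0.0
) -> np.ndarray:
    """Each value divided by the median of all genes within its sample.

    The within-sample median includes the focal gene. Columns whose median
    is zero are NaN (undefined).
    """
    x = compendium.values + pseudocount
    med = np.median(x, axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x / med
    out[np.broadcast_to(med == 0, out.shape)] = np.nan
    return out


def call_outliers(
    compendium: ExpressionCompendium,
    row_cutoff: float = 32.0,
    col_cutoff: float = 64.0,
    pseudocount: float = 0.0,
) -> OutlierCalls:
    """Joint outlier call: both folds defined and strictly above cutoff."""
    if row_cutoff <= 0 or col_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    rf = row_fold(compendium, pseudocount)
    cf = col_fold(compendium, pseudocount)
    with np.errstate(invalid="ignore"):
        flag = (rf > row_cutoff) & (cf > col_cutoff)
    flag &= np.isfinite(rf) & np.isfinite(cf)
    return OutlierCalls(
        gene_ids=compendium.gene_ids,
        sample_ids=compendium.sample_ids,
        row_fold=rf,
        col_fold=cf,
        is_outlier=flag,
        row_cutoff=float(row_cutoff),
        col_cutoff=float(col_cutoff),
    )


def outlier_gene_table(
    calls: OutlierCalls, compendium: ExpressionCompendium
) -> pd.DataFrame:
    """Per (gene, lineage) outlier-sample counts.

    Only (gene, lineage) pairs with at least one outlier sample are listed;
    genes with no outlier samples anywhere are omitted entirely.
    """
    if calls.gene_ids != compendium.gene_ids or (
        calls.sample_ids != compendium.sample_ids
    ):
        raise ValueError("calls do not derive from this compendium")
    labels = compendium.lineage_labels()
    lineage_sizes = pd.Series(labels).value_counts().to_dict()
    rows = []
    for gi, gene in enumerate(calls.gene_ids):
        hits = calls.is_outlier[gi]
        if not hits.any():
            continue
        counts = pd.Series(labels[hits]).value_counts()
        for lineage in sorted(counts.index):
            rows.append((gene, lineage, int(counts[lineage]),
                         int(lineage_sizes[lineage])))
    return pd.DataFrame(
        rows, columns=["gene", "lineage", "n_outlier_samples", "n_lineage_samples"]
    )
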