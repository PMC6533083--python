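"""From outlier calls and knockout perturbations to a lineage-restricted regulon.

Four complementary views:

* ``lineage_enrichment`` — is a gene's outlier pattern over-represented in a
  lineage? One-sided hypergeometric test with Benjamini-Hochberg correction.
* ``confinement`` — is a gene's expression largely confined to the target
  lineage? Ratio of in-lineage to out-of-lineage mean expression.
* ``infer_network`` / ``master_regulator`` — directed signed edges from
  knockout relative-expression tables; the master regulator is the node with
  maximal activation out-degree.
* ``coexpression`` — pairwise correlation of regulon members on
  log2(x + 1)-transformed expression.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import Edge, ExpressionCompendium, OutlierCalls, PerturbationTable, RegulonNetwork


def lineage_enrichment(
    calls: OutlierCalls, compendium: ExpressionCompendium
) -> pd.DataFrame:
    """Hypergeometric over-representation of outlier samples per lineage.

    For gene g and lineage l: of N samples total, K are outliers for g, n
    belong to l, and k are outlier samples inside l. The one-sided p-value
    is P[X >= k] for X ~ Hypergeom(N, K, n). Only (g, l) pairs with k >= 1
    are tested; q-values are BH-adjusted across all tests performed.
    """
    labels = compendium.lineage_labels()
    lineage_names = sorted(set(labels))
    if len(lineage_names) < 2:
        raise ValueError("enrichment needs at least 2 lineages")
    N = compendium.n_samples
    rows = []
    for gi, gene in enumerate(calls.gene_ids):
        hits = calls.is_outlier[gi]
        K = int(hits.sum())
        if K == 0:
            continue
        for lineage in lineage_names:
            in_l = labels == lineage
            k = int((hits & in_l).sum())
            if k == 0:
                continue
            n = int(in_l.sum())
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append((gene, lineage, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["gene", "lineage", "k", "n", "K", "N", "p_value"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def lineage_means(compendium: ExpressionCompendium) -> pd.DataFrame:
    """Per-gene mean expression within each lineage (genes x lineages)."""
    df = compendium.to_frame()
    return df.T.groupby(compendium.lineage_labels()).mean().T


def confinement(
    compendium: ExpressionCompendium,
    target_lineage: str,
    score_threshold: float = 10.0,
    expr_floor: float = 1.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Score how confined each gene's expression is to the target lineage.

    score = mean(in-lineage) / (mean(out-of-lineage) + pseudocount); a gene
    is "confined" when the score clears the threshold and the in-lineage
    mean clears the expression floor (so silent genes cannot qualify).
    """
    labels = compendium.lineage_labels()
    in_l = labels == target_lineage
    if not in_l.any():
        raise ValueError(f"unknown lineage {target_lineage!r}")
    mean_in = compendium.values[:, in_l].mean(axis=1)
    mean_out = compendium.values[:, ~in_l].mean(axis=1)
    score = mean_in / (mean_out + pseudocount)
    confined = (score >= score_threshold) & (mean_in >= expr_floor)
    return pd.DataFrame({
        "gene": list(compendium.gene_ids),
        "mean_in": mean_in,
        "mean_out": mean_out,
        "confinement_score": score,
        "confined": confined,
    })


def infer_network(
    perturbations: PerturbationTable,
    down_threshold: float = 0.5,
    up_threshold: float = 2.0,
) -> RegulonNetwork:
    """Directed signed edges from knockout relative-expression.

    If knocking out k leaves measured gene t (t != k) at rel_expr <=
    down_threshold, k activates t; at rel_expr >= up_threshold, k represses
    t. Edge magnitude is |log2(rel_expr)|. Self-measurements (the knockout's
    own residual expression) are ignored.
    """
    if not (0 < down_threshold < 1 < up_threshold):
        raise ValueError("need 0 < down_threshold < 1 < up_threshold")
    edges = []
    for ki, k in enumerate(perturbations.knockout_ids):
        for ti, t in enumerate(perturbations.measured_ids):
            if t == k:
                continue
            r = perturbations.rel_expr[ki, ti]
            if r <= down_threshold:
                edges.append(Edge(k, t, "activation", abs(float(np.log2(r)))))
            elif r >= up_threshold:
                edges.append(Edge(k, t, "repression", abs(float(np.log2(r)))))
    nodes = set(perturbations.knockout_ids) | set(perturbations.measured_ids)
    return RegulonNetwork(nodes=frozenset(nodes), edges=frozenset(edges))


def master_regulator(network: RegulonNetwork) -> list[str]:
    """Node(s) of maximal activation out-degree, ties sorted lexicographically."""
    if not network.edges:
        raise ValueError("empty network has no master regulator")
    deg = network.activation_out_degree()
    best = max(deg.values())
    return sorted(n for n, d in deg.items() if d == best)


def coexpression(
    compendium: ExpressionCompendium,
    gene_set: Sequence[str],
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise correlation among a gene set across samples.

    Values are log2(x + 1)-transformed by default (RPKM skew); pass
    ``log_transform=False`` for the raw scale. Constant genes produce NaN
    coefficients flagged in the ``defined`` column rather than errors.
    Results are symmetric; each unordered pair appears once.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if compendium.n_samples < 3:
        raise ValueError("correlation needs >= 3 samples")
    index = {g: i for i, g in enumerate(compendium.gene_ids)}
    missing = [g for g in gene_set if g not in index]
    if missing:
        raise ValueError(f"genes not in compendium: {missing}")
    x = compendium.values[[index[g] for g in gene_set]]
    if log_transform:
        x = np.log2(x + 1.0)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    n = compendium.n_samples
    for i, a in enumerate(gene_set):
        for j in range(i + 1, len(gene_set)):
            b = gene_set[j]
            if np.ptp(x[i]) == 0 or np.ptp(x[j]) == 0:
                rows.append((a, b, np.nan, np.nan, n, False))
                continue
            res = corr(x[i], x[j])
            rows.append((a, b, float(res.statistic), float(res.pvalue), n, True))
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "r", "p_value", "n", "defined"]
    )
    q = np.full(len(df), np.nan)
    ok = df["defined"].to_numpy()
    if ok.any():
        q[ok] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["q_value"] = q
    return df
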