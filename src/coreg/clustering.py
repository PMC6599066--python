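"""Clustering of phenotype-term prediction profiles and gene-cluster
enrichment.

Terms whose prediction profiles correlate describe related biology; on a
patient whose phenotype terms split into uncorrelated clusters this can flag
a possible dual diagnosis. Conversely, a cluster of co-regulated genes can
be characterised by which terms' Z-scores separate it from the rest of the
genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .prediction import PredictionMatrix, term_auc


def term_profile_correlation(
    matrix: PredictionMatrix, terms: list[str]
) -> pd.DataFrame:
    """Pearson correlation between term prediction profiles (columns of the
    prediction matrix over all genes)."""
    terms = list(dict.fromkeys(terms))
    if len(terms) < 2:
        raise ValueError("need >=2 terms")
    missing = [t for t in terms if t not in matrix.term_ids]
    if missing:
        raise KeyError(f"terms absent from matrix: {missing}")
    cols = [matrix.term_ids.index(t) for t in terms]
    sub = matrix.z[:, cols]
    complete = np.isfinite(sub).all(axis=1)
    sub = sub[complete]
    if sub.shape[0] < 3:
        raise ValueError("fewer than 3 genes with complete profiles")
    constant = np.ptp(sub, axis=0) == 0
    if constant.any():
        bad = [t for t, c in zip(terms, constant) if c]
        raise ValueError(f"constant prediction profile(s): {bad}")
    corr = np.corrcoef(sub.T)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=terms, columns=terms)


def cluster_terms(
    corr: pd.DataFrame, method: str = "average"
) -> np.ndarray:
    """Hierarchical clustering of terms on distance 1 - r.

    Returns the scipy linkage matrix (merge tree with heights)."""
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(np.clip(d, 0.0, 2.0), checks=False)
    return hierarchy.linkage(condensed, method=method)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy merge tree as a Newick string with branch lengths
    from the merge heights."""
    tree = hierarchy.to_tree(linkage)

    def quote(label: str) -> str:
        if any(c in label for c in " :;,()[]'"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def walk(node):
        if node.is_leaf():
            return quote(labels[node.id]), 0.0
        left_s, left_h = walk(node.left)
        right_s, right_h = walk(node.right)
        s = (
            f"({left_s}:{(node.dist - left_h) / 2:.6g},"
            f"{right_s}:{(node.dist - right_h) / 2:.6g})"
        )
        return s, node.dist

    s, _ = walk(tree)
    return s + ";"


def enrich_gene_cluster(
    genes: list[str], matrix: PredictionMatrix
) -> pd.DataFrame:
    """Which significant terms separate a gene cluster from the rest.

    Per significant term: Mann-Whitney U of cluster vs complement on the
    term's Z column, AUC, raw and Bonferroni-corrected one-sided p; sorted
    by p. Both cluster and complement need >=2 scored genes.
    """
    cluster = [g for g in dict.fromkeys(genes) if g in matrix.gene_ids]
    if len(cluster) < 2:
        raise ValueError("cluster needs >=2 genes present in the matrix")
    in_cluster = np.isin(matrix.gene_ids, cluster)
    if (~in_cluster).sum() < 2:
        raise ValueError("complement needs >=2 genes")
    terms = matrix.significant_terms
    if not terms:
        raise ValueError("no significant terms to test")
    rows = []
    for t in terms:
        j = matrix.term_ids.index(t)
        z_in = matrix.z[in_cluster, j]
        z_out = matrix.z[~in_cluster, j]
        z_in, z_out = z_in[np.isfinite(z_in)], z_out[np.isfinite(z_out)]
        if z_in.size < 2 or z_out.size < 2:
            continue
        auc, p = term_auc(z_in, z_out)
        rows.append({"term_id": t, "auc": auc, "u_p": p})
    out = pd.DataFrame(rows).set_index("term_id")
    out["bonferroni_p"] = np.minimum(out["u_p"] * len(out), 1.0)
    return out.sort_values("u_p")
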