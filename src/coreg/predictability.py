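"""Gene predictability scores.

Some genes have expression patterns that carry no usable co-regulation
signal; for them no gene-set membership can be predicted. The predictability
score quantifies this per gene as the average skewness, across pathway
databases, of the gene's prioritization Z-score distribution over that
database's significant gene sets: a gene whose Z-distribution has a heavy
right tail is predictable for at least some biology, a symmetric one is not.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import PredictionMatrix

logger = logging.getLogger(__name__)


def skewness(z, *, adjusted: bool = True) -> float:
    """Sample skewness of a Z-score vector.

    The bias-adjusted Fisher-Pearson estimator (g1 scaled by
    sqrt(n(n-1))/(n-2)) by default; ``adjusted=False`` gives plain g1.
    Needs >=3 values with nonzero variance (otherwise NaN with a warning).
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 3:
        raise ValueError(f"need >=3 finite values, got {z.size}")
    if np.ptp(z) == 0:
        warnings.warn("constant vector: skewness undefined")
        return float("nan")
    return float(stats.skew(z, bias=not adjusted))


def gene_predictability(
    matrices: list[PredictionMatrix],
    gene: str,
    *,
    adjusted: bool = True,
) -> dict[str, float]:
    """One gene's per-database skewness and overall predictability score.

    Per database, the skewness is taken over the gene's prioritization
    Z-scores for that database's significant terms only; the overall score
    is the unweighted mean of the defined database values.
    """
    row: dict[str, float] = {}
    found = False
    for m in matrices:
        if gene not in m.gene_ids:
            continue
        found = True
        i = m.gene_ids.index(gene)
        cols = [m.term_ids.index(t) for t in m.significant_terms]
        zs = m.z[i, cols] if cols else np.array([])
        zs = zs[np.isfinite(zs)]
        if zs.size >= 3 and np.ptp(zs) > 0:
            row[m.database_name] = skewness(zs, adjusted=adjusted)
        else:
            row[m.database_name] = float("nan")
    if not found:
        raise KeyError(f"gene {gene} absent from every prediction matrix")
    defined = [v for v in row.values() if np.isfinite(v)]
    row["overall"] = float(np.mean(defined)) if defined else float("nan")
    return row


def predictability_table(
    matrices: list[PredictionMatrix],
    *,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Predictability scores for every gene found in any matrix, vectorized
    per database."""
    all_genes: list[str] = []
    for m in matrices:
        for g in m.gene_ids:
            if g not in all_genes:
                all_genes.append(g)
    out = pd.DataFrame(index=all_genes)
    for m in matrices:
        sig_cols = [m.term_ids.index(t) for t in m.significant_terms]
        col = np.full(len(all_genes), np.nan)
        if len(sig_cols) >= 3:
            sub = m.z[:, sig_cols]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sk = stats.skew(sub, axis=1, bias=not adjusted,
                                nan_policy="omit")
                sk = np.asarray(sk, dtype=float)
                # undefined where fewer than 3 finite values or zero spread
                n_finite = np.isfinite(sub).sum(axis=1)
                spread = np.nanmax(sub, axis=1) - np.nanmin(sub, axis=1)
            sk[(n_finite < 3) | ~(spread > 0)] = np.nan
            gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
            for i, g in enumerate(all_genes):
                if g in gene_pos:
                    col[i] = sk[gene_pos[g]]
        else:
            logger.warning(
                "%s: fewer than 3 significant terms; skewness undefined",
                m.database_name,
            )
        out[m.database_name] = col
    out["overall"] = out.mean(axis=1, skipna=True)
    return out
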