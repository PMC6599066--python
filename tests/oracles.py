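"""From-definition reference implementations used as independent oracles.

These deliberately re-derive every statistic from its textbook formula
(explicit loops, direct distribution calls) and stay independent of the
package's vectorized code paths.
"""

import math

import numpy as np
from scipy import stats


def naive_pearson(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def naive_t_z(in_set, background) -> float:
    """Student's two-sample t -> two-sided p -> signed probit Z."""
    x, y = np.asarray(in_set, float), np.asarray(background, float)
    n1, n2 = len(x), len(y)
    s1 = ((x - x.mean()) ** 2).sum() / (n1 - 1)
    s2 = ((y - y.mean()) ** 2).sum() / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    t = (x.mean() - y.mean()) / (sp * math.sqrt(1 / n1 + 1 / n2))
    p_two = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    z = stats.norm.isf(p_two / 2)
    return math.copysign(z, t)


def naive_corr_z(gene_coeffs, profile_z) -> float:
    """Pearson r -> t(k-2) -> two-sided p -> signed probit Z."""
    r = naive_pearson(gene_coeffs, profile_z)
    k = len(gene_coeffs)
    t = r * math.sqrt(k - 2) / math.sqrt(1 - r**2)
    p_two = 2 * stats.t.sf(abs(t), k - 2)
    z = stats.norm.isf(p_two / 2)
    return math.copysign(z, r)


def naive_auc(annotated, background) -> float:
    """AUC by enumerating all pairs; ties count one half."""
    wins = 0.0
    for a in annotated:
        for b in background:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(annotated) * len(background))


def naive_skewness(z, adjusted=True) -> float:
    z = np.asarray(z, float)
    n = len(z)
    m = z.mean()
    m2 = ((z - m) ** 2).sum() / n
    m3 = ((z - m) ** 3).sum() / n
    g1 = m3 / m2**1.5
    if adjusted:
        return g1 * math.sqrt(n * (n - 1)) / (n - 2)
    return g1


def naive_prediction_z(space, sets):
    """Naive full prediction matrix (Z only): per term, per gene.

    Annotated genes are scored against the profile recomputed with the gene
    removed from the set (the removed gene joining the background);
    unannotated genes against the full-set profile. Cells whose LOO set
    would shrink below 2 genes are NaN.
    """
    genes = list(space.gene_ids)
    v = space.eigenvectors[:, : space.n_retained]
    k = v.shape[1]
    z = np.full((len(genes), len(sets)), np.nan)
    for j, (term, members) in enumerate(sets.items()):
        members = [g for g in members if g in genes]
        for i, g in enumerate(genes):
            if g in members:
                reduced = [m for m in members if m != g]
                if len(reduced) < 2:
                    continue
            else:
                reduced = members
                if len(reduced) < 2:
                    continue
            in_rows = [genes.index(m) for m in reduced]
            bg_rows = [r for r in range(len(genes)) if r not in in_rows]
            profile = np.array([
                naive_t_z(v[in_rows, c], v[bg_rows, c]) for c in range(k)
            ])
            z[i, j] = naive_corr_z(v[i], profile)
    return z


def power_iteration_eigs(a, n_eigs, n_iter=5000, tol=1e-12):
    """Leading eigenvalues of a symmetric matrix by power iteration with
    deflation (independent of LAPACK eigensolvers)."""
    a = np.asarray(a, float).copy()
    rng = np.random.default_rng(0)
    vals = []
    for _ in range(n_eigs):
        v = rng.standard_normal(a.shape[0])
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            w = a @ v
            norm = np.linalg.norm(w)
            if norm < tol:
                lam = 0.0
                break
            v_new = w / norm
            lam_new = v_new @ a @ v_new
            if abs(lam_new - lam) < tol:
                lam, v = lam_new, v_new
                break
            lam, v = lam_new, v_new
        vals.append(lam)
        a -= lam * np.outer(v, v)
    return np.array(vals)
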