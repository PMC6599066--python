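"""Gene-set association prediction from the component space.

For each gene set (a phenotype term's annotated genes, or a pathway), every
retained component gets a Z-score from a Student's T-test comparing the
eigenvector coefficients of in-set genes against all background genes. The
vector of these Z-scores is the term's component profile. A gene's
prioritization Z-score for the term is the probit-transformed p-value of the
Pearson correlation between the gene's coefficient vector and the term
profile: a gene regulated by the same components as the set's genes gets a
high score.

Annotated genes are scored leave-one-out — the gene is removed from the set
and the profile recomputed — so known annotations do not inflate their own
scores, and the per-term AUC computed from those scores is an honest measure
of predictive power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pearson_r_to_z, t_test_z, t_test_z_from_moments
from .component_space import ComponentSpace

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 10
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# gene set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Term -> annotated genes, from one database (HPO / pathway style)."""

    database_name: str
    sets: dict[str, tuple[str, ...]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.sets = {
            t: tuple(dict.fromkeys(genes)) for t, genes in self.sets.items()
        }

    @property
    def term_ids(self) -> list[str]:
        return list(self.sets)

    def intersect_with(self, gene_universe) -> "GeneSetCollection":
        """Drop genes absent from the universe; drop sets left empty."""
        universe = set(gene_universe)
        new_sets: dict[str, tuple[str, ...]] = {}
        n_lost = 0
        for term, genes in self.sets.items():
            kept = tuple(g for g in genes if g in universe)
            n_lost += len(genes) - len(kept)
            if kept:
                new_sets[term] = kept
        if n_lost or len(new_sets) != len(self.sets):
            logger.warning(
                "%s: dropped %d gene annotation(s) outside the expression "
                "space; %d of %d set(s) remain",
                self.database_name, n_lost, len(new_sets), len(self.sets),
            )
        return GeneSetCollection(self.database_name, new_sets,
                                 dict(self.term_names))

    @classmethod
    def from_gmt(cls, path: str | Path,
                 database_name: str | None = None) -> "GeneSetCollection":
        path = Path(path)
        sets: dict[str, tuple[str, ...]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"malformed GMT line (need >=3 fields): {line[:80]!r}"
                    )
                term, name, genes = fields[0], fields[1], fields[2:]
                sets[term] = tuple(g for g in genes if g)
                names[term] = name
        return cls(database_name or path.stem, sets, names)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term, genes in self.sets.items():
                name = self.term_names.get(term, term)
                fh.write("\t".join([term, name, *genes]) + "\n")


def contaminate_sets(
    collection: GeneSetCollection,
    fraction: float,
    gene_universe,
    seed: int,
) -> GeneSetCollection:
    """Randomly grow each set by ``round(fraction * size)`` genes drawn from
    the universe outside the set — the robustness experiment of adding 10%
    spurious annotations."""
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    universe = list(gene_universe)
    rng = np.random.default_rng(seed)
    new_sets = {}
    for term, genes in collection.sets.items():
        n_add = int(round(fraction * len(genes)))
        if n_add == 0:
            new_sets[term] = genes
            continue
        pool = [g for g in universe if g not in set(genes)]
        if len(pool) < n_add:
            raise ValueError(
                f"{term}: cannot add {n_add} genes, only {len(pool)} "
                "non-members available"
            )
        added = rng.choice(len(pool), size=n_add, replace=False)
        new_sets[term] = genes + tuple(pool[i] for i in added)
    return GeneSetCollection(collection.database_name, new_sets,
                             dict(collection.term_names))


# ---------------------------------------------------------------------------
# term component profiles
# ---------------------------------------------------------------------------

@dataclass
class TermComponentProfile:
    """Per-component T-test Z-scores for one gene set (length n_retained)."""

    term_id: str
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.isfinite(self.z).all():
            raise ValueError("profile contains non-finite Z-scores")


def component_t_z(coeffs_in_set, coeffs_background, *,
                  welch: bool = False) -> float:
    """Signed Z for one component: in-set vs background eigenvector
    coefficients, Student's T-test by default."""
    return t_test_z(coeffs_in_set, coeffs_background, welch=welch)


def _retained(space: ComponentSpace) -> np.ndarray:
    if space.n_retained is not None:
        return space.eigenvectors[:, : space.n_retained]
    return space.eigenvectors


def term_profile(
    space: ComponentSpace,
    genes_in_set,
    exclude_gene: str | None = None,
    *,
    term_id: str = "adhoc",
    welch: bool = False,
) -> TermComponentProfile:
    """Component profile of a gene set; with ``exclude_gene`` set, the
    leave-one-out profile (the gene moves to the background)."""
    gene_index = {g: i for i, g in enumerate(space.gene_ids)}
    members = [g for g in dict.fromkeys(genes_in_set) if g in gene_index]
    if exclude_gene is not None:
        members = [g for g in members if g != exclude_gene]
    if len(members) < 2:
        raise ValueError(
            f"gene set has {len(members)} usable gene(s) after exclusion; "
            "need >=2"
        )
    v = _retained(space)
    idx = np.array([gene_index[g] for g in members])
    mask = np.zeros(v.shape[0], dtype=bool)
    mask[idx] = True
    z, _ = _profile_from_mask(v, mask, welch=welch)
    return TermComponentProfile(term_id, z)


def _group_moments(v: np.ndarray, mask: np.ndarray):
    n1 = int(mask.sum())
    n2 = v.shape[0] - n1
    s1 = v[mask].sum(axis=0)
    q1 = (v[mask] ** 2).sum(axis=0)
    s_tot = v.sum(axis=0)
    q_tot = (v**2).sum(axis=0)
    m1, m2 = s1 / n1, (s_tot - s1) / n2
    var1 = np.clip(q1 - n1 * m1**2, 0.0, None) / (n1 - 1)
    var2 = np.clip((q_tot - q1) - n2 * m2**2, 0.0, None) / (n2 - 1)
    return m1, var1, n1, m2, var2, n2


def _profile_from_mask(v: np.ndarray, mask: np.ndarray, *, welch: bool):
    return t_test_z_from_moments(*_group_moments(v, mask), welch=welch)


# ---------------------------------------------------------------------------
# prioritization Z
# ---------------------------------------------------------------------------

def prioritization_z(gene_coeffs, profile: TermComponentProfile):
    """Signed Z from the Pearson correlation between a gene's eigenvector
    coefficients and a term's component profile.

    Returns ``(z, capped)``; a constant input vector yields Z=0 with a
    warning (no correlation is defined).
    """
    x = np.asarray(gene_coeffs, dtype=float)
    y = profile.z
    if x.shape != y.shape:
        raise ValueError("gene coefficients and profile differ in length")
    k = x.size
    if k < 3:
        raise ValueError(f"need >=3 components, got {k}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector in prioritization correlation; Z=0")
        return 0.0, False
    r = float(np.corrcoef(x, y)[0, 1])
    return pearson_r_to_z(r, k)


def term_auc(z_annotated, z_background) -> tuple[float, float]:
    """AUC and one-sided Mann-Whitney p for annotated vs background
    prioritization Z-scores.

    AUC = U/(n1*n2) with ties counted one half; p tests whether annotated
    scores are stochastically larger (normal approximation, tie-corrected).
    """
    z1 = np.asarray(z_annotated, dtype=float)
    z2 = np.asarray(z_background, dtype=float)
    if z1.size == 0 or z2.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(z1, z2, alternative="greater",
                             method="asymptotic")
    auc = float(res.statistic) / (z1.size * z2.size)
    return auc, float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# prediction matrix
# ---------------------------------------------------------------------------

@dataclass
class PredictionMatrix:
    """Genes x terms prioritization Z-scores plus per-term statistics.

    ``z`` holds NaN where a score could not be computed (a leave-one-out
    profile from a shrunken set of <2 genes). ``loo`` marks cells scored
    leave-one-out, i.e. the annotated cells. ``term_stats`` has one row per
    term: n_annotated, auc, u_p, bonferroni_p, significant.
    """

    database_name: str
    gene_ids: list[str]
    term_ids: list[str]
    z: np.ndarray
    loo: np.ndarray
    term_stats: pd.DataFrame
    floored: np.ndarray | None = None

    @property
    def significant_terms(self) -> list[str]:
        return list(self.term_stats.index[self.term_stats["significant"]])

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.gene_ids,
                            columns=self.term_ids)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        db = self.database_name
        self.z_frame().to_csv(out / f"predictions_{db}.tsv.gz", sep="\t",
                              index_label="gene")
        self.term_stats.to_csv(out / f"terms_{db}.tsv", sep="\t",
                               index_label="term_id")

    @classmethod
    def load(cls, out_dir: str | Path, database_name: str):
        out = Path(out_dir)
        zf = pd.read_csv(out / f"predictions_{database_name}.tsv.gz",
                         sep="\t", index_col=0)
        ts = pd.read_csv(out / f"terms_{database_name}.tsv", sep="\t",
                         index_col=0)
        ts["significant"] = ts["significant"].astype(bool)
        loo = np.zeros(zf.shape, dtype=bool)  # not persisted; derivable
        return cls(database_name, list(zf.index), list(zf.columns),
                   zf.to_numpy(), loo, ts)


def _corr_with_profile(v_std: np.ndarray, profile_z: np.ndarray) -> np.ndarray:
    """Pearson r between each standardized gene row and a profile vector."""
    k = profile_z.size
    p = profile_z - profile_z.mean()
    sd = p.std()
    if sd == 0:
        return np.zeros(v_std.shape[0])
    return v_std @ (p / sd) / k


def build_prediction_matrix(
    space: ComponentSpace,
    collection: GeneSetCollection,
    *,
    min_genes: int = DEFAULT_MIN_GENES,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> PredictionMatrix:
    """Score every (gene, term) pair.

    Unannotated genes are scored against the full-set profile; annotated
    genes against the profile with themselves excluded (leave-one-out). Terms
    whose LOO set would fall below 2 genes leave those cells NaN. Per-term
    AUC, U-test p, Bonferroni correction and significance flags are filled
    from the LOO scores.
    """
    collection = collection.intersect_with(space.gene_ids)
    v = _retained(space)
    n_genes, k = v.shape
    if k < 3:
        raise ValueError(f"need >=3 retained components, got {k}")
    gene_index = {g: i for i, g in enumerate(space.gene_ids)}

    # row-standardized coefficients for fast correlation against profiles
    v_c = v - v.mean(axis=1, keepdims=True)
    row_sd = v_c.std(axis=1)
    constant_rows = row_sd == 0
    row_sd[constant_rows] = 1.0
    v_std = v_c / row_sd[:, None]

    term_ids = collection.term_ids
    z = np.full((n_genes, len(term_ids)), np.nan)
    loo = np.zeros_like(z, dtype=bool)
    stats_rows = []
    for j, term in enumerate(term_ids):
        members = collection.sets[term]
        idx = np.array([gene_index[g] for g in members])
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        if len(members) >= 2:
            full_profile, _ = _profile_from_mask(v, mask, welch=welch)
            r = _corr_with_profile(v_std, full_profile)
            z_col, _ = pearson_r_to_z(r, k)
            z_col[constant_rows] = 0.0
            z[:, j] = z_col
        else:
            full_profile = None
        # LOO rescoring of annotated genes (needs >=2 genes after removal)
        if len(members) >= 3:
            m1, var1, n1_l, m2, var2, n2_l = _loo_moments(v, idx)
            for pos, g_pos in enumerate(idx):
                loo_profile, _ = t_test_z_from_moments(
                    m1[pos], var1[pos], n1_l, m2[pos], var2[pos], n2_l,
                    welch=welch,
                )
                if constant_rows[g_pos]:
                    z[g_pos, j] = 0.0
                else:
                    r_g = float(
                        _corr_with_profile(v_std[g_pos: g_pos + 1],
                                           np.asarray(loo_profile))[0]
                    )
                    z[g_pos, j], _ = pearson_r_to_z(r_g, k)
                loo[g_pos, j] = True
        else:
            z[idx, j] = np.nan
        bg_scores = z[~mask, j]
        bg_scores = bg_scores[~np.isnan(bg_scores)]
        usable_ann = z[idx, j][loo[idx, j]]
        usable_ann = usable_ann[~np.isnan(usable_ann)]
        if usable_ann.size and bg_scores.size:
            auc, p = term_auc(usable_ann, bg_scores)
        else:
            auc, p = np.nan, 1.0
        stats_rows.append(
            {
                "term_id": term,
                "name": collection.term_names.get(term, term),
                "n_annotated": len(members),
                "auc": auc,
                "u_p": p,
            }
        )
    term_stats = pd.DataFrame(stats_rows).set_index("term_id")
    matrix = PredictionMatrix(
        collection.database_name, list(space.gene_ids), term_ids, z, loo,
        term_stats,
    )
    filter_terms(matrix, min_genes=min_genes, alpha=alpha)
    return matrix


def _loo_moments(v: np.ndarray, idx: np.ndarray):
    """Leave-one-out group moments for every in-set gene, vectorized.

    ``idx`` are the row indices of the set members, in member order; row i
    of each returned array is the moment with member i excluded. For each
    annotated gene g: the set loses g (n1-1 genes) and the background gains
    it (n2+1 genes).
    """
    n1 = len(idx)
    n2 = v.shape[0] - n1
    vs = v[idx]  # n1 x k, member order
    s1, q1 = vs.sum(axis=0), (vs**2).sum(axis=0)
    s_tot, q_tot = v.sum(axis=0), (v**2).sum(axis=0)
    s1_l = s1[None, :] - vs          # set sums without g
    q1_l = q1[None, :] - vs**2
    s2_l = (s_tot - s1)[None, :] + vs  # background sums with g added
    q2_l = (q_tot - q1)[None, :] + vs**2
    n1_l, n2_l = n1 - 1, n2 + 1
    m1 = s1_l / n1_l
    m2 = s2_l / n2_l
    var1 = np.clip(q1_l - n1_l * m1**2, 0.0, None) / (n1_l - 1)
    var2 = np.clip(q2_l - n2_l * m2**2, 0.0, None) / (n2_l - 1)
    return m1, var1, n1_l, m2, var2, n2_l


def filter_terms(
    matrix: PredictionMatrix,
    min_genes: int = DEFAULT_MIN_GENES,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Mark significant terms: >= ``min_genes`` annotated genes and a
    Bonferroni-corrected U-test p <= ``alpha``.

    The Bonferroni denominator is the number of eligible (>= min_genes)
    terms in the same database. Mutates ``matrix.term_stats`` and returns
    the significant term IDs.
    """
    ts = matrix.term_stats
    eligible = ts["n_annotated"] >= min_genes
    n_eligible = max(int(eligible.sum()), 1)
    ts["bonferroni_p"] = np.minimum(ts["u_p"] * n_eligible, 1.0)
    ts["significant"] = eligible & (ts["bonferroni_p"] <= alpha)
    return list(ts.index[ts["significant"]])
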