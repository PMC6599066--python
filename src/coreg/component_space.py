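"""Build the co-regulation component space from an expression matrix.

The substrate of the whole method: genes that are co-regulated across a large
expression compendium share principal components of the gene-gene correlation
matrix. Each gene is summarised by its eigenvector coefficients (loadings) on
the retained components; component retention is gated by a split-half
reliability estimate so that only components that replicate across random
sample halves are used downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

DEFAULT_RELIABILITY_THRESHOLD = 0.7
DEFAULT_N_SPLITS = 5
DEFAULT_SEED = 42


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values; units arbitrary (correlation-based
    downstream). Gene rows must be unique and have nonzero variance."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a TSV (first column gene ID, header = sample IDs); gzip is
        handled transparently by pandas."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls.from_dataframe(df)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        ).to_csv(path, sep="\t", index_label="gene")

    def drop_zero_variance(self) -> "ExpressionMatrix":
        """Drop constant gene rows (they have no correlation structure)."""
        keep = self.values.std(axis=1) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            dropped = [g for g, k in zip(self.gene_ids, keep) if not k]
            logger.warning(
                "dropping %d zero-variance gene(s): %s%s",
                n_dropped, ", ".join(dropped[:5]),
                "..." if n_dropped > 5 else "",
            )
            return ExpressionMatrix(
                [g for g, k in zip(self.gene_ids, keep) if k],
                list(self.sample_ids),
                self.values[keep],
            )
        return self

    def log2(self) -> "ExpressionMatrix":
        return replace(self, values=np.log2(self.values + 1.0))

    def center_scale(self) -> "ExpressionMatrix":
        v = self.values
        sd = v.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError("cannot center-scale zero-variance gene rows")
        return replace(self, values=(v - v.mean(axis=1, keepdims=True)) / sd)


@dataclass
class ComponentSpace:
    """Eigenvectors of the gene-gene correlation matrix plus per-component
    reliabilities.

    ``eigenvectors`` is genes x components, columns orthonormal, eigenvalues
    nonincreasing. ``n_retained`` is set by :func:`select_components`; until
    then all components are nominally available.
    """

    gene_ids: list[str]
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    reliabilities: np.ndarray | None = None
    n_retained: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        n_genes, k = self.eigenvectors.shape
        if n_genes != len(self.gene_ids):
            raise ValueError("eigenvector rows do not match gene_ids")
        if self.eigenvalues.shape != (k,):
            raise ValueError("one eigenvalue per component required")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        if self.reliabilities is not None:
            self.reliabilities = np.asarray(self.reliabilities, dtype=float)
            if self.reliabilities.shape != (k,):
                raise ValueError("one reliability per component required")

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def retained_eigenvectors(self) -> np.ndarray:
        if self.n_retained is None:
            raise ValueError("call select_components first")
        return self.eigenvectors[:, : self.n_retained]

    def check_orthonormal(self, tol: float = 1e-8) -> None:
        v = self.eigenvectors
        gram = v.T @ v
        if not np.allclose(gram, np.eye(v.shape[1]), atol=tol):
            raise ValueError("eigenvector columns are not orthonormal")

    # --- persistence -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        pd.DataFrame(
            self.eigenvectors, index=self.gene_ids, columns=cols
        ).to_csv(out / "eigenvectors.tsv.gz", sep="\t", index_label="gene")
        pd.Series(self.eigenvalues, index=cols, name="eigenvalue").to_csv(
            out / "eigenvalues.tsv", sep="\t", index_label="component"
        )
        if self.reliabilities is not None:
            pd.Series(
                self.reliabilities, index=cols, name="reliability"
            ).to_csv(out / "reliabilities.tsv", sep="\t",
                     index_label="component")
        meta = dict(self.meta)
        meta["n_retained"] = self.n_retained
        (out / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ComponentSpace":
        src = Path(in_dir)
        ev = pd.read_csv(src / "eigenvectors.tsv.gz", sep="\t", index_col=0)
        lam = pd.read_csv(src / "eigenvalues.tsv", sep="\t", index_col=0)
        rel_path = src / "reliabilities.tsv"
        rel = (
            pd.read_csv(rel_path, sep="\t", index_col=0).iloc[:, 0].to_numpy()
            if rel_path.exists()
            else None
        )
        meta = json.loads((src / "meta.json").read_text())
        n_retained = meta.pop("n_retained", None)
        return cls(
            list(ev.index), ev.to_numpy(), lam.iloc[:, 0].to_numpy(),
            reliabilities=rel, n_retained=n_retained, meta=meta,
        )


def compute_gene_correlation(expr: ExpressionMatrix) -> np.ndarray:
    """Pearson gene-gene correlation matrix (genes x genes).

    Requires >=3 samples, >=2 genes and no zero-variance gene rows (drop them
    first with :meth:`ExpressionMatrix.drop_zero_variance`).
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >=3 samples, got {expr.n_samples}")
    if expr.n_genes < 2:
        raise ValueError(f"need >=2 genes, got {expr.n_genes}")
    sd = expr.values.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ValueError(f"zero-variance gene row(s): {', '.join(bad[:10])}")
    corr = np.corrcoef(expr.values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Force each column's largest-|coefficient| entry positive (eigenvector
    sign is arbitrary; this makes runs reproducible)."""
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def decompose(
    corr: np.ndarray,
    gene_ids: list[str] | None = None,
    max_components: int | None = None,
) -> ComponentSpace:
    """Eigendecompose a correlation matrix into a ComponentSpace.

    Eigenvalues are sorted descending; small negative eigenvalues (above
    -1e-8, numerical noise for a PSD correlation matrix) are clipped to 0,
    larger negative ones are rejected.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.isfinite(corr).all():
        raise ValueError("correlation matrix contains non-finite values")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    eigvals, eigvecs = linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise ValueError(
            f"matrix is not positive semi-definite (min eigenvalue "
            f"{eigvals.min():.3g})"
        )
    eigvals = np.clip(eigvals, 0.0, None)
    if max_components is not None:
        eigvals, eigvecs = eigvals[:max_components], eigvecs[:, :max_components]
    eigvecs = _fix_signs(eigvecs)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(corr.shape[0])]
    return ComponentSpace(list(gene_ids), eigvecs, eigvals)


def decompose_expression(
    expr: ExpressionMatrix, max_components: int | None = None
) -> ComponentSpace:
    """Economy path: eigenvectors of the gene correlation matrix via SVD of
    the row-standardized data, avoiding the genes x genes matrix.

    Produces the same (sign-aligned) leading eigenvectors as
    ``decompose(compute_gene_correlation(expr))``.
    """
    if expr.n_samples < 3:
        raise ValueError(f"need >=3 samples, got {expr.n_samples}")
    v = expr.values
    sd = v.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance gene rows present")
    z = (v - v.mean(axis=1, keepdims=True)) / sd
    z /= np.sqrt(v.shape[1])
    u, s, _ = linalg.svd(z, full_matrices=False)
    eigvals = s**2
    if max_components is not None:
        u, eigvals = u[:, :max_components], eigvals[:max_components]
    return ComponentSpace(list(expr.gene_ids), _fix_signs(u), eigvals)


def estimate_reliability(
    expr: ExpressionMatrix,
    space: ComponentSpace,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """Split-half reliability per component.

    Samples are randomly partitioned into two halves; each half's correlation
    matrix is decomposed; each full-data component is matched to the most
    similar component (maximal |loading correlation|) in each half; the
    Spearman-Brown corrected agreement 2r/(1+r) between the two matched
    half-eigenvectors is averaged over ``n_splits`` partitions. A component
    reflecting real co-regulation replicates across halves (reliability near
    1); a noise component does not.
    """
    if n_splits < 2:
        raise ValueError("need >=2 splits")
    n = expr.n_samples
    if n < 6:
        raise ValueError(f"need >=6 samples for two halves of >=3, got {n}")
    rng = np.random.default_rng(seed)
    k = space.n_components
    full = space.eigenvectors
    alphas = np.zeros((n_splits, k))
    for s_idx in range(n_splits):
        perm = rng.permutation(n)
        halves = []
        for sel in (perm[: n // 2], perm[n // 2:]):
            sub = ExpressionMatrix(
                list(expr.gene_ids),
                [expr.sample_ids[i] for i in sel],
                expr.values[:, sel],
            ).drop_zero_variance()
            if set(sub.gene_ids) != set(expr.gene_ids):
                # keep the gene universe aligned: re-add as zero loadings is
                # wrong, so just require enough samples that this is rare
                raise ValueError(
                    "a sample half produced zero-variance genes; "
                    "use more samples"
                )
            halves.append(
                decompose_expression(sub, max_components=k).eigenvectors
            )
        a, b = halves
        # column-wise |correlation| between full-data and half eigenvectors
        ca = np.abs(_column_corr(full, a))
        cb = np.abs(_column_corr(full, b))
        match_a = ca.argmax(axis=1)
        match_b = cb.argmax(axis=1)
        r_ab = np.abs(
            _paired_column_corr(a[:, match_a], b[:, match_b])
        )
        alphas[s_idx] = 2.0 * r_ab / (1.0 + r_ab)
    return alphas.mean(axis=0)


def _standardize_cols(m: np.ndarray) -> np.ndarray:
    c = m - m.mean(axis=0)
    sd = c.std(axis=0)
    sd[sd == 0] = 1.0
    return c / sd


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of a with every column of b."""
    return _standardize_cols(a).T @ _standardize_cols(b) / a.shape[0]


def _paired_column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (_standardize_cols(a) * _standardize_cols(b)).mean(axis=0)


def select_components(
    space: ComponentSpace,
    threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
) -> ComponentSpace:
    """Retain the leading run of components whose reliability passes the gate.

    The prefix rule stops at the first failing component so the retained
    space is always the top-variance, nested one. At least two components
    must survive.
    """
    if space.reliabilities is None:
        raise ValueError("reliabilities not estimated")
    passing = space.reliabilities >= threshold
    n_retained = int(np.argmin(passing)) if not passing.all() else len(passing)
    if n_retained < 2:
        raise ValueError(
            f"only {n_retained} component(s) pass reliability >= {threshold}; "
            "use more samples or a lower threshold"
        )
    return ComponentSpace(
        list(space.gene_ids),
        space.eigenvectors[:, :n_retained],
        space.eigenvalues[:n_retained],
        reliabilities=space.reliabilities[:n_retained],
        n_retained=n_retained,
        meta=dict(space.meta, reliability_threshold=threshold),
    )


def build_component_space(
    expr: ExpressionMatrix,
    threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int = DEFAULT_SEED,
    max_components: int | None = None,
) -> ComponentSpace:
    """Full pipeline: correlation -> eigendecomposition -> reliability gate."""
    expr = expr.drop_zero_variance()
    corr = compute_gene_correlation(expr)
    space = decompose(corr, list(expr.gene_ids), max_components=max_components)
    space.reliabilities = estimate_reliability(
        expr, space, n_splits=n_splits, seed=seed
    )
    space.meta.update(
        seed=seed, n_splits=n_splits,
        input_checksum=checksum_array(expr.values),
    )
    return select_components(space, threshold)


def checksum_array(values: np.ndarray) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(values, dtype=float).tobytes()
    ).hexdigest()[:16]
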