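"""Benchmarking of disease-gene prioritization.

Evaluates how well the method retrospectively ranks known causal genes: for
every disease in a catalog, score every gene in an evaluation universe
against the disease's phenotype terms and record the causal gene's rank.
The leave-one-out scoring upstream guarantees the causal gene's own
annotation does not leak into its score. A phenotype-preserving permutation
(reassign genes to diseases, keeping each disease's terms together and
excluding genes annotated to any of them) provides the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import OntologyGraph
from .prediction import PredictionMatrix
from .prioritize import PatientQuery, combine_z, resolve_terms

logger = logging.getLogger(__name__)


@dataclass
class DiseaseCatalog:
    """Disease ID -> (causal gene IDs, phenotype term IDs)."""

    diseases: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]

    def __post_init__(self):
        for d, (genes, terms) in self.diseases.items():
            if not genes or not terms:
                raise ValueError(f"{d}: needs >=1 gene and >=1 term")
        self.diseases = {
            d: (tuple(dict.fromkeys(g)), tuple(dict.fromkeys(t)))
            for d, (g, t) in self.diseases.items()
        }

    def __len__(self) -> int:
        return len(self.diseases)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseCatalog":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"disease_id", "gene_ids", "term_ids"}
        if not required.issubset(df.columns):
            raise ValueError(f"catalog TSV needs columns {sorted(required)}")
        diseases = {
            row.disease_id: (
                tuple(row.gene_ids.split(";")),
                tuple(row.term_ids.split(";")),
            )
            for row in df.itertuples()
        }
        return cls(diseases)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"disease_id": d, "gene_ids": ";".join(g),
             "term_ids": ";".join(t)}
            for d, (g, t) in self.diseases.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def rank_causal(
    catalog: DiseaseCatalog,
    matrix: PredictionMatrix,
    graph: OntologyGraph,
    universe: list[str],
) -> tuple[pd.DataFrame, dict]:
    """Rank each disease's causal gene(s) among a gene universe.

    Per disease, every universe gene gets a combined Z over the disease's
    resolved terms and the causal gene's average rank (ties averaged) is
    recorded; diseases with several causal genes report the median rank.
    Diseases whose causal gene cannot be scored are flagged and excluded
    from the summary.
    """
    universe = list(dict.fromkeys(universe))
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    u_idx = [gene_index[g] for g in universe if g in gene_index]
    if len(u_idx) < len(universe):
        missing = len(universe) - len(u_idx)
        logger.warning("%d universe gene(s) absent from the matrix", missing)
    u_genes = [g for g in universe if g in gene_index]
    significant = set(matrix.significant_terms)
    term_index = {t: j for j, t in enumerate(matrix.term_ids)}
    rows = []
    for disease, (genes, terms) in catalog.diseases.items():
        try:
            query = PatientQuery(disease, list(terms), list(genes))
            used, _ = resolve_terms(query, significant, graph)
        except ValueError as exc:
            rows.append({"disease_id": disease, "rank": np.nan,
                         "note": str(exc)})
            continue
        cols = [term_index[t] for t in used if t in term_index]
        sub = matrix.z[np.ix_(u_idx, cols)]
        combined = np.array([combine_z(r) for r in sub])
        scored = np.isfinite(combined)
        ranks = np.full(len(u_genes), np.nan)
        ranks[scored] = stats.rankdata(-combined[scored], method="average")
        gene_rank = {g: ranks[i] for i, g in enumerate(u_genes)}
        causal_ranks = [gene_rank.get(g, np.nan) for g in genes]
        causal_ranks = [r for r in causal_ranks if np.isfinite(r)]
        if not causal_ranks:
            rows.append({"disease_id": disease, "rank": np.nan,
                         "note": "causal gene unscored"})
            continue
        rows.append({
            "disease_id": disease,
            "rank": float(np.median(causal_ranks)),
            "note": "",
        })
    per_disease = pd.DataFrame(rows).set_index("disease_id")
    ok = per_disease["rank"].dropna()
    n_universe = len(u_genes)
    summary = {
        "n_diseases": len(catalog),
        "n_evaluated": int(ok.size),
        "n_excluded": int(len(catalog) - ok.size),
        "n_universe": n_universe,
        "median_rank": float(ok.median()) if ok.size else float("nan"),
        "frac_top_5pct": float((ok <= 0.05 * n_universe).mean())
        if ok.size else float("nan"),
        "frac_top_3": float((ok <= 3).mean()) if ok.size else float("nan"),
    }
    return per_disease, summary


def permute_catalog(
    catalog: DiseaseCatalog,
    universe: list[str],
    annotations: dict[str, tuple[str, ...]] | None,
    seed: int,
    max_retries: int = 1000,
) -> DiseaseCatalog:
    """Phenotype-preserving permutation null.

    Each disease keeps its phenotype terms but its gene(s) are replaced by
    random universe genes not annotated to any of the disease's terms.
    ``annotations`` maps term ID -> annotated genes (the training sets);
    pass None for no exclusion constraint.
    """
    rng = np.random.default_rng(seed)
    universe = list(dict.fromkeys(universe))
    ann = annotations or {}
    permuted = {}
    for disease, (genes, terms) in catalog.diseases.items():
        excluded = set()
        for t in terms:
            excluded.update(ann.get(t, ()))
        new_genes = []
        for _ in genes:
            for attempt in range(max_retries):
                g = universe[int(rng.integers(len(universe)))]
                if g not in excluded and g not in new_genes:
                    new_genes.append(g)
                    break
            else:
                raise RuntimeError(
                    f"{disease}: could not draw a gene outside the "
                    f"annotation constraint in {max_retries} tries"
                )
        permuted[disease] = (tuple(new_genes), terms)
    return DiseaseCatalog(permuted)


def subsample_terms(
    catalog: DiseaseCatalog, max_terms: int = 5, seed: int = 42
) -> DiseaseCatalog:
    """Keep at most ``max_terms`` randomly chosen phenotype terms per
    disease (emulating incomplete clinical phenotyping)."""
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for disease, (genes, terms) in catalog.diseases.items():
        if len(terms) <= max_terms:
            out[disease] = (genes, terms)
        else:
            keep = rng.choice(len(terms), size=max_terms, replace=False)
            out[disease] = (genes, tuple(terms[i] for i in sorted(keep)))
    return DiseaseCatalog(out)
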