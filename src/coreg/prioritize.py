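"""Patient-facing gene prioritization.

A patient query is a set of phenotype terms plus a list of candidate genes.
Terms without significant predictive power fall back to their minimal
significant ancestors; per-term prioritization Z-scores are combined across
the used terms by the Z-transform (Stouffer) test, sum(Z)/sqrt(m); genes are
ranked by the combined Z, with combined Z >= 5 flagged as strong candidates
(two-sided tail probability about 5.7e-7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import OntologyGraph, fallback_terms
from .prediction import GeneSetCollection, PredictionMatrix

logger = logging.getLogger(__name__)

STRONG_CANDIDATE_Z = 5.0
DEFAULT_ANNOTATION_FLOOR = 3.0


@dataclass
class PatientQuery:
    patient_id: str
    hpo_terms: list[str]
    candidate_genes: list[str]

    def __post_init__(self):
        self.hpo_terms = list(dict.fromkeys(self.hpo_terms))
        self.candidate_genes = list(dict.fromkeys(self.candidate_genes))
        if not self.candidate_genes:
            raise ValueError(f"{self.patient_id}: no candidate genes")
        if not self.hpo_terms:
            raise ValueError(f"{self.patient_id}: no phenotype terms")

    @classmethod
    def from_files(cls, patient_id: str, terms_path: str | Path,
                   genes_path: str | Path) -> "PatientQuery":
        terms = _read_id_list(terms_path)
        genes = _read_id_list(genes_path)
        return cls(patient_id, terms, genes)


def _read_id_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#")[0].strip()
        if token:
            out.append(token.split("\t")[0])
    return out


@dataclass
class RankedResult:
    patient_id: str
    table: pd.DataFrame  # gene, per-term Z columns, combined_z, rank, flag
    substitutions: dict[str, list[str]]
    unscored_genes: list[str]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    def substitutions_frame(self) -> pd.DataFrame:
        rows = [
            {"queried_term": q, "used_terms": ";".join(u)}
            for q, u in self.substitutions.items()
        ]
        return pd.DataFrame(rows)


def resolve_terms(
    query: PatientQuery,
    significant: set[str],
    graph: OntologyGraph,
) -> tuple[list[str], dict[str, list[str]]]:
    """Map each queried term to itself or its fallback ancestors; the used
    set is deduplicated across the query."""
    substitutions: dict[str, list[str]] = {}
    used: list[str] = []
    for term in query.hpo_terms:
        resolved = fallback_terms(term, significant, graph)
        substitutions[term] = resolved
        for t in resolved:
            if t not in used:
                used.append(t)
    if not used:
        raise ValueError(
            f"{query.patient_id}: none of the queried terms (or their "
            "ancestors) have significant predictive power"
        )
    return used, substitutions


def combine_z(z_per_term) -> float:
    """Z-transform (Stouffer) combination: sum(Z)/sqrt(m) over the finite
    entries; NaN if none contribute."""
    z = np.asarray(z_per_term, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        return float("nan")
    return float(z.sum() / np.sqrt(z.size))


def apply_annotation_floor(
    matrix: PredictionMatrix,
    collection: GeneSetCollection,
    floor: float = DEFAULT_ANNOTATION_FLOOR,
) -> PredictionMatrix:
    """Guarantee every known (gene, term) annotation a minimum prioritization
    Z of ``floor``; unannotated cells are untouched. Annotated cells with no
    computable LOO score also receive the floor (the annotation is known
    even when the expression data cannot score it)."""
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    term_index = {t: j for j, t in enumerate(matrix.term_ids)}
    z = matrix.z.copy()
    floored = np.zeros_like(z, dtype=bool)
    for term, genes in collection.sets.items():
        j = term_index.get(term)
        if j is None:
            continue
        for g in genes:
            i = gene_index.get(g)
            if i is None:
                continue
            if np.isnan(z[i, j]) or z[i, j] < floor:
                z[i, j] = floor
                floored[i, j] = True
    return PredictionMatrix(
        matrix.database_name, list(matrix.gene_ids), list(matrix.term_ids),
        z, matrix.loo.copy(), matrix.term_stats.copy(), floored=floored,
    )


def prioritize(
    query: PatientQuery,
    matrix: PredictionMatrix,
    graph: OntologyGraph,
    *,
    annotation_collection: GeneSetCollection | None = None,
    use_floor: bool = False,
    floor: float = DEFAULT_ANNOTATION_FLOOR,
) -> RankedResult:
    """Rank a patient's candidate genes by combined prioritization Z.

    Terms are resolved through the ontology fallback; per-gene, terms with
    no usable score are skipped (m shrinks); genes with no usable term at
    all are reported in ``unscored_genes``; ties share the average rank.
    """
    if use_floor:
        if annotation_collection is None:
            raise ValueError("use_floor requires annotation_collection")
        matrix = apply_annotation_floor(matrix, annotation_collection, floor)
    significant = set(matrix.significant_terms)
    used_terms, substitutions = resolve_terms(query, significant, graph)
    term_index = {t: j for j, t in enumerate(matrix.term_ids)}
    missing_terms = [t for t in used_terms if t not in term_index]
    if missing_terms:
        raise ValueError(
            f"used terms absent from the prediction matrix: {missing_terms}"
        )
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    present = [g for g in query.candidate_genes if g in gene_index]
    absent = [g for g in query.candidate_genes if g not in gene_index]
    if not present:
        raise ValueError(
            f"{query.patient_id}: no candidate gene is present in the "
            f"prediction matrix (missing: {absent})"
        )
    cols = np.array([term_index[t] for t in used_terms])
    rows = np.array([gene_index[g] for g in present])
    sub = matrix.z[np.ix_(rows, cols)]
    combined = np.array([combine_z(row) for row in sub])
    scored = np.isfinite(combined)
    unscored = absent + [g for g, s in zip(present, scored) if not s]
    table = pd.DataFrame(sub, index=present, columns=used_terms)
    table["combined_z"] = combined
    scored_tbl = table[scored].copy()
    scored_tbl["rank"] = stats.rankdata(-scored_tbl["combined_z"],
                                        method="average")
    scored_tbl["strong_candidate"] = (
        scored_tbl["combined_z"] >= STRONG_CANDIDATE_Z
    )
    scored_tbl = scored_tbl.sort_values("rank")
    if unscored:
        logger.warning("%s: %d gene(s) could not be scored: %s",
                       query.patient_id, len(unscored), unscored)
    return RankedResult(query.patient_id, scored_tbl, substitutions, unscored)
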