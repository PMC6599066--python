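"""Synthetic study generator: a latent-factor expression compendium with
planted co-regulated gene blocks, matching annotation sets, a toy phenotype
ontology and a disease catalog.

The generator emulates exactly the statistical structure the method
exploits: groups of genes sharing a latent regulatory factor are correlated
across samples, so each factor surfaces as one reliable principal component
of the gene-gene correlation matrix, and gene sets drawn from a factor's
block have a strong profile on that component. Ground truth (block
membership, held-out causal genes) is returned alongside so recovery can be
measured.

Everything is a pure function of its parameters and seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .benchmark import DiseaseCatalog
from .component_space import ExpressionMatrix
from .ontology import OntologyGraph, build_ontology
from .prediction import GeneSetCollection
from .prioritize import PatientQuery

ROOT_ID = "TOY:0000001"


@dataclass
class SyntheticCompendium:
    expression: ExpressionMatrix
    loadings: np.ndarray  # genes x factors ground truth
    blocks: list[list[str]]  # genes loading each factor
    snr: np.ndarray  # per-factor signal-to-noise ratio


@dataclass
class SyntheticStudy:
    compendium: SyntheticCompendium
    collection: GeneSetCollection  # leaves + umbrella terms
    term_factor: dict[str, int]  # leaf/tiny term -> factor
    reserved: list[list[str]]  # per factor, held-out (causal) genes
    ontology: OntologyGraph
    obo_text: str
    catalog: DiseaseCatalog
    patients: list[PatientQuery] = field(default_factory=list)


def geometric_blocks(
    n_factors: int, min_block: int, ratio: float = 1.15
) -> list[int]:
    """Block sizes on a geometric ladder (smallest first).

    Co-expression modules in real compendia span a wide range of sizes, so
    the eigenvalue spectrum of the planted factors decays and the components
    are identifiable; equal-size blocks would produce a near-degenerate
    spectrum whose eigenvectors mix arbitrarily between sample splits.
    """
    return [int(round(min_block * ratio**f)) for f in range(n_factors)]


def simulate_compendium(
    n_genes: int = 2000,
    n_samples: int = 500,
    n_factors: int = 12,
    snr: float | np.ndarray = 5.0,
    seed: int = 42,
    block_size: int | list[int] | None = None,
) -> SyntheticCompendium:
    """Expression matrix X = L F + E with disjoint-block factor loadings.

    Each factor loads a disjoint block of genes with unit loading; factor
    scores are standard normal per sample; noise is scaled so loaded genes
    have signal-variance/noise-variance = snr (per factor; scalar or length
    n_factors). Unloaded genes are pure unit-variance noise. ``block_size``
    may be one size for all factors, a per-factor list, or None for the
    default geometric ladder (see :func:`geometric_blocks`).
    """
    snr_arr = np.broadcast_to(np.asarray(snr, dtype=float),
                              (n_factors,)).copy()
    if (snr_arr <= 0).any():
        raise ValueError("snr must be > 0")
    if n_factors >= min(n_genes, n_samples):
        raise ValueError("n_factors must be < min(n_genes, n_samples)")
    if block_size is None:
        sizes = geometric_blocks(n_factors, max(2, n_genes // (4 * n_factors)))
    elif np.isscalar(block_size):
        sizes = [int(block_size)] * n_factors
    else:
        sizes = [int(s) for s in block_size]
        if len(sizes) != n_factors:
            raise ValueError("need one block size per factor")
    if sum(sizes) > n_genes:
        raise ValueError(
            f"blocks cover {sum(sizes)} genes but only {n_genes} available"
        )
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    loadings = np.zeros((n_genes, n_factors))
    noise_sd = np.ones(n_genes)
    blocks = []
    pos = 0
    for f, size in enumerate(sizes):
        loadings[pos: pos + size, f] = 1.0
        noise_sd[pos: pos + size] = np.sqrt(1.0 / snr_arr[f])
        blocks.append(gene_ids[pos: pos + size])
        pos += size
    x = loadings @ rng.standard_normal((n_factors, n_samples))
    x += noise_sd[:, None] * rng.standard_normal((n_genes, n_samples))
    return SyntheticCompendium(
        ExpressionMatrix(gene_ids, sample_ids, x), loadings, blocks, snr_arr
    )


def _leaf_id(factor: int, term: int) -> str:
    return f"TOY:{1000000 + factor * 100 + term:07d}"


def _umbrella_id(factor: int) -> str:
    return f"TOY:{2000000 + factor:07d}"


def simulate_annotations(
    compendium: SyntheticCompendium,
    n_terms_per_factor: int = 3,
    set_size: int = 15,
    label_noise: float = 0.0,
    seed: int = 42,
    reserve_per_block: int = 0,
    database_name: str = "SIM",
) -> tuple[GeneSetCollection, dict[str, int], list[list[str]]]:
    """Gene sets planted on the factor blocks.

    Each term samples ``set_size`` genes from one factor's block (excluding
    ``reserve_per_block`` held-out genes per block, returned for use as
    causal genes) and replaces a ``label_noise`` fraction with random
    off-block genes. ``label_noise`` may be a sequence of length
    ``n_terms_per_factor`` to emulate heterogeneous annotation quality
    across terms. Returns (collection, term->factor map, reserved genes per
    factor).
    """
    noise_arr = np.broadcast_to(
        np.asarray(label_noise, dtype=float), (n_terms_per_factor,)
    )
    if ((noise_arr < 0) | (noise_arr > 1)).any():
        raise ValueError("label_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = compendium.expression.gene_ids
    n_factors = len(compendium.blocks)
    reserved: list[list[str]] = []
    sets: dict[str, tuple[str, ...]] = {}
    names: dict[str, str] = {}
    term_factor: dict[str, int] = {}
    for f, block in enumerate(compendium.blocks):
        if reserve_per_block:
            held_idx = rng.choice(len(block), size=reserve_per_block,
                                  replace=False)
            held = [block[i] for i in held_idx]
        else:
            held = []
        reserved.append(held)
        pool = [g for g in block if g not in set(held)]
        if set_size > len(pool):
            raise ValueError(
                f"factor {f}: set_size {set_size} exceeds available "
                f"block genes {len(pool)}"
            )
        off_block = [g for g in universe if g not in set(block)]
        for t in range(n_terms_per_factor):
            chosen = [pool[i] for i in
                      rng.choice(len(pool), size=set_size, replace=False)]
            n_noise = int(round(noise_arr[t] * set_size))
            if n_noise:
                noise_genes = [
                    off_block[i] for i in
                    rng.choice(len(off_block), size=n_noise, replace=False)
                ]
                chosen = chosen[: set_size - n_noise] + noise_genes
            term = _leaf_id(f, t)
            sets[term] = tuple(chosen)
            names[term] = f"factor {f} phenotype {t}"
            term_factor[term] = f
    return (
        GeneSetCollection(database_name, sets, names),
        term_factor,
        reserved,
    )


def write_obo(edges: list[tuple[str, str]], names: dict[str, str]) -> str:
    """Serialize (child, parent) is_a edges as OBO text."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: toy\n")
    parents: dict[str, list[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, []).append(parent)
    terms = sorted(set(names) | set(parents) | {p for ps in parents.values()
                                                for p in ps})
    for term in terms:
        buf.write(f"\n[Term]\nid: {term}\nname: {names.get(term, term)}\n")
        for parent in parents.get(term, []):
            buf.write(f"is_a: {parent} ! {names.get(parent, parent)}\n")
    return buf.getvalue()


def simulate_ontology_and_catalog(
    compendium: SyntheticCompendium,
    collection: GeneSetCollection,
    term_factor: dict[str, int],
    reserved: list[list[str]],
    diseases_per_factor: int = 2,
    seed: int = 42,
    tiny_leaf_sets: bool = True,
    tiny_set_size: int = 3,
    n_decoys: int = 50,
) -> SyntheticStudy:
    """Toy three-level ontology, disease catalog and patient queries.

    The DAG is root -> per-factor umbrella -> leaf terms. Umbrella terms get
    the union of their children's genes (annotation propagation, as in real
    phenotype ontologies). When ``tiny_leaf_sets`` is on, each factor also
    gets one leaf with only ``tiny_set_size`` genes — too small to ever be
    significant — so ontology fallback is exercised end to end.

    Diseases (``diseases_per_factor`` per factor) use the factor's held-out
    reserved genes as causal genes (never annotated to any set, so their
    scores are annotation-free) and the factor's leaf terms as phenotype
    terms. Each disease yields a patient query with ``n_decoys`` random
    decoy candidate genes.
    """
    rng = np.random.default_rng(seed)
    universe = compendium.expression.gene_ids
    n_factors = len(compendium.blocks)
    sets = dict(collection.sets)
    names = dict(collection.term_names)
    term_factor = dict(term_factor)
    edges: list[tuple[str, str]] = []
    names[ROOT_ID] = "phenotypic abnormality"
    factor_leaves: list[list[str]] = [[] for _ in range(n_factors)]
    for term, f in term_factor.items():
        factor_leaves[f].append(term)
    for f in range(n_factors):
        umbrella = _umbrella_id(f)
        names[umbrella] = f"factor {f} umbrella phenotype"
        edges.append((umbrella, ROOT_ID))
        if tiny_leaf_sets:
            block = compendium.blocks[f]
            pool = [g for g in block if g not in set(reserved[f])]
            tiny = _leaf_id(f, 90)
            chosen = rng.choice(len(pool), size=min(tiny_set_size, len(pool)),
                                replace=False)
            sets[tiny] = tuple(pool[i] for i in chosen)
            names[tiny] = f"factor {f} rare phenotype"
            term_factor[tiny] = f
            factor_leaves[f].append(tiny)
        for leaf in factor_leaves[f]:
            edges.append((leaf, umbrella))
        umbrella_genes: list[str] = []
        for leaf in factor_leaves[f]:
            umbrella_genes.extend(sets[leaf])
        sets[umbrella] = tuple(dict.fromkeys(umbrella_genes))
    obo_text = write_obo(edges, names)
    ontology = build_ontology(edges, names)
    full_collection = GeneSetCollection(collection.database_name, sets, names)

    diseases = {}
    patients = []
    for f in range(n_factors):
        held = reserved[f]
        if not held:
            continue
        for d in range(diseases_per_factor):
            causal = held[d % len(held)]
            disease_id = f"DIS:{f:03d}{d:02d}"
            terms = tuple(t for t in factor_leaves[f]
                          if len(sets[t]) > tiny_set_size)
            if not terms:
                continue
            diseases[disease_id] = ((causal,), terms)
            decoy_pool = [g for g in universe if g != causal]
            decoys = [decoy_pool[i] for i in
                      rng.choice(len(decoy_pool), size=n_decoys,
                                 replace=False)]
            # patients also report the factor's rare (insignificant) leaf so
            # ontology fallback is exercised on every query
            tiny_terms = [t for t in factor_leaves[f]
                          if len(sets[t]) <= tiny_set_size]
            patients.append(
                PatientQuery(f"PAT-{disease_id}", list(terms) + tiny_terms,
                             [causal, *decoys])
            )
    return SyntheticStudy(
        compendium, full_collection, term_factor, reserved, ontology,
        obo_text, DiseaseCatalog(diseases), patients,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # the full-size fixture: 12 strong factors over 2000 genes
    "default": dict(
        n_genes=2000, n_samples=500, n_factors=12, snr=5.0,
        block_size=geometric_blocks(12, 25, 1.13),
        n_terms_per_factor=3, set_size=15, label_noise=0.0,
        reserve_per_block=3, diseases_per_factor=2,
    ),
    # desk-scale: 10 factors (13..36 genes) over a 300-gene universe
    "small": dict(
        n_genes=300, n_samples=1500, n_factors=10, snr=5.0,
        block_size=geometric_blocks(10, 13, 1.12),
        n_terms_per_factor=3, set_size=10, label_noise=0.0,
        reserve_per_block=3, diseases_per_factor=3,
    ),
}


def simulate_study(
    preset: str = "small", seed: int = 42, **overrides
) -> SyntheticStudy:
    """One-call generator: compendium + annotations + ontology + catalog.

    ``overrides`` replace individual preset parameters. Sub-seeds for the
    three generation stages are derived from ``seed`` deterministically.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    params = dict(PRESETS[preset])
    params.update(overrides)
    comp = simulate_compendium(
        n_genes=params["n_genes"], n_samples=params["n_samples"],
        n_factors=params["n_factors"], snr=params["snr"],
        seed=seed, block_size=params["block_size"],
    )
    collection, term_factor, reserved = simulate_annotations(
        comp,
        n_terms_per_factor=params["n_terms_per_factor"],
        set_size=params["set_size"], label_noise=params["label_noise"],
        seed=seed + 1, reserve_per_block=params["reserve_per_block"],
    )
    return simulate_ontology_and_catalog(
        comp, collection, term_factor, reserved,
        diseases_per_factor=params["diseases_per_factor"], seed=seed + 2,
        tiny_leaf_sets=params.get("tiny_leaf_sets", True),
        n_decoys=params.get("n_decoys", 50),
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write all study inputs as plain-text files (expression TSV, GMT, OBO,
    catalog TSV, per-patient term/gene lists)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.compendium.expression.to_tsv(out / "expression.tsv.gz")
    study.collection.to_gmt(out / "genesets.gmt")
    (out / "ontology.obo").write_text(study.obo_text)
    study.catalog.to_tsv(out / "catalog.tsv")
    for patient in study.patients:
        (out / f"{patient.patient_id}_terms.txt").write_text(
            "\n".join(patient.hpo_terms) + "\n"
        )
        (out / f"{patient.patient_id}_genes.txt").write_text(
            "\n".join(patient.candidate_genes) + "\n"
        )
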