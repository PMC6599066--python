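"""Phenotype ontology parsing and parent-term fallback.

Phenotype terms form an ``is_a`` DAG in which parents describe more generic
phenotypes and therefore carry more annotated genes. When a queried term has
no significant prediction profile, its nearest significant ancestors can be
used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)


@dataclass
class OntologyGraph:
    """``is_a`` DAG of phenotype terms; edges point child -> parent."""

    graph: nx.DiGraph
    root: str
    names: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.graph

    def resolve(self, term: str) -> str:
        """Map an alt_id to its canonical term ID (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def name(self, term: str) -> str:
        return self.names.get(self.resolve(term), term)

    def ancestors(self, term: str) -> set[str]:
        """All proper ancestors (more generic terms), including the root."""
        return nx.descendants(self.graph, self.resolve(term))

    def is_ancestor(self, ancestor: str, term: str) -> bool:
        return self.resolve(ancestor) in self.ancestors(term)

    def depth_from(self, term: str, other: str) -> int:
        return nx.shortest_path_length(
            self.graph, self.resolve(term), self.resolve(other)
        )


def build_ontology(
    edges: list[tuple[str, str]],
    names: dict[str, str] | None = None,
    alt_ids: dict[str, str] | None = None,
) -> OntologyGraph:
    """Construct an OntologyGraph from (child, parent) ``is_a`` pairs."""
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(
            f"expected exactly one root term, found {len(roots)}: "
            f"{sorted(roots)[:5]}"
        )
    root = roots[0]
    for node in g.nodes:
        if node != root and not nx.has_path(g, node, root):
            raise ValueError(f"term {node} cannot reach the root {root}")
    return OntologyGraph(g, root, names or {}, alt_ids or {})


def parse_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO file (HPO dialect) into an ``is_a`` DAG.

    Obsolete terms are dropped; ``alt_id`` entries are mapped to their
    canonical IDs; the DAG is validated (single root, acyclic, connected
    to the root).
    """
    multigraph = obonet.read_obo(str(path))  # obsolete terms skipped
    edges = []
    names: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if "name" in data:
            names[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    if not edges:
        raise ValueError(f"{path}: no is_a relationships found")
    graph = build_ontology(edges, names, alt_ids)
    # isolated terms (no is_a) would be unreachable; warn and ignore them
    isolated = set(names) - set(graph.graph.nodes)
    if isolated:
        logger.warning("%s: %d term(s) without is_a edges ignored",
                       path, len(isolated))
    return graph


def fallback_terms(
    term: str,
    significant: set[str],
    graph: OntologyGraph,
) -> list[str]:
    """Terms to use in place of ``term`` when it lacks predictive power.

    A significant term maps to itself. Otherwise the minimal significant
    ancestors are returned: significant ancestors with no significant proper
    descendant that is also an ancestor of ``term`` (so the most specific
    usable umbrella terms), excluding the uninformative root, ordered by
    increasing distance from the queried term. An empty list means no usable
    ancestor exists.
    """
    term = graph.resolve(term)
    if term not in graph.graph:
        raise KeyError(f"unknown term: {term}")
    if term in significant:
        return [term]
    candidates = {
        a for a in graph.ancestors(term)
        if a in significant and a != graph.root
    }
    minimal = [
        a for a in candidates
        if not any(b != a and graph.is_ancestor(a, b) for b in candidates)
    ]
    if not minimal:
        logger.warning(
            "term %s has no significant ancestor below the root; unusable",
            term,
        )
        return []
    return sorted(minimal, key=lambda a: (graph.depth_from(term, a), a))
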