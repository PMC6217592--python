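"""Gene Ontology DAG handling: OBO parsing, is_a edges, term->gene annotation.

Only the ``is_a`` hierarchy of the biological-process namespace is used for
enrichment and subtree labeling; ``part_of`` and other relationship types are
ignored. Annotations are propagated up the is_a hierarchy before counting, so
a gene annotated to a child term counts for every ancestor exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

__all__ = ["GoDag", "read_obo_and_annotation", "read_annotation"]


@dataclass
class GoDag:
    """GO term DAG (child -> parent is_a edges) with term -> gene annotation.

    ``term_to_genes`` holds the direct (unpropagated) annotation;
    :meth:`propagated_annotation` adds each gene to all ancestors of its
    annotated terms. ``universe_size`` defaults to the number of annotated
    genes and can be overridden when the enrichment universe is defined
    externally.
    """

    terms: dict[str, str]                      # term_id -> name
    isa_edges: list[tuple[str, str]]           # (child, parent)
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    universe_size: int | None = None

    def __post_init__(self) -> None:
        for child, parent in self.isa_edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"is_a edge references unknown term: {(child, parent)}")
        graph = self.graph()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"is_a graph contains a cycle: {cycle}")
        unknown = [t for t in self.term_to_genes if t not in self.terms]
        if unknown:
            warnings.warn(
                f"dropping annotation for {len(unknown)} terms absent from the ontology "
                f"(e.g. {unknown[0]!r})"
            )
            for t in unknown:
                del self.term_to_genes[t]
        if self.universe_size is None:
            self.universe_size = len(self.annotated_genes())

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.isa_edges)
        return g

    def annotated_genes(self) -> set[str]:
        genes: set[str] = set()
        for members in self.term_to_genes.values():
            genes |= members
        return genes

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` (excluding itself)."""
        return set(nx.descendants(self.graph(), term))

    def propagated_annotation(self) -> dict[str, set[str]]:
        """Term -> genes with annotation propagated up is_a edges.

        Computed once per call by accumulating along a topological order of
        the child->parent graph, so each gene is counted once per ancestor
        regardless of how many annotation paths reach it.
        """
        graph = self.graph()
        propagated: dict[str, set[str]] = {t: set(g) for t, g in self.term_to_genes.items()}
        for term in nx.topological_sort(graph):  # children before parents
            genes = propagated.get(term)
            if not genes:
                continue
            for parent in graph.successors(term):
                propagated.setdefault(parent, set()).update(genes)
        return {t: g for t, g in propagated.items() if g}


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (term_id, gene_id) into term -> gene sets."""
    table = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"],
                        dtype=str, comment="!")
    ann: dict[str, set[str]] = {}
    for term, genes in table.groupby("term_id")["gene_id"]:
        ann[str(term)] = set(genes)
    return ann


def read_obo_and_annotation(
    obo_path: str | Path,
    annot_path: str | Path | None = None,
    universe_override: int | None = None,
) -> GoDag:
    """Parse an OBO 1.2 ontology plus an optional term->gene annotation file.

    Obsolete terms are dropped (obonet already excludes them); only ``is_a``
    relationships are retained. Annotations referencing terms absent from the
    ontology trigger a warning and are dropped.
    """
    graph = obonet.read_obo(str(obo_path))
    terms = {node: data.get("name", node) for node, data in graph.nodes(data=True)}
    # obonet edges are (child, parent, key) with key = relationship type
    edges = [(c, p) for c, p, key in graph.edges(keys=True) if key == "is_a"]
    annotation = read_annotation(annot_path) if annot_path is not None else {}
    return GoDag(terms, edges, annotation, universe_size=universe_override)
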