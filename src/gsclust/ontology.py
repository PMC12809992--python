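"""Ontology DAGs for semantic gene-set distances.

A :class:`GODag` holds typed child->parent edges (``is_a`` and ``part_of``;
any other relationship is treated as ``part_of``). Only the DAG topology is
needed by the Wang similarity measure; term names are kept for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .exceptions import FormatError

EDGE_TYPES = ("is_a", "part_of")


@dataclass
class GODag:
    """Directed acyclic ontology graph with typed child->parent edges."""

    #: child -> parent edges with a ``relation`` attribute
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_term(self, term: str, name: str | None = None) -> None:
        self.graph.add_node(term, name=name)

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        rel = relation if relation in EDGE_TYPES else "part_of"
        self.graph.add_node(child)
        self.graph.add_node(parent)
        self.graph.add_edge(child, parent, relation=rel)
        if not nx.is_directed_acyclic_graph(self.graph):
            self.graph.remove_edge(child, parent)
            raise FormatError(f"edge {child} -> {parent} would create a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(t for t in self.graph.nodes if self.graph.out_degree(t) == 0)

    def parents(self, term: str) -> tuple[tuple[str, str], ...]:
        """(parent, relation) pairs of ``term``."""
        return tuple(
            (p, self.graph.edges[term, p]["relation"])
            for p in self.graph.successors(term)
        )

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        return frozenset(nx.descendants(self.graph, term)) | {term}

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise FormatError("ontology graph contains a cycle")


def load_obo(path: str | Path) -> GODag:
    """Read an OBO ontology; only is_a and part_of relationships are kept."""
    import obonet

    graph = obonet.read_obo(str(path))
    dag = GODag()
    for term, data in graph.nodes(data=True):
        dag.add_term(term, name=data.get("name"))
    for child, parent, key in graph.edges(keys=True):
        dag.add_edge(child, parent, relation=key)
    dag.validate()
    return dag


def write_obo(dag: GODag, path: str | Path, ontology_name: str = "synthetic") -> None:
    """Write a minimal OBO file (term stanzas with is_a / relationship lines)."""
    lines = [f"format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        name = dag.graph.nodes[term].get("name")
        lines.append(f"name: {name if name else term}")
        for parent, relation in sorted(dag.parents(term)):
            if relation == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {relation} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
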