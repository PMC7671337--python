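"""Phenotype-ontology container: an is_a DAG with per-term levels.

The term *level* follows the MGI browser convention: the root is level 1
and every other term sits at 1 + the length of its shortest is_a path to
the root, so a term in a diamond counts at exactly one level.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import obonet


@dataclass
class OntologyDAG:
    """is_a ontology rooted at ``root``; edges point child -> parent."""

    graph: nx.DiGraph
    root: str
    levels: dict[str, int]
    names: dict[str, str]

    @classmethod
    def from_graph(cls, graph: nx.DiGraph, names: dict[str, str] | None = None) -> "OntologyDAG":
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("is_a graph contains a cycle")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {sorted(roots)}")
        root = roots[0]
        # level = 1 + shortest is_a path to the root
        dist = nx.shortest_path_length(graph.reverse(copy=False), source=root)
        if len(dist) != graph.number_of_nodes():
            missing = set(graph.nodes) - set(dist)
            raise ValueError(f"terms not connected to root: {sorted(missing)[:5]}")
        levels = {term: d + 1 for term, d in dist.items()}
        return cls(graph=graph, root=root, levels=levels, names=names or {})

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of a term (the term itself excluded)."""
        return nx.descendants(self.graph, term)

    def level(self, term: str) -> int:
        return self.levels[term]


def read_obo(path: str) -> OntologyDAG:
    """Read an OBO file, keeping only is_a edges."""
    multi = obonet.read_obo(path)
    graph = nx.DiGraph()
    graph.add_nodes_from(multi.nodes)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    names = {n: data.get("name", n) for n, data in multi.nodes(data=True)}
    return OntologyDAG.from_graph(graph, names=names)


def write_obo(dag: OntologyDAG, path: str) -> None:
    """Minimal OBO writer (id / name / is_a stanzas) for generated ontologies."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-phenotype\n")
        for term in sorted(dag.graph.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            for parent in sorted(dag.graph.successors(term)):
                fh.write(f"is_a: {parent} ! {dag.names.get(parent, parent)}\n")
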