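"""Disease-ontology DAGs and true-path annotation propagation.

A disease ontology (e.g. the Disease Ontology) organises terms in a
directed acyclic graph whose edges point from a child term to its more
general parents.  Annotations attached to a term implicitly apply to all
its ancestors (the true-path rule), which is what makes a *most
informative common ancestor* (MICA) well defined: among the shared
ancestors of two terms, the one with the smallest propagated annotation
set is the most specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["OntologyDAG", "read_ontology"]


@dataclass
class OntologyDAG:
    """A rooted DAG of disease terms, edges directed child -> parent."""

    graph: nx.DiGraph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "OntologyDAG":
        g = nx.DiGraph()
        g.add_nodes_from(str(n).strip() for n in nodes)
        for child, parent in edges:
            g.add_edge(str(child).strip(), str(parent).strip())
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")
        return cls(graph=g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of a term, including the term itself."""
        # edges run child->parent, so ancestors are descendants in nx terms
        return frozenset(nx.descendants(self.graph, term)) | {term}

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        return self.ancestors(t1) & self.ancestors(t2)

    def propagate(
        self, annotations: Mapping[str, frozenset[str]]
    ) -> dict[str, frozenset[str]]:
        """Apply the true-path rule: each term inherits the annotations of
        all its descendants (terms below it in the ontology).

        Terms in ``annotations`` that are absent from the DAG are kept
        unpropagated with a warning.
        """
        propagated: dict[str, set[str]] = {
            n: set(annotations.get(n, ())) for n in self.graph.nodes
        }
        # process children before parents: reverse topological order of the
        # child->parent graph is exactly nx's forward topological order
        for node in nx.topological_sort(self.graph):
            for parent in self.graph.successors(node):
                propagated[parent] |= propagated[node]
        missing = set(annotations) - set(self.graph.nodes)
        if missing:
            logger.warning(
                "%d annotated term(s) missing from the ontology: %s",
                len(missing),
                sorted(missing)[:5],
            )
            for term in missing:
                propagated[term] = set(annotations[term])
        return {t: frozenset(s) for t, s in propagated.items()}


def _parse_obo(path: Path) -> OntologyDAG:
    """Minimal OBO parser: [Term] stanzas, id: and is_a: lines only."""
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    current_id: str | None = None
    in_term = False
    obsolete = False
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                if in_term and current_id and not obsolete:
                    nodes.append(current_id)
                in_term = line == "[Term]"
                current_id = None
                obsolete = False
            elif in_term and line.startswith("id:"):
                current_id = line[3:].strip()
            elif in_term and line.startswith("is_obsolete:"):
                obsolete = "true" in line
            elif in_term and line.startswith("is_a:") and current_id:
                parent = line[5:].strip().split("!")[0].strip()
                edges.append((current_id, parent))
        if in_term and current_id and not obsolete:
            nodes.append(current_id)
    return OntologyDAG.from_edges(edges, nodes=nodes)


def read_ontology(path: str | Path) -> OntologyDAG:
    """Read a disease ontology from OBO (``is_a`` edges) or a two-column
    child/parent TSV (header optional)."""
    path = Path(path)
    if path.suffix.lower() == ".obo":
        return _parse_obo(path)
    edges: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            child, parent = fields[0].strip(), fields[1].strip()
            if lineno == 1 and {child.lower(), parent.lower()} & {
                "child", "child_id", "parent", "parent_id"
            }:
                continue  # header row
            edges.append((child, parent))
    return OntologyDAG.from_edges(edges)
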