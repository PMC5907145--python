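"""The weighted metabolite association network (WMAN).

Nodes are metabolites; an undirected edge links two metabolites whose
similarity is strictly greater than the construction threshold, weighted
by that similarity.  Metabolites incident to no retained edge are dropped
from the network (this is what shrinks the node set relative to the
similarity matrix), and dropped metabolites are reported so users know
which diseases become unreachable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .matrix import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["WMAN", "build_wman", "network_stats", "read_wman", "write_wman"]


@dataclass
class WMAN:
    """Weighted undirected metabolite graph.

    ``nodes`` is the sorted node list; ``graph`` the backing networkx
    Graph with ``weight`` edge attributes.  Edges are normalized with the
    lexicographically smaller id first for stable serialization.
    """

    graph: nx.Graph
    threshold: float = 0.0
    dropped: tuple[str, ...] = field(default_factory=tuple)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str, float], ...]:
        out = []
        for a, b, w in self.graph.edges(data="weight"):
            a, b = (a, b) if a < b else (b, a)
            out.append((a, b, float(w)))
        return tuple(sorted(out))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        if any(a == b for a, b in self.graph.edges):
            raise ValueError("WMAN contains a self-loop")
        for a, b, w in self.graph.edges(data="weight"):
            if not (self.threshold < w <= 1.0 + 1e-12):
                raise ValueError(
                    f"edge ({a}, {b}) weight {w} outside ({self.threshold}, 1]"
                )
        if any(d == 0 for _, d in self.graph.degree):
            raise ValueError("WMAN contains an isolated node")


def build_wman(sim: SimilarityMatrix, threshold: float = 0.7) -> WMAN:
    """Threshold a metabolite similarity matrix into a network.

    Edges are exactly the off-diagonal unordered pairs with similarity
    strictly greater than ``threshold``; nodes are the metabolites
    incident to at least one retained edge.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    vals = sim.values
    iu, ju = np.triu_indices(len(sim.ids), k=1)
    keep = vals[iu, ju] > threshold
    g = nx.Graph()
    for i, j in zip(iu[keep], ju[keep]):
        a, b = sim.ids[i], sim.ids[j]
        if a > b:
            a, b = b, a
        g.add_edge(a, b, weight=float(vals[i, j]))
    dropped = tuple(sorted(set(sim.ids) - set(g.nodes)))
    if g.number_of_nodes() == 0:
        logger.warning(
            "no similarity exceeds threshold %.3g; network is empty", threshold
        )
    elif dropped:
        logger.info(
            "threshold %.3g: %d/%d metabolites retained, %d edges; "
            "%d metabolites dropped",
            threshold,
            g.number_of_nodes(),
            len(sim.ids),
            g.number_of_edges(),
            len(dropped),
        )
    return WMAN(graph=g, threshold=threshold, dropped=dropped)


def network_stats(net: WMAN) -> dict:
    """Node/edge counts, weight quantiles, degree distribution and
    connected-component sizes."""
    g = net.graph
    if g.number_of_nodes() == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "weight_quantiles": {},
            "degree_distribution": {},
            "component_sizes": [],
        }
    weights = np.array([w for _, _, w in g.edges(data="weight")])
    degree_counts: dict[int, int] = {}
    for _, d in g.degree:
        degree_counts[d] = degree_counts.get(d, 0) + 1
    comp_sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    qs = np.quantile(weights, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "weight_quantiles": {
            "min": float(qs[0]),
            "q25": float(qs[1]),
            "median": float(qs[2]),
            "q75": float(qs[3]),
            "max": float(qs[4]),
        },
        "degree_distribution": dict(sorted(degree_counts.items())),
        "component_sizes": comp_sizes,
    }


def write_wman(net: WMAN, path: str | Path) -> None:
    """Write the network as a 3-column TSV edge list."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("metabolite_a\tmetabolite_b\tweight\n")
        for a, b, w in net.edges:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_wman(path: str | Path, threshold: float = 0.0) -> WMAN:
    """Read a 3-column TSV edge list back into a WMAN."""
    g = nx.Graph()
    with Path(path).open("r", encoding="utf-8") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                raise ValueError(f"{path}: empty network file")
            if header.strip() and not header.startswith("#"):
                break
        for lineno, line in enumerate(fh, start=lineno + 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(fields)}"
                )
            a, b, w = fields[0].strip(), fields[1].strip(), float(fields[2])
            if a > b:
                a, b = b, a
            g.add_edge(a, b, weight=w)
    return WMAN(graph=g, threshold=threshold)
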