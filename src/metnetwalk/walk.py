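"""Random walks on the metabolite network.

The scoring engine: a walker starts on the seed metabolites (those
already known for the query disease) and at each step either moves to a
neighbour, proportionally to edge weight, or restarts at a seed with
probability ``gamma`` (0.85 by default).  The stationary probability of
the walk scores every network metabolite's proximity to the seed set:

    P_{t+1} = (1 - gamma) * A @ P_t + gamma * P_0

with ``A`` the column-normalized weighted adjacency and ``P_0`` uniform
over the seeds.  The iteration is a contraction with factor
``1 - gamma``, so it converges geometrically from any start; a direct
linear solve of the fixed point is provided as an independent oracle.
Classic Markov-chain quantities (stationary distribution, fundamental
matrix) are exposed for the same networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .wman import WMAN

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "RWRResult",
    "transition_matrix",
    "rwr",
    "rwr_closed_form",
    "stationary_distribution",
    "fundamental_matrix",
    "rank_metabolites",
]


@dataclass
class TransitionMatrix:
    node_ids: tuple[str, ...]
    values: np.ndarray
    orientation: str  # "column" or "row"


@dataclass
class RWRResult:
    """Converged restart-walk probabilities over the network nodes."""

    node_ids: tuple[str, ...]
    probabilities: np.ndarray
    iterations: int
    converged: bool
    gamma: float
    tolerance: float

    def score(self, node: str) -> float:
        return float(self.probabilities[self.node_ids.index(node)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_ids, map(float, self.probabilities)))


def _adjacency(net: WMAN) -> tuple[tuple[str, ...], np.ndarray]:
    nodes = net.nodes
    if not nodes:
        raise ValueError("network is empty")
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, w in net.graph.edges(data="weight"):
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    return nodes, a


def transition_matrix(net: WMAN, orientation: str = "column") -> TransitionMatrix:
    """Weighted-degree-normalized adjacency.

    ``column`` divides each column by its sum (the orientation the
    restart walk uses); ``row`` divides each row.  For the symmetric
    adjacency the two are transposes of one another.
    """
    if orientation not in ("column", "row"):
        raise ValueError(f"orientation must be 'column' or 'row', got {orientation!r}")
    nodes, a = _adjacency(net)
    degree = a.sum(axis=0)
    if np.any(degree == 0):
        raise ValueError("network has a zero-degree node")
    if orientation == "column":
        values = a / degree[np.newaxis, :]
    else:
        values = a / degree[:, np.newaxis]
    return TransitionMatrix(node_ids=nodes, values=values, orientation=orientation)


def _seed_vector(nodes: Sequence[str], seeds: Iterable[str]) -> np.ndarray:
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    unknown = seeds - set(nodes)
    if unknown:
        raise ValueError(f"seed id(s) not in network: {sorted(unknown)[:5]}")
    p0 = np.zeros(len(nodes))
    idx = [i for i, n in enumerate(nodes) if n in seeds]
    p0[idx] = 1.0 / len(idx)
    return p0


def rwr(
    net: WMAN,
    seeds: Iterable[str],
    gamma: float = 0.85,
    tolerance: float = 1e-10,
    max_iter: int = 1000,
) -> RWRResult:
    """Iterate the restart walk to its fixed point.

    ``P_0`` is uniform over the seeds; iteration stops when the L1 change
    of one step drops below ``tolerance``.  A non-converged result (only
    possible when ``max_iter`` undercuts the contraction bound
    ``log(tol)/log(1-gamma)``) is returned flagged, with a warning.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    tm = transition_matrix(net, orientation="column")
    p0 = _seed_vector(tm.node_ids, seeds)
    p = p0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p_next = (1.0 - gamma) * (tm.values @ p) + gamma * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tolerance:
            converged = True
            break
    if not converged:
        logger.warning(
            "restart walk did not converge in %d iterations (gamma=%g, tol=%g)",
            max_iter,
            gamma,
            tolerance,
        )
    return RWRResult(
        node_ids=tm.node_ids,
        probabilities=p,
        iterations=iterations,
        converged=converged,
        gamma=gamma,
        tolerance=tolerance,
    )


def rwr_closed_form(
    net: WMAN, seeds: Iterable[str], gamma: float = 0.85
) -> np.ndarray:
    """Fixed point by direct linear solve: (I - (1-gamma) A) P = gamma P_0.

    The system is nonsingular for gamma in (0, 1) and column-stochastic A
    (spectral radius of (1-gamma) A is below 1).  Serves as the
    independent oracle for the iterative solver.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    tm = transition_matrix(net, orientation="column")
    p0 = _seed_vector(tm.node_ids, seeds)
    n = len(tm.node_ids)
    return np.linalg.solve(np.eye(n) - (1.0 - gamma) * tm.values, gamma * p0)


def stationary_distribution(net: WMAN) -> np.ndarray:
    """Equilibrium of the unbiased walk: pi_i = degree_i / (2 * total weight).

    On an undirected weighted graph the walk's stationary distribution is
    proportional to weighted degree; it satisfies ``pi @ P_row = pi``.
    """
    _, a = _adjacency(net)
    degree = a.sum(axis=1)
    return degree / a.sum()


def fundamental_matrix(
    net: WMAN, sign_convention: str = "standard_plus"
) -> np.ndarray:
    """Fundamental matrix of the walk's Markov chain.

    With ``W`` stacking the stationary distribution as every row,
    ``standard_plus`` (default) inverts ``I - P + W`` — the classical
    fundamental matrix of a regular chain, whose rows sum to 1.
    ``as_printed_minus`` inverts ``I - P - W`` instead; it is provided
    for comparison but has no standard interpretation.  ``P`` is the
    row-oriented transition matrix.
    """
    if sign_convention not in ("standard_plus", "as_printed_minus"):
        raise ValueError(f"unknown sign convention: {sign_convention!r}")
    tm = transition_matrix(net, orientation="row")
    pi = stationary_distribution(net)
    n = len(tm.node_ids)
    w = np.tile(pi, (n, 1))
    sign = 1.0 if sign_convention == "standard_plus" else -1.0
    m = np.eye(n) - tm.values + sign * w
    try:
        return np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular matrix under convention {sign_convention!r}: {exc}"
        ) from exc


def rank_metabolites(
    result: RWRResult, exclude: Iterable[str] = ()
) -> list[tuple[str, float, int]]:
    """Rank network metabolites by walk score, descending.

    Nodes in ``exclude`` (typically the seeds, which are known a priori)
    are omitted.  Ties share the minimum (competition) rank and are
    secondarily ordered lexicographically for determinism.
    """
    exclude = set(exclude)
    scored = [
        (node, float(score))
        for node, score in zip(result.node_ids, result.probabilities)
        if node not in exclude
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    ranked: list[tuple[str, float, int]] = []
    for i, (node, score) in enumerate(scored):
        if i > 0 and score == ranked[-1][1]:
            rank = ranked[-1][2]
        else:
            rank = i + 1
        ranked.append((node, score, rank))
    return ranked
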