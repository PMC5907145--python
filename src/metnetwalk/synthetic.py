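"""Synthetic association tables and ontologies with planted structure.

Real disease-metabolite annotation sets are extracted from curated
databases and are not redistributable at pipeline-test scale, so every
stage here is exercised on generated data instead: a planted bipartite
block model (groups of metabolites co-annotated to groups of diseases,
plus uniform background noise) whose group labels are known, and a small
random rooted tree standing in for a disease-ontology DAG.  A table with
strong within-group signal should yield high leave-one-out AUC; a table
with no structure should yield AUC near 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .associations import AssociationTable
from .ontology import OntologyDAG

__all__ = [
    "SyntheticSpec",
    "generate_planted_associations",
    "generate_uniform_associations",
    "generate_random_ontology",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted bipartite block model.

    Diseases and metabolites are partitioned round-robin into
    ``k_groups`` blocks of deterministic size; a (disease, metabolite)
    pair is associated with probability ``p_in`` when the two share a
    block and ``p_out`` otherwise.  Entities left isolated are patched
    with one within-block association so the no-isolated-entity table
    invariant holds without rejection sampling.
    """

    n_diseases: int = 40
    n_metabolites: int = 60
    k_groups: int = 4
    p_in: float = 0.8
    p_out: float = 0.02
    min_per_entity: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError(
                f"need 0 <= p_out < p_in <= 1, got p_out={self.p_out}, "
                f"p_in={self.p_in}"
            )
        if self.k_groups < 1 or self.k_groups > min(
            self.n_diseases, self.n_metabolites
        ):
            raise ValueError(
                f"k_groups must be in [1, min(n_diseases, n_metabolites)], "
                f"got {self.k_groups}"
            )


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_planted_associations(
    spec: SyntheticSpec,
) -> tuple[AssociationTable, dict[str, int]]:
    """Draw one table from the block model.

    Returns the validated table and the true group label of every entity
    (disease and metabolite ids share one label namespace).  Identical
    spec (seed included) gives identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    diseases = _ids("D", spec.n_diseases)
    metabolites = _ids("M", spec.n_metabolites)
    d_group = {d: i % spec.k_groups for i, d in enumerate(diseases)}
    m_group = {m: i % spec.k_groups for i, m in enumerate(metabolites)}

    draws = rng.random((spec.n_diseases, spec.n_metabolites))
    pairs: set[tuple[str, str]] = set()
    for i, d in enumerate(diseases):
        for j, m in enumerate(metabolites):
            p = spec.p_in if d_group[d] == m_group[m] else spec.p_out
            if draws[i, j] < p:
                pairs.add((d, m))

    # patch isolated entities with within-group associations
    met_by_group: dict[int, list[str]] = {}
    for m in metabolites:
        met_by_group.setdefault(m_group[m], []).append(m)
    dis_by_group: dict[int, list[str]] = {}
    for d in diseases:
        dis_by_group.setdefault(d_group[d], []).append(d)

    deg_d = {d: 0 for d in diseases}
    deg_m = {m: 0 for m in metabolites}
    for d, m in pairs:
        deg_d[d] += 1
        deg_m[m] += 1
    for d in diseases:
        while deg_d[d] < spec.min_per_entity:
            candidates = [
                m for m in met_by_group[d_group[d]] if (d, m) not in pairs
            ]
            if not candidates:
                break
            m = candidates[rng.integers(len(candidates))]
            pairs.add((d, m))
            deg_d[d] += 1
            deg_m[m] += 1
    for m in metabolites:
        while deg_m[m] < spec.min_per_entity:
            candidates = [
                d for d in dis_by_group[m_group[m]] if (d, m) not in pairs
            ]
            if not candidates:
                break
            d = candidates[rng.integers(len(candidates))]
            pairs.add((d, m))
            deg_d[d] += 1
            deg_m[m] += 1

    labels = {**d_group, **m_group}
    return AssociationTable.from_pairs(pairs), labels


def generate_uniform_associations(
    n_diseases: int,
    n_metabolites: int,
    p: float,
    rng_seed: int = 0,
    min_per_entity: int = 1,
) -> AssociationTable:
    """Structureless null model: every pair associated with probability p.

    Implemented as the planted model with a single block, so the same
    isolation-patching applies.
    """
    spec = SyntheticSpec(
        n_diseases=n_diseases,
        n_metabolites=n_metabolites,
        k_groups=1,
        p_in=p,
        p_out=0.0,
        min_per_entity=min_per_entity,
        rng_seed=rng_seed,
    )
    table, _ = generate_planted_associations(spec)
    return table


def generate_random_ontology(
    n_nodes: int, branching: int = 3, rng_seed: int = 0
) -> OntologyDAG:
    """Random rooted tree (hence a DAG): node ``T0`` is the root and each
    subsequent node attaches to a uniformly chosen existing node with
    fewer than ``branching`` children."""
    if n_nodes < 1:
        raise ValueError(f"n_nodes must be >= 1, got {n_nodes}")
    rng = np.random.default_rng(rng_seed)
    names = _ids("T", n_nodes)
    edges: list[tuple[str, str]] = []
    n_children = {names[0]: 0}
    for name in names[1:]:
        open_parents = [p for p, c in n_children.items() if c < branching]
        parent = open_parents[rng.integers(len(open_parents))]
        edges.append((name, parent))  # child -> parent
        n_children[parent] += 1
        n_children[name] = 0
    return OntologyDAG.from_edges(edges, nodes=names)
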