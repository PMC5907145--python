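"""Metabolite-metabolite similarity by best-match averaging.

Two metabolites are similar when the disease groups they are annotated to
are similar.  For metabolites ``M1`` (disease group ``D1``, size m) and
``M2`` (group ``D2``, size n), every disease in each group is matched to
its most similar disease in the other group and the matches are averaged:

    Similarity(M1, M2) = ( sum_{d in D1} S(d, D2)
                         + sum_{d in D2} S(d, D1) ) / (m + n)

with ``S(d, D) = max_{d' in D} dsim(d, d')``.  This is the best-match
average scheme used to lift disease similarity to gene-product similarity
in the functional-similarity literature; here the underlying disease
similarity is the annotation-cosine matrix of the previous stage, but any
matrix satisfying the SimilarityMatrix invariants is accepted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .associations import AssociationTable
from .disease_similarity import inf_dis_sim_matrix
from .matrix import SimilarityMatrix
from .ontology import OntologyDAG

__all__ = [
    "best_match",
    "misim",
    "misim_matrix",
    "similarity_histogram",
    "MetaboliteSimilarity",
]


def best_match(d: str, group: Iterable[str], dsim: SimilarityMatrix) -> float:
    """S(d, D): the maximum similarity between disease ``d`` and any
    member of the disease group."""
    group = list(group)
    if not group:
        raise ValueError("disease group is empty")
    return max(dsim.loc(d, g) for g in group)


def misim(
    m1: str, m2: str, table: AssociationTable, dsim: SimilarityMatrix
) -> float:
    """Best-match-average similarity of two metabolites."""
    d1 = table.diseases_of(m1)
    d2 = table.diseases_of(m2)
    total = sum(best_match(d, d2, dsim) for d in d1)
    total += sum(best_match(d, d1, dsim) for d in d2)
    return total / (len(d1) + len(d2))


def misim_matrix(
    table: AssociationTable, dsim: SimilarityMatrix
) -> SimilarityMatrix:
    """Full metabolite similarity matrix (vectorized best-match average).

    Every disease appearing in the table must be covered by ``dsim``.
    The diagonal is exactly 1 because each disease's best match within
    its own group is itself.
    """
    missing = [d for d in table.diseases if d not in dsim]
    if missing:
        raise ValueError(
            f"disease similarity matrix is missing {len(missing)} table "
            f"disease(s): {missing[:5]}"
        )
    dis_idx = np.array([dsim.index_of(d) for d in table.diseases])
    S = dsim.values[np.ix_(dis_idx, dis_idx)]  # aligned to table.diseases
    n_dis = len(table.diseases)
    n_met = len(table.metabolites)
    pos = {d: i for i, d in enumerate(table.diseases)}

    # membership B[d, m] and per-metabolite best-match columns
    # V[d, j] = max_{d' in D_j} S[d, d']
    B = np.zeros((n_dis, n_met))
    V = np.empty((n_dis, n_met))
    degrees = np.empty(n_met)
    for j, m in enumerate(table.metabolites):
        group = [pos[d] for d in table.diseases_of(m)]
        B[group, j] = 1.0
        V[:, j] = S[:, group].max(axis=1)
        degrees[j] = len(group)

    # numerator(i, j) = sum_{d in D_i} V[d, j] + sum_{d in D_j} V[d, i]
    half = B.T @ V
    values = (half + half.T) / (degrees[:, None] + degrees[None, :])
    values = np.clip(values, 0.0, 1.0)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    mat = SimilarityMatrix(ids=table.metabolites, values=values)
    mat.validate()
    return mat


def similarity_histogram(
    sim: SimilarityMatrix,
    bins: Sequence[float],
    include_diagonal: bool = True,
) -> dict[tuple[float, float], int]:
    """Count similarity values per half-open bin [lo, hi).

    Counts unordered pairs; self-pairs (the diagonal) are included by
    default, matching the n*(n+1)/2 pair-count convention.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.ndim != 1 or len(bins) < 2 or np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    n = len(sim.ids)
    iu = np.triu_indices(n, k=0 if include_diagonal else 1)
    vals = sim.values[iu]
    counts, _ = np.histogram(vals, bins=bins)
    # np.histogram closes the last bin; re-impose half-open on the right edge
    at_edge = np.count_nonzero(vals == bins[-1])
    counts = counts.copy()
    counts[-1] -= at_edge
    return {
        (float(bins[k]), float(bins[k + 1])): int(counts[k])
        for k in range(len(bins) - 1)
    }


class MetaboliteSimilarity(BaseEstimator):
    """Estimator wrapper: fit on an association table, expose the
    metabolite similarity matrix.

    Parameters
    ----------
    scheme : {"binary", "idf"}
        Disease weight scheme, used only when no precomputed disease
        similarity is supplied.
    ontology : OntologyDAG or None
        Optional ontology for the MICA factor of the disease stage.
    disease_similarity : SimilarityMatrix or None
        Precomputed disease similarity; bypasses the disease stage.

    Attributes
    ----------
    similarity_ : SimilarityMatrix
        Metabolite-metabolite similarity matrix.
    disease_similarity_ : SimilarityMatrix
        The disease matrix actually used.
    """

    def __init__(
        self,
        scheme: str = "binary",
        ontology: OntologyDAG | None = None,
        disease_similarity: SimilarityMatrix | None = None,
    ):
        self.scheme = scheme
        self.ontology = ontology
        self.disease_similarity = disease_similarity

    def fit(self, X: AssociationTable, y=None) -> "MetaboliteSimilarity":
        if not isinstance(X, AssociationTable):
            X = AssociationTable.from_pairs(X)
        if self.disease_similarity is not None:
            self.disease_similarity_ = self.disease_similarity
        else:
            self.disease_similarity_ = inf_dis_sim_matrix(
                X, scheme=self.scheme, dag=self.ontology
            )
        self.similarity_ = misim_matrix(X, self.disease_similarity_)
        self.metabolite_ids_ = self.similarity_.ids
        return self

    def transform(self, X=None) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "similarity_")
        return self.similarity_.values
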