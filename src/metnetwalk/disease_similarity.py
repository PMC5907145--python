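"""Disease-disease similarity from shared metabolite annotations.

Each disease is represented by a weight vector over the global metabolite
ordering; the cosine of two such vectors is the core similarity.  When a
disease ontology is supplied, the cosine is additionally scaled by the
most-informative-common-ancestor (MICA) factor
``|G1|*|G2| / |G_MICA|**2``, where ``G1`` and ``G2`` are the two
diseases' annotated metabolite sets and ``G_MICA`` is the propagated
metabolite set of their most specific common ancestor.

Two weight schemes are provided.  ``binary`` sets ``w[d, i] = 1`` iff
metabolite ``i`` is annotated to ``d``.  ``idf`` down-weights promiscuous
metabolites by ``log(n_diseases / diseases_per_metabolite)``, the closest
self-contained analogue of annotation informativeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .associations import AssociationTable
from .matrix import SimilarityMatrix
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseWeightVectors",
    "build_weight_vectors",
    "inf_similarity",
    "mica_factor",
    "inf_dis_sim_matrix",
    "DiseaseSimilarity",
]

WEIGHT_SCHEMES = ("binary", "idf")


@dataclass
class DiseaseWeightVectors:
    """Weight vectors of all diseases, stacked as a (diseases x metabolites)
    matrix aligned with the table's sorted id orderings."""

    disease_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]
    weights: np.ndarray  # shape (n_diseases, n_metabolites), non-negative

    def vector(self, disease: str) -> np.ndarray:
        return self.weights[self.disease_ids.index(disease)]


def build_weight_vectors(
    table: AssociationTable, scheme: str = "binary"
) -> DiseaseWeightVectors:
    """Build one weight vector per disease over the metabolite ordering."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(
            f"unknown weight scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}"
        )
    met_index = {m: j for j, m in enumerate(table.metabolites)}
    w = np.zeros((len(table.diseases), len(table.metabolites)))
    for i, d in enumerate(table.diseases):
        for m in table.metabolites_of(d):
            w[i, met_index[m]] = 1.0
    if scheme == "idf":
        n_dis = len(table.diseases)
        dpm = np.array(
            [len(table.diseases_of(m)) for m in table.metabolites], dtype=float
        )
        w = w * np.log(n_dis / dpm)[np.newaxis, :]
    return DiseaseWeightVectors(
        disease_ids=table.diseases,
        metabolite_ids=table.metabolites,
        weights=w,
    )


def inf_similarity(wv1: np.ndarray, wv2: np.ndarray) -> float:
    """Cosine similarity of two non-negative weight vectors."""
    wv1 = np.asarray(wv1, dtype=float)
    wv2 = np.asarray(wv2, dtype=float)
    if wv1.shape != wv2.shape:
        raise ValueError("weight vectors have different lengths")
    n1 = np.linalg.norm(wv1)
    n2 = np.linalg.norm(wv2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm weight vector")
    return float(wv1 @ wv2 / (n1 * n2))


def mica_factor(
    d1: str,
    d2: str,
    table: AssociationTable,
    dag: OntologyDAG | None = None,
    _propagated: dict[str, frozenset[str]] | None = None,
) -> float:
    """MICA scaling factor ``|G1|*|G2| / |G_MICA|**2``.

    ``G1`` and ``G2`` are the diseases' direct annotation sets; ``G_MICA``
    is the true-path-propagated set of the most informative common
    ancestor (the common ancestor with the smallest propagated set, ties
    broken lexicographically).  Without an ontology, or for diseases the
    ontology does not cover, the factor degrades to 1.
    """
    g1 = table.metabolites_of(d1)
    g2 = table.metabolites_of(d2)
    if dag is None:
        return 1.0
    if d1 not in dag or d2 not in dag:
        logger.warning(
            "disease %r or %r not in ontology; MICA factor set to 1",
            d1,
            d2,
        )
        return 1.0
    if _propagated is None:
        annotations = {d: table.metabolites_of(d) for d in table.diseases}
        _propagated = dag.propagate(annotations)
    common = dag.common_ancestors(d1, d2)
    candidates = [t for t in common if _propagated.get(t)]
    if not candidates:
        logger.warning("no annotated common ancestor of %r and %r", d1, d2)
        return 1.0
    mica = min(candidates, key=lambda t: (len(_propagated[t]), t))
    return len(g1) * len(g2) / len(_propagated[mica]) ** 2


def inf_dis_sim_matrix(
    table: AssociationTable,
    scheme: str = "binary",
    dag: OntologyDAG | None = None,
    clamp: bool = True,
) -> SimilarityMatrix:
    """Full disease-disease similarity matrix: cosine x MICA factor.

    The diagonal is forced to exactly 1 (needed by the best-match stage
    when disease groups overlap) and, with ``clamp`` (default), entries
    are clipped to [0, 1] so downstream thresholding stays on the unit
    scale even when the MICA factor exceeds 1.
    """
    wvs = build_weight_vectors(table, scheme=scheme)
    w = wvs.weights
    norms = np.linalg.norm(w, axis=1)
    if np.any(norms == 0):
        bad = [table.diseases[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm weight vector(s) for disease(s): {bad}")
    cos = (w @ w.T) / np.outer(norms, norms)

    if dag is not None:
        annotations = {d: table.metabolites_of(d) for d in table.diseases}
        propagated = dag.propagate(annotations)
        n = len(table.diseases)
        factor = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                f = mica_factor(
                    table.diseases[i],
                    table.diseases[j],
                    table,
                    dag,
                    _propagated=propagated,
                )
                factor[i, j] = factor[j, i] = f
        cos = cos * factor

    if clamp:
        cos = np.clip(cos, 0.0, 1.0)
    cos = (cos + cos.T) / 2  # kill round-off asymmetry
    np.fill_diagonal(cos, 1.0)
    mat = SimilarityMatrix(ids=table.diseases, values=cos)
    if clamp:
        mat.validate()
    return mat


class DiseaseSimilarity(BaseEstimator):
    """Estimator wrapper: fit on an association table, expose the
    disease similarity matrix.

    Parameters
    ----------
    scheme : {"binary", "idf"}
        Weight scheme for the disease annotation vectors.
    ontology : OntologyDAG or None
        Optional disease-ontology DAG enabling the MICA factor.
    clamp : bool
        Clip similarities to [0, 1] (default True).

    Attributes
    ----------
    similarity_ : SimilarityMatrix
        The fitted disease-disease similarity matrix.
    disease_ids_ : tuple of str
        Row/column ordering of ``similarity_``.
    """

    def __init__(
        self,
        scheme: str = "binary",
        ontology: OntologyDAG | None = None,
        clamp: bool = True,
    ):
        self.scheme = scheme
        self.ontology = ontology
        self.clamp = clamp

    def fit(self, X: AssociationTable, y=None) -> "DiseaseSimilarity":
        if not isinstance(X, AssociationTable):
            X = AssociationTable.from_pairs(X)
        self.similarity_ = inf_dis_sim_matrix(
            X, scheme=self.scheme, dag=self.ontology, clamp=self.clamp
        )
        self.disease_ids_ = self.similarity_.ids
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the fitted similarity matrix values."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "similarity_")
        return self.similarity_.values
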