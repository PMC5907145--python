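"""End-to-end prioritization estimator.

``MetaboliteRanker`` chains the whole pipeline behind a scikit-learn
style interface: ``fit`` takes the association table (the prior
knowledge) and builds the disease similarity matrix, the metabolite
similarity matrix and the thresholded network; ``rank`` then scores the
network metabolites for a query disease by a restart walk seeded on the
disease's known metabolites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .associations import AssociationTable
from .disease_similarity import inf_dis_sim_matrix
from .matrix import SimilarityMatrix
from .metabolite_similarity import misim_matrix
from .ontology import OntologyDAG
from .walk import rank_metabolites, rwr
from .wman import build_wman

logger = logging.getLogger(__name__)

__all__ = ["MetaboliteRanker", "UnreachableDisease"]


@dataclass
class UnreachableDisease:
    """A query disease none of whose known metabolites survived the
    network threshold: the walk has no seeds and no ranking exists."""

    disease_id: str
    known_metabolites: tuple[str, ...]
    reason: str = "no known metabolite in the network"


class MetaboliteRanker(BaseEstimator):
    """Score candidate disease-metabolite associations by network
    propagation over a similarity-derived metabolite network.

    Parameters
    ----------
    scheme : {"binary", "idf"}
        Disease annotation weight scheme.
    ontology : OntologyDAG or None
        Optional disease ontology enabling the MICA factor.
    disease_similarity : SimilarityMatrix or None
        Precomputed disease similarity matrix, bypassing stage 1.
    threshold : float
        Similarity threshold for network edges (default 0.7).
    gamma : float
        Restart probability of the walk (default 0.85).
    tolerance, max_iter :
        Convergence controls of the walk iteration.

    Attributes
    ----------
    table_ : AssociationTable
        The fitted prior knowledge.
    disease_similarity_, metabolite_similarity_ : SimilarityMatrix
    network_ : WMAN
        The thresholded metabolite network.
    """

    def __init__(
        self,
        scheme: str = "binary",
        ontology: OntologyDAG | None = None,
        disease_similarity: SimilarityMatrix | None = None,
        threshold: float = 0.7,
        gamma: float = 0.85,
        tolerance: float = 1e-10,
        max_iter: int = 1000,
    ):
        self.scheme = scheme
        self.ontology = ontology
        self.disease_similarity = disease_similarity
        self.threshold = threshold
        self.gamma = gamma
        self.tolerance = tolerance
        self.max_iter = max_iter

    def fit(self, X: AssociationTable, y=None) -> "MetaboliteRanker":
        """Build similarity matrices and the network from the prior
        knowledge ``X`` (an AssociationTable or an iterable of pairs)."""
        if not isinstance(X, AssociationTable):
            X = AssociationTable.from_pairs(X)
        self.table_ = X
        if self.disease_similarity is not None:
            self.disease_similarity_ = self.disease_similarity
        else:
            self.disease_similarity_ = inf_dis_sim_matrix(
                X, scheme=self.scheme, dag=self.ontology
            )
        self.metabolite_similarity_ = misim_matrix(X, self.disease_similarity_)
        self.network_ = build_wman(
            self.metabolite_similarity_, threshold=self.threshold
        )
        return self

    def seeds_for(self, disease_id: str) -> frozenset[str]:
        """The disease's known metabolites that survived the threshold."""
        check_is_fitted(self, "network_")
        return self.table_.metabolites_of(disease_id) & set(self.network_.nodes)

    def rank(
        self, disease_id: str, include_seeds: bool = False
    ) -> pd.DataFrame | UnreachableDisease:
        """Ranked candidate metabolites for one disease.

        Returns a DataFrame with columns ``rank``, ``metabolite_id``,
        ``score`` (walk probabilities, descending), or an
        ``UnreachableDisease`` record when no known metabolite of the
        disease is in the network.  Seeds are excluded from the
        candidates by default — they are the already-known associations.
        """
        check_is_fitted(self, "network_")
        seeds = self.seeds_for(disease_id)
        if not seeds:
            known = tuple(sorted(self.table_.metabolites_of(disease_id)))
            logger.warning(
                "disease %r unreachable: none of its %d metabolite(s) is in "
                "the network",
                disease_id,
                len(known),
            )
            return UnreachableDisease(disease_id=disease_id, known_metabolites=known)
        result = rwr(
            self.network_,
            seeds,
            gamma=self.gamma,
            tolerance=self.tolerance,
            max_iter=self.max_iter,
        )
        exclude = () if include_seeds else seeds
        rows = rank_metabolites(result, exclude=exclude)
        return pd.DataFrame(
            [(r, m, s) for m, s, r in rows],
            columns=["rank", "metabolite_id", "score"],
        )

    def predict(self, X) -> list:
        """Rank for each disease id in ``X`` (sequence of ids)."""
        return [self.rank(d) for d in X]
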