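"""Leave-one-out validation of the prioritization pipeline.

Each known disease-metabolite pair is withheld in turn; the similarity
matrices and the network are rebuilt from the remaining pairs, the
disease's remaining metabolites seed a restart walk, and the withheld
metabolite's score is compared with the scores of network metabolites not
known for that disease.  The withheld pair is the positive group (PG);
the non-associated metabolites are the negative group (NG).  Scores
pooled across all folds give a rank-based (Mann-Whitney) AUC.

Folds whose withheld metabolite falls out of the rebuilt network, or
whose disease is left without in-network seeds, are recorded as skipped
with a machine-readable reason rather than silently dropped — at a high
similarity threshold many metabolites are disconnected, and the
denominator must stay transparent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .associations import AssociationTable
from .disease_similarity import inf_dis_sim_matrix
from .matrix import SimilarityMatrix
from .metabolite_similarity import misim_matrix
from .ontology import OntologyDAG
from .walk import rwr
from .wman import build_wman

logger = logging.getLogger(__name__)

__all__ = ["LoocvConfig", "LoocvRecord", "LoocvResult", "auc", "loocv"]

SKIP_SEEDLESS = "seedless-disease"
SKIP_ABSENT = "held-out-node-absent-from-network"


def auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> float:
    """Rank-based AUC: P(positive > negative) with half credit for ties.

    Equals the Mann-Whitney U statistic divided by ``|pos| * |neg|`` and
    the area under the empirical ROC curve.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


@dataclass(frozen=True)
class LoocvConfig:
    """Knobs of one validation run, stamped into the result."""

    scheme: str = "binary"
    threshold: float = 0.7
    gamma: float = 0.85
    tolerance: float = 1e-10
    max_iter: int = 1000
    fixed_dsim: bool = False
    ontology: OntologyDAG | None = field(default=None, compare=False)


@dataclass
class LoocvRecord:
    disease_id: str
    metabolite_id: str
    score: float  # nan when skipped
    rank: int  # rank among PG + NG, 0 when skipped
    n_negatives: int
    skipped: bool
    reason: str  # "" when scored


@dataclass
class LoocvResult:
    records: list[LoocvRecord]
    auc: float  # pooled over all scored folds; nan if none
    per_disease_auc: dict[str, float]
    mean_fold_auc: float  # mean of per-fold AUCs (1 positive vs its NG)
    config: LoocvConfig

    @property
    def n_scored(self) -> int:
        return sum(not r.skipped for r in self.records)

    @property
    def n_skipped(self) -> int:
        return sum(r.skipped for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "disease_id": r.disease_id,
                    "metabolite_id": r.metabolite_id,
                    "score": r.score,
                    "rank": r.rank,
                    "n_negatives": r.n_negatives,
                    "skipped": r.skipped,
                    "reason": r.reason,
                }
                for r in self.records
            ]
        )


def loocv(
    table: AssociationTable,
    dsim: SimilarityMatrix | None = None,
    config: LoocvConfig | None = None,
) -> LoocvResult:
    """Run the five-step leave-one-out validation over every pair.

    With ``config.fixed_dsim`` (or an externally supplied ``dsim``) the
    disease similarity matrix is computed once from the full table and
    reused across folds; removing one pair perturbs only one disease's
    weight vector, so this is a close, much faster approximation of the
    full per-fold rebuild.  The mode used is stamped into the result.
    """
    if config is None:
        config = LoocvConfig()
    if table.n_pairs < 2:
        raise ValueError("leave-one-out needs at least 2 association pairs")

    fixed = dsim is not None or config.fixed_dsim
    if fixed and dsim is None:
        dsim = inf_dis_sim_matrix(table, scheme=config.scheme, dag=config.ontology)
    if fixed:
        config = LoocvConfig(
            scheme=config.scheme,
            threshold=config.threshold,
            gamma=config.gamma,
            tolerance=config.tolerance,
            max_iter=config.max_iter,
            fixed_dsim=True,
            ontology=config.ontology,
        )

    records: list[LoocvRecord] = []
    pos_scores: list[float] = []
    neg_scores: list[float] = []
    by_disease_pos: dict[str, list[float]] = {}
    by_disease_neg: dict[str, list[float]] = {}
    fold_aucs: list[float] = []

    for d, m in sorted(table.pairs):
        reduced = table.remove_pair(d, m)
        fold_dsim = (
            dsim
            if fixed
            else inf_dis_sim_matrix(reduced, scheme=config.scheme, dag=config.ontology)
        )
        msim = misim_matrix(reduced, fold_dsim)
        net = build_wman(msim, threshold=config.threshold)
        net_nodes = set(net.nodes)

        if m not in net_nodes:
            records.append(
                LoocvRecord(d, m, float("nan"), 0, 0, True, SKIP_ABSENT)
            )
            continue
        seeds = (
            (table.metabolites_of(d) - {m}) & net_nodes
            if d in reduced.diseases
            else frozenset()
        )
        if not seeds:
            records.append(
                LoocvRecord(d, m, float("nan"), 0, 0, True, SKIP_SEEDLESS)
            )
            continue

        result = rwr(
            net,
            seeds,
            gamma=config.gamma,
            tolerance=config.tolerance,
            max_iter=config.max_iter,
        )
        scores = result.as_dict()
        known = table.metabolites_of(d)  # full prior knowledge defines "known"
        negatives = sorted(net_nodes - known)
        if not negatives:
            records.append(
                LoocvRecord(d, m, scores[m], 1, 0, False, "")
            )
            pos_scores.append(scores[m])
            by_disease_pos.setdefault(d, []).append(scores[m])
            continue

        m_score = scores[m]
        neg = [scores[x] for x in negatives]
        rank = 1 + sum(s > m_score for s in neg)
        records.append(LoocvRecord(d, m, m_score, rank, len(neg), False, ""))
        pos_scores.append(m_score)
        neg_scores.extend(neg)
        by_disease_pos.setdefault(d, []).append(m_score)
        by_disease_neg.setdefault(d, []).extend(neg)
        fold_aucs.append(auc([m_score], neg))

    pooled = (
        auc(pos_scores, neg_scores) if pos_scores and neg_scores else float("nan")
    )
    per_disease = {
        d: auc(by_disease_pos[d], by_disease_neg[d])
        for d in by_disease_pos
        if by_disease_neg.get(d)
    }
    mean_fold = float(np.mean(fold_aucs)) if fold_aucs else float("nan")
    logger.info(
        "LOOCV: %d folds, %d scored, %d skipped, pooled AUC %.4f",
        len(records),
        len(pos_scores),
        len(records) - len(pos_scores),
        pooled,
    )
    return LoocvResult(
        records=records,
        auc=pooled,
        per_disease_auc=per_disease,
        mean_fold_auc=mean_fold,
        config=config,
    )
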