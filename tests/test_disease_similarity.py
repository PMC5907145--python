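"""Disease similarity: weight vectors, cosine, MICA factor, full matrix."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metnetwalk import (
    AssociationTable,
    DiseaseSimilarity,
    OntologyDAG,
    SyntheticSpec,
    build_weight_vectors,
    generate_planted_associations,
    inf_dis_sim_matrix,
    inf_similarity,
    mica_factor,
)


class TestWeightVectors:
    def test_binary_membership(self):
        t = AssociationTable.from_pairs(
            [("d1", "m1"), ("d1", "m2"), ("d2", "m3"), ("d2", "m1")]
        )
        wvs = build_weight_vectors(t, scheme="binary")
        assert wvs.metabolite_ids == ("m1", "m2", "m3")
        np.testing.assert_array_equal(wvs.vector("d1"), [1, 1, 0])
        np.testing.assert_array_equal(wvs.vector("d2"), [1, 0, 1])

    def test_idf_ubiquitous_metabolite_weight_zero(self):
        # m1 annotated to every disease -> idf weight log(2/2) = 0 everywhere
        t = AssociationTable.from_pairs(
            [("d1", "m1"), ("d2", "m1"), ("d1", "m2"), ("d2", "m3")]
        )
        wvs = build_weight_vectors(t, scheme="idf")
        j = wvs.metabolite_ids.index("m1")
        assert np.all(wvs.weights[:, j] == 0)

    def test_idf_exclusive_metabolite_weight_log2(self):
        t = AssociationTable.from_pairs([("d1", "m1"), ("d1", "m2"), ("d2", "m2")])
        wvs = build_weight_vectors(t, scheme="idf")
        j = wvs.metabolite_ids.index("m1")
        i = wvs.disease_ids.index("d1")
        assert wvs.weights[i, j] == pytest.approx(math.log(2), abs=1e-12)

    def test_unknown_scheme(self, toy_table):
        with pytest.raises(ValueError, match="scheme"):
            build_weight_vectors(toy_table, scheme="tfidf")


class TestInfSimilarity:
    def test_identical_vectors(self):
        assert inf_similarity([1, 2, 0.5], [1, 2, 0.5]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert inf_similarity([1, 0], [0, 3]) == 0.0

    def test_half_overlap(self):
        assert inf_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            inf_similarity([0, 0], [1, 0])


class TestMicaFactor:
    def test_no_dag_degenerates_to_one(self, toy_table):
        assert mica_factor("d1", "d2", toy_table) == 1.0

    def test_chain_hand_propagation(self):
        # r <- a <- {d1, d2}; d1 -> {m1}, d2 -> {m2}; propagated G_a = {m1, m2}
        table = AssociationTable.from_pairs([("d1", "m1"), ("d2", "m2")])
        dag = OntologyDAG.from_edges([("a", "r"), ("d1", "a"), ("d2", "a")])
        assert mica_factor("d1", "d2", table, dag) == pytest.approx(0.25)

    def test_disease_missing_from_dag_warns(self, toy_table, caplog):
        dag = OntologyDAG.from_edges([("d1", "r")])
        with caplog.at_level("WARNING"):
            f = mica_factor("d1", "d2", toy_table, dag)
        assert f == 1.0
        assert any("MICA" in r.message for r in caplog.records)

    def test_self_pair_factor_at_most_one(self):
        # propagation makes ancestor sets supersets, so |G_t|^2/|G_MICA|^2 <= 1
        table = AssociationTable.from_pairs(
            [("t", "m1"), ("t", "m2"), ("s", "m3")]
        )
        dag = OntologyDAG.from_edges([("t", "r"), ("s", "r")])
        assert mica_factor("t", "t", table, dag) <= 1.0


def _set_cosine(table, d1, d2):
    g1, g2 = table.metabolites_of(d1), table.metabolites_of(d2)
    return len(g1 & g2) / math.sqrt(len(g1) * len(g2))


class TestInfDisSimMatrix:
    def test_self_similarity_is_one(self, toy_table):
        mat = inf_dis_sim_matrix(toy_table)
        assert mat.loc("d1", "d1") == 1.0

    def test_disjoint_diseases_zero(self):
        t = AssociationTable.from_pairs([("d1", "m1"), ("d2", "m2")])
        assert inf_dis_sim_matrix(t).loc("d1", "d2") == 0.0

    def test_matches_brute_force_cosine_on_toy(self):
        pairs = [
            ("a", "m1"), ("a", "m2"), ("b", "m2"), ("b", "m3"),
            ("c", "m1"), ("c", "m3"), ("d", "m1"), ("d", "m2"), ("d", "m3"),
            ("e", "m4"),
        ]
        t = AssociationTable.from_pairs(pairs)
        mat = inf_dis_sim_matrix(t, scheme="binary")
        for d1 in t.diseases:
            for d2 in t.diseases:
                expected = 1.0 if d1 == d2 else _set_cosine(t, d1, d2)
                assert mat.loc(d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_set_based_oracle_on_planted(self, planted_table):
        mat = inf_dis_sim_matrix(planted_table, scheme="binary")
        rng = np.random.default_rng(0)
        diseases = list(planted_table.diseases)
        for _ in range(100):
            d1, d2 = rng.choice(diseases, size=2, replace=False)
            assert mat.loc(d1, d2) == pytest.approx(
                _set_cosine(planted_table, d1, d2), abs=1e-12
            )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_invariants_on_random_tables(self, seed):
        spec = SyntheticSpec(
            n_diseases=8, n_metabolites=12, k_groups=2, p_in=0.7, p_out=0.1,
            rng_seed=seed,
        )
        table, _ = generate_planted_associations(spec)
        mat = inf_dis_sim_matrix(table)
        mat.validate()  # symmetry, unit diagonal, [0, 1]

    def test_monotone_in_shared_metabolite(self):
        # adding a common metabolite never decreases binary cosine
        base = [("d1", "m1"), ("d1", "m2"), ("d2", "m2"), ("d2", "m3")]
        before = inf_dis_sim_matrix(AssociationTable.from_pairs(base))
        after = inf_dis_sim_matrix(
            AssociationTable.from_pairs(base + [("d1", "m9"), ("d2", "m9")])
        )
        assert after.loc("d1", "d2") >= before.loc("d1", "d2")

    def test_mica_factor_applied(self):
        table = AssociationTable.from_pairs([("d1", "m1"), ("d2", "m1")])
        dag = OntologyDAG.from_edges([("d1", "a"), ("d2", "a")])
        plain = inf_dis_sim_matrix(table)
        scaled = inf_dis_sim_matrix(table, dag=dag)
        # cosine 1, factor 1*1/1^2 = 1 (G_a propagated = {m1}) -> unchanged
        assert scaled.loc("d1", "d2") == pytest.approx(plain.loc("d1", "d2"))


class TestEstimator:
    def test_sklearn_params_and_fit(self, planted_table):
        from sklearn.base import clone

        est = DiseaseSimilarity(scheme="idf")
        assert clone(est).get_params()["scheme"] == "idf"
        est.fit(planted_table)
        assert est.similarity_.ids == planted_table.diseases
        assert est.transform().shape == (40, 40)
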