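"""Shared-variant matrices, disease/pathway cross-tabulation, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirvarmap.annotation import (
    AnnotationError, DiseaseTable, PathwayTable, cluster_order, hive_edges,
    pathway_category_profile, population_disease_matrix, shared_variant_matrix,
)


def site(pos):
    return ("1", pos, "T")


@pytest.fixture
def disease_table():
    return DiseaseTable(pd.DataFrame({
        "mirna": ["mir-1", "mir-1", "mir-2", "mir-3"],
        "disease": ["glioma", "colitis", "lymphoma", "glioma"],
        "category": ["cancer", "inflammatory", "cancer", "cancer"],
    }))


@pytest.fixture
def pathway_table():
    return PathwayTable(
        targets=pd.DataFrame({"mirna": ["mir-1", "mir-1", "mir-2"],
                              "gene": ["g1", "g2", "g3"]}),
        pathways=pd.DataFrame({
            "gene": ["g1", "g3", "g4", "g5", "g6"],
            "pathway": ["pw1", "pw2", "pw3", "pw4", "pw5"],
            "category": ["signaling", "signaling", "signaling", "signaling", "metabolism"],
        }),
    )


class TestSharedVariantMatrix:
    def test_disjoint_sets_zero_off_diagonal(self):
        m = shared_variant_matrix({"A": {site(1)}, "B": {site(2)}})
        assert m.matrix.loc["A", "B"] == 0
        assert m.matrix.loc["A", "A"] == 1

    def test_identical_sets_fill_matrix(self):
        s = {site(i) for i in range(5)}
        m = shared_variant_matrix({"A": set(s), "B": set(s)})
        assert (m.matrix.values == 5).all()

    def test_fuzzed_matrix_equals_brute_force_and_invariants(self):
        rng = np.random.default_rng(21)
        pops = {f"P{k}": {site(int(p)) for p in rng.integers(0, 40, size=25)} for k in range(5)}
        m = shared_variant_matrix(pops)
        m.validate()
        for a in pops:
            for b in pops:
                assert m.matrix.loc[a, b] == len(pops[a] & pops[b])

    def test_seed_only_entrywise_below_all(self):
        rng = np.random.default_rng(22)
        pops = {f"P{k}": {site(int(p)) for p in rng.integers(0, 40, size=25)} for k in range(4)}
        seed_sites = {site(i) for i in range(0, 40, 3)}
        m_all = shared_variant_matrix(pops)
        m_seed = shared_variant_matrix(pops, scope="seed-only", seed_sites=seed_sites)
        assert (m_seed.matrix.values <= m_all.matrix.values).all()

    def test_unknown_population_rejected(self):
        with pytest.raises(AnnotationError, match="unknown"):
            shared_variant_matrix({"A": set()}, populations=["A", "Z"])

    def test_seed_scope_requires_seed_sites(self):
        with pytest.raises(AnnotationError, match="seed_sites"):
            shared_variant_matrix({"A": set()}, scope="seed-only")


class TestDiseaseMatrix:
    def test_pleiotropy_counts_each_category(self, disease_table):
        pairs = {"P1": [(site(1), "mir-1")]}
        m = population_disease_matrix(pairs, disease_table)
        assert m.loc["P1", "cancer"] == 1
        assert m.loc["P1", "inflammatory"] == 1

    def test_mirna_absent_from_table_contributes_nothing(self, disease_table):
        m = population_disease_matrix({"P1": [(site(1), "mir-unknown")]}, disease_table)
        assert (m.values == 0).all()

    def test_distinct_positions_counted_once_per_category(self, disease_table):
        pairs = {"P1": [(site(1), "mir-1"), (site(1), "mir-1"), (site(2), "mir-2")]}
        m = population_disease_matrix(pairs, disease_table)
        assert m.loc["P1", "cancer"] == 2  # sites 1 and 2

    def test_planted_links_recovered_exactly(self, small_cohort, small_map):
        """Synthetic cohort: matrix equals a direct recount from truth tables."""
        table = DiseaseTable(small_cohort.truth.disease_links)
        pairs = small_map.population_site_mirnas()
        m = population_disease_matrix(pairs, table)
        links = small_cohort.truth.disease_links
        cat_of = links.groupby("mirna")["category"].agg(set).to_dict()
        for pop in pairs:
            per_cat = {c: set() for c in table.categories}
            for s, mirna in pairs[pop]:
                for c in cat_of.get(mirna, ()):  # miRNAs without links drop out
                    per_cat[c].add(s)
            for c in table.categories:
                assert m.loc[pop, c] == len(per_cat[c])


class TestPathwayProfile:
    def test_no_seed_variants_all_zero(self, pathway_table):
        prof = pathway_category_profile({"P1": set()}, pathway_table)
        assert (prof.values == 0).all()

    def test_single_hit_in_four_pathway_category(self, pathway_table):
        prof = pathway_category_profile({"P1": {"mir-2"}}, pathway_table)
        # mir-2 targets g3 -> pw2, one of 4 signaling pathways
        assert prof.loc["P1", "signaling"] == pytest.approx(25.0)
        assert prof.loc["P1", "metabolism"] == 0.0

    def test_pathway_with_conflicting_categories_rejected(self):
        with pytest.raises(AnnotationError, match="several categories"):
            PathwayTable(
                targets=pd.DataFrame({"mirna": ["m"], "gene": ["g"]}),
                pathways=pd.DataFrame({
                    "gene": ["g", "h"], "pathway": ["pw", "pw"],
                    "category": ["a", "b"],
                }),
            )


class TestHiveEdges:
    def test_single_mirna_two_edges(self, disease_table):
        pairs = {"P1": [(site(1), "mir-2")]}
        mp, mc = hive_edges(pairs, disease_table=disease_table)
        assert len(mp) == 1 and len(mc) == 1
        assert mp.iloc[0]["weight"] == 1

    def test_empty_map_empty_edges(self, disease_table):
        mp, mc = hive_edges({}, disease_table=disease_table)
        assert mp.empty and mc.empty

    def test_edge_weights_marginalize_to_disease_matrix(self, small_cohort, small_map):
        table = DiseaseTable(small_cohort.truth.disease_links)
        pairs = small_map.population_site_mirnas()
        m = population_disease_matrix(pairs, table)
        mp, _ = hive_edges(pairs, disease_table=table)
        cat_of = {mir: table.categories_of(mir) for mir in set(mp["mirna"])}
        for pop in m.index:
            sub = mp[mp["population"] == pop]
            for cat in m.columns:
                total = int(sub[sub["mirna"].map(lambda x: cat in cat_of[x])]["weight"].sum())
                assert total == m.loc[pop, cat]


class TestClusterOrder:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"])
        order = cluster_order(m)
        first_merge = set(order.row_linkage[0, :2].astype(int))
        assert first_merge == {0, 1}
        assert order.row_linkage[0, 2] == pytest.approx(0.0)

    def test_colinear_toy_matches_hand_computation(self):
        """Points 0, 1, 3 on a line: merge {0,1} at distance 1, then the
        pair joins 3 at complete-linkage distance max(2,3)=3."""
        m = pd.DataFrame([[0.0], [1.0], [3.0]], index=["x", "y", "z"])
        order = cluster_order(m)
        assert set(order.row_linkage[0, :2].astype(int)) == {0, 1}
        assert order.row_linkage[0, 2] == pytest.approx(1.0)
        assert order.row_linkage[1, 2] == pytest.approx(3.0)

    def test_merge_heights_invariant_under_row_permutation(self):
        rng = np.random.default_rng(23)
        m = pd.DataFrame(rng.random((6, 4)), index=list("abcdef"))
        perm = m.sample(frac=1, random_state=1)
        h1 = sorted(cluster_order(m).row_linkage[:, 2])
        h2 = sorted(cluster_order(perm).row_linkage[:, 2])
        np.testing.assert_allclose(h1, h2)

    def test_constant_matrix_deterministic(self):
        m = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        o1 = cluster_order(m)
        o2 = cluster_order(m)
        assert o1.row_order == o2.row_order

    def test_single_row_rejected(self):
        with pytest.raises(AnnotationError, match="2 rows"):
            cluster_order(pd.DataFrame([[1.0, 2.0]]))


class TestTableValidation:
    def test_empty_disease_names_rejected(self):
        with pytest.raises(AnnotationError, match="empty disease"):
            DiseaseTable(pd.DataFrame({"mirna": ["m"], "disease": [""], "category": ["c"]}))

    def test_disease_with_two_categories_rejected(self):
        with pytest.raises(AnnotationError, match="several categories"):
            DiseaseTable(pd.DataFrame({
                "mirna": ["m", "n"], "disease": ["d", "d"], "category": ["a", "b"],
            }))
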