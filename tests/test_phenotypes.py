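"""Ontology propagation, per-level pleiotropy counts, rank-sum comparisons."""

import networkx as nx
import numpy as np
import pytest

from geneloss.ontology import OntologyDAG
from geneloss.phenotypes import (
    NO_ABNORMAL_PHENOTYPE,
    count_phenotypes,
    direct_annotations,
    filter_single_gene_knockouts,
    gene_level_counts,
    pleiotropy_compare,
    propagate,
    rank_sum_normal_approx,
    wilcoxon_rank_sum,
)

from oracles import closure_oracle, exact_rank_sum_p, level_oracle, random_dag


def dag_from_edges(edges: list[tuple[str, str]]) -> OntologyDAG:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return OntologyDAG.from_graph(g)


class TestFiltering:
    def test_digenic_removed_monogenic_kept(self):
        rows = [("g1", "T1", 1), ("g1", "T2", 2), ("g2", "T1", 1)]
        kept = filter_single_gene_knockouts(rows)
        assert kept == [("g1", "T1", 1), ("g2", "T1", 1)]

    def test_mixed_table_counts(self):
        rows = [("g", f"T{i}", 1) for i in range(6)] + [
            ("g", f"T{i}", 2) for i in range(4)
        ]
        assert len(filter_single_gene_knockouts(rows)) == 6


class TestPropagation:
    def test_chain_closure(self):
        dag = dag_from_edges([("T1", "R"), ("T2", "T1")])
        closed = propagate({"g": {"T2"}}, dag)
        assert closed["g"] == {"T1", "T2"}  # root excluded

    def test_diamond_closure_matches_oracle(self):
        edges = [("A", "R"), ("B", "R"), ("C", "A"), ("C", "B")]
        dag = dag_from_edges(edges)
        closed = propagate({"g": {"C"}}, dag)
        oracle = closure_oracle({"C": {"A", "B"}, "A": {"R"}, "B": {"R"}}, "C")
        assert closed["g"] == ({"C"} | oracle) - {"R"}

    def test_idempotent(self):
        dag = dag_from_edges([("A", "R"), ("B", "A"), ("C", "B")])
        once = propagate({"g": {"C"}}, dag)
        twice = propagate(once, dag)
        assert once == twice

    def test_unknown_term_rejected(self):
        dag = dag_from_edges([("A", "R")])
        with pytest.raises(KeyError):
            propagate({"g": {"ZZ"}}, dag)


class TestCounting:
    def test_per_level_counts(self):
        dag = dag_from_edges([("T1", "R"), ("T2", "T1")])
        closed = propagate({"g": {"T2"}}, dag)["g"]
        assert count_phenotypes(closed, dag, level=2, excluded_terms=frozenset()) == 1
        assert count_phenotypes(closed, dag, level=3, excluded_terms=frozenset()) == 1

    def test_exclusion_list_applied(self):
        dag = dag_from_edges(
            [("MP:0002873", "R"), (NO_ABNORMAL_PHENOTYPE, "MP:0002873")]
        )
        closed = propagate({"g": {NO_ABNORMAL_PHENOTYPE}}, dag)["g"]
        assert count_phenotypes(closed, dag, level=3) == 0
        assert (
            count_phenotypes(closed, dag, level=3, excluded_terms=frozenset()) == 1
        )

    def test_random_dags_match_bruteforce(self, rng):
        for _ in range(30):
            dag = random_dag(rng, int(rng.integers(5, 40)))
            terms = sorted(dag.terms - {dag.root})
            if not terms:
                continue
            k = int(rng.integers(1, min(4, len(terms)) + 1))
            chosen = {terms[int(i)] for i in rng.choice(len(terms), k, replace=False)}
            closed = propagate({"g": chosen}, dag)["g"]
            edges = {t: set(dag.graph.successors(t)) for t in dag.terms}
            expect = set()
            for term in chosen:
                expect |= {term} | closure_oracle(edges, term)
            expect.discard(dag.root)
            assert closed == expect
            for level in (2, 3, 4):
                want = sum(
                    1
                    for t in expect
                    if level_oracle(edges, dag.root, t) == level
                )
                got = count_phenotypes(closed, dag, level, frozenset())
                assert got == want

    def test_monotone_in_annotations(self):
        dag = dag_from_edges([("A", "R"), ("B", "R"), ("C", "A")])
        before = propagate({"g": {"C"}}, dag)["g"]
        after = propagate({"g": {"C", "B"}}, dag)["g"]
        for level in (2, 3):
            assert count_phenotypes(after, dag, level, frozenset()) >= count_phenotypes(
                before, dag, level, frozenset()
            )


class TestGeneLevelCounts:
    def _dag(self):
        return dag_from_edges(
            [("L2a", "R"), ("L3a", "L2a"), ("L4a", "L3a"), ("L4b", "L3a")]
        )

    def test_counts_frame(self):
        rows = [("m1", "L4a", 1), ("m1", "L4b", 1), ("m2", "L4a", 2)]
        df = gene_level_counts(rows, self._dag())
        assert list(df.index) == ["m1"]  # m2 only had a digenic row
        assert df.loc["m1", "level4_count"] == 2
        assert df.loc["m1", "level3_count"] == 1
        assert df.loc["m1", "level2_count"] == 1

    def test_ortholog_translation(self):
        rows = [("mouse1", "L4a", 1)]
        df = gene_level_counts(rows, self._dag(), ortholog_map={"mouse1": "HUM1"})
        assert list(df.index) == ["HUM1"]

    def test_empty_after_exclusion_dropped_by_default(self):
        dag = dag_from_edges(
            [("MP:0002873", "R"), (NO_ABNORMAL_PHENOTYPE, "MP:0002873")]
        )
        rows = [("g", NO_ABNORMAL_PHENOTYPE, 1)]
        assert len(gene_level_counts(rows, dag)) == 0
        assert len(gene_level_counts(rows, dag, include_empty=True)) == 1


class TestRankSum:
    def test_exact_small_example(self):
        # complete separation of 3 vs 3: p = 2 / C(6,3) = 0.1
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)
        assert r.rank_biserial == -1.0

    def test_identical_groups_p_one(self):
        r = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exact_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = list(rng.permutation(20)[:5].astype(float))
        y = list((rng.permutation(20)[:6] + 0.5).astype(float))
        r = wilcoxon_rank_sum(x, y)
        assert r.p_value == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_asymptotic_matches_formula_with_ties(self, rng):
        x = list(rng.integers(0, 6, 60).astype(float))
        y = list(rng.integers(0, 6, 80).astype(float))
        r = wilcoxon_rank_sum(x, y)
        assert r.method == "asymptotic"
        assert r.p_value == pytest.approx(rank_sum_normal_approx(x, y), abs=1e-6)

    def test_pairwise_compare_frame(self):
        groups = {"no_loss": [3, 4, 5], "single": [2, 3, 4], "multi": [1, 2, 3]}
        df = pleiotropy_compare(groups)
        assert len(df) == 3
        assert set(df["group_a"]) <= set(groups)


def test_direct_annotations_groups_terms():
    rows = [("g1", "A", 1), ("g1", "B", 1), ("g2", "A", 1)]
    assert direct_annotations(rows) == {"g1": {"A", "B"}, "g2": {"A"}}
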