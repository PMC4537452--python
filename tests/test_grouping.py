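"""Hypergeometric term enrichment, Cohen's kappa and term grouping."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vdnet.grouping import (
    TermAnnotation,
    annotation_universe,
    build_kappa_graph,
    enrich_terms,
    group_terms,
    kappa_stat,
)

UNIVERSE10 = [f"g{i}" for i in range(1, 11)]


def bruteforce_tail_p(M, K, n, k):
    """Independent oracle: P[X >= k] by binomial-coefficient enumeration."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, x) * math.comb(M - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


class TestEnrichment:
    def test_worked_example(self):
        term = TermAnnotation("T1", "t", frozenset(UNIVERSE10[:5]))
        df = enrich_terms(UNIVERSE10[:4], [term], UNIVERSE10)
        assert df["p"].iloc[0] == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        term = TermAnnotation("T1", "t", frozenset(UNIVERSE10[5:]))
        df = enrich_terms(UNIVERSE10[:3], [term], UNIVERSE10)
        assert df["p"].iloc[0] == 1.0

    def test_bh_never_below_raw(self):
        rng = np.random.default_rng(0)
        terms = [
            TermAnnotation(f"T{i}", "t", frozenset(
                rng.choice(UNIVERSE10, size=int(rng.integers(2, 8)),
                           replace=False)))
            for i in range(8)
        ]
        df = enrich_terms(UNIVERSE10[:4], terms, UNIVERSE10)
        assert (df["p_adj"] >= df["p"] - 1e-15).all()

    def test_empty_query_rejected(self):
        term = TermAnnotation("T1", "t", frozenset(UNIVERSE10[:5]))
        with pytest.raises(ValueError):
            enrich_terms([], [term], UNIVERSE10)

    def test_matches_bruteforce_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            M = int(rng.integers(5, 31))
            universe = [f"u{i}" for i in range(M)]
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            term_genes = frozenset(rng.choice(universe, K, replace=False))
            query = list(rng.choice(universe, n, replace=False))
            df = enrich_terms(query, [TermAnnotation("T", "t", term_genes)],
                              universe)
            k = len(term_genes & set(query))
            assert df["p"].iloc[0] == pytest.approx(
                bruteforce_tail_p(M, K, n, k), abs=1e-12
            )


class TestKappa:
    def test_identical_sets(self):
        assert kappa_stat(set(UNIVERSE10[:4]), set(UNIVERSE10[:4]),
                          UNIVERSE10).kappa == 1.0

    def test_worked_partial_overlap(self):
        res = kappa_stat({"g1", "g2", "g3", "g4"}, {"g3", "g4", "g5", "g6"},
                         UNIVERSE10)
        assert res.p_o == pytest.approx(0.6)
        assert res.p_e == pytest.approx(0.52)
        assert res.kappa == pytest.approx(0.1667, abs=1e-4)

    def test_complementary_halves(self):
        res = kappa_stat(set(UNIVERSE10[:5]), set(UNIVERSE10[5:]), UNIVERSE10)
        assert res.kappa == -1.0

    def test_full_universe_both_defined_as_one(self):
        assert kappa_stat(set(UNIVERSE10), set(UNIVERSE10),
                          UNIVERSE10).kappa == 1.0

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            kappa_stat({"zz"}, {"g1"}, UNIVERSE10)

    @given(st.data())
    def test_symmetry_and_relabelling_invariance(self, data):
        n = data.draw(st.integers(4, 20))
        universe = [f"u{i}" for i in range(n)]
        a = set(data.draw(st.sets(st.sampled_from(universe), max_size=n)))
        b = set(data.draw(st.sets(st.sampled_from(universe), max_size=n)))
        k_ab = kappa_stat(a, b, universe).kappa
        k_ba = kappa_stat(b, a, universe).kappa
        assert k_ab == pytest.approx(k_ba, abs=1e-12)
        relabel = {u: f"x{i}" for i, u in enumerate(universe)}
        k_rel = kappa_stat({relabel[g] for g in a}, {relabel[g] for g in b},
                           relabel.values()).kappa
        assert k_ab == pytest.approx(k_rel, abs=1e-12)


class TestKappaGraph:
    def _terms(self):
        return [
            TermAnnotation("TA", "a", frozenset(UNIVERSE10[:4])),
            TermAnnotation("TB", "b", frozenset(UNIVERSE10[1:5])),
            TermAnnotation("TC", "c", frozenset(UNIVERSE10[6:])),
        ]

    def test_threshold_boundary_inclusive(self):
        terms = self._terms()
        kappa = kappa_stat(terms[0].genes, terms[1].genes, UNIVERSE10).kappa
        g_above = build_kappa_graph(terms, UNIVERSE10,
                                    kappa_threshold=kappa)
        g_below = build_kappa_graph(terms, UNIVERSE10,
                                    kappa_threshold=kappa + 1e-9)
        assert g_above.has_edge("TA", "TB")
        assert not g_below.has_edge("TA", "TB")

    def test_graph_symmetric_and_weighted(self):
        g = build_kappa_graph(self._terms(), UNIVERSE10, kappa_threshold=0.3)
        for u, v in g.edges:
            assert g.has_edge(v, u)
            assert -1.0 <= g[u][v]["weight"] <= 1.0

    def test_isolated_term_has_degree_zero(self):
        g = build_kappa_graph(self._terms(), UNIVERSE10, kappa_threshold=0.3)
        assert g.degree("TC") == 0


class TestGroupTerms:
    def _enrichment(self, term_ids, ps=None):
        ps = ps or [0.01 * (i + 1) for i in range(len(term_ids))]
        return pd.DataFrame({"term_id": term_ids, "p": ps})

    def test_overlapping_seed_groups_merge(self):
        # T1-T2-T3 clique and T3-T4-T5 clique share enough terms to merge
        g = nx.Graph()
        for a, b in [("T1", "T2"), ("T2", "T3"), ("T1", "T3"),
                     ("T3", "T4"), ("T4", "T5"), ("T3", "T5")]:
            g.add_edge(a, b, weight=0.6)
        groups, unassigned = group_terms(
            g, self._enrichment(["T1", "T2", "T3", "T4", "T5"])
        )
        assert len(groups) == 1
        assert set(groups[0].members) == {"T1", "T2", "T3", "T4", "T5"}
        assert not unassigned

    def test_isolated_term_unassigned(self):
        g = nx.Graph()
        g.add_edge("T1", "T2", weight=0.5)
        g.add_node("T9")
        groups, unassigned = group_terms(g, self._enrichment(["T1", "T2", "T9"]))
        assert unassigned == ["T9"]

    def test_leading_term_has_smallest_p(self):
        g = nx.Graph()
        g.add_edge("T1", "T2", weight=0.5)
        groups, _ = group_terms(
            g, self._enrichment(["T1", "T2"], ps=[0.04, 0.001])
        )
        assert groups[0].leading_term == "T2"

    def test_groups_partition_and_members_similar(self):
        """On generated family-structured terms the final groups are disjoint
        and every grouped term is kappa-similar to its own group."""
        from vdnet.simulate import ScenarioConfig, generate_annotations

        cfg = ScenarioConfig(seed=3)
        genes = [f"G{i:04d}" for i in range(1, 2001)]
        terms, _ = generate_annotations(cfg, genes, genes[:15])
        universe = annotation_universe(terms)
        graph = build_kappa_graph(terms, universe)
        enrichment = enrich_terms(list(terms[0].genes)[:10], terms, universe)
        groups, unassigned = group_terms(graph, enrichment)
        seen = {}
        for group in groups:
            for t in group.members:
                assert t not in seen
                seen[t] = group.group_id
                assert any(
                    graph.has_edge(t, other)
                    for other in group.members if other != t
                ) or len(group.members) == 1
        assert set(seen) | set(unassigned) == set(graph.nodes)
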