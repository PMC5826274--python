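"""Prioritization: module/term significance arithmetic, interaction scaling
against a brute-force ranking oracle, cross-module filtering, and the
three-stage visualization sparsifier."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet.annotate import (
    cross_module_filter,
    edge_width,
    module_significance,
    scale_interactions,
    score_terms,
    sparsify_for_viz,
    term_significance,
)


@pytest.fixture()
def kme_fixture():
    genes = pd.Index([f"g{i}" for i in range(10)])
    kme = pd.Series(np.linspace(0.1, 1.0, 10), index=genes)
    return genes, kme


class TestModuleSignificance:
    def test_mean_kme_times_one_minus_p(self, kme_fixture):
        genes, kme = kme_fixture
        module = genes[:6]
        term = genes[2:4]  # kME 0.3, 0.4 -> mean 0.35
        ms = module_significance(term, 0.2, module, kme)
        assert ms == pytest.approx(0.35 * 0.8)

    def test_p_one_gives_zero(self, kme_fixture):
        genes, kme = kme_fixture
        assert module_significance(genes[:3], 1.0, genes[:5], kme) == pytest.approx(0.0)

    def test_perfect_membership_zero_p_is_maximum(self):
        genes = pd.Index(["a", "b"])
        kme = pd.Series([1.0, 1.0], index=genes)
        assert module_significance(genes, 0.0, genes, kme) == pytest.approx(1.0)

    def test_no_overlap_is_nan(self, kme_fixture):
        genes, kme = kme_fixture
        assert np.isnan(module_significance(genes[8:], 0.1, genes[:3], kme))


class TestTermSignificance:
    def test_zero_gene_significance_zero_ts(self, kme_fixture):
        genes, kme = kme_fixture
        gs = pd.Series(0.0, index=genes)
        ts = term_significance(genes[:4], 0.2, genes[:6], kme, gs)
        assert ts == pytest.approx(0.0)

    def test_product_form(self, kme_fixture):
        genes, kme = kme_fixture
        gs = pd.Series(0.5, index=genes)
        ms = module_significance(genes[:4], 0.2, genes[:6], kme)
        assert term_significance(genes[:4], 0.2, genes[:6], kme, gs) == pytest.approx(
            ms * 0.5
        )

    def test_absolute_vs_signed_weighting(self, kme_fixture):
        genes, kme = kme_fixture
        gs = pd.Series([-0.5, 0.5] * 5, index=genes)
        ts_abs = term_significance(genes[:4], 0.0, genes[:6], kme, gs)
        ts_signed = term_significance(genes[:4], 0.0, genes[:6], kme, gs, signed=True)
        assert ts_abs == pytest.approx(kme[genes[:4]].mean() * 0.5)
        assert ts_signed == pytest.approx(0.0)

    def test_score_terms_ranking_matches_bruteforce(self, rng):
        """Oracle loop: recompute every (term, module) score independently."""
        genes = pd.Index([f"g{i}" for i in range(60)])
        labels = pd.Series(
            ["m1"] * 20 + ["m2"] * 20 + ["grey"] * 20, index=genes
        )
        kme = pd.Series(rng.uniform(0.2, 1.0, 60), index=genes)
        gs = pd.Series(rng.uniform(-1, 1, 60), index=genes)
        terms = pd.DataFrame(
            {
                "term_id": [f"T{t}" for t in range(10)],
                "category": ["go_bp"] * 10,
                "p_value": rng.uniform(0, 1, 10),
                "gene_ids": [
                    ",".join(rng.choice(genes, 8, replace=False)) for _ in range(10)
                ],
            }
        )
        table = score_terms(terms, labels, kme, gs_trait=gs)
        for _, row in table.iterrows():
            term = terms.loc[terms.term_id == row["term_id"]].iloc[0]
            term_genes = pd.Index(term["gene_ids"].split(","))
            module_genes = labels.index[labels == row["module"]]
            inside = term_genes.intersection(module_genes)
            expected_ms = kme.loc[inside].mean() * (1 - term["p_value"])
            assert row["module_significance"] == pytest.approx(expected_ms)
            expected_ts = expected_ms * gs.loc[inside].abs().mean()
            assert row["term_significance"] == pytest.approx(expected_ts)


class TestScaleInteractions:
    @pytest.fixture()
    def edges_stats(self, rng):
        genes = [f"g{i}" for i in range(20)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        idx = rng.choice(len(pairs), 50, replace=False)
        edges = pd.DataFrame(
            {
                "gene_i": [pairs[i][0] for i in idx],
                "gene_j": [pairs[i][1] for i in idx],
                "confidence": rng.uniform(0.5, 1.0, 50),
            }
        )
        stats = pd.DataFrame(
            {
                "kIN": rng.uniform(0, 30, 20),
                "dk": rng.uniform(-10, 10, 20),
                "gs": rng.uniform(-1, 1, 20),
            },
            index=pd.Index(genes),
        )
        return edges, stats

    def test_low_confidence_excluded_any_metric(self, edges_stats):
        edges, stats = edges_stats
        edges.loc[0, "confidence"] = 0.85
        for metric in (1, 2, 3, 4):
            ranked = scale_interactions(edges, stats, metric)
            assert (ranked["confidence"] >= 0.9).all()

    def test_metric1_hand_value(self):
        edges = pd.DataFrame(
            {"gene_i": ["a"], "gene_j": ["b"], "confidence": [0.9]}
        )
        stats = pd.DataFrame({"kIN": [2.0, 3.0]}, index=["a", "b"])
        ranked = scale_interactions(edges, stats, 1)
        assert ranked["score"].iloc[0] == pytest.approx(5.4)

    @pytest.mark.parametrize("metric", [1, 2, 3, 4])
    def test_full_ranking_matches_bruteforce(self, edges_stats, metric):
        edges, stats = edges_stats
        ranked = scale_interactions(edges, stats, metric)

        def factor(g):
            s = stats.loc[g]
            return {1: s.kIN, 2: s.dk, 3: s.gs, 4: s.kIN * s.gs}[metric]

        expected = []
        for _, e in edges.iterrows():
            if e.confidence < 0.9:
                continue
            expected.append(
                (e.confidence * factor(e.gene_i) * factor(e.gene_j), e.gene_i, e.gene_j)
            )
        expected.sort(key=lambda r: (-r[0], r[1], r[2]))
        assert [(round(s, 9)) for s, *_ in expected] == [
            round(s, 9) for s in ranked["score"]
        ]
        assert [(a, b) for _, a, b in expected] == list(
            zip(ranked["gene_i"], ranked["gene_j"])
        )

    def test_missing_statistic_dropped_with_warning(self):
        edges = pd.DataFrame(
            {"gene_i": ["a", "a"], "gene_j": ["b", "c"], "confidence": [0.95, 0.95]}
        )
        stats = pd.DataFrame({"kIN": [1.0, 2.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="missing"):
            ranked = scale_interactions(edges, stats, 1)
        assert len(ranked) == 1

    def test_equal_stats_reduce_to_confidence_order(self, edges_stats):
        """All four metrics agree when every scaling statistic is equal."""
        edges, stats = edges_stats
        stats.loc[:, ["kIN", "dk", "gs"]] = 2.0
        orders = [
            list(zip(*[scale_interactions(edges, stats, m)[c] for c in ("gene_i", "gene_j")]))
            for m in (1, 2, 3, 4)
        ]
        assert orders[0] == orders[1] == orders[2] == orders[3]
        confs = scale_interactions(edges, stats, 1)["confidence"]
        assert (np.diff(confs) <= 1e-12).all()


class TestCrossModuleFilter:
    def test_fixture_keeps_only_cross_class_edges(self):
        labels = pd.Series(
            {"l1": "green", "l2": "darkred", "s1": "black", "s2": "blue", "o1": "pink"}
        )
        edges = pd.DataFrame(
            {
                "gene_i": ["l1", "l1", "s1", "l2", "o1", "l1"],
                "gene_j": ["l2", "s1", "s2", "s2", "s1", "o1"],
                "confidence": [0.95] * 6,
            }
        )
        kept = cross_module_filter(
            edges, labels, source_modules={"green", "darkred"},
            target_modules={"black", "blue"},
        )
        assert sorted(zip(kept["gene_i"], kept["gene_j"])) == [
            ("l1", "s1"), ("l2", "s2"),
        ]


class TestSparsifyForViz:
    def _edges(self, triples):
        return pd.DataFrame(
            [{"gene_i": a, "gene_j": b, "weight": w} for a, b, w in triples]
        )

    def test_smaller_component_removed(self):
        big = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "e", 1.0)]
        small = [("x", "y", 1.0), ("y", "z", 1.0)]
        g = sparsify_for_viz(self._edges(big + small), keep_fraction=1.0)
        assert set(g.nodes) == {"a", "b", "c", "d", "e"}

    def test_ties_at_cutoff_all_retained(self):
        edges = self._edges([("a", "b", 0.5), ("b", "c", 0.5), ("c", "a", 0.5)])
        g = sparsify_for_viz(edges, keep_fraction=0.01)
        assert g.number_of_edges() == 3

    def test_idempotent_at_same_fraction(self, rng):
        n = 40
        triples = [
            (f"n{i}", f"n{j}", float(rng.uniform()))
            for i in range(n)
            for j in range(i + 1, n)
        ]
        g1 = sparsify_for_viz(self._edges(triples), keep_fraction=0.05)
        again = pd.DataFrame(
            [
                {"gene_i": u, "gene_j": v, "weight": d["weight"]}
                for u, v, d in g1.edges(data=True)
            ]
        )
        g2 = sparsify_for_viz(again, keep_fraction=1.0)
        assert nx.utils.graphs_equal(g1, g2)

    def test_node_counts_never_increase(self, rng):
        triples = [
            (f"n{i}", f"n{j}", float(rng.uniform())) for i in range(30) for j in range(i + 1, 30)
        ]
        edges = self._edges(triples)
        n_keep = max(1, int(np.ceil(0.05 * len(edges))))
        cutoff = np.sort(edges["weight"])[::-1][n_keep - 1]
        thresholded = edges[edges["weight"] >= cutoff]
        g = sparsify_for_viz(edges, keep_fraction=0.05)
        nodes_after_threshold = set(thresholded["gene_i"]) | set(thresholded["gene_j"])
        assert set(g.nodes) <= nodes_after_threshold

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            sparsify_for_viz(self._edges([]), keep_fraction=0.02)


class TestEdgeWidth:
    def test_matches_metric1_form(self):
        assert edge_width(0.9, 2.0, 3.0) == pytest.approx(5.4)

    def test_vectorized_and_validated(self):
        out = edge_width(np.array([1.0, 0.5]), np.array([2.0, 2.0]), np.array([1.0, 4.0]))
        assert np.allclose(out, [2.0, 4.0])
        with pytest.raises(ValueError):
            edge_width(-0.1, 1.0, 1.0)
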