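"""Composite selection: supersets, AUC-ranked unions, the C-Index and the
composite-evaluation protocol, on both the packaged tables and planted
benchmarks."""

import logging

import numpy as np
import pytest

from conftest import shifted_matrix
from netsig import (
    CompositeSpec,
    MetricParams,
    SyntheticConfig,
    build_superset,
    c_index_select,
    enumerate_compositions,
    evaluate_composition,
    generate_linked,
    load_fixtures,
    precision,
    rank_union,
)


@pytest.fixture(scope="module")
def fx():
    return load_fixtures()


class TestSuperset:
    def test_fixture_union_size(self, fx):
        union = build_superset(
            {m: fx.table1a[m] for m in ("clustering_coefficient", "bottleneck")}
        )
        assert len(union) == 32  # 21 + 11, disjoint lists

    def test_identical_sets_idempotent(self):
        union = build_superset({"a": ["X", "Y"], "b": ["X", "Y"]})
        assert set(union) == {"X", "Y"}
        assert union["X"] == ["a", "b"]

    def test_order_invariance_and_monotonicity(self, fx):
        two = build_superset(
            {m: fx.table1a[m] for m in ("clustering_coefficient", "bottleneck")}
        )
        rev = build_superset(
            {m: fx.table1a[m] for m in ("bottleneck", "clustering_coefficient")}
        )
        assert set(two) == set(rev)
        three = build_superset(
            {m: fx.table1a[m]
             for m in ("clustering_coefficient", "bottleneck", "eccentricity")}
        )
        assert set(two) <= set(three)


class TestRankUnion:
    def test_fixture_union_top_ranks_are_reference_hits(self, fx):
        union = build_superset(
            {m: fx.table1a[m] for m in ("clustering_coefficient", "bottleneck")}
        )
        ranked = rank_union(union, fx.auc_by_gene)
        top10 = ranked.genes[:10]
        hits = set(top10) & set(fx.top_auc_genes(10))
        assert len(hits) == 7
        # the 7 reference hits carry the highest AUCs in the union
        assert set(ranked.genes[:7]) == hits

    def test_tie_breaks_alphabetically(self):
        ranked = rank_union(["B", "A", "C"], {"A": 0.9, "B": 0.9, "C": 0.8})
        assert ranked.genes == ["A", "B", "C"]
        assert [r for _, _, r in ranked.entries] == [1, 1, 3]

    def test_unscored_members_rank_last(self):
        ranked = rank_union(["A", "Z", "M"], {"A": 0.7})
        assert ranked.genes == ["A", "M", "Z"]

    def test_no_auc_errors(self):
        with pytest.raises(ValueError):
            rank_union(["A"], {})

    def test_effect_size_order_recovered(self):
        """With well-separated planted effects, AUC ranking recovers the
        effect-size order for most adjacent pairs."""
        rng = np.random.default_rng(0)
        deltas = np.linspace(0.2, 2.0, 10)
        n = 500
        x = rng.normal(8, 1, (10, 2 * n))
        x[:, n:] += deltas[:, None]
        from conftest import make_matrix

        m = make_matrix(x, n, n, genes=[f"e{i}" for i in range(10)])
        ranked = rank_union(m.genes, m)
        order = [int(g[1:]) for g in ranked.genes]  # best (largest delta) first
        adjacent_ok = sum(a > b for a, b in zip(order, order[1:]))
        assert adjacent_ok >= 0.9 * (len(order) - 1)


class TestCIndex:
    def test_fixture_standin_reproduces_70_percent(self, fx):
        """Published worked example: clustering+bottleneck union, ranked by
        the printed AUCs, hits 7 of the overall top-10."""
        union = build_superset(
            {m: fx.table1a[m] for m in ("clustering_coefficient", "bottleneck")}
        )
        top10 = rank_union(union, fx.auc_by_gene).genes[:10]
        assert precision(top10, fx.top_auc_genes(10), 10).precision == pytest.approx(0.70)

    def test_planted_benchmark_beats_degree(self):
        from netsig.metrics import degree_scores, top_k

        g, m, truth = generate_linked(SyntheticConfig(seed=11))
        informative = set(truth.informative_genes)
        panel = c_index_select(g, m, k_select=10, params=MetricParams(seed=11))
        assert len(panel.genes) == 10
        deg10 = [x for x, _, _ in top_k(degree_scores(g), 10).entries[:10]]
        assert len(set(panel.genes) & informative) > len(set(deg10) & informative)

    def test_k_select_larger_than_union_warns(self, caplog):
        g, m, _ = generate_linked(SyntheticConfig(seed=1))
        with caplog.at_level(logging.WARNING):
            panel = c_index_select(g, m, k_component=3, k_select=60,
                                   params=MetricParams(seed=1))
        assert "returning all" in caplog.text
        assert len(panel.genes) < 60

    def test_insufficient_overlap_errors(self):
        g, _, _ = generate_linked(SyntheticConfig(seed=1))
        m = shifted_matrix(5, 0, delta=0.0, n_control=5, n_case=5, seed=0)
        with pytest.raises(ValueError, match="share"):
            c_index_select(g, m, k_select=10)

    def test_deterministic_without_epc(self):
        g, m, _ = generate_linked(SyntheticConfig(seed=2))
        p1 = c_index_select(g, m, k_select=10, params=MetricParams(seed=1))
        p2 = c_index_select(g, m, k_select=10, params=MetricParams(seed=999))
        assert p1.genes == p2.genes  # no EPC involved, seeds irrelevant


class TestEvaluateComposition:
    def test_fixture_based_precision(self, fx):
        union = build_superset(
            {m: fx.table1a[m] for m in ("clustering_coefficient", "bottleneck")}
        )
        sel = rank_union(union, fx.auc_by_gene).genes[:10]
        assert precision(sel, fx.top_auc_genes(10), 10).precision == 0.70

    def test_duplicated_metric_equals_single(self):
        g, m, _ = generate_linked(SyntheticConfig(seed=3))
        reference = sorted(m.genes)[:20]
        spec = CompositeSpec(("clustering_coefficient", "clustering_coefficient"))
        ev = evaluate_composition(spec, g, m, reference)
        from netsig.metrics import clustering_coefficient_scores, top_k

        single = top_k(clustering_coefficient_scores(g), 10)
        assert ev.superset_size == len(single)

    def test_cindex_spec_beats_degree_betweenness(self):
        """The degree+betweenness pairing selects hub decoys and misses the
        planted informative genes more often than the C-Index pairing."""
        wins = ties = 0
        cindex = CompositeSpec(("clustering_coefficient", "bottleneck"))
        conventional = CompositeSpec(("degree", "betweenness"))
        from netsig import individual_aucs

        for seed in range(20):
            g, m, truth = generate_linked(SyntheticConfig(seed=400 + seed))
            reference = (
                individual_aucs(m, m.genes)
                .sort_values("auc", ascending=False)
                .index.tolist()
            )  # overall disease-correlated ranking, as in the protocol
            ev_c = evaluate_composition(cindex, g, m, reference, MetricParams(seed=1))
            ev_d = evaluate_composition(conventional, g, m, reference,
                                        MetricParams(seed=1))
            if ev_d.precision[10] < ev_c.precision[10]:
                wins += 1
        assert wins >= 16

    def test_short_reference_errors(self):
        g, m, _ = generate_linked(SyntheticConfig(seed=3))
        with pytest.raises(ValueError):
            evaluate_composition(
                CompositeSpec(("degree", "bottleneck")), g, m, ["only_one"]
            )


class TestEnumerateCompositions:
    def test_pair_count_and_sorting(self):
        g, m, _ = generate_linked(SyntheticConfig(seed=5))
        reference = sorted(m.genes)[:20]
        metrics = ["degree", "betweenness", "clustering_coefficient", "bottleneck"]
        table = enumerate_compositions(metrics, [2], g, m, reference,
                                       params=MetricParams(seed=5))
        assert len(table) == 6
        aucs = table["integrated_auc@10"].to_numpy()
        assert (np.diff(aucs) <= 1e-12).all()

    def test_best_pair_mixes_local_and_global(self):
        from netsig.metrics import GLOBAL_METRICS, LOCAL_METRICS

        metrics = ["degree", "clustering_coefficient", "bottleneck", "betweenness"]
        from netsig import individual_aucs

        mixed = 0
        for seed in range(20):
            g, m, truth = generate_linked(SyntheticConfig(seed=500 + seed))
            reference = (
                individual_aucs(m, m.genes)
                .sort_values("auc", ascending=False)
                .index.tolist()
            )
            table = enumerate_compositions(metrics, [2], g, m, reference,
                                           params=MetricParams(seed=1))
            best = table.iloc[0]["composition"].split("+")
            if set(best) & set(LOCAL_METRICS) and set(best) & set(GLOBAL_METRICS):
                mixed += 1
        assert mixed >= 14
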