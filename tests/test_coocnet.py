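"""Ensemble co-occurrence network: metrics, candidates, significance,
p-value merging, FDR and degree bookkeeping."""

import math

import numpy as np
import pytest

from polarfunc.coocnet import (
    EdgeRecord,
    NodeAttribution,
    association_scores,
    attribute_nodes,
    bh_correct,
    candidate_edges,
    edge_significance,
    filter_nodes,
    infer_network,
    merge_pvalues,
    metric_matrices,
    mi_bins,
    relative_abundance,
    summarize_network,
)
from polarfunc.synthetic import CommunitySpec, generate_null_table, generate_zotu_table
from polarfunc.zotu_io import ZotuTable, parse_taxonomy


def make_table(counts, samples=None) -> ZotuTable:
    counts = np.asarray(counts)
    ids = [f"Z{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return ZotuTable(
        zotu_ids=ids,
        sample_ids=samples,
        counts=counts,
        taxonomy={z: parse_taxonomy("Bacteria;X") for z in ids},
    )


class TestFilterAndAttribution:
    def test_min_total_is_strict(self):
        table = make_table([[5, 5], [6, 5], [0, 1]])
        out = filter_nodes(table, min_total=10)
        assert out.zotu_ids == ["Z1"]  # total 10 removed, 11 kept

    def test_min_total_zero_keeps_any_read(self):
        table = make_table([[0, 1], [0, 0]])
        out = filter_nodes(table, min_total=0)
        assert out.zotu_ids == ["Z0"]

    @pytest.mark.parametrize(
        "reads,expected_lake,expected_frac",
        [
            ((95, 3, 2), "s0", 0.95),
            ((40, 35, 25), "N.A.", 0.40),
            ((80, 15, 5), "N.A.", 0.80),  # (0.70, 0.90] still N.A.
            ((91, 9, 0), "s0", 0.91),
        ],
    )
    def test_lake_attribution_thresholds(self, reads, expected_lake, expected_frac):
        table = make_table([list(reads)])
        (attr,) = attribute_nodes(table)
        assert attr.lake == expected_lake
        assert attr.specificity_fraction == pytest.approx(expected_frac)

    def test_samples_summed_per_lake(self):
        table = make_table([[50, 45, 5]], samples=["a1", "a2", "b1"])
        (attr,) = attribute_nodes(
            table, lake_of={"a1": "A", "a2": "A", "b1": "B"}
        )
        assert attr.lake == "A"
        assert attr.specificity_fraction == pytest.approx(0.95)

    def test_zero_read_zotu_errors(self):
        table = make_table([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="zero reads"):
            attribute_nodes(table)


# -- independent per-formula oracles ----------------------------------------

def oracle_pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def oracle_spearman(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    return oracle_pearson(ranks(x), ranks(y))


def oracle_bray_curtis(x, y):
    return sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))


def oracle_kl_sym(x, y, pseudocount):
    a = [v + pseudocount for v in x]
    b = [v + pseudocount for v in y]
    a = [v / sum(a) for v in a]
    b = [v / sum(b) for v in b]
    kl_ab = sum(p * math.log(p / q) for p, q in zip(a, b))
    kl_ba = sum(q * math.log(q / p) for p, q in zip(a, b))
    return 0.5 * (kl_ab + kl_ba)


def oracle_mutual_information(x, y, bins):
    def digitize(v):
        order = sorted(range(len(v)), key=lambda i: (v[i], i))
        rank = [0] * len(v)
        for pos, i in enumerate(order):
            rank[i] = pos
        return [r * bins // len(v) for r in rank]

    dx, dy = digitize(x), digitize(y)
    n = len(x)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            joint = sum(1 for i in range(n) if dx[i] == a and dy[i] == b) / n
            px = sum(1 for i in range(n) if dx[i] == a) / n
            py = sum(1 for i in range(n) if dy[i] == b) / n
            if joint > 0:
                mi += joint * math.log(joint / (px * py))
    return mi


class TestAssociationScores:
    def test_identical_vectors(self):
        rel = relative_abundance(
            np.array([[10, 20, 30, 40], [10, 20, 30, 40], [80, 60, 40, 20]])
        )
        mats = metric_matrices(rel)
        assert mats["pearson"][0, 1] == pytest.approx(1.0)
        assert mats["spearman"][0, 1] == pytest.approx(1.0)
        assert mats["bray_curtis"][0, 1] == pytest.approx(0.0)
        assert mats["kullback_leibler"][0, 1] == pytest.approx(0.0)

    def test_anti_ranked_vectors(self):
        rel = relative_abundance(
            np.array([[1, 2, 3, 4], [4, 3, 2, 1], [2, 2, 2, 2]])
        )
        mats = metric_matrices(rel)
        assert mats["spearman"][0, 1] == pytest.approx(-1.0)

    def test_constant_vector_scores_missing(self):
        counts = np.array([[5, 5, 5, 5], [1, 2, 3, 4], [4, 3, 2, 1]])
        rel = counts / counts.sum(axis=0)  # row 0 constant in rel? no: normalise
        rel = np.vstack([np.full(4, 0.25), rel[1] / 4, rel[2] / 4])
        mats = metric_matrices(rel)
        assert np.isnan(mats["pearson"][0, 1])
        assert np.isfinite(mats["bray_curtis"][0, 1])

    def test_all_metrics_match_brute_force(self):
        """Every metric matrix entry equals an independent plain-Python
        evaluation of its defining formula."""
        rng = np.random.default_rng(31)
        counts = rng.integers(1, 200, size=(4, 6)).astype(float)
        rel = relative_abundance(counts)
        bins = mi_bins(6)
        mats = metric_matrices(rel)
        pseudocount = 0.5 * rel[rel > 0].min()
        for i in range(4):
            for j in range(i + 1, 4):
                x, y = rel[i].tolist(), rel[j].tolist()
                assert mats["pearson"][i, j] == pytest.approx(oracle_pearson(x, y))
                assert mats["spearman"][i, j] == pytest.approx(oracle_spearman(x, y))
                assert mats["bray_curtis"][i, j] == pytest.approx(
                    oracle_bray_curtis(x, y)
                )
                assert mats["kullback_leibler"][i, j] == pytest.approx(
                    oracle_kl_sym(x, y, pseudocount)
                )
                assert mats["mutual_information"][i, j] == pytest.approx(
                    oracle_mutual_information(x, y, bins)
                )

    def test_matrices_symmetric_and_bounded(self):
        rng = np.random.default_rng(8)
        rel = relative_abundance(rng.integers(0, 50, size=(6, 8)) + 1)
        mats = metric_matrices(rel)
        for name, m in mats.items():
            assert np.allclose(m, m.T, equal_nan=True), name
        assert (np.abs(mats["pearson"]) <= 1 + 1e-12).all()
        assert ((mats["bray_curtis"] >= 0) & (mats["bray_curtis"] <= 1)).all()
        assert (mats["mutual_information"] >= 0).all()
        assert (mats["kullback_leibler"] >= 0).all()


class TestCandidateEdges:
    def test_three_nodes_k1(self):
        rel = relative_abundance(
            np.array([[10, 20, 30, 40], [11, 19, 31, 39], [40, 30, 20, 10]])
        )
        scores = association_scores(rel, ["a", "b", "c"])
        edges = candidate_edges(scores, k=1)
        pairs = {e.pair for e in edges}
        assert ("a", "b") in pairs  # strongest co-occurrence
        ab = next(e for e in edges if e.pair == ("a", "b"))
        assert ab.directions["pearson"] == 1

    def test_k_larger_than_pair_count_takes_all(self):
        rng = np.random.default_rng(2)
        rel = relative_abundance(rng.integers(1, 30, size=(4, 5)))
        scores = association_scores(rel)
        edges = candidate_edges(scores, k=100)
        assert len(edges) == 6  # all C(4,2) pairs

    def test_planted_pair_tops_every_metric(self):
        spec = CommunitySpec(
            n_lakes=1, zotus_per_lake=0, n_shared=10, samples_per_lake=12,
            depth_mean=5000, planted_edges=[((2, 7), "positive", 3.0)], seed=17,
        )
        table, _ = generate_zotu_table(spec)
        rel = relative_abundance(table.counts)
        scores = association_scores(rel, table.zotu_ids)
        edges = candidate_edges(scores, k=3)
        planted = next(
            e for e in edges if e.pair == ("Zotu0003", "Zotu0008")
        )
        # the scale-invariant metrics must all rank the planted pair top
        for metric in ("pearson", "spearman", "kullback_leibler"):
            assert planted.directions.get(metric) == 1, metric
        assert planted.consensus_sign() == "positive"
        # Bray-Curtis keeps the abundance offset between the two profiles,
        # so the pair ranks high but not necessarily first; a slightly wider
        # top set picks it up with the co-occurrence direction
        wider = candidate_edges(scores, k=5)
        planted = next(e for e in wider if e.pair == ("Zotu0003", "Zotu0008"))
        assert planted.directions.get("bray_curtis") == 1

    def test_mi_contributes_no_bottom_edges_by_default(self):
        rng = np.random.default_rng(4)
        rel = relative_abundance(rng.integers(1, 30, size=(6, 9)))
        edges = candidate_edges(association_scores(rel), k=2)
        assert all(
            e.directions.get("mutual_information", 1) == 1 for e in edges
        )


class TestEdgeSignificance:
    def test_planted_pair_significant(self):
        spec = CommunitySpec(
            n_lakes=1, zotus_per_lake=0, n_shared=12, samples_per_lake=20,
            depth_mean=2000, planted_edges=[((0, 1), "positive", 3.0)], seed=5,
        )
        table, _ = generate_zotu_table(spec)
        rel = relative_abundance(table.counts)
        scores = association_scores(rel, table.zotu_ids)
        edges = candidate_edges(scores, k=2)
        edge_significance(table.counts, table.zotu_ids, edges, n_iter=100, seed=9)
        planted = next(e for e in edges if e.pair == ("Zotu0001", "Zotu0002"))
        assert planted.p_values["pearson"] < 0.05

    def test_determinism(self):
        table = generate_null_table(8, 10, 1000, seed=3)
        rel = relative_abundance(table.counts)
        scores = association_scores(rel, table.zotu_ids)

        def run():
            edges = candidate_edges(scores, k=3)
            edge_significance(
                table.counts, table.zotu_ids, edges, n_iter=50, seed=21
            )
            return {(e.pair, m): p for e in edges for m, p in e.p_values.items()}

        assert run() == run()

    def test_pvalues_clamped_positive(self):
        spec = CommunitySpec(
            n_lakes=1, zotus_per_lake=0, n_shared=6, samples_per_lake=30,
            depth_mean=5000, planted_edges=[((0, 1), "positive", 4.0)], seed=2,
        )
        table, _ = generate_zotu_table(spec)
        rel = relative_abundance(table.counts)
        edges = candidate_edges(association_scores(rel, table.zotu_ids), k=1)
        edge_significance(table.counts, table.zotu_ids, edges, n_iter=50, seed=4)
        for e in edges:
            for p in e.p_values.values():
                assert 1 / 51 <= p <= 1.0

    def test_small_n_iter_rejected(self):
        table = generate_null_table(5, 8, 500, seed=0)
        rel = relative_abundance(table.counts)
        edges = candidate_edges(association_scores(rel, table.zotu_ids), k=1)
        with pytest.raises(ValueError, match="n_iter"):
            edge_significance(table.counts, table.zotu_ids, edges, n_iter=5, seed=0)


class TestMergePvalues:
    def test_fisher_limit_closed_form(self):
        """With zero covariance Brown reduces to Fisher: psi = -2 ln(0.01^2)
        = 18.42 referred to chi2(4) gives ~1.0e-3."""
        merged = merge_pvalues([0.01, 0.01], null_scores=None)
        from scipy.stats import chi2

        psi = -2 * (math.log(0.01) + math.log(0.01))
        assert psi == pytest.approx(18.42, abs=0.01)
        assert merged == pytest.approx(chi2.sf(psi, 4))
        assert merged == pytest.approx(1.03e-3, rel=0.02)

    def test_duplicate_metrics_collapse_to_single(self):
        """Perfectly dependent replicates of one metric must not gain
        significance: merged p ~= the single-metric p."""
        rng = np.random.default_rng(14)
        null = rng.standard_normal(200)
        dup = np.stack([null, null, null])
        p = 0.03
        merged = merge_pvalues([p, p, p], null_scores=dup)
        assert merged == pytest.approx(p, rel=0.05)

    def test_single_p_identity(self):
        assert merge_pvalues([0.2], null_scores=None) == pytest.approx(0.2)

    def test_zero_p_clamped(self):
        rng = np.random.default_rng(1)
        nulls = rng.standard_normal((2, 100))
        merged = merge_pvalues([0.0, 0.01], null_scores=nulls)
        assert 0.0 < merged < 1.0

    def test_independent_nulls_near_fisher(self):
        rng = np.random.default_rng(6)
        nulls = rng.standard_normal((2, 5000))
        merged = merge_pvalues([0.02, 0.04], null_scores=nulls)
        fisher = merge_pvalues([0.02, 0.04], null_scores=None)
        assert merged == pytest.approx(fisher, rel=0.25)


class TestBhCorrect:
    def bh_oracle(self, pvals, q):
        """Plain step-up rule: largest i with p_(i) <= i q / m."""
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        cutoff = -1
        for rank, i in enumerate(order, start=1):
            if pvals[i] <= rank * q / m:
                cutoff = rank
        kept = set(order[:cutoff]) if cutoff > 0 else set()
        return np.array([i in kept for i in range(m)])

    @pytest.mark.parametrize(
        "pvals",
        [
            [0.01, 0.02, 0.04],  # all three kept at q=0.05
            [1.0, 1.0, 1.0],  # none kept
            [0.04],  # single p kept
            [0.001, 0.02, 0.03, 0.9, 0.04, 0.6],
        ],
    )
    def test_matches_step_up_oracle(self, pvals):
        kept, q = bh_correct(pvals, q_threshold=0.05)
        assert np.array_equal(kept, self.bh_oracle(pvals, 0.05))
        assert ((q >= 0) & (q <= 1)).all()

    def test_out_of_range_p_errors(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.5])


class TestSummarize:
    def attr(self, zotu, lake):
        return NodeAttribution(zotu_id=zotu, lake=lake, specificity_fraction=0.95)

    def edge(self, a, b, direction):
        return EdgeRecord(
            zotu_a=a, zotu_b=b, directions={"pearson": direction}
        )

    def test_positive_edge_counts_both_endpoints(self):
        summary = summarize_network(
            [self.edge("x", "y", 1)],
            [self.attr("x", "A"), self.attr("y", "A")],
        )
        assert summary.positive_degree["A"] == 2
        assert summary.n_edges == 1

    def test_conflicting_edge_dropped_and_counted(self):
        e = EdgeRecord(
            zotu_a="x", zotu_b="y",
            directions={"pearson": 1, "bray_curtis": -1},
        )
        summary = summarize_network(
            [e], [self.attr("x", "A"), self.attr("y", "B")]
        )
        assert summary.n_conflicts == 1
        assert summary.n_edges == 0
        assert summary.degree_total() == 0

    def test_degree_total_is_twice_edge_count(self):
        edges = [
            self.edge("a", "b", 1),
            self.edge("b", "c", -1),
            self.edge("a", "c", 1),
        ]
        attrs = [self.attr(z, lake) for z, lake in
                 [("a", "A"), ("b", "B"), ("c", "N.A.")]]
        summary = summarize_network(edges, attrs)
        assert summary.degree_total() == 2 * summary.n_edges == 6

    def test_missing_attribution_errors(self):
        with pytest.raises(ValueError, match="no attribution"):
            summarize_network([self.edge("x", "y", 1)], [self.attr("x", "A")])


class TestInferNetwork:
    def test_full_run_deterministic(self):
        spec = CommunitySpec(
            n_lakes=3, zotus_per_lake=4, n_shared=3, samples_per_lake=3,
            depth_mean=1500, planted_edges=[((0, 1), "positive", 2.5)], seed=12,
        )
        table, truth = generate_zotu_table(spec)

        def run():
            res = infer_network(
                table, lake_of=truth["lake_of_sample"], min_total=10,
                k=4, n_iter=40, seed=77,
            )
            return [(e.pair, e.sign, e.merged_p, e.q) for e in res.accepted]

        assert run() == run()

    def test_degree_invariant_and_graph_consistency(self):
        spec = CommunitySpec(
            n_lakes=3, zotus_per_lake=5, n_shared=2, samples_per_lake=3,
            depth_mean=2000,
            planted_edges=[((0, 1), "positive", 3.0), ((5, 6), "positive", 3.0)],
            seed=6,
        )
        table, truth = generate_zotu_table(spec)
        res = infer_network(
            table, lake_of=truth["lake_of_sample"], min_total=10,
            k=5, n_iter=60, seed=13,
        )
        assert res.summary.degree_total() == 2 * res.summary.n_edges
        assert res.graph.number_of_edges() == res.summary.n_edges
        for _, _, data in res.graph.edges(data=True):
            assert data["sign"] in ("positive", "negative")
            assert data["q"] <= 0.05
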