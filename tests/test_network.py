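"""Network stage: filtering, merging, correlations, edges, graph statistics."""

import io
import itertools

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mecnet.counts import CountTable
from mecnet.network import (
    build_network,
    cophenetic_distances,
    edge_density,
    filter_asvs,
    merge_close_asvs,
    network_properties,
    sign_percentages,
    sparcc,
    sparcc_pvalues,
    spearman_matrix,
)
from mecnet.synthetic import (
    CommunityParams,
    planted_covariance,
    simulate_count_tables,
    simulate_tree,
)


class TestFilterAsvs:
    def test_toy_rule_by_hand(self, toy_table):
        kept = filter_asvs(toy_table, min_samples=2, min_relabund=0.001)
        assert set(kept.asv_ids) == {"ASV_b", "ASV_d"}

    def test_idempotent(self, toy_table):
        once = filter_asvs(toy_table)
        twice = filter_asvs(once)
        assert once.counts.equals(twice.counts)

    def test_matches_bruteforce_predicates(self, random_table):
        kept = set(filter_asvs(random_table, 2, 0.001).asv_ids)
        rel = random_table.relative_abundances()
        expected = {
            a
            for a in random_table.asv_ids
            if (random_table.counts[a] > 0).sum() >= 2 and (rel[a] > 0.001).any()
        }
        assert kept == expected

    def test_sample_set_unchanged(self, toy_table):
        assert filter_asvs(toy_table).sample_ids == toy_table.sample_ids

    def test_all_removed_warns_but_returns(self, toy_table):
        with pytest.warns(UserWarning, match="all ASVs removed"):
            out = filter_asvs(toy_table, min_samples=4)
        assert out.n_asvs == 0


class TestCophenetic:
    def test_two_tip_tree_path_sum(self):
        d = cophenetic_distances("(A:0.1,B:0.2);")
        assert d.loc["A", "B"] == pytest.approx(0.3)
        assert d.loc["A", "A"] == 0.0

    def test_matches_graph_path_oracle(self):
        nwk = simulate_tree(10, seed=17)
        d = cophenetic_distances(nwk)
        tree = dendropy.Tree.get(file=io.StringIO(nwk), schema="newick")
        g = nx.Graph()
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None and edge.length is not None:
                g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length)
        tips = {lf.taxon.label: id(lf) for lf in tree.leaf_node_iter()}
        for a, b in itertools.combinations(tips, 2):
            ref = nx.shortest_path_length(g, tips[a], tips[b], weight="weight")
            assert d.loc[a, b] == pytest.approx(ref)

    def test_missing_tips_reported(self):
        with pytest.raises(ValueError, match="ASVX"):
            cophenetic_distances("(A:0.1,B:0.2);", asv_ids=["A", "ASVX"])


def _table(columns: dict, samples=None) -> CountTable:
    df = pd.DataFrame(columns)
    df.index = samples or [f"s{i}" for i in range(len(df))]
    return CountTable(df)


class TestMergeCloseAsvs:
    @staticmethod
    def _dist(ids, pairs):
        d = pd.DataFrame(1.0, index=ids, columns=ids)
        for i in ids:
            d.loc[i, i] = 0.0
        for a, b, val in pairs:
            d.loc[a, b] = d.loc[b, a] = val
        return d

    def test_pair_within_epsilon_merges_and_sums(self):
        table = _table({"A": [10, 0], "B": [5, 7], "C": [1, 1]})
        d = self._dist(["A", "B", "C"], [("A", "B", 0.002)])
        merged, mapping = merge_close_asvs(table, d, epsilon=0.004)
        assert merged.n_asvs == 2
        rep = next(iter(mapping))
        assert mapping[rep] == ["A", "B"]
        assert merged.counts[rep].tolist() == [15, 7]

    def test_zero_epsilon_is_identity(self):
        table = _table({"A": [10, 0], "B": [5, 7]})
        d = self._dist(["A", "B"], [("A", "B", 0.0)])
        merged, mapping = merge_close_asvs(table, d, epsilon=0.0)
        assert merged.counts.equals(table.counts)
        assert mapping == {}

    def test_single_linkage_chain_with_unionfind_oracle(self, rng):
        ids = [f"A{i}" for i in range(6)]
        # chain a-b <= eps, b-c <= eps, a-c > eps: all three merge
        pairs = [("A0", "A1", 0.003), ("A1", "A2", 0.003), ("A0", "A2", 0.01)]
        d = self._dist(ids, pairs)
        counts = {i: rng.integers(0, 20, 4) for i in ids}
        table = _table(counts)
        merged, mapping = merge_close_asvs(table, d, epsilon=0.004)

        # union-find oracle
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a in ids:
            for b in ids:
                if a < b and d.loc[a, b] <= 0.004:
                    parent[find(a)] = find(b)
        clusters = {}
        for i in ids:
            clusters.setdefault(find(i), set()).add(i)
        expected_sizes = sorted(len(c) for c in clusters.values())
        got_sizes = sorted(
            len(mapping.get(a, [a])) for a in merged.asv_ids
        )
        assert got_sizes == expected_sizes
        assert (merged.counts.sum(axis=1) == table.counts.sum(axis=1)).all()

    def test_representative_is_most_abundant_member(self):
        table = _table({"A": [1, 1], "B": [50, 50], "C": [2, 2]})
        d = self._dist(["A", "B", "C"], [("A", "B", 0.001)])
        merged, mapping = merge_close_asvs(table, d, epsilon=0.004)
        assert "B" in mapping and set(mapping["B"]) == {"A", "B"}

    def test_negative_epsilon_rejected(self):
        table = _table({"A": [1], "B": [1]}, samples=["s0"])
        with pytest.raises(ValueError):
            merge_close_asvs(table, self._dist(["A", "B"], []), epsilon=-1)


class TestSpearman:
    def test_monotone_and_antimonotone(self):
        # constant per-sample totals so relative abundances preserve ranks
        table = _table({
            "up": [1, 2, 3, 4, 5],
            "up2": [10, 20, 30, 40, 50],
            "down": [5, 4, 3, 2, 1],
            "filler": [44, 34, 24, 14, 4],
        })
        rho, p = spearman_matrix(table)
        assert rho.loc["up", "up2"] == pytest.approx(1.0)
        assert rho.loc["up", "down"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        counts = rng.integers(0, 5, size=(8, 5))  # many ties
        table = CountTable(pd.DataFrame(counts, columns=list("abcde")))
        rho, _ = spearman_matrix(table)
        rel = table.relative_abundances()
        for x, y in itertools.combinations("abcde", 2):
            rx = stats.rankdata(rel[x])
            ry = stats.rankdata(rel[y])
            ref = np.corrcoef(rx, ry)[0, 1]
            if np.isnan(ref):
                assert np.isnan(rho.loc[x, y])
            else:
                assert rho.loc[x, y] == pytest.approx(ref)

    def test_constant_column_flagged_not_zero(self):
        # equal per-sample totals so the 'const' column stays constant as a
        # proportion too
        table = _table({
            "const": [10, 10, 10, 10, 10],
            "a": [1, 2, 3, 4, 5],
            "b": [5, 4, 3, 2, 1],
            "c": [4, 4, 4, 4, 4],
        })
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(table)
        assert np.isnan(rho.loc["const", "a"])


class TestSparcc:
    def test_output_shape_and_bounds(self, rng):
        params = CommunityParams(n_samples=30, n_asvs=10, library_size=5000, seed=21)
        table, _ = simulate_count_tables(params)
        r = sparcc(table, seed=0)
        arr = r.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 1.0)
        assert (np.abs(arr) <= 1.0 + 1e-12).all()

    def test_null_independent_data_small_correlations(self):
        params = CommunityParams(n_samples=500, n_asvs=30, library_size=20000, seed=11)
        table, _ = simulate_count_tables(params)
        r = sparcc(table, seed=1).to_numpy()
        np.fill_diagonal(r, 0)
        assert np.abs(r).max() < 0.3

    def test_recovers_planted_positive_pair(self):
        cov = planted_covariance(30, [(0, 1, 0.8)])
        params = CommunityParams(
            n_samples=500, n_asvs=30, library_size=20000,
            planted_covariance=cov, seed=12,
        )
        table, _ = simulate_count_tables(params)
        r = sparcc(table, seed=2)
        assert r.iloc[0, 1] == pytest.approx(0.8, abs=0.15)

    def test_sample_order_invariance_to_tolerance(self, rng):
        cov = planted_covariance(20, [(0, 1, 0.8), (2, 3, -0.8)])
        params = CommunityParams(
            n_samples=150, n_asvs=20, library_size=20000,
            planted_covariance=cov, seed=31,
        )
        table, _ = simulate_count_tables(params)
        perm = rng.permutation(table.n_samples)
        shuffled = table.subset_samples([table.sample_ids[k] for k in perm])
        r1 = sparcc(table, seed=5).to_numpy()
        r2 = sparcc(shuffled, seed=6).to_numpy()
        assert np.abs(r1 - r2).max() < 0.15

    def test_too_few_asvs_rejected(self):
        table = _table({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1], "c": [1, 1, 2, 2]})
        with pytest.raises(ValueError, match="underdetermined"):
            sparcc(table)


class TestSparccPvalues:
    def test_bounds_and_planted_pair_at_minimum(self):
        cov = planted_covariance(12, [(0, 1, 0.9)])
        params = CommunityParams(
            n_samples=80, n_asvs=12, library_size=10000,
            planted_covariance=cov, seed=41,
        )
        table, _ = simulate_count_tables(params)
        r = sparcc(table, seed=1)
        p = sparcc_pvalues(table, r, n_bootstraps=19, seed=2)
        arr = p.to_numpy()
        assert (arr > 0).all() and (arr <= 1).all()
        assert p.iloc[0, 1] == pytest.approx(1 / 20)

    def test_invalid_bootstraps_rejected(self, random_table):
        r = sparcc(random_table, seed=0)
        with pytest.raises(ValueError):
            sparcc_pvalues(random_table, r, n_bootstraps=0)


def _pair_frames(entries, ids):
    rho = pd.DataFrame(0.0, index=ids, columns=ids)
    rho_p = pd.DataFrame(1.0, index=ids, columns=ids)
    r = pd.DataFrame(0.0, index=ids, columns=ids)
    r_p = pd.DataFrame(1.0, index=ids, columns=ids)
    for (i, j), (rh, rhp, rr, rrp) in entries.items():
        rho.loc[i, j] = rho.loc[j, i] = rh
        rho_p.loc[i, j] = rho_p.loc[j, i] = rhp
        r.loc[i, j] = r.loc[j, i] = rr
        r_p.loc[i, j] = r_p.loc[j, i] = rrp
    return rho, rho_p, r, r_p


class TestBuildNetwork:
    ids = ["x", "y", "z"]

    def test_all_criteria_met_positive_edge(self):
        frames = _pair_frames({("x", "y"): (0.9, 0.001, 0.8, 0.01)}, self.ids)
        g = build_network(*frames)
        assert g.has_edge("x", "y")
        assert g["x"]["y"]["sign"] == 1
        assert g["x"]["y"]["weight"] == pytest.approx(0.8)

    def test_sparcc_magnitude_failure_blocks_edge(self):
        frames = _pair_frames({("x", "y"): (0.9, 0.001, 0.4, 0.01)}, self.ids)
        assert build_network(*frames).number_of_edges() == 0

    def test_sign_conflict_blocks_edge(self):
        frames = _pair_frames({("x", "y"): (0.7, 0.01, -0.7, 0.01)}, self.ids)
        assert build_network(*frames).number_of_edges() == 0

    def test_isolated_nodes_dropped(self):
        frames = _pair_frames({("x", "y"): (0.9, 0.001, 0.8, 0.01)}, self.ids)
        g = build_network(*frames)
        assert set(g.nodes) == {"x", "y"}

    def test_invalid_threshold_rejected(self):
        frames = _pair_frames({}, self.ids)
        with pytest.raises(ValueError):
            build_network(*frames, threshold=1.5)


class TestNetworkProperties:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], sign=1)
        props = network_properties(g)
        assert props.n_modules == 2
        assert props.modularity == pytest.approx(0.5)
        assert props.clustering == pytest.approx(1.0)
        assert props.edge_density == pytest.approx(2 * 6 / (6 * 5))

    def test_sign_percentages_sum_to_100(self):
        g = nx.Graph()
        g.add_edge(0, 1, sign=1)
        g.add_edge(1, 2, sign=-1)
        g.add_edge(2, 3, sign=-1)
        props = network_properties(g)
        assert props.positive_pct + props.negative_pct == 100.0
        assert props.positive_edges == 1 and props.negative_edges == 2

    def test_greedy_partition_not_worse_than_random_partitions(self, rng):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (3, 5)])
        props = network_properties(g)
        for _ in range(50):
            labels = rng.integers(0, 2, 6)
            parts = [
                {n for n in g.nodes if labels[n] == k}
                for k in range(2)
                if (labels == k).any()
            ]
            q_rand = nx.community.modularity(g, parts)
            assert props.modularity >= q_rand - 1e-9

    def test_clustering_matches_hand_computation(self):
        # square with one diagonal: local coefficients 2/3, 1, 2/3, 1
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        props = network_properties(g)
        assert props.clustering == pytest.approx((2 / 3 + 1 + 2 / 3 + 1) / 4)

    def test_empty_network_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty"):
            props = network_properties(nx.Graph())
        assert props.n_nodes == 0 and props.edge_density == 0.0

    def test_density_and_percentage_helpers(self):
        assert edge_density(133, 337) == pytest.approx(0.038, abs=5e-4)
        pos, neg = sign_percentages(236, 101)
        assert pos + neg == 100.0
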