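import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import all_segmentations, best_segmentation
from netseg.data_io import ExpressionMatrix
from netseg.multseg import (
    PairTable,
    PenaltyConfig,
    bp_penalty_count,
    bp_penalty_length,
    build_dag,
    enumerate_pairs,
    lambda_bounds,
    max_weight_min_length_path,
    pair_weight_table,
    penalized_path,
    sweep,
)


def table(T, L_min, weights):
    return PairTable(T=T, L_min=L_min, weights=weights)


def random_table(rng, T, L_min=1):
    return table(T, L_min, {t: float(rng.random()) for t in enumerate_pairs(T, L_min)})


def brute_pairs(T, L_min):
    out = []
    for a in range(1, T + 1):
        for i in range(a, T):
            for b in range(i + 1, T + 1):
                if i - a + 1 >= L_min and b - i >= L_min:
                    out.append((a, i, b))
    return sorted(out)


class TestEnumeratePairs:
    def test_known_counts(self):
        assert len(enumerate_pairs(25, 1)) == 2600
        assert enumerate_pairs(2, 1) == [(1, 1, 2)]
        assert len(enumerate_pairs(6, 2)) == 10

    @pytest.mark.parametrize("T", range(2, 13))
    def test_closed_form_and_brute_force(self, T):
        pairs = enumerate_pairs(T, 1)
        assert pairs == brute_pairs(T, 1)
        assert len(pairs) == T * (T * T - 1) // 6

    @pytest.mark.parametrize("T,L", [(7, 2), (9, 3), (10, 4)])
    def test_brute_force_with_min_length(self, T, L):
        assert enumerate_pairs(T, L) == brute_pairs(T, L)

    def test_sorted_and_unique(self):
        pairs = enumerate_pairs(9, 2)
        assert pairs == sorted(set(pairs))

    def test_no_admissible_pair_errors(self):
        with pytest.raises(ValueError, match="no segment pair"):
            enumerate_pairs(5, 3)


class TestPairTable:
    def test_missing_triple_rejected(self):
        weights = {t: 1.0 for t in enumerate_pairs(4, 1)}
        weights.pop((1, 2, 4))
        with pytest.raises(ValueError, match="missing"):
            table(4, 1, weights)

    def test_invalid_weight_rejected(self):
        weights = {t: 1.0 for t in enumerate_pairs(3, 1)}
        weights[(1, 1, 2)] = -0.5
        with pytest.raises(ValueError, match="invalid weight"):
            table(3, 1, weights)

    def test_tsv_roundtrip(self, tmp_path, rng):
        pt = random_table(rng, 6)
        path = tmp_path / "pairs.tsv"
        pt.to_tsv(path)
        back = PairTable.from_tsv(path, T=6, L_min=1)
        assert back.weights == pt.weights

    def test_size_matches_enumeration(self, rng):
        pt = random_table(rng, 7, 2)
        assert len(pt) == len(enumerate_pairs(7, 2))


class TestPairWeightTable:
    def make_matrix(self, rng, n=5, T=6):
        return ExpressionMatrix(
            [f"g{i}" for i in range(n)],
            [f"t{j}" for j in range(T)],
            rng.normal(size=(n, T)),
        )

    def test_identical_edge_sets_give_zero(self):
        # two constant-correlation profiles: every segment yields the same
        # complete graph, so all pair distances vanish
        values = np.vstack([np.arange(6.0), np.arange(6.0) * 2 + 1])
        m = ExpressionMatrix(["a", "b"], [f"t{j}" for j in range(6)], values)
        pt = pair_weight_table(m, L_min=2, thresholds=0.5)
        assert all(v == 0.0 for v in pt.weights.values())

    def test_matches_per_pair_hand_evaluation(self, rng):
        from netseg.graph_metrics import global_sd_distance
        from netseg.netrecon import Segment, build_segment_network

        m = self.make_matrix(rng)
        pt = pair_weight_table(m, L_min=2, thresholds=0.6)
        for (a, i, b), d in pt.weights.items():
            g1 = build_segment_network(m, Segment(a, i), tau=0.6)
            g2 = build_segment_network(m, Segment(i + 1, b), tau=0.6)
            assert d == pytest.approx(global_sd_distance(g1, g2))

    def test_lp_route_matches_property_vectors(self, rng):
        from netseg.graph_metrics import degree_vector, lp_property_distance
        from netseg.netrecon import Segment, build_segment_network

        m = self.make_matrix(rng)
        pt = pair_weight_table(
            m, L_min=2, property="degree", distance="lp", p=1, thresholds=0.6
        )
        for (a, i, b), d in pt.weights.items():
            g1 = build_segment_network(m, Segment(a, i), tau=0.6)
            g2 = build_segment_network(m, Segment(i + 1, b), tau=0.6)
            assert d == pytest.approx(
                lp_property_distance(degree_vector(g1), degree_vector(g2), p=1)
            )

    def test_invalid_combinations_error(self, rng):
        m = self.make_matrix(rng)
        with pytest.raises(ValueError, match="global distance"):
            pair_weight_table(m, L_min=2, property="degree", distance="global")
        with pytest.raises(ValueError, match="lp distance"):
            pair_weight_table(
                m, L_min=2, property="relative_density", distance="lp"
            )


def dag_paths(dag):
    """All s-t paths as breakpoint tuples, by DFS over the successor lists."""
    paths = []

    def walk(j, bps):
        bps = bps + (dag.nodes[j][1],)
        if dag.terminal[j]:
            paths.append(bps)
        for v in dag.succs[j]:
            walk(v, bps)

    for j in dag.firsts:
        walk(j, ())
    return paths


class TestSegDAG:
    def test_node_count_at_T25(self):
        pt = table(25, 1, {t: 1.0 for t in enumerate_pairs(25, 1)})
        assert build_dag(pt).node_count == 2602

    def test_three_paths_at_T3(self, rng):
        dag = build_dag(random_table(rng, 3))
        assert sorted(dag_paths(dag)) == [(1,), (1, 2), (2,)]

    def test_paths_biject_with_segmentations(self, rng):
        for T in range(2, 8):
            for L in (1, 2):
                if T < 2 * L:
                    continue
                dag = build_dag(random_table(rng, T, L))
                assert sorted(dag_paths(dag)) == sorted(all_segmentations(T, L))

    def test_edges_respect_topological_order(self, rng):
        dag = build_dag(random_table(rng, 6))
        for u, vs in enumerate(dag.succs):
            for v in vs:
                assert dag.nodes[v][2] > dag.nodes[u][2]  # right end grows

    def test_path_weight_equals_sum_of_pair_weights(self, rng):
        # edge-weight placement: every s-t path weight is the sum of d over
        # its pair nodes
        pt = random_table(rng, 5)
        dag = build_dag(pt)
        edges = {(str(u), str(v)): w for u, v, w in dag.edge_list()}
        for bps in dag_paths(dag):
            nodes = path_nodes(bps, 5)
            hop_weight = sum(
                edges[(str(u), str(v))]
                for u, v in zip(["s", *nodes], [*nodes, "t"])
            )
            assert hop_weight == pytest.approx(
                sum(pt.weights[n] for n in nodes)
            )


def path_nodes(bps, T):
    cuts = [*bps, T]
    nodes = []
    prev_start = 1
    for j in range(len(cuts) - 1):
        nodes.append((prev_start, cuts[j], cuts[j + 1]))
        prev_start = cuts[j] + 1
    return nodes


class TestUnpenalizedDP:
    def test_equal_weights_prefer_finest(self):
        pt = table(4, 1, {t: 1.0 for t in enumerate_pairs(4, 1)})
        res = max_weight_min_length_path(build_dag(pt))
        assert res.breakpoints == (1, 2, 3)
        assert res.n_segments == 4
        assert res.objective == 3.0

    def test_single_pair_instance(self):
        pt = table(2, 1, {(1, 1, 2): 0.7})
        res = max_weight_min_length_path(build_dag(pt))
        assert res.n_segments == 2 and res.objective == 0.7

    def test_tie_broken_to_fewest_segments(self):
        # a single heavy pair equals the total of the finest path: the
        # two-segment solution must win the tie
        weights = {t: 0.0 for t in enumerate_pairs(3, 1)}
        weights[(1, 1, 3)] = 1.0
        weights[(1, 1, 2)] = 0.5
        weights[(1, 2, 3)] = 0.5  # path (1|2|3) also sums to 1.0
        res = max_weight_min_length_path(build_dag(table(3, 1, weights)))
        assert res.breakpoints == (1,)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(100):
            T = int(rng.integers(2, 8))
            pt = random_table(rng, T)
            res = max_weight_min_length_path(build_dag(pt))
            score, k, bps, F = best_segmentation(pt.weights, T, 1)
            assert res.breakpoints == bps
            assert res.objective == pytest.approx(F)
            assert res.n_segments == k

    def test_objective_identity(self, rng):
        pt = random_table(rng, 7)
        res = max_weight_min_length_path(build_dag(pt))
        assert res.objective == pytest.approx(pt.path_objective(res.breakpoints))


class TestPenalties:
    def test_zero_lambda_is_free(self):
        assert bp_penalty_count(3, 35, 0.0) == 0.0
        assert bp_penalty_length(4, 0.0) == 0.0

    def test_count_penalty_monotone_in_depth(self):
        vals = [bp_penalty_count(d, 35, 1.3) for d in range(1, 36)]
        assert all(v1 < v2 for v1, v2 in zip(vals, vals[1:]))

    def test_count_penalty_value(self):
        assert bp_penalty_count(1, 35, 1.0) == pytest.approx(1 / 35)

    def test_length_penalty_reciprocal(self):
        assert bp_penalty_length(4, 1.0) == pytest.approx(0.25)
        vals = [bp_penalty_length(l, 2.0) for l in range(1, 10)]
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            bp_penalty_count(0, 35, 1.0)
        with pytest.raises(ValueError):
            bp_penalty_count(2, 35, -1.0)
        with pytest.raises(ValueError):
            bp_penalty_length(0, 1.0)


class TestPenalizedDP:
    def test_zero_lambda_equals_unpenalized(self, rng):
        for _ in range(10):
            T = int(rng.integers(3, 8))
            dag = build_dag(random_table(rng, T))
            plain = max_weight_min_length_path(dag)
            for crit in ("count", "length"):
                pen = penalized_path(dag, PenaltyConfig(criterion=crit, lam=0.0))
                assert pen.breakpoints == plain.breakpoints
                assert pen.score == pytest.approx(plain.objective)

    @pytest.mark.parametrize("criterion", ["count", "length"])
    def test_matches_exhaustive_search(self, rng, criterion):
        for _ in range(100):
            T = int(rng.integers(3, 8))
            pt = random_table(rng, T)
            lam = float(rng.random() * 2)
            res = penalized_path(
                build_dag(pt), PenaltyConfig(criterion=criterion, lam=lam)
            )
            score, k, bps, F = best_segmentation(
                pt.weights, T, 1, lam=lam, criterion=criterion
            )
            assert res.breakpoints == bps
            assert res.score == pytest.approx(score)

    def test_penalty_bookkeeping(self, rng):
        pt = random_table(rng, 6)
        res = penalized_path(build_dag(pt), PenaltyConfig(criterion="count", lam=0.8))
        assert res.objective == pytest.approx(pt.path_objective(res.breakpoints))
        assert res.score == pytest.approx(res.objective - res.penalty_total)
        assert res.penalty_total >= 0.0


class TestLambdaBounds:
    def test_low_is_min_positive_high_is_path_weight(self, rng):
        pt = random_table(rng, 6)
        low, high = lambda_bounds(pt)
        assert low == min(v for v in pt.weights.values() if v > 0)
        assert high == pytest.approx(
            max_weight_min_length_path(build_dag(pt)).objective
        )

    def test_scaling_invariance(self, rng):
        pt = random_table(rng, 5)
        low, high = lambda_bounds(pt)
        scaled = table(5, 1, {t: 3.0 * v for t, v in pt.weights.items()})
        low3, high3 = lambda_bounds(scaled)
        assert low3 == pytest.approx(3 * low)
        assert high3 == pytest.approx(3 * high)

    def test_degenerate_all_zero_errors(self):
        pt = table(3, 1, {t: 0.0 for t in enumerate_pairs(3, 1)})
        with pytest.raises(ValueError, match="zero"):
            lambda_bounds(pt)


class TestSweep:
    def test_single_point_grid_runs_at_lower_bound(self, rng):
        pt = random_table(rng, 6)
        dag = build_dag(pt)
        res = sweep(dag, PenaltyConfig(criterion="count"), (0.2, 0.9), n_grid=1)
        assert len(res.per_lambda) == 1
        assert res.per_lambda[0].lam == 0.2
        direct = penalized_path(dag, PenaltyConfig(criterion="count", lam=0.2))
        assert res.breakpoints == direct.breakpoints

    def test_constant_solution_is_consensus(self, rng):
        pt = random_table(rng, 4)
        dag = build_dag(pt)
        res = sweep(dag, PenaltyConfig(criterion="count"), (1e-9, 2e-9), n_grid=5)
        assert res.meta["consensus_support"] == 5
        assert res.breakpoints == max_weight_min_length_path(dag).breakpoints

    def test_count_criterion_k_monotone_along_grid(self, rng):
        for _ in range(20):
            T = int(rng.integers(4, 8))
            pt = random_table(rng, T)
            dag = build_dag(pt)
            res = sweep(
                dag, PenaltyConfig(criterion="count"), lambda_bounds(pt, dag), 20
            )
            ks = [s.n_segments for s in res.per_lambda]
            assert all(k1 >= k2 for k1, k2 in zip(ks, ks[1:]))

    def test_grid_size_respected(self, rng):
        pt = random_table(rng, 5)
        res = sweep(build_dag(pt), PenaltyConfig(criterion="length"), (0.1, 1.0), 7)
        assert len(res.per_lambda) == 7
        assert res.per_lambda[0].lam == pytest.approx(0.1)
        assert res.per_lambda[-1].lam == pytest.approx(1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(2, 9), st.integers(1, 3))
def test_pair_count_closed_form_property(T, L_min):
    if T < 2 * L_min:
        return
    pairs = enumerate_pairs(T, L_min)
    assert len(set(pairs)) == len(pairs)
    if L_min == 1:
        assert len(pairs) == T * (T * T - 1) // 6
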