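"""Association index, node metrics and stratified checkerboard swaps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from psforage.gatherings import GatheringEvent, GroupByIndividual
from psforage.network import (
    association_matrix,
    average_group_size_per_bird,
    gbi_metric,
    make_swapper,
    node_metrics,
    permute_stream,
)

from oracles import (
    betweenness_reference,
    enumerate_gbi_matrices,
    reachable_checkerboard_states,
    sri_reference,
)


def gbi_from_matrix(mat, strata=None):
    mat = np.asarray(mat, dtype=np.int8)
    K, N = mat.shape
    if strata is None:
        strata = np.array(["s0"] * K)
    return GroupByIndividual(
        mat, [f"B{j}" for j in range(N)], np.asarray(strata),
        [f"e{k}" for k in range(K)],
    )


def event(eid, members, feeder="F0", date=5, start=0.0, end=10.0):
    return GatheringEvent(eid, feeder, date, start, end, tuple(members), len(members))


class TestSRI:
    def test_partial_overlap(self):
        # i in {e1,e2}, j in {e2,e3} -> 1 shared of 3 total
        mat = [[1, 0], [1, 1], [0, 1]]
        A = association_matrix(gbi_from_matrix(mat))
        assert A.iloc[0, 1] == pytest.approx(1 / 3)

    def test_always_together_is_one(self):
        A = association_matrix(gbi_from_matrix([[1, 1], [1, 1], [1, 1]]))
        assert A.iloc[0, 1] == 1.0

    def test_never_together_is_zero(self):
        A = association_matrix(gbi_from_matrix([[1, 0], [0, 1]]))
        assert A.iloc[0, 1] == 0.0

    def test_matches_set_counting_exhaustively(self):
        """All binary GBIs up to 3x3 plus random draws up to 6x6 agree
        with the explicit set-counting oracle."""
        for K, N in [(1, 2), (2, 2), (2, 3), (3, 2), (3, 3)]:
            for mat in enumerate_gbi_matrices(K, N):
                A = association_matrix(gbi_from_matrix(mat))
                np.testing.assert_allclose(A.to_numpy(), sri_reference(mat))
        rng = np.random.default_rng(0)
        for _ in range(300):
            K = int(rng.integers(1, 7))
            N = int(rng.integers(2, 7))
            mat = (rng.random((K, N)) < 0.4).astype(np.int8)
            A = association_matrix(gbi_from_matrix(mat))
            np.testing.assert_allclose(A.to_numpy(), sri_reference(mat))

    def test_symmetry_zero_diag_bounds(self, rng):
        mat = (rng.random((12, 9)) < 0.3).astype(np.int8)
        A = association_matrix(gbi_from_matrix(mat)).to_numpy()
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 0.0)
        assert A.min() >= 0.0 and A.max() <= 1.0


class TestNodeMetrics:
    def test_path_graph_betweenness(self):
        # i-j-k: only the middle node carries a shortest path
        A = pd.DataFrame(
            [[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]],
            index=list("ijk"), columns=list("ijk"),
        )
        nm = node_metrics(A)
        assert nm.loc["j", "betweenness"] == 1.0
        assert nm.loc["i", "betweenness"] == 0.0

    def test_star_graph_betweenness(self):
        names = ["c", "l1", "l2", "l3", "l4"]
        M = np.zeros((5, 5))
        M[0, 1:] = M[1:, 0] = 0.3
        nm = node_metrics(pd.DataFrame(M, index=names, columns=names))
        assert nm.loc["c", "betweenness"] == 6.0  # all 4C2 leaf pairs
        assert (nm.loc[["l1", "l2", "l3", "l4"], "betweenness"] == 0).all()

    def test_complete_graph_betweenness_zero(self):
        M = np.ones((5, 5)) - np.eye(5)
        nm = node_metrics(pd.DataFrame(M, index=list("abcde"), columns=list("abcde")))
        assert (nm["betweenness"] == 0).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_betweenness_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 9))
        adj = np.triu((rng.random((N, N)) < 0.45).astype(int), 1)
        adj = adj + adj.T
        names = [f"B{i}" for i in range(N)]
        nm = node_metrics(pd.DataFrame(adj.astype(float), index=names, columns=names))
        ref = betweenness_reference(adj)
        np.testing.assert_allclose(nm["betweenness"].to_numpy(), ref, atol=1e-9)

    def test_strength_is_row_sum_and_degree_counts(self, rng):
        mat = (rng.random((10, 8)) < 0.4).astype(np.int8)
        gbi = gbi_from_matrix(mat)
        A = association_matrix(gbi)
        nm = node_metrics(A)
        np.testing.assert_allclose(nm["strength"], A.sum(axis=1))
        np.testing.assert_allclose(nm["degree"], (A > 0).sum(axis=1))
        assert (nm["strength"] <= nm["degree"] + 1e-12).all()


class TestAvgGroupSize:
    def test_mean_of_attended_sizes(self):
        evs = [event("e1", ["A", "B"]), event("e2", ["A", "B", "C", "D"])]
        ag = average_group_size_per_bird(evs)
        assert ag["A"] == 3.0
        assert ag["C"] == 4.0

    def test_always_alone(self):
        evs = [event("e1", ["A"]), event("e2", ["A"])]
        assert average_group_size_per_bird(evs)["A"] == 1.0

    def test_gbi_route_matches_event_route(self, rng):
        mat = (rng.random((15, 10)) < 0.4).astype(np.int8)
        mat[mat.sum(axis=1) == 0, 0] = 1
        gbi = gbi_from_matrix(mat)
        evs = [
            event(f"e{k}", [gbi.birds[j] for j in np.flatnonzero(mat[k])])
            for k in range(15)
        ]
        a = average_group_size_per_bird(evs)
        b = average_group_size_per_bird(gbi)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index(), check_names=False)


class TestPermutation:
    def test_single_event_stratum_unchanged(self, rng):
        mat = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
        gbi = gbi_from_matrix(mat, strata=["s0", "s1"])
        out = permute_stream(gbi, 500, rng)
        np.testing.assert_array_equal(out.gbi.matrix, mat)
        assert out.n_swaps == 0

    def test_margins_preserved_after_every_swap(self, rng):
        """Stratum-wise row and column sums are invariant along the chain,
        checked after every accepted swap."""
        mat = (rng.random((12, 8)) < 0.4).astype(np.int8)
        strata = np.repeat(["s0", "s1", "s2"], 4)
        gbi = gbi_from_matrix(mat, strata=strata)
        work, attempt = make_swapper(gbi)
        ref_rows = work.sum(axis=1).copy()
        ref_cols = {
            s: work[strata == s].sum(axis=0).copy() for s in np.unique(strata)
        }
        accepted = 0
        for _ in range(2000):
            if attempt(rng) is not None:
                accepted += 1
                assert (work.sum(axis=1) == ref_rows).all()
                for s in np.unique(strata):
                    assert (work[strata == s].sum(axis=0) == ref_cols[s]).all()
        assert accepted > 0

    def test_chain_visits_every_reachable_state(self, rng):
        """On a 3x3 toy GBI the swap chain reaches the full brute-force
        set of checkerboard-reachable configurations."""
        mat = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int8)
        strata = ["s0", "s0", "s0"]
        reachable = reachable_checkerboard_states(mat, strata)
        gbi = gbi_from_matrix(mat, strata=strata)
        work, attempt = make_swapper(gbi)
        visited = {work.tobytes()}
        for _ in range(10_000):
            attempt(rng)
            visited.add(work.tobytes())
        assert visited == reachable
        assert len(reachable) == 6  # 3x3 permutation matrices

    def test_cross_stratum_swaps_never_occur(self, rng):
        mat = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.int8)
        strata = ["s0", "s0", "s1", "s1"]
        gbi = gbi_from_matrix(mat, strata=strata)
        out = permute_stream(gbi, 3000, rng, log_swaps=True)
        for r1, r2, _, _, s in out.swap_log:
            assert {strata[r1], strata[r2]} == {s}


def test_gbi_metric_matches_node_metrics(rng):
    mat = (rng.random((14, 9)) < 0.35).astype(np.int8)
    mat[mat.sum(axis=1) == 0, 0] = 1
    gbi = gbi_from_matrix(mat)
    A = association_matrix(gbi)
    nm = node_metrics(A)
    for metric in ("strength", "degree", "betweenness"):
        np.testing.assert_allclose(
            gbi_metric(gbi, metric).to_numpy(float),
            nm[metric].to_numpy(float),
        )


def test_strength_correlates_with_group_size(small_sim):
    """On generator output, gregarious birds feed in larger groups:
    strength and average attended group size are positively correlated."""
    from psforage.gatherings import build_gbi, detect_gatherings

    fv = small_sim.visits[small_sim.visits["device_type"] == "feeder"]
    events = detect_gatherings(fv, seed=0)
    gbi = build_gbi(events)
    nm = node_metrics(association_matrix(gbi), events)
    r = nm["strength"].corr(nm["avg_group_size"])
    assert r > 0
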