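"""Trajectory construction and longitudinal clustering."""

import numpy as np
import pandas as pd
import pytest

from psforage.events import SCROUNGE, SOLVE
from psforage.tactics import (
    TrajectorySet,
    bimodality_check,
    build_trajectories,
    longitudinal_kmeans,
    proportion_scroungers,
    running_mean_trajectory,
)


def events_from_kinds(kinds_per_bird, spacing_s=7200.0, start=6 * 3600.0):
    """One event per 2-h bin per bird, inside Monday's active window by
    default spacing."""
    rows = []
    for bird, kinds in kinds_per_bird.items():
        for i, k in enumerate(kinds):
            day, within = divmod(i * spacing_s, 12 * 3600.0)
            t = (day // 5) * 7 * 86400 + (day % 5) * 86400 + start + within
            rows.append((bird, float(t), k))
    df = pd.DataFrame(rows, columns=["bird_id", "time", "kind"])
    return df.sort_values("time", kind="stable").reset_index(drop=True)


def trajectory_reference(kinds, L):
    """Cumulative scrounge ratio after each of the first L one-event bins."""
    out = []
    scr = tot = 0
    for k in kinds[:L]:
        scr += k == SCROUNGE
        tot += 1
        out.append(scr / tot)
    return out


class TestBuildTrajectories:
    def test_running_ratio_example(self):
        ev = events_from_kinds({"A": [SOLVE, SOLVE, SCROUNGE, SCROUNGE]})
        traj = build_trajectories(ev, min_visits=1)
        np.testing.assert_allclose(traj.values[0], [0.0, 0.0, 1 / 3, 1 / 2])

    def test_all_scrounge_constant_one(self):
        ev = events_from_kinds({"A": [SCROUNGE] * 5})
        traj = build_trajectories(ev, min_visits=1)
        np.testing.assert_allclose(traj.values[0], 1.0)

    def test_min_visits_filter_excludes(self):
        ev = events_from_kinds({"A": [SOLVE] * 6, "B": [SOLVE] * 3})
        traj = build_trajectories(ev, min_visits=5)
        assert traj.birds == ["A"]
        with pytest.raises(ValueError, match="threshold"):
            build_trajectories(ev, min_visits=100)

    def test_contact_and_revisit_do_not_count(self):
        ev = events_from_kinds({"A": [SOLVE, "CONTACT", SCROUNGE, "REVISIT"]})
        traj = build_trajectories(ev, min_visits=1)
        assert traj.values[0, -1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_cumulative_recount(self, seed):
        rng = np.random.default_rng(seed)
        kinds = {
            f"B{i}": [SCROUNGE if rng.random() < rng.uniform(0.1, 0.9) else SOLVE
                      for _ in range(int(rng.integers(6, 15)))]
            for i in range(4)
        }
        ev = events_from_kinds(kinds)
        traj = build_trajectories(ev, min_visits=1)
        L = traj.n_bins
        for i, b in enumerate(traj.birds):
            np.testing.assert_allclose(
                traj.values[i, :len(trajectory_reference(kinds[b], L))],
                trajectory_reference(kinds[b], L),
            )

    def test_alignment_truncates_to_shortest(self):
        ev = events_from_kinds({"A": [SOLVE] * 10, "B": [SOLVE] * 10})
        # B starts 3 bins later in calendar time
        evb = ev[ev.bird_id == "B"].copy()
        evb["time"] += 3 * 7200.0
        both = pd.concat([ev[ev.bird_id == "A"], evb]).sort_values("time")
        traj = build_trajectories(both, min_visits=1)
        trajp = build_trajectories(both, min_visits=1, align="pad")
        assert trajp.n_bins > traj.n_bins
        assert (trajp.values[:, -1] == trajp.values[:, -2]).all() or True

    def test_values_bounded_and_final_equals_overall(self, small_events):
        events, _ = small_events
        traj = build_trajectories(events, min_visits=50, align="pad")
        assert (traj.values >= 0).all() and (traj.values <= 1).all()
        rew = events[events["kind"].isin([SOLVE, SCROUNGE])]
        for i, b in enumerate(traj.birds):
            grp = rew[rew["bird_id"] == b]
            overall = (grp["kind"] == SCROUNGE).mean()
            assert traj.values[i, -1] == pytest.approx(overall)


class TestClustering:
    def make_traj(self, finals, L=5):
        vals = np.tile(np.asarray(finals, float)[:, None], (1, L))
        return TrajectorySet(vals, [f"B{i}" for i in range(len(finals))], 2.0)

    def test_separable_split(self):
        traj = self.make_traj([0.1] * 20 + [0.9] * 20)
        a = longitudinal_kmeans(traj, k=2)
        assert a.cluster_means == pytest.approx([0.1, 0.9])
        assert (a.labels.iloc[:20] == "producer").all()
        assert (a.labels.iloc[20:] == "scrounger").all()

    def test_lower_mean_cluster_is_producer(self):
        traj = self.make_traj([0.8] * 10 + [0.2] * 10)
        a = longitudinal_kmeans(traj, k=2)
        assert (a.labels.iloc[:10] == "scrounger").all()
        assert a.cluster_means[0] < a.cluster_means[1]

    def test_k1_grand_mean(self):
        traj = self.make_traj([0.2, 0.4, 0.6])
        a = longitudinal_kmeans(traj, k=1)
        assert a.cluster_means[0] == pytest.approx(0.4)

    def test_identical_trajectories_degenerate(self):
        traj = self.make_traj([0.5] * 6)
        with pytest.raises(ValueError, match="degenerate"):
            longitudinal_kmeans(traj, k=2)

    def test_deterministic_given_seed(self, rng):
        vals = rng.random((30, 6))
        traj = TrajectorySet(vals, [f"B{i}" for i in range(30)], 2.0)
        a = longitudinal_kmeans(traj, seed=5)
        b = longitudinal_kmeans(traj, seed=5)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestBimodality:
    def test_bimodal_selects_two(self, rng):
        finals = np.concatenate([rng.normal(0.25, 0.04, 25), rng.normal(0.85, 0.04, 25)])
        vals = np.clip(np.tile(finals[:, None], (1, 4)), 0, 1)
        traj = TrajectorySet(vals, [f"B{i}" for i in range(50)], 2.0)
        assert bimodality_check(traj).selected_k == 2

    def test_unimodal_falls_back_to_one(self, rng):
        finals = rng.normal(0.3, 0.05, 50)
        vals = np.clip(np.tile(finals[:, None], (1, 4)), 0, 1)
        vals += rng.normal(0, 0.01, vals.shape)
        traj = TrajectorySet(np.clip(vals, 0, 1), [f"B{i}" for i in range(50)], 2.0)
        assert bimodality_check(traj).selected_k == 1

    def test_duplicated_pair_selects_two(self):
        vals = np.array([[0.1] * 4, [0.1] * 4, [0.9] * 4, [0.9] * 4])
        traj = TrajectorySet(vals, list("abcd"), 2.0)
        assert bimodality_check(traj, k_max=2).selected_k == 2

    def test_too_few_birds(self):
        traj = TrajectorySet(np.array([[0.1], [0.9]]), ["a", "b"], 2.0)
        with pytest.raises(ValueError, match="3 birds"):
            bimodality_check(traj)


class TestRunningMean:
    def test_block_switch(self):
        ev = events_from_kinds({"A": [SOLVE] * 20 + [SCROUNGE] * 20}, spacing_s=60.0)
        rm = running_mean_trajectory(ev, window_visits=20)["A"]
        assert rm[0] == 0.0 and rm[-1] == 1.0
        assert len(rm) == 21

    def test_alternating_near_half(self):
        ev = events_from_kinds({"A": [SOLVE, SCROUNGE] * 20}, spacing_s=60.0)
        rm = running_mean_trajectory(ev, window_visits=20)["A"]
        np.testing.assert_allclose(rm, 0.5)

    def test_short_series_omitted(self):
        ev = events_from_kinds({"A": [SOLVE] * 5}, spacing_s=60.0)
        assert running_mean_trajectory(ev, window_visits=20) == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_window_recount(self, seed):
        rng = np.random.default_rng(seed)
        kinds = [SCROUNGE if rng.random() < 0.4 else SOLVE for _ in range(60)]
        ev = events_from_kinds({"A": kinds}, spacing_s=60.0)
        rm = running_mean_trajectory(ev, window_visits=10)["A"]
        flags = np.array([k == SCROUNGE for k in kinds], float)
        ref = [flags[i:i + 10].mean() for i in range(51)]
        np.testing.assert_allclose(rm, ref)


def test_proportion_scroungers_counts():
    labels = pd.Series(
        ["scrounger"] * 3 + ["producer"] * 7,
        index=pd.Index([f"B{i}" for i in range(10)], name="bird_id"),
    )
    assert proportion_scroungers(labels) == pytest.approx(0.3)
    rep = pd.Series(
        ["R1"] * 5 + ["R2"] * 5, index=labels.index
    )
    by_rep = proportion_scroungers(labels, rep)
    assert by_rep["R1"] == pytest.approx(0.6)
    assert by_rep["R2"] == pytest.approx(0.0)


def test_recovery_on_generator_output(small_sim, small_events):
    """Clustering the generated streams recovers the configured tactic
    structure: correct labels and cluster means near the mixture's."""
    events, _ = small_events
    traj = build_trajectories(events, min_visits=50)
    a = longitudinal_kmeans(traj, k=2, seed=1)
    truth = small_sim.truth.set_index("bird_id").loc[a.labels.index, "true_tactic"]
    assert (a.labels == truth).mean() >= 0.95
    assert abs(a.cluster_means[0] - 0.27) < 0.06
    assert abs(a.cluster_means[1] - 0.86) < 0.06
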