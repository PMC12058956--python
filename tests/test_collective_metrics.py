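import numpy as np
import pytest

from shoalnet.collective_metrics import (
    IncompleteDesignError,
    UndefinedMetricError,
    activity,
    behavior_table,
    cohesion,
    interaction_time,
)
from tests.conftest import make_trajectory


def random_walk_traj(rng, n_frames=500, step=1.0):
    pos = np.cumsum(rng.normal(0, step, (n_frames, 8, 2)), axis=0)
    return make_trajectory(pos, fps=2.0)


class TestActivity:
    def test_stationary_fish_swims_zero(self):
        t = make_trajectory(np.ones((10, 8, 2)))
        assert activity(t, "f1") == 0.0

    def test_unit_steps_sum(self):
        pos = np.zeros((11, 8, 2))
        pos[:, 0, 0] = np.arange(11)  # fish 1 moves 1 cm per frame
        t = make_trajectory(pos)
        assert activity(t, "f1") == pytest.approx(10.0)

    def test_matches_brute_force_step_sum(self):
        rng = np.random.default_rng(42)
        t = random_walk_traj(rng)
        for fish in ("f1", "f5"):
            k = t.fish_ids.index(fish)
            expected = 0.0
            for f in range(1, t.n_frames):
                dx = t.positions[f, k, 0] - t.positions[f - 1, k, 0]
                dy = t.positions[f, k, 1] - t.positions[f - 1, k, 1]
                expected += np.hypot(dx, dy)
            assert activity(t, fish) == pytest.approx(expected, rel=1e-12)

    def test_gap_frames_contribute_no_distance(self):
        pos = np.zeros((4, 8, 2))
        pos[:, 0, 0] = [0, 1, 5, 6]
        # frame numbers 0,1,3,4: the 1->5 jump spans a dropped frame
        t = make_trajectory(pos, frame_index=np.array([0, 1, 3, 4]))
        assert activity(t, "f1") == pytest.approx(2.0)

    def test_too_few_frames(self):
        t = make_trajectory(np.zeros((1, 8, 2)))
        with pytest.raises(UndefinedMetricError):
            activity(t, "f1")


class TestCohesion:
    def test_coincident_fish_have_zero_cohesion(self):
        t = make_trajectory(np.full((5, 8, 2), 3.0))
        for fish in t.fish_ids:
            assert cohesion(t, fish) == 0.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(-40, 40, (50, 8, 2))
        t = make_trajectory(pos)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pos @ R.T + np.array([5.0, -3.0])
        t2 = make_trajectory(moved)
        for fish in ("f1", "f8"):
            assert cohesion(t2, fish) == pytest.approx(cohesion(t, fish), rel=1e-12)

    def test_octagon_closed_form(self):
        # 8 fish fixed at the vertices of a regular octagon of radius r:
        # centroid is the center, so every fish's cohesion equals r
        r = 10.0
        ang = 2 * np.pi * np.arange(8) / 8
        pos = np.tile(r * np.stack([np.cos(ang), np.sin(ang)], axis=1), (6, 1, 1))
        t = make_trajectory(pos)
        for fish in t.fish_ids:
            assert cohesion(t, fish) == pytest.approx(r, rel=1e-12)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-40, 40, (30, 8, 2))
        t1, t2 = make_trajectory(pos), make_trajectory(2.5 * pos)
        assert cohesion(t2, "f3") == pytest.approx(2.5 * cohesion(t1, "f3"))
        assert activity(t2, "f3") == pytest.approx(2.5 * activity(t1, "f3"))


class TestInteractionTime:
    def test_coincident_pair_scores_full_duration(self):
        # 20-min trial at 1 fps: 1200 frames, always within threshold
        t = make_trajectory(np.zeros((1200, 8, 2)), fps=1.0)
        assert interaction_time(t, "f1", "f2") == pytest.approx(1200.0)

    def test_distant_pair_scores_zero(self):
        pos = np.zeros((100, 8, 2))
        pos[:, 1, 0] = 50.0  # fish 2 is 50 cm away; threshold = 4 cm
        t = make_trajectory(pos)
        assert interaction_time(t, "f1", "f2") == 0.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(3)
        t = make_trajectory(rng.uniform(-60, 60, (200, 8, 2)))
        for i, j in [("f1", "f2"), ("f3", "f7")]:
            assert interaction_time(t, i, j) == interaction_time(t, j, i)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        t = make_trajectory(rng.uniform(-20, 20, (300, 8, 2)))
        times = [
            interaction_time(t, "f1", "f2", threshold_bl=b) for b in (0.5, 1.0, 2.0, 4.0)
        ]
        assert times == sorted(times)

    def test_uniform_positions_match_geometric_expectation(self):
        # independent uniform positions in a disc arena: P(pair within d) is
        # the mean over positions of the overlap of a d-disc with the arena;
        # estimated here by an independent Monte-Carlo geometry oracle
        rng = np.random.default_rng(5)
        R, d, n_frames = 60.0, 8.0, 120_000
        def uniform_disc(n):
            r = R * np.sqrt(rng.uniform(size=n))
            th = rng.uniform(0, 2 * np.pi, n)
            return np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
        pos = np.stack([uniform_disc(n_frames) for _ in range(8)], axis=1)
        t = make_trajectory(pos, fps=1.0, body_lengths={f"f{i}": d for i in range(1, 9)})
        observed = interaction_time(t, "f1", "f2") / n_frames
        oracle = (
            np.linalg.norm(uniform_disc(200_000) - uniform_disc(200_000), axis=-1) <= d
        ).mean()
        assert observed == pytest.approx(oracle, abs=0.003)

    def test_unknown_fish_rejected(self):
        t = make_trajectory(np.zeros((5, 8, 2)))
        with pytest.raises(KeyError):
            interaction_time(t, "f1", "nope")


class TestBehaviorTable:
    def test_full_design_counts(self, small_behavior):
        assert len(small_behavior.individual) == 480
        assert len(small_behavior.pairs) == 1680

    def test_single_group_counts(self):
        rng = np.random.default_rng(6)
        ts = [
            make_trajectory(rng.uniform(-50, 50, (40, 8, 2)), trial=tr, group_id="g1")
            for tr in (1, 2)
        ]
        b = behavior_table(ts)
        assert len(b.individual) == 16
        assert len(b.pairs) == 56

    def test_strength_equals_pair_row_sums(self, small_behavior):
        ind, pairs = small_behavior.individual, small_behavior.pairs
        for _, row in ind.head(24).iterrows():
            sub = pairs[(pairs["group_id"] == row["group_id"]) & (pairs["trial"] == row["trial"])]
            total = sub.loc[
                (sub["fish_i"] == row["fish_id"]) | (sub["fish_j"] == row["fish_id"]),
                "interaction_time",
            ].sum()
            assert row["strength"] == pytest.approx(total, rel=1e-12)

    def test_conservation_identity(self, small_behavior):
        # sum of strengths = twice the sum of pairwise times, per group-trial
        ind = small_behavior.individual.groupby(["group_id", "trial"])["strength"].sum()
        pair = small_behavior.pairs.groupby(["group_id", "trial"])["interaction_time"].sum()
        np.testing.assert_allclose(ind.to_numpy(), 2 * pair.to_numpy(), rtol=1e-12)

    def test_missing_trial_is_design_error(self):
        rng = np.random.default_rng(7)
        ts = [make_trajectory(rng.uniform(-50, 50, (10, 8, 2)), trial=1, group_id="g1")]
        with pytest.raises(IncompleteDesignError, match="g1"):
            behavior_table(ts)
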