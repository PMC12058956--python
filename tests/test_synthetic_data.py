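import numpy as np
import pandas as pd
import pytest

from shoalnet.collective_metrics import activity, cohesion
from shoalnet.morphometrics import ancova_slope
from shoalnet.synthetic_data import (
    DEFAULT_POPULATIONS,
    SimulationConfig,
    simulate_dataset,
    simulate_latency,
    simulate_morphology,
    simulate_traits,
    simulate_trajectories,
)

TINY = dict(fps=5.0, trial_duration_s=30.0)


def one_group_config(**kw):
    base = dict(populations=(("PopA", "benthic", 2, 1),), seed=0, **TINY)
    base.update(kw)
    return SimulationConfig(**base)


class TestDesign:
    def test_default_design_counts(self):
        cfg = SimulationConfig()
        assert cfg.n_groups == 30
        assert cfg.n_fish == 240
        traits = simulate_traits(cfg)
        assert len(traits) == 240
        assert traits["population"].nunique() == 8
        assert traits.groupby("population")["ecotype"].nunique().eq(1).all()
        assert (traits.groupby("group_id").size() == 8).all()
        # 4 benthic and 4 limnetic populations
        eco = traits.drop_duplicates("population")["ecotype"]
        assert (eco == "benthic").sum() == 4

    def test_families_between_two_and_four_fish_per_group(self):
        traits = simulate_traits(SimulationConfig())
        per = traits.groupby(["group_id", "family"]).size()
        assert per.between(2, 4).all()

    def test_behavior_observation_counts(self, small_behavior):
        assert len(small_behavior.individual) == 480
        assert len(small_behavior.pairs) == 1680


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        a = simulate_dataset(SimulationConfig(seed=21, **TINY))
        b = simulate_dataset(SimulationConfig(seed=21, **TINY))
        np.testing.assert_array_equal(
            a.trajectories[0].positions, b.trajectories[0].positions
        )
        pd.testing.assert_frame_equal(a.morphology, b.morphology)
        pd.testing.assert_frame_equal(a.latency, b.latency)

    def test_different_seed_differs(self):
        a = simulate_dataset(SimulationConfig(seed=21, **TINY))
        b = simulate_dataset(SimulationConfig(seed=22, **TINY))
        assert not np.array_equal(
            a.trajectories[0].positions, b.trajectories[0].positions
        )


class TestKinematics:
    def test_positions_stay_inside_arena(self):
        cfg = SimulationConfig(seed=2, **TINY)
        traj = simulate_trajectories(simulate_traits(cfg), cfg)
        R = cfg.arena_diameter_cm / 2
        for t in traj[:6]:
            r = np.linalg.norm(t.positions, axis=-1)
            assert np.nanmax(r) <= R + 1e-9

    def test_ballistic_limit_activity_equals_speed_times_time(self):
        # persistence 1, no attraction, no noise: straight-line motion at the
        # speed trait; specular wall reflections preserve speed
        cfg = one_group_config(
            persistence=1.0,
            noise_scale=0.0,
            sociability_mean=0.0,
            sociability_sd_population=0.0,
            sociability_sd_family=0.0,
            sociability_sd_fish=0.0,
            sociability_sd_trial=0.0,
            speed_mean=4.0,
            speed_sd_population=0.0,
            speed_sd_family=0.0,
            speed_sd_fish=0.0,
            speed_sd_trial=0.0,
            missing_frame_rate=0.0,
        )
        traj = simulate_trajectories(simulate_traits(cfg), cfg)
        t = traj[0]
        expected = 4.0 * (t.n_frames - 1) / cfg.fps
        for fish in t.fish_ids:
            assert activity(t, fish) == pytest.approx(expected, rel=0.02)

    def test_sociability_tightens_the_shoal(self):
        coh = {}
        for soc in (0.05, 2.0):
            cfg = one_group_config(
                sociability_mean=soc,
                sociability_sd_population=0.0,
                sociability_sd_family=0.0,
                sociability_sd_fish=0.0,
                sociability_sd_trial=0.0,
                missing_frame_rate=0.0,
                trial_duration_s=60.0,
            )
            traj = simulate_trajectories(simulate_traits(cfg), cfg)
            coh[soc] = np.mean(
                [cohesion(t, f) for t in traj for f in t.fish_ids]
            )
        assert coh[2.0] < coh[0.05]

    def test_missing_fraction_near_configured_rate(self):
        cfg = SimulationConfig(seed=3, missing_frame_rate=0.01, **TINY)
        traj = simulate_trajectories(simulate_traits(cfg), cfg)
        incomplete = np.mean(
            [1 - t.complete_mask().mean() for t in traj]
        )
        assert incomplete == pytest.approx(0.01, abs=0.005)


def test_trait_variance_matches_hierarchy_sum():
    # many small populations: across-fish variance approaches the sum of
    # population + family + fish variance components
    pops = tuple((f"P{k}", "benthic" if k % 2 else "limnetic", 2, 1) for k in range(60))
    cfg = SimulationConfig(
        populations=pops,
        seed=4,
        speed_sd_population=0.8,
        speed_sd_family=0.4,
        speed_sd_fish=0.6,
        **TINY,
    )
    traits = simulate_traits(cfg)
    expected = 0.8**2 + 0.4**2 + 0.6**2
    assert traits["speed"].var(ddof=1) == pytest.approx(expected, rel=0.25)


def test_family_members_identical_when_fish_and_trial_sd_zero():
    cfg = one_group_config(
        speed_sd_fish=0.0, speed_sd_family=0.5, speed_sd_population=0.0
    )
    traits = simulate_traits(cfg)
    assert (traits.groupby("family")["speed"].nunique() == 1).all()


class TestMorphology:
    def test_zero_noise_recovers_slope_exactly(self):
        cfg = SimulationConfig(
            seed=5,
            morph_noise_sd=0.0,
            morph_sd_population=0.0,
            morph_benthic_body_depth_shift=0.0,
            **TINY,
        )
        meta = simulate_traits(cfg)
        morph = simulate_morphology(cfg, meta)
        b = ancova_slope(
            morph["body_depth"], morph["standard_length"], morph["population"]
        )
        assert b == pytest.approx(cfg.morph_slopes["body_depth"], abs=1e-9)

    def test_measured_subset_size_and_exclusions(self):
        cfg = SimulationConfig(seed=6, **TINY)
        meta = simulate_traits(cfg)
        morph = simulate_morphology(cfg, meta)
        assert len(morph) == 159
        assert not morph["population"].isin(cfg.morph_excluded_populations).any()

    def test_benthic_body_depth_shift_detectable(self):
        cfg = SimulationConfig(seed=7, **TINY)
        meta = simulate_traits(cfg)
        morph = simulate_morphology(cfg, meta)
        log_ratio = np.log10(
            morph[morph["ecotype"] == "benthic"]["body_depth"]
        ).mean() - np.log10(morph[morph["ecotype"] == "limnetic"]["body_depth"]).mean()
        assert log_ratio == pytest.approx(
            cfg.morph_benthic_body_depth_shift, abs=0.03
        )


class TestLatency:
    def test_ceiling_enforced(self):
        cfg = SimulationConfig(seed=8, latency_mean_limnetic=900.0, **TINY)
        lat = simulate_latency(cfg, simulate_traits(cfg))
        assert lat["latency"].max() <= 600
        assert (lat["latency"] == 600).any()

    def test_ecotype_ordering_matches_config(self):
        cfg = SimulationConfig(seed=9, **TINY)
        lat = simulate_latency(cfg, simulate_traits(cfg))
        assert (
            lat[lat["ecotype"] == "benthic"]["latency"].mean()
            < lat[lat["ecotype"] == "limnetic"]["latency"].mean()
        )

    def test_poisson_config_not_overdispersed(self):
        cfg = SimulationConfig(
            seed=10,
            latency_nb_size=None,
            latency_sd_population=0.0,
            latency_sd_family=0.0,
            **TINY,
        )
        lat = simulate_latency(cfg, simulate_traits(cfg))
        for eco in ("benthic", "limnetic"):
            sub = lat[lat["ecotype"] == eco]["latency"]
            assert sub.var() / sub.mean() == pytest.approx(1.0, abs=0.35)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(missing_frame_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(fps=0)
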