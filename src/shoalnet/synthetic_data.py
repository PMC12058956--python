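"""Synthetic shoaling data with known ground truth.

The generator emulates the structure of a lab common-garden study of
collective behavior in three-spined stickleback: 8 lake populations (4
benthic, 4 limnetic ecotype), families nested within populations, 30
experimental groups of 8 fish drawn from a single population each, and two
20-minute trials per group in a circular arena of diameter 1.2 m.  The
default layout (families and groups per population) mirrors the uneven
real design, giving 240 fish, 480 individual-level and 1680 pair-level
behavior observations.

Individual differences enter through two latent traits drawn
hierarchically (ecotype shift -> population deviate -> family deviate ->
fish deviate): **sociability** (attraction toward the group centroid) and
**speed** (magnitude of locomotor noise).  Traits persist across the two
trials — that persistence, diluted by a trial-level deviate and by
trajectory stochasticity, is the source of behavioral repeatability.  The
movement model is a deliberately minimal attraction + persistence + noise
kernel with reflective arena walls: enough to induce the variance
structure the statistics consume, cheap enough to simulate thousands of
times, and not a biomechanical model of fish locomotion.

Morphology follows a log-log allometric model per trait with a benthic
body-depth shift; latency to emerge is an overdispersed count (seconds)
with a log-scale ecotype difference and a hard ceiling at 600 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from shoalnet.trajectory_io import TrajectorySet, N_FISH

# (name, ecotype, n_families, n_groups) — mirrors the uneven real design:
# 30 groups, 240 fish, four lakes per ecotype, 2-4 families per lake.
DEFAULT_POPULATIONS = (
    ("FingerLk", "benthic", 4, 7),
    ("TernLk", "benthic", 2, 2),
    ("WalbyLk", "benthic", 4, 3),
    ("WatsonLk", "benthic", 2, 3),
    ("LongLk", "limnetic", 3, 4),
    ("SpiritLk", "limnetic", 3, 5),
    ("SRollyLk", "limnetic", 3, 4),
    ("WikLk", "limnetic", 2, 2),
)

MORPH_TRAITS = ("body_depth", "caudal_peduncle_depth", "head_length", "snout_length")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic study.

    Trait units: speed in cm/s (sets the scale of locomotor noise),
    sociability in cm/s per frame of centroid attraction.  SD fields are
    the standard deviations of the corresponding level of the hierarchy
    (population, family-within-population, fish-within-family, and a
    trial-level deviate that is the within-fish component of variance).
    """

    populations: tuple = DEFAULT_POPULATIONS
    fish_per_group: int = N_FISH
    trials: int = 2
    trial_duration_s: float = 1200.0
    fps: float = 30.0
    arena_diameter_cm: float = 120.0
    missing_frame_rate: float = 0.01  # realized missing fraction stays <= 2%

    # movement kernel
    persistence: float = 0.8
    noise_scale: float | None = None  # default sqrt((1-persistence^2)/2)

    # speed trait (cm/s)
    speed_mean: float = 5.0
    speed_ecotype_shift: float = 0.0  # limnetic minus benthic
    speed_sd_population: float = 0.8
    speed_sd_family: float = 0.3
    speed_sd_fish: float = 1.0
    speed_sd_trial: float = 0.7

    # sociability trait (centroid attraction, cm/s per frame)
    sociability_mean: float = 0.5
    sociability_ecotype_shift: float = 0.0
    sociability_sd_population: float = 0.15
    sociability_sd_family: float = 0.05
    sociability_sd_fish: float = 0.12
    sociability_sd_trial: float = 0.08

    # morphology (log10 scale); standard length in cm
    sl_mean: float = 4.5
    sl_sd: float = 0.35
    morph_slopes: dict = field(
        default_factory=lambda: {
            "body_depth": 1.2,
            "caudal_peduncle_depth": 1.1,
            "head_length": 0.95,
            "snout_length": 0.9,
        }
    )
    morph_baselines: dict = field(
        default_factory=lambda: {
            "body_depth": 1.0,
            "caudal_peduncle_depth": 0.25,
            "head_length": 1.2,
            "snout_length": 0.45,
        }
    )
    morph_benthic_body_depth_shift: float = 0.04  # log10 units (~+10%)
    morph_sd_population: float = 0.02
    morph_noise_sd: float = 0.02
    n_morph: int = 159
    morph_excluded_populations: tuple = ("TernLk", "WikLk")

    # latency to emerge (seconds, ceiling-censored at 600)
    latency_mean_benthic: float = 150.0
    latency_mean_limnetic: float = 250.0
    latency_nb_size: float | None = 3.0  # None -> Poisson (dispersion 1)
    latency_sd_population: float = 0.25  # log scale
    latency_sd_family: float = 0.10
    latency_ceiling: float = 600.0

    seed: int = 0

    def __post_init__(self):
        for name, val in asdict(self).items():
            if name.endswith(("_sd", "_rate")) or "_sd_" in name:
                if isinstance(val, (int, float)) and val < 0:
                    raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.missing_frame_rate <= 1:
            raise ValueError("missing_frame_rate must be in [0, 1]")
        if self.fps <= 0 or self.trial_duration_s <= 0:
            raise ValueError("fps and trial duration must be positive")

    @property
    def n_groups(self) -> int:
        return sum(g for *_, g in self.populations)

    @property
    def n_fish(self) -> int:
        return self.n_groups * self.fish_per_group

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration_s * self.fps))

    def effective_noise_scale(self) -> float:
        # chosen so the stationary RMS velocity of a lone fish equals its
        # speed trait: Var(v) per axis = (c*speed)^2 / (1 - P^2) with
        # c = sqrt((1-P^2)/2)  =>  E|v|^2 = speed^2
        if self.noise_scale is not None:
            return self.noise_scale
        return float(np.sqrt((1.0 - self.persistence**2) / 2.0))


def _hierarchical_trait(
    rng, meta, mean, eco_shift, sd_pop, sd_fam, sd_fish, floor
):
    pops = meta["population"].unique()
    fams = meta["family"].unique()
    pop_dev = dict(zip(pops, rng.normal(0, sd_pop, len(pops))))
    fam_dev = dict(zip(fams, rng.normal(0, sd_fam, len(fams))))
    eco = np.where(meta["ecotype"] == "limnetic", 0.5, -0.5) * eco_shift
    vals = (
        mean
        + eco
        + meta["population"].map(pop_dev).to_numpy()
        + meta["family"].map(fam_dev).to_numpy()
        + rng.normal(0, sd_fish, len(meta))
    )
    return np.clip(vals, floor, None)


def simulate_traits(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """Draw the fish roster with latent sociability and speed traits.

    Returns one row per fish with metadata columns (fish_id, population,
    ecotype, family, group_id, standard_length) plus the latent traits.
    Within each group, fish are assigned to the population's families
    round-robin, giving 2-4 fish per family per group.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    rows = []
    g_index = 0
    for pop, ecotype, n_fam, n_groups in cfg.populations:
        families = [f"{pop}_fam{j + 1}" for j in range(n_fam)]
        for _ in range(n_groups):
            g_index += 1
            gid = f"g{g_index:02d}"
            for k in range(cfg.fish_per_group):
                rows.append(
                    {
                        "fish_id": f"{gid}_i{k + 1}",
                        "population": pop,
                        "ecotype": ecotype,
                        "family": families[k % n_fam],
                        "group_id": gid,
                    }
                )
    meta = pd.DataFrame(rows)
    meta["standard_length"] = np.clip(
        rng.normal(cfg.sl_mean, cfg.sl_sd, len(meta)), 2.0, None
    )
    meta["speed"] = _hierarchical_trait(
        rng,
        meta,
        cfg.speed_mean,
        cfg.speed_ecotype_shift,
        cfg.speed_sd_population,
        cfg.speed_sd_family,
        cfg.speed_sd_fish,
        floor=0.5,
    )
    meta["sociability"] = _hierarchical_trait(
        rng,
        meta,
        cfg.sociability_mean,
        cfg.sociability_ecotype_shift,
        cfg.sociability_sd_population,
        cfg.sociability_sd_family,
        cfg.sociability_sd_fish,
        floor=0.0,
    )
    return meta


def simulate_trajectories(traits: pd.DataFrame, cfg: SimulationConfig, rng=None):
    """Simulate per-frame positions for every group and trial.

    Discrete-time kinematics per fish (velocity v in cm/s, per frame):

        v <- persistence * v + sociability_t * u_centroid + noise_scale * speed_t * xi

    where u_centroid is the unit vector toward the group centroid and xi is
    2D standard normal noise; positions advance by v / fps and reflect
    specularly off the circular arena wall.  sociability_t and speed_t are
    the fish's traits plus a trial-level deviate (redrawn each trial, the
    within-individual variance source); the velocity noise is also
    reinitialized between trials.  A fraction ``missing_frame_rate`` of
    frames lose one randomly chosen fish, emulating tracking dropouts.

    Returns a list of :class:`TrajectorySet`, one per group-trial.
    """
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    R = cfg.arena_diameter_cm / 2.0
    F = cfg.n_frames
    dt = 1.0 / cfg.fps
    c_noise = cfg.effective_noise_scale()

    batches = []  # (group_id, trial, fish_ids, body_lengths, speed, soc)
    for gid, sub in traits.groupby("group_id", sort=True):
        sub = sub.sort_values("fish_id")
        for trial in range(1, cfg.trials + 1):
            speed_t = np.clip(
                sub["speed"].to_numpy()
                + rng.normal(0, cfg.speed_sd_trial, len(sub)),
                0.5,
                None,
            )
            soc_t = np.clip(
                sub["sociability"].to_numpy()
                + rng.normal(0, cfg.sociability_sd_trial, len(sub)),
                0.0,
                None,
            )
            batches.append(
                (
                    gid,
                    trial,
                    list(sub["fish_id"]),
                    dict(zip(sub["fish_id"], sub["standard_length"])),
                    speed_t,
                    soc_t,
                )
            )

    B = len(batches)
    n = cfg.fish_per_group
    speed = np.stack([b[4] for b in batches])  # (B, n)
    soc = np.stack([b[5] for b in batches])

    # initial positions uniform in a disc of 0.9 R; velocities at trait speed
    r0 = 0.9 * R * np.sqrt(rng.uniform(size=(B, n)))
    th0 = rng.uniform(0, 2 * np.pi, size=(B, n))
    pos = np.stack([r0 * np.cos(th0), r0 * np.sin(th0)], axis=-1)
    phi0 = rng.uniform(0, 2 * np.pi, size=(B, n))
    vel = speed[..., None] * np.stack([np.cos(phi0), np.sin(phi0)], axis=-1)

    out = np.empty((B, F, n, 2))
    for f in range(F):
        out[:, f] = pos
        centroid = pos.mean(axis=1, keepdims=True)
        to_c = centroid - pos
        dist = np.linalg.norm(to_c, axis=-1, keepdims=True)
        u = np.divide(to_c, dist, out=np.zeros_like(to_c), where=dist > 1e-9)
        xi = rng.standard_normal((B, n, 2))
        vel = (
            cfg.persistence * vel
            + soc[..., None] * u
            + c_noise * speed[..., None] * xi
        )
        pos = pos + vel * dt
        # specular reflection at the circular wall
        r = np.linalg.norm(pos, axis=-1)
        outside = r > R
        if outside.any():
            nrm = pos[outside] / r[outside][:, None]
            new_r = np.clip(2 * R - r[outside], 0.0, R)
            pos[outside] = nrm * new_r[:, None]
            vdotn = (vel[outside] * nrm).sum(axis=-1, keepdims=True)
            vel[outside] = vel[outside] - 2 * vdotn * nrm

    # tracking dropouts: a fraction of frames lose one random fish
    if cfg.missing_frame_rate > 0:
        drop = rng.uniform(size=(B, F)) < cfg.missing_frame_rate
        which = rng.integers(0, n, size=(B, F))
        bb, ff = np.nonzero(drop)
        out[bb, ff, which[bb, ff], :] = np.nan

    sets = []
    frame_index = np.arange(F)
    for bi, (gid, trial, fish_ids, bls, _, _) in enumerate(batches):
        sets.append(
            TrajectorySet(
                group_id=gid,
                trial=trial,
                fps=cfg.fps,
                fish_ids=fish_ids,
                positions=out[bi],
                frame_index=frame_index.copy(),
                body_lengths=bls,
                arena_diameter=cfg.arena_diameter_cm,
            )
        )
    return sets


def simulate_morphology(
    cfg: SimulationConfig, meta: pd.DataFrame, rng=None
) -> pd.DataFrame:
    """Allometric morphology for the measured subset of fish.

    log10(trait) = log10(baseline) + b * (log10 SL - log10 SL_mean)
                   + population deviate + ecotype shift (body depth only)
                   + N(0, noise_sd).

    Fish from the excluded populations are not measured; of the rest, a
    random subset of ``n_morph`` fish is retained, emulating incomplete
    measurement coverage.
    """
    rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    pool = meta[~meta["population"].isin(cfg.morph_excluded_populations)]
    n = min(cfg.n_morph, len(pool))
    idx = rng.choice(pool.index.to_numpy(), size=n, replace=False)
    morph = pool.loc[np.sort(idx), ["fish_id", "population", "ecotype", "standard_length"]].copy()
    log_sl = np.log10(morph["standard_length"].to_numpy())
    log_sl_c = log_sl - np.log10(cfg.sl_mean)
    pops = morph["population"].unique()
    for trait in MORPH_TRAITS:
        pop_dev = dict(zip(pops, rng.normal(0, cfg.morph_sd_population, len(pops))))
        log_t = (
            np.log10(cfg.morph_baselines[trait])
            + cfg.morph_slopes[trait] * log_sl_c
            + morph["population"].map(pop_dev).to_numpy()
            + rng.normal(0, cfg.morph_noise_sd, len(morph))
        )
        if trait == "body_depth":
            log_t = log_t + np.where(
                morph["ecotype"] == "benthic", 0.5, -0.5
            ) * cfg.morph_benthic_body_depth_shift
        morph[trait] = 10.0**log_t
    return morph.reset_index(drop=True)


def simulate_latency(cfg: SimulationConfig, meta: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Latency to emerge (integer seconds), overdispersed, ceiling at 600 s.

    Counts are negative-binomial (Poisson if ``latency_nb_size`` is None)
    around a log-scale linear predictor with ecotype means and population
    and family deviates; values at or above the ceiling are recorded as the
    ceiling (the assay stops at 600 s).
    """
    rng = np.random.default_rng(cfg.seed + 3 if rng is None else rng)
    pops = meta["population"].unique()
    fams = meta["family"].unique()
    pop_dev = dict(zip(pops, rng.normal(0, cfg.latency_sd_population, len(pops))))
    fam_dev = dict(zip(fams, rng.normal(0, cfg.latency_sd_family, len(fams))))
    log_mu = (
        np.where(
            meta["ecotype"] == "benthic",
            np.log(cfg.latency_mean_benthic),
            np.log(cfg.latency_mean_limnetic),
        )
        + meta["population"].map(pop_dev).to_numpy()
        + meta["family"].map(fam_dev).to_numpy()
    )
    mu = np.exp(log_mu)
    if cfg.latency_nb_size is None:
        y = rng.poisson(mu)
    else:
        k = cfg.latency_nb_size
        y = rng.negative_binomial(k, k / (k + mu))
    lat = meta[["fish_id", "population", "ecotype", "family", "group_id"]].copy()
    lat["latency"] = np.minimum(y, cfg.latency_ceiling).astype(int)
    return lat


@dataclass
class SimulatedDataset:
    """Full synthetic input bundle with its generating config."""

    config: SimulationConfig
    traits: pd.DataFrame  # roster + latent traits (ground truth)
    meta: pd.DataFrame  # FishMeta columns only
    trajectories: list  # TrajectorySet per group-trial
    morphology: pd.DataFrame
    latency: pd.DataFrame


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None):
    """Generate the complete input bundle (deterministic given config + seed)."""
    from dataclasses import replace

    cfg = cfg or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    traits = simulate_traits(cfg)
    meta_cols = [
        "fish_id",
        "population",
        "ecotype",
        "family",
        "group_id",
        "standard_length",
    ]
    meta = traits[meta_cols].copy()
    trajectories = simulate_trajectories(traits, cfg)
    morphology = simulate_morphology(cfg, meta)
    latency = simulate_latency(cfg, meta)
    return SimulatedDataset(
        config=cfg,
        traits=traits,
        meta=meta,
        trajectories=trajectories,
        morphology=morphology,
        latency=latency,
    )
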