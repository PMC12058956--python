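"""Config-driven orchestration of the full analysis.

Stage order follows the study workflow: morphology (size adjustment, PCA,
ecotype/population models) -> latency to emerge (quasi-Poisson GLMMs) ->
shoaling metrics -> social networks -> behavior PCA and mixed models ->
adjusted repeatability -> trait correlations.  Every stage is a pure
function of its inputs plus the config, and the run is deterministic given
the seed; a JSON manifest records the seed, config, and SHA-256 hashes of
every table written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from shoalnet import (
    collective_metrics,
    inference,
    morphometrics,
    synthetic_data,
    trajectory_io,
)
from shoalnet.social_network import build_network

log = logging.getLogger("shoalnet")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Either ``simulation`` holds SimulationConfig overrides (synthetic run),
    or ``input_dir`` points at a directory with ``metadata.csv``,
    ``morphology.csv``, ``latency.csv`` and ``trajectories/<group>_t<trial>.csv``
    files in the canonical dialect.
    """

    outdir: str = "shoalnet_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    input_dir: str | None = None
    fps: float = 30.0
    calibration: float = 1.0
    arena_diameter: float = 120.0
    qc_missing_threshold: float = 0.02
    threshold_bl: float = 1.0
    clustering_variant: str = "onnela"
    pca_scale: bool = True
    n_boot: int = 1000
    n_perm: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, hashes: dict) -> None:
    df.to_csv(path, index=False)
    hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def load_inputs(cfg: RunConfig):
    """Load (meta, trajectories, morphology, latency) per the config."""
    if cfg.input_dir is None:
        sim_kwargs = dict(cfg.simulation)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = synthetic_data.simulate_dataset(
            synthetic_data.SimulationConfig(**sim_kwargs)
        )
        return sim.meta, sim.trajectories, sim.morphology, sim.latency
    root = Path(cfg.input_dir)
    meta = trajectory_io.read_metadata(root / "metadata.csv")
    trajectories = []
    for path in sorted((root / "trajectories").glob("*.csv")):
        gid, trial = path.stem.rsplit("_t", 1)
        fish = meta[meta["group_id"] == gid].sort_values("fish_id")
        trajectories.append(
            trajectory_io.read_trajectories(
                path,
                fps=cfg.fps,
                calibration=cfg.calibration,
                group_id=gid,
                trial=int(trial),
                fish_ids=list(fish["fish_id"]),
                body_lengths=dict(zip(fish["fish_id"], fish["standard_length"])),
                arena_diameter=cfg.arena_diameter,
            )
        )
    morph = pd.read_csv(root / "morphology.csv", dtype={"fish_id": str})
    latency = pd.read_csv(root / "latency.csv", dtype={"fish_id": str})
    return meta, trajectories, morph, latency


def _model_rows(result, response):
    chi2, df, p = result.wald_for(result.wald.iloc[0]["term"])
    return {
        "response": response,
        "term": result.wald.iloc[0]["term"],
        "chi2": chi2,
        "df": df,
        "p": p,
        "n": result.n,
        "dispersion": result.dispersion,
    }


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the result bundle and writes CSVs + manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashes: dict = {}
    rng = np.random.default_rng(cfg.seed)
    bundle: dict = {}
    stage = "load"
    try:
        meta, trajectories, morph, latency = load_inputs(cfg)
        trajectory_io.validate_metadata(meta)

        stage = "morphology"
        log.info("stage %s", stage)
        morph_adj, slopes = morphometrics.adjust_morphology(morph)
        adj_cols = [f"{t}_adj" for t in morphometrics.MORPH_TRAITS]
        pca_m = inference.run_pca(morph_adj[adj_cols], scale=cfg.pca_scale)
        morph_scores = morph_adj[["fish_id", "population", "ecotype"]].copy()
        morph_scores["family"] = morph_scores["fish_id"].map(
            meta.set_index("fish_id")["family"]
        )
        morph_scores[["PC1_M", "PC2_M"]] = pca_m.scores[["PC1", "PC2"]].to_numpy()
        model_rows = []
        for pc in ("PC1_M", "PC2_M"):
            model_rows.append(
                _model_rows(
                    inference.fit_ecotype_model(morph_scores, pc, include_group=False),
                    pc,
                )
            )
            pop_m = inference.fit_population_model(
                morph_scores, pc, include_group=False
            )
            model_rows.append(_model_rows(pop_m, pc))
        bundle["morphology"] = morph_adj
        bundle["morph_slopes"] = slopes
        bundle["pca_morphology"] = pca_m
        _write(morph_adj, outdir / "morphology_adjusted.csv", hashes)

        stage = "latency"
        log.info("stage %s", stage)
        lat = latency.copy()
        model_rows.append(
            _model_rows(
                inference.fit_latency_model(lat, "latency", fixed="ecotype"),
                "latency",
            )
        )
        model_rows.append(
            _model_rows(
                inference.fit_latency_model(lat, "latency", fixed="population"),
                "latency",
            )
        )

        stage = "metrics"
        log.info("stage %s", stage)
        btable = collective_metrics.behavior_table(
            trajectories,
            meta,
            threshold_bl=cfg.threshold_bl,
            clustering_variant=cfg.clustering_variant,
            qc_missing_threshold=cfg.qc_missing_threshold,
        )
        bundle["behavior"] = btable
        _write(btable.individual, outdir / "behavior_individual.csv", hashes)
        _write(btable.pairs, outdir / "behavior_pairs.csv", hashes)

        stage = "networks"
        log.info("stage %s", stage)
        edges = []
        for (gid, trial), _ in btable.pairs.groupby(["group_id", "trial"]):
            net = build_network(btable, gid, trial)
            el = net.edge_list()
            el.insert(0, "group_id", gid)
            el.insert(1, "trial", trial)
            edges.append(el)
        edges = pd.concat(edges, ignore_index=True)
        _write(edges, outdir / "network_edges.csv", hashes)

        stage = "behavior_pca"
        log.info("stage %s", stage)
        means = inference.mean_across_trials(btable)
        pca_cb = inference.run_pca(
            means[list(inference.BEHAVIORS)], scale=cfg.pca_scale
        )
        means[["PC1_CB", "PC2_CB"]] = pca_cb.scores[["PC1", "PC2"]].to_numpy()
        bundle["behavior_means"] = means
        bundle["pca_behavior"] = pca_cb
        _write(means, outdir / "behavior_means.csv", hashes)

        stage = "models"
        log.info("stage %s", stage)
        posthoc_tables = {}
        for pc in ("PC1_CB", "PC2_CB"):
            model_rows.append(
                _model_rows(inference.fit_ecotype_model(means, pc), pc)
            )
            pop_fit = inference.fit_population_model(means, pc)
            model_rows.append(_model_rows(pop_fit, pc))
            posthoc = inference.posthoc_pairwise(pop_fit, "population")
            posthoc.insert(0, "response", pc)
            posthoc_tables[pc] = posthoc
        models = pd.DataFrame(model_rows)
        bundle["models"] = models
        _write(models, outdir / "mixed_models.csv", hashes)
        posthoc_all = pd.concat(posthoc_tables.values(), ignore_index=True)
        _write(posthoc_all, outdir / "posthoc_contrasts.csv", hashes)
        bundle["posthoc"] = posthoc_tables

        stage = "repeatability"
        log.info("stage %s", stage)
        rep_rows = []
        for beh in inference.BEHAVIORS:
            res = inference.adjusted_repeatability(
                btable.individual,
                beh,
                transform=inference.DEFAULT_TRANSFORMS[beh],
                n_boot=cfg.n_boot,
                n_perm=cfg.n_perm,
                rng=rng.spawn(1)[0],
            )
            rep_rows.append(res)
        pairs = btable.pairs.copy()
        pairs["pair_id"] = pairs["fish_i"] + ":" + pairs["fish_j"]
        rep_rows.append(
            inference.adjusted_repeatability(
                pairs,
                "interaction_time",
                id_col="pair_id",
                transform=inference.DEFAULT_TRANSFORMS["interaction_time"],
                n_boot=cfg.n_boot,
                n_perm=cfg.n_perm,
                rng=rng.spawn(1)[0],
                label="pairwise_interaction",
            )
        )
        rep = pd.DataFrame(
            [
                {
                    "behavior": r.label,
                    "R": r.R,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_boot": r.p_boot,
                    "p_perm": r.p_perm,
                    "transform": r.transform,
                    "n_boot": r.n_boot,
                    "n_perm": r.n_perm,
                }
                for r in rep_rows
            ]
        )
        bundle["repeatability"] = rep
        _write(rep, outdir / "repeatability.csv", hashes)

        stage = "correlations"
        log.info("stage %s", stage)
        joint = means.merge(
            morph_scores[["fish_id", "PC1_M", "PC2_M"]], on="fish_id", how="inner"
        ).merge(lat[["fish_id", "latency"]], on="fish_id", how="left")
        cors = []
        pairs_to_test = [
            ("PC1_M", "PC1_CB"),
            ("PC1_M", "PC2_CB"),
            ("PC2_M", "PC1_CB"),
            ("PC2_M", "PC2_CB"),
            ("latency", "PC1_CB"),
            ("latency", "PC2_CB"),
            ("latency", "PC1_M"),
            ("latency", "PC2_M"),
        ]
        for a, b in pairs_to_test:
            sub = joint[[a, b]].dropna()
            sp = inference.spearman(
                sub[a], sub[b], n_boot=cfg.n_boot, rng=rng.spawn(1)[0]
            )
            cors.append(
                {
                    "x": a,
                    "y": b,
                    "rho": sp.rho,
                    "ci_low": sp.ci_low,
                    "ci_high": sp.ci_high,
                    "p": sp.p,
                    "n": sp.n,
                }
            )
        cors = pd.DataFrame(cors)
        bundle["correlations"] = cors
        _write(cors, outdir / "spearman_correlations.csv", hashes)

        stage = "manifest"
        pca_tables = pd.concat(
            [
                pca_m.loadings.assign(
                    pca="morphology", variable=pca_m.loadings.index
                ),
                pca_cb.loadings.assign(
                    pca="behavior", variable=pca_cb.loadings.index
                ),
            ],
            ignore_index=True,
        )
        _write(pca_tables, outdir / "pca_loadings.csv", hashes)
        manifest = {
            "seed": cfg.seed,
            "config": asdict(cfg),
            "clustering_variant": cfg.clustering_variant,
            "pca_variance_explained": {
                "morphology": pca_m.variance_explained.tolist(),
                "behavior": pca_cb.variance_explained.tolist(),
            },
            "allometric_slopes": slopes,
            "n_individual_obs": int(len(btable.individual)),
            "n_pair_obs": int(len(btable.pairs)),
            "tables": hashes,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        bundle["manifest"] = manifest
        return bundle
    except Exception as err:
        log.error("pipeline failed at stage %r: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def write_simulated_inputs(sim, outdir) -> None:
    """Dump a SimulatedDataset as the canonical on-disk input bundle."""
    outdir = Path(outdir)
    (outdir / "trajectories").mkdir(parents=True, exist_ok=True)
    sim.meta.to_csv(outdir / "metadata.csv", index=False)
    sim.morphology.to_csv(outdir / "morphology.csv", index=False)
    sim.latency.to_csv(outdir / "latency.csv", index=False)
    sim.traits.to_csv(outdir / "ground_truth_traits.csv", index=False)
    with open(outdir / "ground_truth_config.json", "w") as fh:
        json.dump(asdict(sim.config), fh, indent=2, default=str)
    for t in sim.trajectories:
        trajectory_io.write_trajectories(
            t, outdir / "trajectories" / f"{t.group_id}_t{t.trial}.csv"
        )
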