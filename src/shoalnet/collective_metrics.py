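"""Frame-level collective-behavior metrics for 8-fish shoals.

Four individual-level phenotypes are computed per fish per trial:

* **activity** — total distance swum (cm), summed over consecutive frames;
* **cohesion** — mean distance (cm) from the group centroid (lower values
  mean a tighter shoal);
* **strength** — sum of a fish's pairwise interaction times (s), i.e. the
  node strength in the proximity network;
* **clustering** — weighted local clustering coefficient of the proximity
  network (dimensionless, in [0, 1]).

plus one pair-level phenotype, the **social interaction rate**: the time (s)
a pair spends within one body length of each other.  All metrics are
computed on complete frames only (frames where every fish was detected).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from shoalnet.trajectory_io import (
    N_FISH,
    TrajectorySet,
    filter_complete_frames,
)


class UndefinedMetricError(ValueError):
    """Metric has no defined value on the given frames (too few / empty)."""


class IncompleteDesignError(ValueError):
    """A group is missing one of its two trials."""


def _require_complete(t: TrajectorySet) -> None:
    if not t.complete_mask().all():
        raise ValueError(
            "metrics require complete frames only; run filter_complete_frames first"
        )


def activity(t: TrajectorySet, fish) -> float:
    """Distance swum (cm): sum of Euclidean step lengths between frames.

    Steps are only accumulated between retained frames whose original video
    frame numbers are adjacent, so gaps left by excluded (incomplete) frames
    contribute no distance and cannot inflate the estimate.
    """
    _require_complete(t)
    if t.n_frames < 2:
        raise UndefinedMetricError("activity needs at least 2 frames")
    k = t.fish_index(fish)
    pos = t.positions[:, k, :]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    adjacent = np.diff(t.frame_index) == 1
    return float(steps[adjacent].sum())


def cohesion(t: TrajectorySet, fish) -> float:
    """Mean distance (cm) of a fish from the centroid of all 8 fish."""
    _require_complete(t)
    if t.n_frames == 0:
        raise UndefinedMetricError("cohesion needs at least 1 frame")
    k = t.fish_index(fish)
    centroid = t.positions.mean(axis=1)
    d = np.linalg.norm(t.positions[:, k, :] - centroid, axis=1)
    return float(d.mean())


def pair_body_length(t: TrajectorySet, i, j, rule: str = "pair_mean") -> float:
    """Body-length scale (cm) for the pair interaction threshold.

    ``pair_mean`` (default): mean of the two fish's standard lengths.
    ``focal``: the first fish's standard length (asymmetric; for
    sensitivity analyses only).  ``group_mean``: mean over all 8 fish.
    """
    bl = t.body_lengths
    if rule == "pair_mean":
        return 0.5 * (bl[i] + bl[j])
    if rule == "focal":
        return float(bl[i])
    if rule == "group_mean":
        return float(np.mean([bl[f] for f in t.fish_ids]))
    raise ValueError(f"unknown body-length rule {rule!r}")


def interaction_time(
    t: TrajectorySet,
    i,
    j,
    threshold_bl: float = 1.0,
    bl_rule: str = "pair_mean",
) -> float:
    """Time (s) fish i and j spent within ``threshold_bl`` body lengths.

    The distance is between tracker centers of mass; a frame counts when
    distance <= threshold_bl * BL(i, j).  Symmetric in (i, j) under the
    default pair-mean body-length rule.
    """
    _require_complete(t)
    if i == j:
        raise ValueError("interaction_time requires two distinct fish")
    ki, kj = t.fish_index(i), t.fish_index(j)
    d = np.linalg.norm(t.positions[:, ki, :] - t.positions[:, kj, :], axis=1)
    thresh = threshold_bl * pair_body_length(t, i, j, bl_rule)
    return float((d <= thresh).sum() / t.fps)


def _pairwise_times(t: TrajectorySet, threshold_bl: float, bl_rule: str):
    """All 28 pair interaction times at once (vectorized over frames)."""
    pos = t.positions  # (F, 8, 2)
    diff = pos[:, :, None, :] - pos[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)  # (F, 8, 8)
    out = {}
    for ki, kj in combinations(range(N_FISH), 2):
        i, j = t.fish_ids[ki], t.fish_ids[kj]
        thresh = threshold_bl * pair_body_length(t, i, j, bl_rule)
        out[(i, j)] = float((dist[:, ki, kj] <= thresh).sum() / t.fps)
    return out


@dataclass
class BehaviorTable:
    """Tidy behavior tables for a full study design.

    ``individual``: one row per (fish_id, trial) with columns activity,
    cohesion, strength, clustering (480 rows at the full 240-fish x 2-trial
    design).  ``pairs``: one row per unordered fish pair per trial with
    column interaction_time (1680 rows at full design: 28 pairs x 30 groups
    x 2 trials).  Metadata columns (population, ecotype, family, group_id)
    are merged in when available.
    """

    individual: pd.DataFrame
    pairs: pd.DataFrame

    def network_weights(self, group_id, trial) -> pd.DataFrame:
        sub = self.pairs[
            (self.pairs["group_id"] == group_id) & (self.pairs["trial"] == trial)
        ]
        return sub[["fish_i", "fish_j", "interaction_time"]]

    def to_csv(self, individual_path, pairs_path) -> None:
        self.individual.to_csv(individual_path, index=False)
        self.pairs.to_csv(pairs_path, index=False)


def behavior_table(
    trajectories,
    meta: pd.DataFrame | None = None,
    *,
    threshold_bl: float = 1.0,
    bl_rule: str = "pair_mean",
    clustering_variant: str = "onnela",
    prefiltered: bool = False,
    qc_missing_threshold: float = 0.02,
) -> BehaviorTable:
    """Compute the full BehaviorTable from a collection of TrajectorySets.

    Every group must contribute trials 1 and 2.  Strength and clustering
    are computed from the pairwise proximity network (see
    :mod:`shoalnet.social_network`).  Input sets may contain incomplete
    frames; they are filtered here unless ``prefiltered`` is set.
    """
    from shoalnet import social_network  # deferred: circular at import time

    seen = {}
    for t in trajectories:
        key = (t.group_id, t.trial)
        if key in seen:
            raise ValueError(f"duplicate trajectory for group {key}")
        seen[key] = t
    groups = sorted({g for g, _ in seen})
    missing = [
        (g, trial) for g in groups for trial in (1, 2) if (g, trial) not in seen
    ]
    if missing:
        raise IncompleteDesignError(
            f"missing group-trials: {missing} (each group needs trials 1 and 2)"
        )

    ind_rows, pair_rows = [], []
    for (group_id, trial), t in sorted(seen.items()):
        if not prefiltered:
            t, _ = filter_complete_frames(t, qc_missing_threshold)
        times = _pairwise_times(t, threshold_bl, bl_rule)
        for (i, j), w in times.items():
            pair_rows.append(
                {
                    "fish_i": i,
                    "fish_j": j,
                    "group_id": group_id,
                    "trial": trial,
                    "interaction_time": w,
                }
            )
        net = social_network.SocialNetwork.from_pair_times(
            t.fish_ids, times, group_id=group_id, trial=trial
        )
        clus = social_network.weighted_clustering_all(net, clustering_variant)
        for fish in t.fish_ids:
            ind_rows.append(
                {
                    "fish_id": fish,
                    "group_id": group_id,
                    "trial": trial,
                    "activity": activity(t, fish),
                    "cohesion": cohesion(t, fish),
                    "strength": social_network.strength(net, fish),
                    "clustering": clus[fish],
                }
            )

    individual = pd.DataFrame(ind_rows)
    pairs = pd.DataFrame(pair_rows)
    if meta is not None:
        keep = ["fish_id", "population", "ecotype", "family", "standard_length"]
        keep = [c for c in keep if c in meta.columns]
        individual = individual.merge(meta[keep], on="fish_id", how="left")
        if "population" in meta.columns:
            gmeta = meta[["group_id", "population", "ecotype"]].drop_duplicates()
            pairs = pairs.merge(gmeta, on="group_id", how="left")
    return BehaviorTable(individual=individual, pairs=pairs)
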