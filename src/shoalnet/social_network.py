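"""Weighted proximity networks and node-level metrics.

Each group-trial yields an 8-node undirected network: nodes are fish,
edge weights are pairwise interaction times (seconds spent within one body
length of each other).  Two node metrics are computed:

* **strength** — sum of edge weights at a node, the weighted analogue of
  degree;
* **weighted local clustering** — how strongly a node's neighbours are
  themselves connected ("are my friends friends with each other?").

Three clustering variants are available.  The default is the Onnela
cube-root form, which still varies with edge weights on topologically
complete graphs — the usual situation for 8 fish sharing a small arena,
where every pair interacts at least briefly.  The Barrat form (and the
Clemente–Grassi strength-based form, which coincides with it on undirected
graphs) is identically 1 on complete graphs, so it discards all weight
information exactly where these data live; both are provided for
cross-checks and sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from shoalnet.trajectory_io import N_FISH

CLUSTERING_VARIANTS = ("onnela", "barrat", "clemente_grassi")


class IncompleteNetworkError(ValueError):
    """Pair rows for some of the 28 pairs are missing."""


@dataclass
class SocialNetwork:
    """Symmetric weighted interaction network for one group-trial."""

    fish_ids: list
    W: np.ndarray  # (8, 8) seconds, symmetric, zero diagonal
    group_id: str = ""
    trial: int = 1

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.fish_ids), len(self.fish_ids)):
            raise ValueError("weight matrix shape does not match node count")
        if np.any(self.W < 0):
            raise ValueError("negative edge weight")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal must be zero")

    @classmethod
    def from_pair_times(cls, fish_ids, pair_times: dict, group_id="", trial=1):
        """Build from a dict {(fish_i, fish_j): seconds} covering all pairs."""
        fish_ids = list(fish_ids)
        n = len(fish_ids)
        idx = {f: k for k, f in enumerate(fish_ids)}
        W = np.zeros((n, n))
        for (i, j), w in pair_times.items():
            W[idx[i], idx[j]] = W[idx[j], idx[i]] = w
        return cls(fish_ids=fish_ids, W=W, group_id=group_id, trial=trial)

    def node_index(self, fish) -> int:
        try:
            return self.fish_ids.index(fish)
        except ValueError:
            raise KeyError(f"unknown fish id {fish!r}") from None

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.fish_ids)
        n = len(self.fish_ids)
        for a in range(n):
            for b in range(a + 1, n):
                if self.W[a, b] > 0:
                    G.add_edge(self.fish_ids[a], self.fish_ids[b], weight=self.W[a, b])
        return G

    def edge_list(self) -> pd.DataFrame:
        """Weighted edge list (all pairs, including zero-weight) as a DataFrame."""
        rows = []
        n = len(self.fish_ids)
        for a in range(n):
            for b in range(a + 1, n):
                rows.append(
                    {
                        "fish_i": self.fish_ids[a],
                        "fish_j": self.fish_ids[b],
                        "weight": self.W[a, b],
                    }
                )
        return pd.DataFrame(rows)


def build_network(b, group_id, trial) -> SocialNetwork:
    """Assemble the SocialNetwork for one group-trial from a BehaviorTable.

    Raises :class:`IncompleteNetworkError` unless all 28 pair rows exist.
    """
    sub = b.network_weights(group_id, trial)
    fish = sorted(set(sub["fish_i"]) | set(sub["fish_j"]))
    n_expected = N_FISH * (N_FISH - 1) // 2
    if len(fish) != N_FISH or len(sub) != n_expected:
        raise IncompleteNetworkError(
            f"group {group_id} trial {trial}: found {len(sub)} pair rows over "
            f"{len(fish)} fish, need {n_expected} rows over {N_FISH} fish"
        )
    times = {
        (r.fish_i, r.fish_j): r.interaction_time for r in sub.itertuples(index=False)
    }
    return SocialNetwork.from_pair_times(fish, times, group_id=group_id, trial=trial)


def strength(net: SocialNetwork, fish) -> float:
    """Node strength: sum of all edge weights at the node (seconds)."""
    return float(net.W[net.node_index(fish)].sum())


def degenerate_nodes(net: SocialNetwork) -> set:
    """Nodes with fewer than 2 positive edges; clustering there is set to 0."""
    k = (net.W > 0).sum(axis=1)
    return {f for f, kk in zip(net.fish_ids, k) if kk < 2}


def _clustering_vector(W: np.ndarray, variant: str) -> np.ndarray:
    A = (W > 0).astype(float)
    k = A.sum(axis=1)
    s = W.sum(axis=1)
    n = len(W)
    out = np.zeros(n)
    ok = k >= 2
    if variant == "onnela":
        wmax = W.max()
        if wmax == 0:
            return out
        Wh = np.cbrt(W / wmax)
        tri = np.diag(Wh @ Wh @ Wh)
        out[ok] = tri[ok] / (k[ok] * (k[ok] - 1))
    elif variant in ("barrat", "clemente_grassi"):
        # On undirected graphs the Clemente-Grassi strength-based coefficient
        # reduces algebraically to Barrat's: (W A^2)_ii / (s_i (k_i - 1)).
        tri = np.diag(W @ A @ A)
        denom = s * (k - 1)
        ok = ok & (denom > 0)
        out[ok] = tri[ok] / denom[ok]
    else:
        raise ValueError(
            f"unknown clustering variant {variant!r}; choose from {CLUSTERING_VARIANTS}"
        )
    return out


def weighted_clustering(net: SocialNetwork, fish, variant: str = "onnela") -> float:
    """Weighted local clustering coefficient of one node, in [0, 1].

    Onnela (default): C_i = ((W-hat^{1/3})^3)_ii / (k_i (k_i - 1)) with
    W-hat = W / max(W).  Barrat / Clemente-Grassi:
    C_i = (W A^2)_ii / (s_i (k_i - 1)).  Isolated nodes and nodes with a
    single edge have no defined triangle fraction and return 0 (see
    :func:`degenerate_nodes` for the flag).
    """
    return float(_clustering_vector(net.W, variant)[net.node_index(fish)])


def weighted_clustering_all(net: SocialNetwork, variant: str = "onnela") -> dict:
    """Clustering coefficients for every node as {fish_id: value}."""
    vec = _clustering_vector(net.W, variant)
    return {f: float(v) for f, v in zip(net.fish_ids, vec)}
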