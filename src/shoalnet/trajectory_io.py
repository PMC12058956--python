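"""Reading, validation and frame-filtering of multi-individual trajectories.

The canonical on-disk dialect is a CSV with header ``frame,x1,y1,...,x8,y8``,
one file per group-trial, holding the tracker's center-of-mass coordinates
for each of the 8 identified individuals in every video frame.  Missing
detections are encoded as empty fields / NA.  Coordinates are converted to
centimetres (origin at the arena center) via a calibration factor supplied
by the caller, since pixel scale varies between recording setups.

A companion manifest (the per-fish metadata table) maps column index to
fish identity; see :func:`read_metadata`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

N_FISH = 8
DEFAULT_ARENA_DIAMETER_CM = 120.0
DEFAULT_QC_MISSING_THRESHOLD = 0.02


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (header, frame order, or column count)."""


class EmptyDataError(ValueError):
    """No usable frames remain after filtering."""


class MissingFramesWarning(UserWarning):
    """Fraction of incomplete frames exceeded the QC threshold."""


@dataclass
class TrajectorySet:
    """Per-frame positions of one 8-fish group in one trial.

    Attributes
    ----------
    group_id : str
        Identifier of the experimental group.
    trial : int
        Trial number (1 or 2; each group is assayed twice).
    fps : float
        Video frame rate, frames per second.
    fish_ids : list of str
        The 8 member identities, in column order of ``positions``.
    positions : ndarray, shape (n_frames, 8, 2)
        (x, y) coordinates in cm, origin at the arena center.  NaN marks a
        missing detection.
    frame_index : ndarray of int, shape (n_frames,)
        Original (strictly increasing) video frame numbers; retained across
        filtering so that gaps from excluded frames stay visible.
    body_lengths : dict
        fish_id -> standard length in cm (used for the pairwise
        interaction-distance threshold).
    arena_diameter : float
        Arena diameter in cm.
    """

    group_id: str
    trial: int
    fps: float
    fish_ids: list
    positions: np.ndarray
    frame_index: np.ndarray
    body_lengths: dict = field(default_factory=dict)
    arena_diameter: float = DEFAULT_ARENA_DIAMETER_CM

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (N_FISH, 2):
            raise TrajectoryFormatError(
                f"positions must have shape (n_frames, {N_FISH}, 2), "
                f"got {self.positions.shape}"
            )
        if len(self.fish_ids) != N_FISH:
            raise TrajectoryFormatError(
                f"expected {N_FISH} fish ids, got {len(self.fish_ids)}"
            )
        if len(self.frame_index) != len(self.positions):
            raise TrajectoryFormatError("frame_index length mismatch")
        if len(self.frame_index) > 1 and np.any(np.diff(self.frame_index) <= 0):
            bad = int(np.argmax(np.diff(self.frame_index) <= 0)) + 1
            raise TrajectoryFormatError(
                f"frame indices not strictly increasing at row {bad}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def complete_mask(self) -> np.ndarray:
        """Boolean mask of frames where all 8 fish were detected."""
        return ~np.isnan(self.positions).any(axis=(1, 2))

    def fish_index(self, fish_id) -> int:
        try:
            return self.fish_ids.index(fish_id)
        except ValueError:
            raise KeyError(f"unknown fish id {fish_id!r}") from None


def _coordinate_columns():
    cols = []
    for i in range(1, N_FISH + 1):
        cols += [f"x{i}", f"y{i}"]
    return cols


def read_trajectories(
    path,
    fps: float,
    calibration: float = 1.0,
    *,
    group_id: str = "",
    trial: int = 1,
    fish_ids=None,
    body_lengths=None,
    arena_diameter: float = DEFAULT_ARENA_DIAMETER_CM,
) -> TrajectorySet:
    """Read a trajectory CSV and scale coordinates to cm.

    Parameters
    ----------
    path : path-like
        CSV with header ``frame,x1,y1,...,x8,y8``; missing detections as NA.
    fps : float
        Frame rate of the source video.
    calibration : float
        cm per coordinate unit (1.0 if the file is already in cm).
    fish_ids : sequence of str, optional
        Identities for columns 1..8; defaults to ``f1..f8``.

    Raises
    ------
    TrajectoryFormatError
        On a malformed header, a wrong number of coordinate pairs, or
        non-monotone frame numbers (the error message names the offender).
    """
    df = pd.read_csv(path)
    expected = ["frame"] + _coordinate_columns()
    got = list(df.columns)
    if got != expected:
        n_pairs = sum(c.startswith("x") for c in got)
        if n_pairs != N_FISH:
            raise TrajectoryFormatError(
                f"{path}: expected {N_FISH} coordinate pairs, found {n_pairs} "
                f"(header: {','.join(got)})"
            )
        raise TrajectoryFormatError(
            f"{path}: malformed header {','.join(got)!r}; expected "
            f"{','.join(expected)!r}"
        )
    frames = df["frame"].to_numpy()
    if np.any(pd.isna(frames)):
        raise TrajectoryFormatError(f"{path}: NA frame number")
    positions = df[_coordinate_columns()].to_numpy(dtype=float)
    positions = positions.reshape(-1, N_FISH, 2) * float(calibration)
    # a half-missing detection (x without y) is treated as missing
    half = np.isnan(positions).any(axis=2) & ~np.isnan(positions).all(axis=2)
    positions[half] = np.nan
    if fish_ids is None:
        fish_ids = [f"f{i}" for i in range(1, N_FISH + 1)]
    try:
        return TrajectorySet(
            group_id=group_id,
            trial=trial,
            fps=fps,
            fish_ids=list(fish_ids),
            positions=positions,
            frame_index=frames.astype(int),
            body_lengths=dict(body_lengths or {}),
            arena_diameter=arena_diameter,
        )
    except TrajectoryFormatError as err:
        raise TrajectoryFormatError(f"{path}: {err}") from None


def write_trajectories(t: TrajectorySet, path, float_format: str = "%.6f") -> None:
    """Write a TrajectorySet in the canonical CSV dialect (coordinates in cm)."""
    data = {"frame": t.frame_index}
    flat = t.positions.reshape(len(t.frame_index), -1)
    for k, col in enumerate(_coordinate_columns()):
        data[col] = flat[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)


def filter_complete_frames(
    t: TrajectorySet,
    qc_missing_threshold: float = DEFAULT_QC_MISSING_THRESHOLD,
):
    """Drop frames where any of the 8 fish was not detected.

    All collective metrics are computed on complete frames only, because the
    group centroid and the full set of pairwise distances require all eight
    individuals.

    Returns
    -------
    (TrajectorySet, float)
        The filtered set (original frame numbers preserved) and the missing
        fraction ``1 - kept/total``.  If the missing fraction exceeds
        ``qc_missing_threshold`` (default 2%, the QC level expected of a
        well-tracked video) a :class:`MissingFramesWarning` is emitted and
        the data are still returned.

    Raises
    ------
    EmptyDataError
        If no complete frame remains.
    """
    total = t.n_frames
    if total == 0:
        raise EmptyDataError(f"{t.group_id} trial {t.trial}: no frames")
    mask = t.complete_mask()
    kept = int(mask.sum())
    if kept == 0:
        raise EmptyDataError(
            f"{t.group_id} trial {t.trial}: zero complete frames out of {total}"
        )
    missing_fraction = 1.0 - kept / total
    if missing_fraction > qc_missing_threshold + 1e-12:
        warnings.warn(
            f"{t.group_id} trial {t.trial}: {missing_fraction:.1%} of frames "
            f"incomplete (QC threshold {qc_missing_threshold:.1%})",
            MissingFramesWarning,
            stacklevel=2,
        )
    filtered = replace(
        t, positions=t.positions[mask], frame_index=t.frame_index[mask]
    )
    return filtered, missing_fraction


METADATA_COLUMNS = [
    "fish_id",
    "population",
    "ecotype",
    "family",
    "group_id",
    "standard_length",
]

ECOTYPES = ("benthic", "limnetic")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the per-fish metadata table.

    Columns: fish_id, population, ecotype (benthic/limnetic), family
    (nested in population), group_id, standard_length (cm).  Validates the
    nesting structure: ecotype and family constant within population, and
    every group drawn from a single population.
    """
    df = pd.read_csv(path, dtype={"fish_id": str, "group_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing metadata columns {missing}")
    validate_metadata(df)
    return df


def validate_metadata(df: pd.DataFrame) -> None:
    bad = set(df["ecotype"]) - set(ECOTYPES)
    if bad:
        raise ValueError(f"unknown ecotype values {sorted(bad)}")
    if df["fish_id"].duplicated().any():
        raise ValueError("duplicate fish_id in metadata")
    eco_per_pop = df.groupby("population")["ecotype"].nunique()
    if (eco_per_pop > 1).any():
        raise ValueError(
            "ecotype varies within population(s): "
            f"{list(eco_per_pop[eco_per_pop > 1].index)}"
        )
    pops_per_family = df.groupby("family")["population"].nunique()
    if (pops_per_family > 1).any():
        raise ValueError("family assigned to more than one population")
    pops_per_group = df.groupby("group_id")["population"].nunique()
    if (pops_per_group > 1).any():
        raise ValueError(
            "group contains fish from more than one population: "
            f"{list(pops_per_group[pops_per_group > 1].index)}"
        )
    group_sizes = df.groupby("group_id").size()
    if (group_sizes != N_FISH).any():
        raise ValueError(
            f"groups must contain exactly {N_FISH} fish; offending groups: "
            f"{list(group_sizes[group_sizes != N_FISH].index)}"
        )
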