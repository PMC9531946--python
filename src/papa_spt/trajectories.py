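"""Trajectory container shared across the simulation and analysis modules.

Trajectories live in a tidy :class:`pandas.DataFrame` with one row per
localization and at minimum the columns ``trajectory, frame, x_um, y_um``.
Extra columns (ground-truth ``component`` / ``double_labeled`` labels from
the simulator, PAPA/DR ``class`` labels from the classifier, intensities
from the tracker) ride along unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TrajectorySet", "read_trajectories", "write_trajectories"]

REQUIRED_COLUMNS = ("trajectory", "frame", "x_um", "y_um")


@dataclass
class TrajectorySet:
    """A set of 2-D single-molecule trajectories.

    Invariants: frames are strictly increasing within a trajectory; all
    coordinates are finite.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required trajectory columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    # -- basic queries ---------------------------------------------------

    @property
    def n_localizations(self) -> int:
        return len(self.df)

    @property
    def n_trajectories(self) -> int:
        return int(self.df["trajectory"].nunique())

    def __len__(self) -> int:
        return self.n_trajectories

    def trajectory_ids(self) -> np.ndarray:
        return self.df["trajectory"].unique()

    def subset(self, ids: Iterable) -> "TrajectorySet":
        ids = pd.unique(pd.Series(list(ids)))
        out = self.df[self.df["trajectory"].isin(ids)].copy()
        return TrajectorySet(out)

    def lengths(self) -> pd.Series:
        """Number of localizations per trajectory."""
        return self.df.groupby("trajectory", sort=False).size()

    # -- displacement statistics ----------------------------------------

    def jump_stats(self) -> pd.DataFrame:
        """Per-trajectory count and sum of squared 2-D displacements.

        Only consecutive-frame displacements are counted; jumps spanning a
        gap are excluded. Trajectories with zero usable jumps are dropped.
        Returns a frame with columns ``trajectory, n_jumps, sum_r2``.
        """
        df = self.df.sort_values(["trajectory", "frame"], kind="stable")
        same = df["trajectory"].to_numpy()[1:] == df["trajectory"].to_numpy()[:-1]
        dframe = np.diff(df["frame"].to_numpy())
        dx = np.diff(df["x_um"].to_numpy())
        dy = np.diff(df["y_um"].to_numpy())
        ok = same & (dframe == 1)
        r2 = dx**2 + dy**2
        traj = df["trajectory"].to_numpy()[1:][ok]
        agg = pd.DataFrame({"trajectory": traj, "r2": r2[ok]}).groupby(
            "trajectory", sort=False
        )["r2"]
        out = pd.DataFrame(
            {"n_jumps": agg.size(), "sum_r2": agg.sum()}
        ).reset_index()
        return out

    def concat(self, other: "TrajectorySet", relabel: bool = False) -> "TrajectorySet":
        a, b = self.df.copy(), other.df.copy()
        if relabel:
            b = b.copy()
            offset = (a["trajectory"].max() + 1) if len(a) else 0
            b["trajectory"] = b["trajectory"] + offset
        return TrajectorySet(pd.concat([a, b], ignore_index=True))


def write_trajectories(trajectories: TrajectorySet, path: "str | Path") -> None:
    """Write a trajectory CSV (lossless round-trip, extra columns kept)."""
    trajectories.df.to_csv(path, index=False)


def read_trajectories(path: "str | Path") -> TrajectorySet:
    """Read a trajectory CSV.

    Frames are sorted within each trajectory on read; a warning is issued
    if the file was unsorted. Missing required columns raise a
    ``ValueError`` naming them.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required trajectory columns: {missing}")
    sorted_df = df.sort_values(["trajectory", "frame"], kind="stable").reset_index(
        drop=True
    )
    frames_unsorted = not (
        df.groupby("trajectory", sort=False)["frame"]
        .apply(lambda s: bool(s.is_monotonic_increasing))
        .all()
    ) if len(df) else False
    if frames_unsorted:
        warnings.warn("trajectory file had unsorted frames; sorted on read")
    return TrajectorySet(sorted_df)
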