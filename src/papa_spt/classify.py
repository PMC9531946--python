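"""Classify trajectories into PAPA and DR sets; single-molecule scoring.

PAPA trajectories are segments observed within the first ``window``
frames after a green (561 nm) pulse; DR trajectories follow violet
(405 nm) pulses. Localizations outside all windows are dropped, and a
long-lived source trajectory may contribute segments to several windows
(each segment gets its own id and a reference to its source pulse).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .illumination import Channel, IlluminationProtocol, ProtocolError
from .trajectories import TrajectorySet

__all__ = [
    "split_trajectories",
    "balance",
    "select_isolated",
    "score_persistence",
    "segment_summary",
]

logger = logging.getLogger(__name__)


def _window_lookup(
    windows: Sequence[tuple[int, int]], n_frames: int
) -> np.ndarray:
    """frame -> window index (or -1 outside all windows)."""
    lut = np.full(n_frames, -1, dtype=int)
    for i, (a, b) in enumerate(windows):
        lut[a:b] = i
    return lut


def _extract_class(
    df: pd.DataFrame,
    windows: Sequence[tuple[int, int]],
    pulse_frames: np.ndarray,
    n_frames: int,
    label: str,
) -> pd.DataFrame:
    lut = _window_lookup(windows, n_frames)
    frames = df["frame"].to_numpy(dtype=int)
    widx = lut[frames]
    sel = df[widx >= 0].copy()
    sel["source_trajectory"] = sel["trajectory"]
    sel["source_pulse"] = pulse_frames[widx[widx >= 0]]
    sel["class"] = label
    # one segment per (source trajectory, window)
    sel["trajectory"] = sel.groupby(
        ["source_trajectory", "source_pulse"], sort=True
    ).ngroup()
    return sel.reset_index(drop=True)


def split_trajectories(
    trajectories: TrajectorySet,
    protocol: IlluminationProtocol,
    window: int = 30,
) -> tuple[TrajectorySet, TrajectorySet]:
    """Split into (PAPA, DR) segment sets by post-pulse windows.

    A trajectory overlapping a window is clipped to the window; its
    localizations inside become one segment. Overlap between green and
    violet windows is a protocol error.
    """
    green_w = protocol.post_pulse_windows(Channel.GREEN, window)
    violet_w = protocol.post_pulse_windows(Channel.VIOLET, window)
    for a, b in green_w:
        for c, d in violet_w:
            if a < d and c < b:
                raise ProtocolError("green and violet windows overlap")

    df = trajectories.df
    n_frames = protocol.n_frames
    papa_df = _extract_class(
        df, green_w, protocol.pulse_frames(Channel.GREEN), n_frames, "PAPA"
    )
    dr_df = _extract_class(
        df, violet_w, protocol.pulse_frames(Channel.VIOLET), n_frames, "DR"
    )
    n_multi = 0
    for part in (papa_df, dr_df):
        if len(part):
            per_source = part.groupby("source_trajectory")["source_pulse"].nunique()
            n_multi += int((per_source > 1).sum())
    if n_multi:
        logger.info(
            "%d source trajectories contributed segments to multiple windows",
            n_multi,
        )
    return TrajectorySet(papa_df), TrajectorySet(dr_df)


def balance(
    papa: TrajectorySet, dr: TrajectorySet, seed
) -> tuple[TrajectorySet, TrajectorySet]:
    """Equalize trajectory counts by uniform subsampling without replacement.

    The larger of the two sets is subsampled down to the size of the
    smaller one; the smaller set is returned untouched. Deterministic
    given the seed.
    """
    if papa.n_trajectories == 0 or dr.n_trajectories == 0:
        raise ValueError("both PAPA and DR sets must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(papa.n_trajectories, dr.n_trajectories)

    def shrink(ts: TrajectorySet) -> TrajectorySet:
        if ts.n_trajectories == n:
            return ts
        ids = np.sort(ts.trajectory_ids())
        keep = rng.choice(ids, size=n, replace=False)
        return ts.subset(keep)

    return shrink(papa), shrink(dr)


def select_isolated(
    positions: np.ndarray, min_separation_px: float = 8.0
) -> np.ndarray:
    """Keep positions whose nearest neighbour is at least ``min_separation``.

    ``positions`` is an (N, 2) array (e.g. first-frame localizations, in
    pixels). Returns the retained positions.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pos) <= 1:
        return pos
    tree = cKDTree(pos)
    dists, _ = tree.query(pos, k=2)
    return pos[dists[:, 1] >= min_separation_px]


def score_persistence(
    localizations: pd.DataFrame,
    reference_positions: np.ndarray,
    n_frames: int,
    radius_px: float = 4.0,
    x_col: str = "x_px",
    y_col: str = "y_px",
) -> tuple[np.ndarray, np.ndarray]:
    """Score single immobilized molecules as fluorescent per frame.

    A reference molecule is fluorescent in frame t iff at least one
    localization lies within ``radius_px`` of its initial position.
    Returns ``(fluorescent, surviving_fraction)`` where ``fluorescent``
    is a (n_references, n_frames) boolean matrix and the surviving
    fraction is its per-frame mean.
    """
    refs = np.asarray(reference_positions, dtype=float).reshape(-1, 2)
    out = np.zeros((len(refs), n_frames), dtype=bool)
    if len(refs) == 0:
        return out, np.zeros(n_frames)
    ref_tree = cKDTree(refs)
    for frame, group in localizations.groupby("frame"):
        f = int(frame)
        if not 0 <= f < n_frames:
            continue
        pts = group[[x_col, y_col]].to_numpy(dtype=float)
        hits = ref_tree.query_ball_point(pts, r=radius_px)
        for lst in hits:
            out[lst, f] = True
    return out, out.mean(axis=0)


def segment_summary(papa: TrajectorySet, dr: TrajectorySet) -> dict:
    """Segment counts per pulse, JSON-ready."""

    def per_pulse(ts: TrajectorySet) -> dict:
        if ts.n_localizations == 0:
            return {}
        g = ts.df.groupby("source_pulse")["trajectory"].nunique()
        return {int(k): int(v) for k, v in g.items()}

    return {
        "n_papa_segments": papa.n_trajectories,
        "n_dr_segments": dr.n_trajectories,
        "papa_segments_per_pulse": per_pulse(papa),
        "dr_segments_per_pulse": per_pulse(dr),
    }
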