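"""Ensemble-intensity analytics for PAPA experiments.

Works on per-frame summed field-of-view intensity traces ("sawtooth"
data): per-pulse fluorescence increases, the PAPA/DR ratio, linear
rate fits of ratio vs. green pulse duration, fractional-reactivation
kinetics, and localization-rate traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .illumination import Channel, IlluminationProtocol, ProtocolError

__all__ = [
    "IntensityTrace",
    "PulseResponse",
    "total_intensity",
    "average_traces",
    "pulse_response",
    "pulse_increases",
    "papa_dr_ratio",
    "fit_linear_rate",
    "relative_rate",
    "phase_mean_intensities",
    "fractional_reactivation",
    "fit_exponential_reactivation",
    "localization_rate_trace",
    "plot_sawtooth",
]


@dataclass
class IntensityTrace:
    """Per-frame summed field-of-view intensity aligned to a protocol."""

    values: np.ndarray
    protocol: IlluminationProtocol | None = None
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("intensity trace must be 1-D")
        if self.protocol is not None and len(self.values) != self.protocol.n_frames:
            raise ValueError(
                f"trace length {len(self.values)} != protocol frames "
                f"{self.protocol.n_frames}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PulseResponse:
    """Per-pulse intensity increases for green and violet pulses."""

    green: np.ndarray
    violet: np.ndarray
    w_pre: int
    w_post: int

    def mean_increase(self, channel: Channel) -> float:
        arr = self.green if Channel(channel) is Channel.GREEN else self.violet
        if arr.size == 0:
            raise ValueError(f"no {Channel(channel).name} pulses in response")
        return float(arr.mean())

    def stderr(self, channel: Channel) -> float:
        arr = self.green if Channel(channel) is Channel.GREEN else self.violet
        if arr.size < 2:
            return float("nan")
        return float(arr.std(ddof=1) / np.sqrt(arr.size))


def total_intensity(
    movie: np.ndarray,
    protocol: IlluminationProtocol | None = None,
    cell_id: str | None = None,
) -> IntensityTrace:
    """Sum all pixels per frame. Raw values, no background subtraction."""
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, y, x) stack")
    return IntensityTrace(
        values=movie.sum(axis=(1, 2)).astype(float),
        protocol=protocol,
        cell_id=cell_id,
    )


def average_traces(traces: Sequence[IntensityTrace]) -> IntensityTrace:
    """Frame-by-frame mean over cells (traces must have equal length)."""
    if not traces:
        raise ValueError("need at least one trace")
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    stacked = np.stack([t.values for t in traces])
    return IntensityTrace(values=stacked.mean(axis=0), protocol=traces[0].protocol)


def _single_channel_increases(
    values: np.ndarray,
    pulses: np.ndarray,
    other_pulses: np.ndarray,
    w_pre: int,
    w_post: int,
    skip_first: bool,
    detrend: bool = False,
) -> np.ndarray:
    if skip_first and pulses.size:
        pulses = pulses[1:]
    all_pulses = np.concatenate([pulses, other_pulses])
    out = []
    n = len(values)
    for p in pulses:
        a_pre, b_pre = p - w_pre, p  # [p-w_pre, p)
        a_post, b_post = p + 1, p + 1 + w_post  # [p+1, p+1+w_post)
        if a_pre < 0 or b_post > n:
            raise ProtocolError(
                f"pulse at frame {p}: response windows fall outside the movie"
            )
        for a, b in ((a_pre, b_pre), (a_post, b_post)):
            clash = (all_pulses >= a) & (all_pulses < b) & (all_pulses != p)
            if clash.any():
                raise ProtocolError(
                    f"pulse at frame {p}: response window collides with "
                    f"another pulse"
                )
        if detrend and w_pre >= 2:
            # extrapolate the pre-window linear trend under the post window
            # so a decaying baseline (re-shelving/bleaching) does not bias
            # the step estimate
            x_pre = np.arange(a_pre, b_pre)
            slope, icpt = np.polyfit(x_pre, values[a_pre:b_pre], 1)
            x_post = np.arange(a_post, b_post)
            baseline = slope * x_post + icpt
            out.append(float((values[a_post:b_post] - baseline).mean()))
        else:
            out.append(
                values[a_post:b_post].mean() - values[a_pre:b_pre].mean()
            )
    return np.asarray(out)


def pulse_increases(
    trace: IntensityTrace,
    channel: Channel,
    protocol: IlluminationProtocol | None = None,
    w_pre: int = 10,
    w_post: int = 10,
    skip_first: bool = False,
    detrend: bool = False,
) -> np.ndarray:
    """Per-pulse intensity increases for a single channel.

    Useful when only one colour's response is well-defined (e.g. a green
    probe pulse after a multi-frame violet train). With ``detrend`` the
    pre-window linear trend is extrapolated under the post window, which
    removes the bias a decaying baseline would otherwise add to the step.
    """
    if protocol is None:
        protocol = trace.protocol
    if protocol is None:
        raise ValueError("no protocol attached to trace and none given")
    channel = Channel(channel)
    pulses = protocol.pulse_frames(channel)
    other = (
        protocol.pulse_frames(Channel.VIOLET)
        if channel is Channel.GREEN
        else protocol.pulse_frames(Channel.GREEN)
    )
    return _single_channel_increases(
        trace.values, pulses, other, w_pre, w_post, skip_first, detrend
    )


def pulse_response(
    trace: IntensityTrace,
    protocol: IlluminationProtocol | None = None,
    w_pre: int = 10,
    w_post: int = 10,
    skip_first: bool = False,
    detrend: bool = False,
) -> PulseResponse:
    """Per-pulse intensity increase for every green and violet pulse.

    The increase at a pulse in frame ``p`` is
    ``mean(trace[p+1 : p+1+w_post]) − mean(trace[p−w_pre : p])``; the
    pulse frame itself is excluded from both windows. ``skip_first`` drops
    the first pulse of each colour in the movie, avoiding the transient
    shelving phase at the start of short protocols. ``detrend`` removes
    the pre-window linear baseline trend (see :func:`pulse_increases`).
    """
    if protocol is None:
        protocol = trace.protocol
    if protocol is None:
        raise ValueError("no protocol attached to trace and none given")
    green = protocol.pulse_frames(Channel.GREEN)
    violet = protocol.pulse_frames(Channel.VIOLET)
    return PulseResponse(
        green=_single_channel_increases(
            trace.values, green, violet, w_pre, w_post, skip_first, detrend
        ),
        violet=_single_channel_increases(
            trace.values, violet, green, w_pre, w_post, skip_first, detrend
        ),
        w_pre=w_pre,
        w_post=w_post,
    )


def papa_dr_ratio(response: PulseResponse) -> float:
    """Mean green-pulse increase divided by mean violet-pulse increase."""
    if response.green.size == 0 or response.violet.size == 0:
        raise ValueError("PAPA/DR ratio needs at least one pulse of each colour")
    return response.mean_increase(Channel.GREEN) / response.mean_increase(
        Channel.VIOLET
    )


def fit_linear_rate(
    durations_ms: Sequence[float],
    ratios: Sequence[float],
    stderrs: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Weighted least-squares fit of ratio = a * duration through the origin.

    Returns ``(a, r_squared)`` where R² is the uncentered coefficient of
    determination appropriate for a through-origin fit. Weights are
    inverse-variance when standard errors are supplied.
    """
    x = np.asarray(durations_ms, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two pulse durations")
    if stderrs is not None:
        se = np.asarray(stderrs, dtype=float)
        w = 1.0 / se**2
    else:
        w = np.ones_like(x)
    denom = float(np.sum(w * x * x))
    if denom == 0:
        raise ValueError("degenerate durations: all zero")
    a = float(np.sum(w * x * y) / denom)
    ss_res = float(np.sum(w * (y - a * x) ** 2))
    ss_tot = float(np.sum(w * y * y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, r2


def relative_rate(slope: float, slope_reference: float) -> float:
    """Reactivation rate relative to a reference construct's slope."""
    if slope_reference == 0:
        raise ValueError("reference slope is zero")
    return slope / slope_reference


def phase_mean_intensities(
    trace: IntensityTrace, protocol: IlluminationProtocol | None = None
) -> list[float]:
    """Mean trace value within each protocol phase (single-cycle order).

    Convenience for five-phase reactivation-kinetics protocols whose
    measurement phases bracket a shelving and a reactivation phase.
    """
    if protocol is None:
        protocol = trace.protocol
    if protocol is None:
        raise ValueError("no protocol attached to trace and none given")
    offsets = np.cumsum([0] + [ph.n_frames for ph in protocol.phases])
    out = []
    for c in range(protocol.n_cycles):
        base = c * protocol.frames_per_cycle
        for i in range(len(protocol.phases)):
            seg = trace.values[base + offsets[i] : base + offsets[i + 1]]
            out.append(float(seg.mean()))
    return out


def fractional_reactivation(i1: float, i3: float, i5: float) -> float:
    """Fraction of the shelving-induced intensity drop recovered.

    ``i1``, ``i3``, ``i5`` are the mean intensities of the measurement
    phases before shelving, after shelving, and after the reactivation
    pulse train. Returns ``(i5 − i3) / (i1 − i3)``.
    """
    if i1 <= i3:
        raise ValueError(
            "no shelving-induced intensity drop (i1 <= i3); "
            "fractional reactivation is undefined"
        )
    return (i5 - i3) / (i1 - i3)


def fit_exponential_reactivation(
    durations: Sequence[float], fractions: Sequence[float]
) -> tuple[float, float, np.ndarray]:
    """Fit f(N) = A · (1 − exp(−k·N)) to reactivation vs. pulse number.

    Returns ``(A, k, covariance)``. ``durations`` is typically the number
    of violet frames N; ``A`` is the saturation plateau (the reactivatable
    i.e. shelvable fraction) and ``k`` the per-unit reactivation rate.
    """
    x = np.asarray(durations, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points to fit amplitude and rate")
    if np.allclose(y, 0):
        return 0.0, 0.0, np.zeros((2, 2))

    def model(n, a, k):
        return a * -np.expm1(-k * n)

    a0 = max(float(y.max()), 1e-6)
    # initial rate from the first point on the rise
    k0 = 1.0 / max(float(x[np.argmax(y > 0.5 * a0)]), 1e-6)
    popt, pcov = curve_fit(
        model, x, y, p0=(a0, k0), bounds=([0, 0], [np.inf, np.inf]), maxfev=10000
    )
    return float(popt[0]), float(popt[1]), pcov


def localization_rate_trace(
    localizations: pd.DataFrame,
    n_frames: int,
    n_cells: int = 1,
) -> np.ndarray:
    """Localization counts per frame, averaged over cells.

    ``localizations`` needs a ``frame`` column; pass the pooled table from
    several cells together with ``n_cells`` to get the per-cell average.
    """
    counts = np.zeros(n_frames)
    if len(localizations):
        frames = localizations["frame"].to_numpy(dtype=int)
        valid = (frames >= 0) & (frames < n_frames)
        np.add.at(counts, frames[valid], 1.0)
    return counts / max(n_cells, 1)


def plot_sawtooth(trace: IntensityTrace, ax=None, protocol=None):
    """Plot a sawtooth trace with green/violet pulse markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.values, color="0.2", lw=0.8)
    protocol = protocol or trace.protocol
    if protocol is not None:
        for p in protocol.pulse_frames(Channel.GREEN):
            ax.axvline(p, color="green", lw=0.6, alpha=0.6)
        for p in protocol.pulse_frames(Channel.VIOLET):
            ax.axvline(p, color="purple", lw=0.6, alpha=0.6)
    ax.set_xlabel("frame")
    ax.set_ylabel("summed intensity (photons)")
    return ax
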