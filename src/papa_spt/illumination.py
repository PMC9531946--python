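"""Illumination protocols for PAPA-SPT experiments.

A protocol is an ordered list of phases, repeated for a number of cycles.
Each phase delivers a light pulse of one channel (red 639 nm imaging light,
green 561 nm sender excitation, violet 405 nm direct reactivation, or no
light) on every frame of the phase, optionally together with a concurrent
red pulse in the same frame (e.g. ``1 V [0.5 ms] + R [2 ms]``).

Protocols are written in the compact bracket notation used in the field,
e.g.::

    10 cycles of 250 R [2 ms], 1 V [7 ms], 500 R [2 ms], 1 G [7 ms], 250 R [2 ms]

Frames are 0-based and analysis windows are half-open ``[start, end)``.
The pulse frame itself is excluded from its post-pulse window: reactivated
molecules are counted from the next frame onward.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Channel",
    "IlluminationPhase",
    "IlluminationProtocol",
    "ProtocolError",
    "parse_protocol",
    "protocol_to_string",
    "load_protocol",
    "save_protocol",
]

DEFAULT_FRAME_INTERVAL_MS = 7.48


class ProtocolError(ValueError):
    """Raised for malformed or unsupported illumination protocols."""


class Channel(str, Enum):
    RED = "R"
    GREEN = "G"
    VIOLET = "V"
    OFF = "off"


_CHANNEL_TOKENS = {
    "r": Channel.RED,
    "g": Channel.GREEN,
    "v": Channel.VIOLET,
    "off": Channel.OFF,
    "red": Channel.RED,
    "green": Channel.GREEN,
    "violet": Channel.VIOLET,
}


@dataclass(frozen=True)
class IlluminationPhase:
    """One block of identically illuminated frames.

    Parameters
    ----------
    channel : Channel
        Light channel pulsed on every frame of the phase.
    n_frames : int
        Number of camera frames in the phase (per cycle).
    pulse_ms : float
        Pulse duration per frame, milliseconds.
    concurrent_red_ms : float
        Optional red pulse co-delivered in the same frame (for mixed
        stimulation/imaging frames such as ``1 V [0.5 ms] + R [2 ms]``).
    """

    channel: Channel
    n_frames: int
    pulse_ms: float = 0.0
    concurrent_red_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ProtocolError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.pulse_ms < 0 or self.concurrent_red_ms < 0:
            raise ProtocolError("pulse durations must be non-negative")
        if self.channel is Channel.RED and self.concurrent_red_ms:
            raise ProtocolError("red phase cannot carry a second red pulse")
        if self.channel is Channel.OFF and self.pulse_ms:
            raise ProtocolError("off phase cannot deliver a pulse")


@dataclass(frozen=True)
class IlluminationProtocol:
    """Frame-indexed schedule of red/green/violet pulses.

    ``pre_shelving_s`` is an optional continuous red exposure delivered
    before frame 0, used to shelve/bleach receiver fluorophores (the
    paper-style "illuminated 10 s with 639 nm light" step).
    """

    phases: tuple[IlluminationPhase, ...]
    n_cycles: int = 1
    frame_interval_ms: float = DEFAULT_FRAME_INTERVAL_MS
    pre_shelving_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise ProtocolError("protocol needs at least one phase")
        if self.n_cycles < 1:
            raise ProtocolError("n_cycles must be >= 1")
        if self.frame_interval_ms <= 0:
            raise ProtocolError("frame_interval_ms must be positive")
        if self.pre_shelving_s < 0:
            raise ProtocolError("pre_shelving_s must be non-negative")
        for ph in self.phases:
            # Pulses are delivered simultaneously within a frame, so each
            # individual pulse must fit in the frame interval.
            if ph.pulse_ms > self.frame_interval_ms or ph.concurrent_red_ms > self.frame_interval_ms:
                raise ProtocolError(
                    f"pulse longer than frame interval ({self.frame_interval_ms} ms): {ph}"
                )

    # -- frame arithmetic ------------------------------------------------

    @property
    def frames_per_cycle(self) -> int:
        return sum(ph.n_frames for ph in self.phases)

    @property
    def n_frames(self) -> int:
        return self.n_cycles * self.frames_per_cycle

    def _phase_offsets(self) -> np.ndarray:
        return np.cumsum([0] + [ph.n_frames for ph in self.phases])

    def phase_of_frame(self, frame: int) -> tuple[int, int]:
        """Return (phase index, offset within phase) for a 0-based frame."""
        if not 0 <= frame < self.n_frames:
            raise ProtocolError(
                f"frame {frame} out of range [0, {self.n_frames})"
            )
        in_cycle = frame % self.frames_per_cycle
        offsets = self._phase_offsets()
        i = int(np.searchsorted(offsets, in_cycle, side="right") - 1)
        return i, in_cycle - int(offsets[i])

    def frame_channel(self, frame: int) -> set[tuple[Channel, float]]:
        """Every illumination dose (channel, duration ms) delivered in a frame."""
        i, _ = self.phase_of_frame(frame)
        ph = self.phases[i]
        doses: set[tuple[Channel, float]] = set()
        if ph.channel is not Channel.OFF and ph.pulse_ms > 0:
            doses.add((ph.channel, ph.pulse_ms))
        if ph.concurrent_red_ms > 0:
            doses.add((Channel.RED, ph.concurrent_red_ms))
        return doses

    def doses_per_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame (red, green, violet) dose arrays in ms, length n_frames."""
        cyc = np.zeros((3, self.frames_per_cycle))
        offsets = self._phase_offsets()
        for i, ph in enumerate(self.phases):
            sl = slice(int(offsets[i]), int(offsets[i + 1]))
            if ph.channel is Channel.RED:
                cyc[0, sl] += ph.pulse_ms
            elif ph.channel is Channel.GREEN:
                cyc[1, sl] += ph.pulse_ms
            elif ph.channel is Channel.VIOLET:
                cyc[2, sl] += ph.pulse_ms
            cyc[0, sl] += ph.concurrent_red_ms
        full = np.tile(cyc, self.n_cycles)
        return full[0], full[1], full[2]

    def pulse_frames(self, channel: Channel) -> np.ndarray:
        """0-based frames on which the given channel delivers a pulse."""
        channel = Channel(channel)
        cyc = np.zeros(self.frames_per_cycle, dtype=bool)
        offsets = self._phase_offsets()
        for i, ph in enumerate(self.phases):
            hit = (ph.channel is channel and ph.pulse_ms > 0) or (
                channel is Channel.RED and ph.concurrent_red_ms > 0
            )
            if hit:
                cyc[int(offsets[i]) : int(offsets[i + 1])] = True
        base = np.flatnonzero(cyc)
        return np.concatenate(
            [base + c * self.frames_per_cycle for c in range(self.n_cycles)]
        ) if base.size else np.array([], dtype=int)

    def post_pulse_windows(
        self, channel: Channel, window: int = 30
    ) -> list[tuple[int, int]]:
        """Half-open frame ranges ``[p+1, p+1+window)`` after each pulse.

        The pulse frame itself is excluded. Windows are clipped at the end
        of the movie. Overlapping windows, or windows that run into another
        reactivation pulse, signal a protocol this analysis does not
        support and raise :class:`ProtocolError`.
        """
        if window < 1:
            raise ProtocolError("window must be >= 1")
        channel = Channel(channel)
        if channel not in (Channel.GREEN, Channel.VIOLET):
            raise ProtocolError("post-pulse windows are defined for GREEN/VIOLET")
        pulses = self.pulse_frames(channel)
        ranges = [
            (int(p) + 1, min(int(p) + 1 + window, self.n_frames))
            for p in pulses
            if p + 1 < self.n_frames
        ]
        for (a, b), (c, _) in zip(ranges, ranges[1:]):
            if c < b:
                raise ProtocolError("post-pulse windows overlap; reduce window")
        reactivation = np.concatenate(
            [self.pulse_frames(Channel.GREEN), self.pulse_frames(Channel.VIOLET)]
        )
        for a, b in ranges:
            inside = (reactivation >= a) & (reactivation < b)
            if inside.any():
                raise ProtocolError(
                    "post-pulse window overlaps another reactivation pulse"
                )
        return ranges

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cycles": self.n_cycles,
            "frame_interval_ms": self.frame_interval_ms,
            "pre_shelving_s": self.pre_shelving_s,
            "phases": [
                {
                    "channel": ph.channel.value,
                    "frames": ph.n_frames,
                    "pulse_ms": ph.pulse_ms,
                    "red_ms": ph.concurrent_red_ms,
                }
                for ph in self.phases
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IlluminationProtocol":
        phases = [
            IlluminationPhase(
                channel=_parse_channel(p["channel"]),
                n_frames=int(p["frames"]),
                pulse_ms=float(p.get("pulse_ms", 0.0)),
                concurrent_red_ms=float(p.get("red_ms", 0.0)),
            )
            for p in d["phases"]
        ]
        return cls(
            phases=tuple(phases),
            n_cycles=int(d.get("cycles", 1)),
            frame_interval_ms=float(d.get("frame_interval_ms", DEFAULT_FRAME_INTERVAL_MS)),
            pre_shelving_s=float(d.get("pre_shelving_s", 0.0)),
        )

    def to_string(self) -> str:
        return protocol_to_string(self)


def _parse_channel(token: str) -> Channel:
    try:
        return _CHANNEL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ProtocolError(f"unknown channel token {token!r}") from None


_PHASE_RE = re.compile(
    r"""^\s*(?P<n>\d+)\s+(?P<ch>[A-Za-z]+)
        \s*(?:\[\s*(?P<dur>[\d.]+)\s*ms\s*\])?
        \s*(?:\+\s*R\s*\[\s*(?P<red>[\d.]+)\s*ms\s*\])?\s*$""",
    re.VERBOSE,
)

_CYCLES_RE = re.compile(r"^\s*(\d+)\s+cycles?\s+of\s+(.*)$", re.IGNORECASE)


def parse_protocol(
    spec: "str | dict | IlluminationProtocol",
    *,
    frame_interval_ms: float = DEFAULT_FRAME_INTERVAL_MS,
    pre_shelving_s: float = 0.0,
) -> IlluminationProtocol:
    """Parse a protocol from bracket notation or a dict.

    Examples of accepted strings::

        "10 cycles of 250 R [2 ms], 1 V [7 ms], 500 R [2 ms], 1 G [7 ms], 250 R [2 ms]"
        "5 cycles of 100 R [7 ms], 1 V [7 ms] + R [7 ms], 200 R [7 ms]"
        "1 cycle of 1 R [2 ms]"
        "20 off"

    Round trip: ``parse_protocol(protocol_to_string(p)) == p``.
    """
    if isinstance(spec, IlluminationProtocol):
        return spec
    if isinstance(spec, dict):
        return IlluminationProtocol.from_dict(spec)
    text = spec.strip()
    n_cycles = 1
    m = _CYCLES_RE.match(text)
    if m:
        n_cycles = int(m.group(1))
        text = m.group(2)
    phases = []
    for part in text.split(","):
        pm = _PHASE_RE.match(part)
        if not pm:
            raise ProtocolError(f"cannot parse phase {part!r}")
        channel = _parse_channel(pm.group("ch"))
        dur = float(pm.group("dur")) if pm.group("dur") else 0.0
        red = float(pm.group("red")) if pm.group("red") else 0.0
        if channel is not Channel.OFF and pm.group("dur") is None:
            raise ProtocolError(f"missing pulse duration in {part!r}")
        phases.append(
            IlluminationPhase(
                channel=channel,
                n_frames=int(pm.group("n")),
                pulse_ms=dur,
                concurrent_red_ms=red,
            )
        )
    return IlluminationProtocol(
        phases=tuple(phases),
        n_cycles=n_cycles,
        frame_interval_ms=frame_interval_ms,
        pre_shelving_s=pre_shelving_s,
    )


def _fmt(x: float) -> str:
    return f"{x:g}"


def protocol_to_string(protocol: IlluminationProtocol) -> str:
    """Serialize a protocol back to canonical bracket notation."""
    parts = []
    for ph in protocol.phases:
        if ph.channel is Channel.OFF:
            s = f"{ph.n_frames} off"
        else:
            s = f"{ph.n_frames} {ph.channel.value} [{_fmt(ph.pulse_ms)} ms]"
        if ph.concurrent_red_ms > 0:
            s += f" + R [{_fmt(ph.concurrent_red_ms)} ms]"
        parts.append(s)
    body = ", ".join(parts)
    if protocol.n_cycles == 1:
        return f"1 cycle of {body}"
    return f"{protocol.n_cycles} cycles of {body}"


def load_protocol(path: "str | Path") -> IlluminationProtocol:
    """Load a protocol from a YAML/JSON file (dict schema or a string)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, str):
        return parse_protocol(data)
    return IlluminationProtocol.from_dict(data)


def save_protocol(protocol: IlluminationProtocol, path: "str | Path") -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(protocol.to_dict(), fh, sort_keys=False)
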