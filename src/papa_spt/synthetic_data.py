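"""Synthetic PAPA-SPT data with known ground truth.

This module generates every input the analysis pipeline consumes:

* per-molecule photophysical state histories (bright / dark / bleached)
  driven by an illumination protocol, including sender-dependent green
  reactivation (PAPA), violet direct reactivation (DR), red-light shelving
  and bleaching, and spontaneous recovery;
* two-state (bound/free) Brownian trajectories with localization error,
  emitted only on bright frames;
* camera movies (integrated Gaussian PSF + Poisson noise);
* ensemble "sawtooth" intensity traces;
* TCSPC decay histograms for the FLIM stage.

Kinetics use a discrete-frame Markov approximation: a rate k (per ms of
delivered light dose) becomes a per-frame transition probability
``1 - exp(-k * dose_ms)``. Doses are short (<= 7 ms per frame) relative to
the dynamics of interest, so the approximation error is negligible; at
most one transition occurs per molecule per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import IntensityTrace
from .flim import DecayHistogram
from .illumination import Channel, IlluminationProtocol
from .trajectories import TrajectorySet

__all__ = [
    "BRIGHT",
    "DARK",
    "BLEACHED",
    "PhotophysicsModel",
    "MotionModel",
    "LabelingModel",
    "MixtureComponent",
    "CameraModel",
    "PhotophysicsResult",
    "simulate_photophysics",
    "simulate_trajectories",
    "simulate_two_state_trajectories",
    "render_movie",
    "simulate_intensity_trace",
    "simulate_flim_decay",
]

BRIGHT, DARK, BLEACHED = 0, 1, 2


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PhotophysicsModel:
    """Per-molecule Markov model of receiver/sender photophysics.

    Rates are per millisecond of delivered light dose unless stated
    otherwise. Only a ``shelvable_fraction`` of receivers can enter the
    recoverable dark state (roughly 10% for JFX650-SNAPf under imaging
    conditions); the rest can only bleach. Dark-state molecules are
    reactivated by violet light (direct reactivation, sender-independent),
    by green light at a high rate when an unbleached sender dye is
    attached (PAPA) and at a residual background rate otherwise, and
    spontaneously at a small per-frame probability.
    """

    p_shelve_per_ms_red: float = 0.0025
    p_bleach_per_ms_red: float = 0.0005
    shelvable_fraction: float = 0.10
    k_dr_per_ms_violet: float = 0.05
    k_papa_per_ms_green: float = 0.05
    k_papa_background_per_ms_green: float = 0.002
    p_spont_per_frame: float = 1e-5
    p_sender_bleach_per_ms_green: float = 0.01
    p_dark_bleach_per_frame: float = 0.0  # dark state recoverable by default

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0 <= self.shelvable_fraction <= 1:
            raise ValueError("shelvable_fraction must lie in [0, 1]")
        for name in ("p_spont_per_frame", "p_dark_bleach_per_frame"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} is a probability and must be <= 1")


@dataclass(frozen=True)
class MotionModel:
    """Two-state (bound/free) Brownian motion with localization error.

    Positions evolve inside a square field of view with reflecting
    boundaries. ``k_bind_per_s``/``k_unbind_per_s`` enable bound<->free
    switching within a trajectory; the default 0 assigns each molecule a
    static state with probability ``f_bound``.
    """

    d_bound: float = 0.01  # um^2/s
    d_free: float = 8.3  # um^2/s
    f_bound: float = 0.0
    k_bind_per_s: float = 0.0
    k_unbind_per_s: float = 0.0
    sigma_loc: float = 0.035  # um, per axis
    frame_interval_ms: float = 7.48
    fov_um: float = 24.0

    def __post_init__(self) -> None:
        if not 0 <= self.f_bound <= 1:
            raise ValueError("f_bound must lie in [0, 1]")
        if min(self.d_bound, self.d_free, self.sigma_loc) < 0:
            raise ValueError("d_bound, d_free, sigma_loc must be >= 0")
        if self.frame_interval_ms <= 0 or self.fov_um <= 0:
            raise ValueError("frame_interval_ms and fov_um must be positive")


@dataclass(frozen=True)
class MixtureComponent:
    """One molecular species in a defined mixture."""

    name: str
    n_molecules: int
    double_labeled: bool = False
    motion: MotionModel | None = None


@dataclass(frozen=True)
class LabelingModel:
    """Sender/receiver labeling of the simulated molecule population.

    Either a homogeneous population of ``n_molecules`` with a given
    ``fraction_double_labeled``, or an explicit list of mixture
    components (e.g. a receiver-only "H2B-like" species plus a
    double-labeled "NLS-like" species).
    """

    n_molecules: int = 0
    fraction_double_labeled: float = 1.0
    components: tuple[MixtureComponent, ...] | None = None

    def __post_init__(self) -> None:
        if self.components is not None:
            object.__setattr__(self, "components", tuple(self.components))
        if not 0 <= self.fraction_double_labeled <= 1:
            raise ValueError("fraction_double_labeled must lie in [0, 1]")
        if self.components is None and self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    def assign(self) -> pd.DataFrame:
        """Deterministic per-molecule labels: component, double_labeled."""
        if self.components is not None:
            parts = []
            for comp in self.components:
                parts.append(
                    pd.DataFrame(
                        {
                            "component": comp.name,
                            "double_labeled": comp.double_labeled,
                        },
                        index=range(comp.n_molecules),
                    )
                )
            return pd.concat(parts, ignore_index=True)
        n = self.n_molecules
        n_double = int(round(n * self.fraction_double_labeled))
        return pd.DataFrame(
            {
                "component": ["default"] * n,
                "double_labeled": [True] * n_double + [False] * (n - n_double),
            }
        )


@dataclass(frozen=True)
class CameraModel:
    """Idealized camera: integrated Gaussian PSF, Poisson shot noise."""

    pixel_size_um: float = 0.16
    psf_sigma_um: float = 0.16  # 1.0 pixel
    photons_per_bright_frame: float = 300.0
    background_photons_per_pixel: float = 2.0
    n_pixels: int = 150  # square image side

    def __post_init__(self) -> None:
        if min(
            self.pixel_size_um,
            self.psf_sigma_um,
            self.photons_per_bright_frame,
            self.background_photons_per_pixel,
        ) < 0 or self.n_pixels < 1:
            raise ValueError("camera parameters must be non-negative")


@dataclass
class PhotophysicsResult:
    """States and sender survival for every molecule and frame.

    ``states[m, f]`` is the state of molecule ``m`` during frame ``f``
    (BRIGHT=0, DARK=1, BLEACHED=2); transitions caused by light delivered
    in frame ``f`` take effect from frame ``f+1``. ``sender_alive`` is the
    analogous matrix for the attached sender dye (False throughout for
    receiver-only molecules).
    """

    states: np.ndarray  # (n_molecules, n_frames) int8
    sender_alive: np.ndarray  # (n_molecules, n_frames) bool
    shelvable: np.ndarray  # (n_molecules,) bool
    labels: pd.DataFrame  # component, double_labeled
    protocol: IlluminationProtocol

    @property
    def n_molecules(self) -> int:
        return self.states.shape[0]

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def n_bright(self) -> np.ndarray:
        return (self.states == BRIGHT).sum(axis=0)


def simulate_photophysics(
    model: PhotophysicsModel,
    labeling: LabelingModel,
    protocol: IlluminationProtocol,
    seed,
) -> PhotophysicsResult:
    """Simulate bright/dark/bleached state histories under a protocol.

    ``pre_shelving_s`` of the protocol is applied as a single continuous
    red dose before frame 0 using the exact competing-risks solution
    (spontaneous reactivation is not applied during pre-shelving).
    """
    if protocol.n_frames < 1:
        raise ValueError("protocol must have at least one frame")
    rng = _rng(seed)
    labels = labeling.assign()
    n = len(labels)
    red, green, violet = protocol.doses_per_frame()
    n_frames = protocol.n_frames

    shelvable = rng.random(n) < model.shelvable_fraction
    ks = np.where(shelvable, model.p_shelve_per_ms_red, 0.0)
    kb = model.p_bleach_per_ms_red
    ktot = ks + kb
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_dark = np.divide(ks, ktot, out=np.zeros_like(ks), where=ktot > 0)

    state = np.zeros(n, dtype=np.int8)
    sender = labels["double_labeled"].to_numpy().copy()

    pre_dose = protocol.pre_shelving_s * 1000.0
    if pre_dose > 0:
        p_any = -np.expm1(-ktot * pre_dose)
        trans = rng.random(n) < p_any
        to_dark = trans & (rng.random(n) < frac_dark)
        state[trans] = BLEACHED
        state[to_dark] = DARK

    states = np.empty((n, n_frames), dtype=np.int8)
    sender_alive = np.empty((n, n_frames), dtype=bool)
    kg_vec = np.empty(n)

    for f in range(n_frames):
        states[:, f] = state
        sender_alive[:, f] = sender
        cur_bright = state == BRIGHT
        cur_dark = state == DARK
        r, g, v = red[f], green[f], violet[f]

        # bright -> dark / bleached (competing risks under red dose)
        if r > 0:
            idx = np.flatnonzero(cur_bright)
            if idx.size:
                p_any = -np.expm1(-ktot[idx] * r)
                trans = idx[rng.random(idx.size) < p_any]
                if trans.size:
                    dark_sel = rng.random(trans.size) < frac_dark[trans]
                    state[trans] = np.where(dark_sel, DARK, BLEACHED).astype(np.int8)

        # dark -> bright (DR + PAPA + spontaneous, one combined draw)
        idx = np.flatnonzero(cur_dark)
        if idx.size:
            k_eff = model.k_dr_per_ms_violet * v
            if g > 0:
                kg = np.where(
                    sender[idx],
                    model.k_papa_per_ms_green,
                    model.k_papa_background_per_ms_green,
                )
                k_eff = k_eff + kg * g
            p_re = -np.expm1(-np.broadcast_to(np.asarray(k_eff, dtype=float), idx.shape))
            p_tot = 1.0 - (1.0 - p_re) * (1.0 - model.p_spont_per_frame)
            if model.p_dark_bleach_per_frame > 0:
                # dark -> bleached competes with reactivation
                u = rng.random(idx.size)
                react = u < p_tot
                dbl = (~react) & (
                    rng.random(idx.size) < model.p_dark_bleach_per_frame
                )
                state[idx[react]] = BRIGHT
                state[idx[dbl]] = BLEACHED
            else:
                react = rng.random(idx.size) < p_tot
                state[idx[react]] = BRIGHT

        # sender bleaching under green excitation
        if g > 0 and model.p_sender_bleach_per_ms_green > 0:
            idx = np.flatnonzero(sender)
            if idx.size:
                pb = -np.expm1(-model.p_sender_bleach_per_ms_green * g)
                sender[idx[rng.random(idx.size) < pb]] = False

    return PhotophysicsResult(
        states=states,
        sender_alive=sender_alive,
        shelvable=shelvable,
        labels=labels,
        protocol=protocol,
    )


def _reflect(pos: np.ndarray, fov: float) -> np.ndarray:
    # single reflection is sufficient: per-frame steps are << fov
    pos = np.where(pos < 0, -pos, pos)
    pos = np.where(pos > fov, 2 * fov - pos, pos)
    return np.clip(pos, 0.0, fov)


def simulate_trajectories(
    motion: "MotionModel | Mapping[str, MotionModel]",
    photophysics: PhotophysicsResult,
    seed,
    max_gap: int = 0,
) -> TrajectorySet:
    """Brownian trajectories conditioned on a photophysics simulation.

    Localizations are emitted only on BRIGHT frames. A molecule's run of
    consecutive bright frames forms one trajectory; dark gaps longer than
    ``max_gap`` frames split trajectories. Observed positions are the true
    positions plus isotropic Gaussian localization error.

    ``motion`` is a single :class:`MotionModel`, or a mapping from
    component name to model for mixtures (all components must share
    ``sigma_loc``, ``frame_interval_ms`` and ``fov_um``).
    """
    rng = _rng(seed)
    labels = photophysics.labels
    n, n_frames = photophysics.states.shape

    if isinstance(motion, MotionModel):
        motion_by_comp = {c: motion for c in labels["component"].unique()}
    else:
        motion_by_comp = dict(motion)
    ref = next(iter(motion_by_comp.values()))
    for m in motion_by_comp.values():
        if (
            m.sigma_loc != ref.sigma_loc
            or m.frame_interval_ms != ref.frame_interval_ms
            or m.fov_um != ref.fov_um
        ):
            raise ValueError(
                "mixture components must share sigma_loc, frame_interval_ms, fov_um"
            )
    dt_s = ref.frame_interval_ms / 1000.0
    fov = ref.fov_um

    comp = labels["component"].to_numpy()
    f_bound = np.empty(n)
    d_bound = np.empty(n)
    d_free = np.empty(n)
    k_on = np.empty(n)
    k_off = np.empty(n)
    for name, m in motion_by_comp.items():
        sel = comp == name
        f_bound[sel] = m.f_bound
        d_bound[sel] = m.d_bound
        d_free[sel] = m.d_free
        k_on[sel] = m.k_bind_per_s
        k_off[sel] = m.k_unbind_per_s

    bound = rng.random(n) < f_bound
    switching = (k_on > 0) | (k_off > 0)
    p_bind = -np.expm1(-k_on * dt_s)
    p_unbind = -np.expm1(-k_off * dt_s)

    pos = rng.uniform(0.0, fov, size=(n, 2))
    bright = photophysics.states == BRIGHT

    frames_out, mols_out, xs_out, ys_out, bound_out = [], [], [], [], []
    for f in range(n_frames):
        idx = np.flatnonzero(bright[:, f])
        if idx.size:
            noise = rng.normal(0.0, ref.sigma_loc, size=(idx.size, 2))
            obs = pos[idx] + noise
            frames_out.append(np.full(idx.size, f))
            mols_out.append(idx)
            xs_out.append(obs[:, 0])
            ys_out.append(obs[:, 1])
            bound_out.append(bound[idx].copy())
        # propagate to next frame
        d = np.where(bound, d_bound, d_free)
        step_sd = np.sqrt(2.0 * d * dt_s)
        pos = _reflect(pos + rng.normal(size=(n, 2)) * step_sd[:, None], fov)
        if switching.any():
            u = rng.random(n)
            flip = np.where(bound, u < p_unbind, u < p_bind) & switching
            bound = np.where(flip, ~bound, bound)

    if not frames_out:
        df = pd.DataFrame(
            columns=["trajectory", "frame", "x_um", "y_um", "molecule"]
        )
        return TrajectorySet(df)

    frame_arr = np.concatenate(frames_out)
    mol_arr = np.concatenate(mols_out)
    order = np.lexsort((frame_arr, mol_arr))
    frame_arr = frame_arr[order]
    mol_arr = mol_arr[order]
    x_arr = np.concatenate(xs_out)[order]
    y_arr = np.concatenate(ys_out)[order]
    b_arr = np.concatenate(bound_out)[order]

    new_traj = np.ones(len(frame_arr), dtype=bool)
    same_mol = mol_arr[1:] == mol_arr[:-1]
    gap_ok = (frame_arr[1:] - frame_arr[:-1]) <= 1 + max_gap
    new_traj[1:] = ~(same_mol & gap_ok)
    traj_ids = np.cumsum(new_traj) - 1

    df = pd.DataFrame(
        {
            "trajectory": traj_ids,
            "frame": frame_arr,
            "x_um": x_arr,
            "y_um": y_arr,
            "molecule": mol_arr,
            "component": labels["component"].to_numpy()[mol_arr],
            "double_labeled": labels["double_labeled"].to_numpy()[mol_arr],
            "bound": b_arr,
        }
    )
    return TrajectorySet(df)


def simulate_two_state_trajectories(
    n_trajectories: int,
    motion: MotionModel,
    seed,
    mean_track_length: float = 8.0,
) -> TrajectorySet:
    """Plain two-state trajectories without the photophysics layer.

    Track lengths (in localizations) are ``1 + Geometric`` with the given
    mean and a minimum of 2, so every trajectory carries at least one
    displacement. Each trajectory is bound with probability ``f_bound``
    (static assignment). Intended for calibrating and testing the
    diffusion-spectrum estimators.
    """
    if mean_track_length <= 2:
        raise ValueError("mean_track_length must exceed 2")
    rng = _rng(seed)
    lengths = 1 + rng.geometric(1.0 / (mean_track_length - 1.0), size=n_trajectories)
    bound = rng.random(n_trajectories) < motion.f_bound
    d = np.where(bound, motion.d_bound, motion.d_free)
    dt_s = motion.frame_interval_ms / 1000.0

    total = int(lengths.sum())
    traj = np.repeat(np.arange(n_trajectories), lengths)
    starts = np.zeros(total, dtype=bool)
    starts[np.cumsum(lengths)[:-1]] = True
    starts[0] = True
    # within-trajectory frame index
    frame = np.arange(total) - np.repeat(
        np.concatenate(([0], np.cumsum(lengths)[:-1])), lengths
    )

    step_sd = np.sqrt(2.0 * np.repeat(d, lengths) * dt_s)
    steps = rng.normal(size=(total, 2)) * step_sd[:, None]
    origins = rng.uniform(0.0, motion.fov_um, size=(n_trajectories, 2))
    steps[starts] = origins[np.arange(n_trajectories)]
    pos = np.cumsum(steps, axis=0)
    # subtract the running offset so each trajectory restarts at its origin
    offsets = np.maximum.accumulate(np.where(starts, np.arange(total), -1))
    pos = pos - pos[offsets] + steps[offsets]

    obs = pos + rng.normal(0.0, motion.sigma_loc, size=(total, 2))
    df = pd.DataFrame(
        {
            "trajectory": traj,
            "frame": frame,
            "x_um": obs[:, 0],
            "y_um": obs[:, 1],
            "bound": np.repeat(bound, lengths),
        }
    )
    return TrajectorySet(df)


def render_movie(
    trajectories: TrajectorySet,
    camera: CameraModel,
    seed,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render a localization table into a 16-bit movie.

    Each localization contributes a pixel-integrated 2-D Gaussian with
    total expected photons ``photons_per_bright_frame``; pixel values are
    Poisson draws around signal + uniform background.
    """
    from scipy.special import erf

    rng = _rng(seed)
    df = trajectories.df
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    npx = camera.n_pixels
    sigma_px = camera.psf_sigma_um / camera.pixel_size_um
    expected = np.full(
        (n_frames, npx, npx), camera.background_photons_per_pixel, dtype=float
    )

    half = max(1, int(np.ceil(4 * sigma_px)))
    sq2s = np.sqrt(2.0) * sigma_px
    for frame, x_um, y_um in zip(df["frame"], df["x_um"], df["y_um"]):
        f = int(frame)
        if f >= n_frames:
            continue
        xc = x_um / camera.pixel_size_um
        yc = y_um / camera.pixel_size_um
        x0 = int(np.floor(xc)) - half
        y0 = int(np.floor(yc)) - half
        xs = np.arange(max(x0, 0), min(x0 + 2 * half + 2, npx))
        ys = np.arange(max(y0, 0), min(y0 + 2 * half + 2, npx))
        if xs.size == 0 or ys.size == 0:
            continue
        fx = 0.5 * (erf((xs + 1 - xc) / sq2s) - erf((xs - xc) / sq2s))
        fy = 0.5 * (erf((ys + 1 - yc) / sq2s) - erf((ys - yc) / sq2s))
        expected[f, np.ix_(ys, xs)[0], np.ix_(ys, xs)[1]] += (
            camera.photons_per_bright_frame * np.outer(fy, fx)
        )

    movie = rng.poisson(expected)
    return np.clip(movie, 0, 2**16 - 1).astype(np.uint16)


def simulate_intensity_trace(
    photophysics: PhotophysicsResult,
    photons_per_bright_frame: float,
    background: float,
    seed,
    gate_on_red: bool = True,
) -> IntensityTrace:
    """Per-frame summed field-of-view intensity ("sawtooth" trace).

    Each frame's expected intensity is ``n_bright * photons + background``
    and the realized value is one Poisson draw. With ``gate_on_red`` (the
    default), frames that deliver no red excitation contribute only
    background — receiver dyes emit in the red channel only while excited.
    """
    rng = _rng(seed)
    n_bright = (photophysics.states == BRIGHT).sum(axis=0).astype(float)
    if gate_on_red:
        red, _, _ = photophysics.protocol.doses_per_frame()
        n_bright = np.where(red > 0, n_bright, 0.0)
    expected = n_bright * photons_per_bright_frame + background
    values = rng.poisson(expected).astype(float)
    return IntensityTrace(values=values, protocol=photophysics.protocol)


def simulate_flim_decay(
    tau_ns: float,
    n_photons: int,
    bin_width_ns: float,
    n_bins: int,
    seed,
) -> DecayHistogram:
    """Simulate a TCSPC decay: exponential arrival times, histogrammed.

    Photons arriving after the record length ``bin_width_ns * n_bins`` are
    truncated and counted in ``n_truncated``.
    """
    if tau_ns <= 0:
        raise ValueError("tau_ns must be positive")
    rng = _rng(seed)
    times = rng.exponential(tau_ns, size=int(n_photons))
    record = bin_width_ns * n_bins
    kept = times[times < record]
    edges = np.arange(n_bins + 1) * bin_width_ns
    counts, _ = np.histogram(kept, bins=edges)
    return DecayHistogram(
        bin_edges_ns=edges,
        counts=counts.astype(np.int64),
        n_truncated=int(n_photons - kept.size),
    )
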