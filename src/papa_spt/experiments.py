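"""Canonical in-silico PAPA experiments with known ground truth.

Each function runs one self-contained simulated study — the same study
designs exercised by the test suite and the reproduction script — and
returns a dict of the quantities the analysis recovers. Problem sizes
default to values that resolve the effect well while keeping each study
in the seconds-to-a-minute range on one CPU; they are parameters, not
constants.
"""

from __future__ import annotations

import numpy as np

from .classify import balance, split_trajectories
from .ensemble import (
    fit_exponential_reactivation,
    fit_linear_rate,
    fractional_reactivation,
    papa_dr_ratio,
    phase_mean_intensities,
    pulse_increases,
    pulse_response,
)
from .flim import fit_monoexponential, fret_efficiency
from .illumination import Channel, parse_protocol
from .spectrum import (
    DiffusionGrid,
    fit_reduced,
    fraction_bound,
    infer_spectrum,
    jump_loglik,
    local_maxima,
)
from .synthetic_data import (
    LabelingModel,
    MixtureComponent,
    MotionModel,
    PhotophysicsModel,
    simulate_flim_decay,
    simulate_intensity_trace,
    simulate_photophysics,
    simulate_two_state_trajectories,
    simulate_trajectories,
)
from .trajectories import TrajectorySet
from .unmix import MixtureFit, component_ratio, fit_mixture, fold_enrichment

__all__ = [
    "worked_example_enrichment",
    "two_state_recovery",
    "spectrum_peaks",
    "mixture_enrichment",
    "papa_dr_linearity",
    "sender_dependence",
    "occlusion",
    "reactivation_kinetics",
    "em_oracle_check",
    "displacement_moment_check",
    "flim_recovery",
]

# Standard nuclear-protein motion regime: bound anchor at the grid floor,
# free diffusion near the fast nucleoplasmic peak.
D_BOUND = 0.01  # um^2/s
D_FREE = 8.3  # um^2/s


def worked_example_enrichment() -> dict:
    """Fold enrichment from the canonical two-component mixture fractions.

    DR trajectories split 53%/47% between the double-labeled and
    single-labeled components; PAPA trajectories split 91%/9%. The
    component ratio rises from ~1.1 to ~10, i.e. roughly ninefold
    enrichment of double-labeled molecules.
    """
    dr = MixtureFit(0.53, 0.47, 0.0)
    papa = MixtureFit(0.91, 0.09, 0.0)
    return {
        "ratio_dr": component_ratio(dr),
        "ratio_papa": component_ratio(papa),
        "fold_enrichment": fold_enrichment(papa, dr),
    }


def _two_state_sim(seed, n_trajectories=2000, f_bound=0.70) -> TrajectorySet:
    motion = MotionModel(d_bound=D_BOUND, d_free=D_FREE, f_bound=f_bound)
    return simulate_two_state_trajectories(
        n_trajectories, motion, seed=seed, mean_track_length=8.0
    )


def two_state_recovery(seed, n_trajectories: int = 2000) -> dict:
    """Recover a 70% bound fraction with the reduced {0.01, 8.3} model."""
    ts = _two_state_sim(seed, n_trajectories)
    fit = fit_reduced(ts, (D_BOUND, D_FREE))
    return {
        "bound_fraction": fit.fraction_bound(),
        "true_bound_fraction": 0.70,
        "n_trajectories": ts.n_trajectories,
    }


def spectrum_peaks(seed, n_trajectories: int = 2000) -> dict:
    """Diffusion spectrum of the 70/30 bound/free mixture.

    The spectrum should peak at the grid minimum (immobile mass) and near
    the free diffusion coefficient of 8.3 µm²/s.
    """
    ts = _two_state_sim(seed, n_trajectories)
    grid = DiffusionGrid()
    spec = infer_spectrum(ts, grid)
    peaks = local_maxima(spec, min_occupation=0.02)
    free_idx = int(np.argmin(np.abs(np.log(grid.d_values) - np.log(D_FREE))))
    near_free = [
        d
        for d in peaks
        if abs(int(np.argmin(np.abs(grid.d_values - d))) - free_idx) <= 2
    ]
    return {
        "peaks": peaks.tolist(),
        "has_bound_peak": bool(np.any(peaks == grid.d_values[0])),
        "free_peak_d": float(near_free[0]) if near_free else float("nan"),
        "fraction_bound": fraction_bound(spec),
        "n_trajectories": ts.n_trajectories,
    }


# -- defined two-component mixture experiment ---------------------------

MIXTURE_PROTOCOL = (
    "10 cycles of 250 R [2 ms], 1 V [1 ms] + R [2 ms], 500 R [2 ms], "
    "1 G [2 ms] + R [2 ms], 250 R [2 ms]"
)


def _mixture_photophysics() -> PhotophysicsModel:
    return PhotophysicsModel(
        p_shelve_per_ms_red=0.0025,
        p_bleach_per_ms_red=0.001,
        shelvable_fraction=0.10,
        k_dr_per_ms_violet=0.05,
        k_papa_per_ms_green=0.05,
        k_papa_background_per_ms_green=0.002,
        p_spont_per_frame=1e-5,
        p_sender_bleach_per_ms_green=0.01,
    )


def mixture_enrichment(
    seed, n_molecules: int = 10_000, n_basis: int = 2000, window: int = 30
) -> dict:
    """Full PAPA-SPT pipeline on a defined two-component mixture.

    Half the molecules are a free-diffusing, double-labeled species
    ("nls_like"); half are a chromatin-bound, receiver-only species
    ("h2b_like"). After 10 s of pre-shelving, ten illumination cycles
    alternate violet (DR) and green (PAPA) reactivation. Trajectories
    are split into post-pulse segments, balanced, converted to diffusion
    spectra, and unmixed against single-component reference spectra.
    """
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=6)
    protocol = parse_protocol(MIXTURE_PROTOCOL, pre_shelving_s=10.0)
    half = n_molecules // 2
    labeling = LabelingModel(
        components=(
            MixtureComponent("nls_like", half, double_labeled=True),
            MixtureComponent("h2b_like", n_molecules - half, double_labeled=False),
        )
    )
    motion = {
        "nls_like": MotionModel(f_bound=0.0, d_free=D_FREE),
        "h2b_like": MotionModel(f_bound=1.0, d_bound=D_BOUND),
    }
    photo = simulate_photophysics(
        _mixture_photophysics(), labeling, protocol, seeds[0]
    )
    ts = simulate_trajectories(motion, photo, seeds[1])
    papa, dr = split_trajectories(ts, protocol, window=window)

    def p_component_a(segments: TrajectorySet) -> float:
        comp = segments.df.groupby("trajectory")["component"].first()
        return float((comp == "nls_like").mean())

    p_a_papa = p_component_a(papa)
    p_a_dr = p_component_a(dr)

    papa_b, dr_b = balance(papa, dr, seeds[2])
    grid = DiffusionGrid()
    spec_papa = infer_spectrum(papa_b, grid)
    spec_dr = infer_spectrum(dr_b, grid)
    basis_a = infer_spectrum(
        simulate_two_state_trajectories(n_basis, motion["nls_like"], seeds[3]),
        grid,
    )
    basis_b = infer_spectrum(
        simulate_two_state_trajectories(n_basis, motion["h2b_like"], seeds[4]),
        grid,
    )
    papa_fit = fit_mixture(spec_papa, basis_a, basis_b, "nls_like", "h2b_like")
    dr_fit = fit_mixture(spec_dr, basis_a, basis_b, "nls_like", "h2b_like")
    return {
        "p_double_labeled_papa": p_a_papa,
        "p_double_labeled_dr": p_a_dr,
        "delta_p": p_a_papa - p_a_dr,
        "f_papa": papa_fit.f_a,
        "f_dr": dr_fit.f_a,
        "ratio_papa": component_ratio(papa_fit),
        "ratio_dr": component_ratio(dr_fit),
        "fold_enrichment": fold_enrichment(papa_fit, dr_fit),
        "n_papa_segments": papa.n_trajectories,
        "n_dr_segments": dr.n_trajectories,
        "n_molecules": n_molecules,
    }


# -- ensemble intensity experiments -------------------------------------


def _ensemble_protocol(green_ms: float, violet_ms: float = 0.5) -> str:
    return (
        f"10 cycles of 50 R [2 ms], 1 V [{violet_ms:g} ms], 100 R [2 ms], "
        f"1 G [{green_ms:g} ms], 50 R [2 ms]"
    )


def papa_dr_linearity(
    seed,
    durations_ms=(0.5, 1.0, 2.0, 4.0, 7.0),
    n_molecules: int = 50_000,
    k_papa: float = 0.007,
) -> dict:
    """PAPA/DR ratio vs. green pulse duration in the linear regime.

    With k_papa · dose ≤ 0.05 the per-pulse green reactivation
    probability is nearly proportional to the pulse duration, so the
    ratio follows y = a·x through the origin.
    """
    seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=2 * len(durations_ms)
    )
    model = PhotophysicsModel(
        p_shelve_per_ms_red=0.0025,
        p_bleach_per_ms_red=0.0005,
        shelvable_fraction=0.10,
        k_dr_per_ms_violet=0.05,
        k_papa_per_ms_green=k_papa,
        k_papa_background_per_ms_green=0.0,
        p_spont_per_frame=0.0,
        p_sender_bleach_per_ms_green=0.0,
    )
    labeling = LabelingModel(n_molecules=n_molecules, fraction_double_labeled=1.0)
    ratios, stderrs = [], []
    for i, g_ms in enumerate(durations_ms):
        protocol = parse_protocol(_ensemble_protocol(g_ms), pre_shelving_s=10.0)
        photo = simulate_photophysics(model, labeling, protocol, seeds[2 * i])
        trace = simulate_intensity_trace(photo, 400.0, 1000.0, seeds[2 * i + 1])
        resp = pulse_response(trace, protocol, skip_first=True)
        ratios.append(papa_dr_ratio(resp))
        g_se = resp.stderr(Channel.GREEN) / resp.mean_increase(Channel.VIOLET)
        stderrs.append(abs(g_se))
    slope, r2 = fit_linear_rate(durations_ms, ratios)
    return {
        "durations_ms": list(durations_ms),
        "ratios": ratios,
        "stderrs": stderrs,
        "slope_per_ms": slope,
        "r_squared": r2,
        "n_molecules": n_molecules,
    }


def sender_dependence(seed, n_molecules: int = 30_000) -> dict:
    """Green reactivation requires a sender; violet does not.

    With no double-labeled molecules and zero background PAPA rate, the
    mean green-pulse intensity increase should be statistically zero
    while the violet-pulse increase stays positive.
    """
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    model = PhotophysicsModel(
        p_shelve_per_ms_red=0.0025,
        p_bleach_per_ms_red=0.0005,
        shelvable_fraction=0.10,
        k_dr_per_ms_violet=0.05,
        k_papa_per_ms_green=0.05,
        k_papa_background_per_ms_green=0.0,
        p_spont_per_frame=1e-5,
    )
    labeling = LabelingModel(n_molecules=n_molecules, fraction_double_labeled=0.0)
    # thorough pre-bleaching: the null test needs the non-reactivatable
    # bright background (and its decay curvature) gone before probing
    protocol = parse_protocol(_ensemble_protocol(7.0), pre_shelving_s=20.0)
    photo = simulate_photophysics(model, labeling, protocol, seeds[0])
    trace = simulate_intensity_trace(photo, 400.0, 1000.0, seeds[1])
    # detrend: the test is against a zero *reactivation* step, so the
    # slow re-shelving decay of the baseline must not masquerade as a
    # negative response
    resp = pulse_response(trace, protocol, detrend=True)
    return {
        "green_mean": resp.mean_increase(Channel.GREEN),
        "green_se": resp.stderr(Channel.GREEN),
        "violet_mean": resp.mean_increase(Channel.VIOLET),
        "violet_se": resp.stderr(Channel.VIOLET),
        "n_molecules": n_molecules,
    }


def occlusion(seed, n_molecules: int = 50_000) -> dict:
    """DR and PAPA recover the same dark state (mutual occlusion).

    A saturating violet train immediately before a green pulse empties
    the shared dark-state pool, suppressing the green response relative
    to a matched run where the violet train is replaced by dark frames.
    """
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=4)
    model = PhotophysicsModel(
        p_shelve_per_ms_red=0.0025,
        p_bleach_per_ms_red=0.0005,
        shelvable_fraction=0.10,
        k_dr_per_ms_violet=0.05,
        k_papa_per_ms_green=0.05,
        k_papa_background_per_ms_green=0.0,
        p_spont_per_frame=0.0,
        p_sender_bleach_per_ms_green=0.0,
    )
    labeling = LabelingModel(n_molecules=n_molecules, fraction_double_labeled=1.0)
    occluded_str = (
        "1 cycle of 20 R [2 ms], 20 V [7 ms], 10 R [2 ms], 1 G [7 ms], 30 R [2 ms]"
    )
    control_str = (
        "1 cycle of 20 R [2 ms], 20 off, 10 R [2 ms], 1 G [7 ms], 30 R [2 ms]"
    )

    def green_response(protocol_str, s0, s1) -> float:
        protocol = parse_protocol(protocol_str, pre_shelving_s=10.0)
        photo = simulate_photophysics(model, labeling, protocol, s0)
        trace = simulate_intensity_trace(photo, 400.0, 1000.0, s1)
        # detrend: after the violet train the re-brightened population
        # decays during the probe windows; the linear-baseline estimator
        # isolates the green reactivation step from that decay
        return float(
            pulse_increases(trace, Channel.GREEN, protocol, detrend=True).mean()
        )

    # matched photophysics seed: the two runs share molecule identities
    occ = green_response(occluded_str, seeds[0], seeds[1])
    ctrl = green_response(control_str, seeds[0], seeds[3])
    return {
        "green_occluded": occ,
        "green_control": ctrl,
        "reduction": 1.0 - occ / ctrl,
        "n_molecules": n_molecules,
    }


def reactivation_kinetics(
    seed,
    n_violet_frames=(1, 2, 4, 8, 16, 32, 64),
    n_molecules: int = 30_000,
) -> dict:
    """Fractional reactivation vs. violet pulse number (five-phase assay).

    Phases: (1) 20 probe frames, (2) 400 shelving frames, (3) 20 probe
    frames, (4) N violet frames, (5) 20 probe frames. The fractional
    reactivation (i5−i3)/(i1−i3) saturates at the fraction of the
    intensity drop that is recoverable — approximately the shelvable
    fraction — with per-frame rate k_dr · 7 ms.
    """
    rates = PhotophysicsModel(
        p_shelve_per_ms_red=0.0025,
        p_bleach_per_ms_red=0.0005,
        shelvable_fraction=0.10,
        k_dr_per_ms_violet=0.05,
        k_papa_per_ms_green=0.0,
        k_papa_background_per_ms_green=0.0,
        p_spont_per_frame=0.0,
    )
    labeling = LabelingModel(n_molecules=n_molecules, fraction_double_labeled=0.0)
    seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=2 * len(n_violet_frames)
    )
    fractions = []
    for i, n_v in enumerate(n_violet_frames):
        protocol = parse_protocol(
            f"1 cycle of 20 R [1 ms], 400 R [7 ms], 20 R [1 ms], "
            f"{n_v} V [7 ms], 20 R [1 ms]"
        )
        photo = simulate_photophysics(rates, labeling, protocol, seeds[2 * i])
        trace = simulate_intensity_trace(photo, 200.0, 100.0, seeds[2 * i + 1])
        i1, _, i3, _, i5 = phase_mean_intensities(trace, protocol)
        fractions.append(fractional_reactivation(i1, i3, i5))
    amplitude, rate, _ = fit_exponential_reactivation(n_violet_frames, fractions)
    return {
        "n_violet_frames": list(n_violet_frames),
        "fractions": fractions,
        "plateau": amplitude,
        "rate_per_frame": rate,
        "configured_rate_per_frame": rates.k_dr_per_ms_violet * 7.0,
        "shelvable_fraction": rates.shelvable_fraction,
        "n_molecules": n_molecules,
    }


# -- estimator cross-checks ---------------------------------------------


def em_oracle_check(seed, n_instances: int = 20) -> dict:
    """Reduced-model EM vs. brute-force simplex search on tiny inputs.

    On instances of at most 5 trajectories with at most 3 jumps each, the
    EM bound fraction is compared with an exhaustive grid search over the
    two-state fraction simplex at 0.01 resolution.
    """
    rng = np.random.default_rng(seed)
    grid = DiffusionGrid(d_values=np.array([D_BOUND, D_FREE]))
    b = grid.b_values()
    max_dev = 0.0
    for _ in range(n_instances):
        n_traj = int(rng.integers(1, 6))
        motion = MotionModel(
            d_bound=D_BOUND, d_free=D_FREE, f_bound=float(rng.random())
        )
        ts = simulate_two_state_trajectories(
            n_traj, motion, seed=int(rng.integers(2**31 - 1)),
            mean_track_length=2.5,
        )
        stats = ts.jump_stats()
        n_j = stats["n_jumps"].to_numpy(float)
        s_r2 = stats["sum_r2"].to_numpy(float)
        # brute force over the fraction simplex
        fs = np.linspace(0.0, 1.0, 101)
        best_f, best_ll = 0.0, -np.inf
        for f in fs:
            w = np.array([f, 1.0 - f])
            with np.errstate(divide="ignore"):
                per_state = (
                    -np.outer(n_j, np.log(b)) - np.outer(s_r2, 1.0 / b)
                    + np.log(w)[None, :]
                )
            ll = float(
                np.sum(
                    np.logaddexp(per_state[:, 0], per_state[:, 1])
                )
            )
            if ll > best_ll:
                best_f, best_ll = float(f), ll
        fit = fit_reduced(ts, (D_BOUND, D_FREE))
        max_dev = max(max_dev, abs(fit.fractions[0] - best_f))
    return {"max_abs_deviation": max_dev, "n_instances": n_instances}


def displacement_moment_check(seed, n_jumps_target: int = 100_000) -> dict:
    """Monte-Carlo displacement statistics vs. the likelihood model.

    The mean squared 2-D displacement must equal b = 4(DΔt + σ²), and the
    grid D maximizing the jump log-likelihood must match the moment
    estimator (mean r²/4 − σ²)/Δt.
    """
    motion = MotionModel(d_bound=D_BOUND, d_free=2.0, f_bound=0.0)
    mean_len = 51.0
    n_traj = int(np.ceil(n_jumps_target / (mean_len - 1)))
    ts = simulate_two_state_trajectories(
        n_traj, motion, seed=seed, mean_track_length=mean_len
    )
    stats = ts.jump_stats()
    n_jumps = int(stats["n_jumps"].sum())
    mean_r2 = float(stats["sum_r2"].sum()) / n_jumps
    dt_s = motion.frame_interval_ms / 1000.0
    b_true = 4.0 * (motion.d_free * dt_s + motion.sigma_loc**2)
    d_moment = (mean_r2 / 4.0 - motion.sigma_loc**2) / dt_s
    dense = np.linspace(0.5 * motion.d_free, 1.5 * motion.d_free, 2001)
    n_tot, s_tot = float(stats["n_jumps"].sum()), float(stats["sum_r2"].sum())
    b = 4.0 * (dense * dt_s + motion.sigma_loc**2)
    lls = -n_tot * np.log(b) - s_tot / b  # pooled jump_loglik over the grid
    d_ml = float(dense[int(np.argmax(lls))])
    return {
        "mean_r2": mean_r2,
        "b_true": b_true,
        "rel_err_mean_r2": abs(mean_r2 - b_true) / b_true,
        "d_moment": d_moment,
        "d_ml": d_ml,
        "rel_dev_ml_vs_moment": abs(d_ml - d_moment) / d_moment,
        "n_jumps": n_jumps,
    }


def flim_recovery(seed, tau_ns: float = 2.5, n_photons: int = 100_000) -> dict:
    """Lifetime recovery from a simulated decay, plus the FRET identity."""
    decay = simulate_flim_decay(tau_ns, n_photons, bin_width_ns=0.05, n_bins=500, seed=seed)
    fit = fit_monoexponential(decay)
    tau0 = 4.1  # donor-only reference lifetime, ns
    return {
        "tau_true_ns": tau_ns,
        "tau_fit_ns": fit.tau_ns,
        "rel_err": abs(fit.tau_ns - tau_ns) / tau_ns,
        "fret_short_linker": fret_efficiency(0.729 * tau0, tau0),
        "n_photons": n_photons,
    }
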