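# Methods

This note documents the models, estimators, and design choices behind
`papa_spt`, and what the simulation-based validation does and does not
demonstrate.

## Background

Proximity-assisted photoactivation (PAPA) is a photophysical effect in
rhodamine-family dyes: a "receiver" fluorophore (e.g. JFX650) that has been
driven into a reversible dark state by intense red illumination
("shelving") can be reactivated by exciting a nearby "sender" fluorophore
(e.g. JF549) with green light. Violet light reactivates the same dark
state directly (direct reactivation, DR), independent of any sender. The
ratio of green- to violet-induced recovery therefore reports on
sender–receiver proximity, i.e. on protein–protein interaction when the
two dyes label different proteins; and single-particle trajectories that
start right after a green pulse are optically enriched for double-labeled
complexes.

## Illumination model

A protocol is an ordered list of phases repeated over cycles, written in
bracket notation (`250 R [2 ms]` = 250 frames, one 2 ms red pulse per
frame). The camera runs at a fixed frame interval (default 7.48 ms).
Frames are 0-based; analysis windows are half-open `[start, end)`. The
post-pulse window for classifying trajectories excludes the pulse frame
itself — stimulation frames may carry no red excitation, and counting
reactivated molecules from the next frame is the conservative choice.
Mixed frames such as `1 V [0.5 ms] + R [2 ms]` carry a concurrent red dose
so imaging continues through stimulation. Each pulse must fit within the
frame interval individually; simultaneous pulses in one frame may sum to
more than the interval.

## Photophysics model

Each receiver molecule is a discrete-frame Markov chain over
{BRIGHT, DARK, BLEACHED}, advanced once per frame using the light doses
delivered in that frame. A rate k (per ms of dose) converts to a per-frame
transition probability `1 − exp(−k · dose_ms)`; with doses ≤ 7 ms this
approximation is accurate to well under a percent for the rates of
interest. At most one transition happens per molecule per frame;
transitions caused by light in frame f take effect from frame f+1.

States and transitions:

* **BRIGHT → DARK / BLEACHED** under red dose, as competing risks with
  rates `p_shelve_per_ms_red` (default 0.0025/ms) and `p_bleach_per_ms_red`
  (default 0.0005/ms). Only a `shelvable_fraction` of molecules (default
  0.10, matching the observed ~10% recoverable fraction for
  JFX650-SNAPf-class labels) carries the shelving rate; the rest can only
  bleach. A continuous pre-shelving exposure (e.g. 10 s of red before
  acquisition) is applied with the exact competing-risks solution rather
  than frame stepping.
* **DARK → BRIGHT** with rate `k_dr_per_ms_violet` per ms of violet dose;
  rate `k_papa_per_ms_green` per ms of green dose if the molecule carries
  an unbleached sender, else `k_papa_background_per_ms_green` (the residual
  sender-independent green reactivation observed experimentally); plus a
  spontaneous per-frame probability `p_spont_per_frame` (default 1e-5).
  The three routes are combined into a single per-frame draw.
* **Sender bleaching** under green dose (`p_sender_bleach_per_ms_green`),
  which silently converts a double-labeled molecule into an effectively
  receiver-only one.
* The dark state is recoverable by default (`p_dark_bleach_per_frame = 0`),
  consistent with green and violet light recovering the same pool; a
  dark-state bleaching rate is available but off by default.

Default rates were chosen once to reproduce the qualitative experimental
regime: near-complete shelving/bleaching after ~10 s of intense red,
percent-scale per-pulse reactivation probabilities, and a dark pool that
re-forms over a few hundred frames of imaging after each reactivation
pulse. The simulator deliberately encodes only an *effective* per-green-ms
reactivation rate; the physical mechanism of PAPA (diffusible intermediate
vs. long-range energy transfer) is left open by the data and is not
modeled.

## Motion and imaging model

Molecules move by two-state Brownian motion in a square field of view with
reflecting boundaries: diffusion coefficients `d_bound` (default 0.01
µm²/s) and `d_free` (default 8.3 µm²/s), a bound fraction `f_bound`, and
optional bound↔free switching rates (static assignment by default).
Localizations are emitted only on BRIGHT frames, as the true position plus
isotropic Gaussian localization error (`sigma_loc`, default 0.035 µm per
axis). Runs of consecutive bright frames form trajectories; dark gaps
split them unless gap bridging is enabled.

Camera rendering integrates a 2-D Gaussian PSF (σ = 1 pixel by default,
0.16 µm pixels) over pixel areas and adds Poisson shot noise on signal
plus uniform background. The instrument's pixel size and localization
precision are not uniquely fixed by the experimental design; the defaults
are typical for HILO single-molecule microscopes of this class and are
exposed in the configuration. Ensemble intensity traces are generated as
Poisson draws around `n_bright × photons + background`, with frames
lacking red excitation contributing background only (receiver dyes emit
in the red channel only while excited).

Not modeled, by design: defocalization (loss of fast molecules from the
focal plane — this is a single-plane 2-D world), motion blur during the
2 ms stroboscopic pulses (stroboscopic illumination exists precisely to
suppress it), 3-D PSFs, EMCCD gain statistics, and sender-channel image
formation (the sender is simulated kinetically only). Consequences:
simulated free-molecule trajectories are longer than real ones, absolute
bound-fraction estimates are free of the defocalization bias real data
carries, and passing tests say nothing about those corrections.

## Tracking

Spot detection band-passes each frame with a difference of Gaussians
(σ, 2σ), takes local maxima above a threshold expressed in estimated
integrated photons (converted analytically to a filter-response
threshold), refines positions by least-squares fit of a fixed-σ 2-D
Gaussian with an intensity-weighted-centroid fallback, and merges
duplicates within 2σ keeping the brighter. Linking is greedy
nearest-neighbour per frame transition, resolved globally in ascending
distance order with a canonical (x, y) sort for order independence;
pairs beyond `max_disp_um` (default 1.5 µm, >4σ of an 8.3 µm²/s jump at
7.48 ms) start new tracks. This is a functional stand-in for standard
sparse-field SPT trackers, validated on synthetic movies (≥90% recall at
≥300 photons/spot and ≥90% correct links at sparse density); it does not
attempt bit-parity with any particular package.

## Trajectory classification

PAPA trajectories are the localization segments falling in the first
`window` frames (default 30) after each green pulse; DR segments follow
violet pulses. Trajectories overlapping a window are clipped to it;
localizations outside all windows are dropped; a long-lived molecule may
contribute segments to several windows (each segment gets a fresh id and
a `source_pulse` reference). Whether segments should instead be required
to *start* inside a window is not uniquely determined by the assay; the
clipping rule is this package's choice. Before comparing classes, the
larger set is subsampled uniformly without replacement to match the
smaller (seeded, deterministic). Segments with fewer than two
localizations carry no displacement information and are ignored by the
spectrum estimators, which report usable trajectory and jump counts.

## Diffusion-spectrum inference

Each trajectory is assumed to sample one diffusive state from a fixed
ascending grid (default 100 log-spaced values, 0.01–100 µm²/s). Given a
state with coefficient D, each squared 2-D displacement over one frame
interval is exponential with mean `b = 4(DΔt + σ²)`; jumps within a
trajectory are treated as independent given the state (the standard
state-array approximation), and gap-spanning jumps are excluded. Grid
occupations are estimated by expectation–maximization of the mixture
posterior with a symmetric Dirichlet(α) prior — MAP-EM, flat (α = 1) by
default, tolerance 1e-6 on occupations, at most 1000 iterations, with the
log-posterior guaranteed non-decreasing and the convergence status
reported. This is the package's own estimator in the spirit of
state-array samplers; it claims no numerical parity with external
implementations, whose priors and defocalization handling differ.

Because σ is a fixed input rather than estimated, states below
σ²/Δt ≈ 0.16 µm²/s are not resolvable and truly immobile molecules pile
up at the grid minimum (0.01 µm²/s), the conventional "bound" anchor.
`fraction_bound` sums occupations strictly below a threshold (default
0.15 µm²/s). Reduced fixed-state fits (e.g. {0.01, 8.3} µm²/s, or
three-state and {0.01, 4.4} sets) use the same EM on a small grid and
return maximum-likelihood fractions.

## Spectral unmixing and fold enrichment

A measured spectrum is decomposed as `f·A + (1−f)·B` over two
single-component reference spectra on the same grid by simplex-constrained
least squares (closed form for two components). Maximum-likelihood
spectra concentrate mass on a few grid atoms whose exact positions jitter
between datasets, which biases a raw L2 projection; all three occupation
vectors therefore pass through the same moving-average filter (width 5
grid points) before projection. The filter is linear, so any target that
is exactly a convex combination of the bases is still recovered exactly,
and label-swap symmetry is preserved. The component ratio is `f_a/f_b`
(reported to 2 significant figures), and fold enrichment is the PAPA
ratio divided by the DR ratio. Zero denominators are reported as infinite
and refuse to propagate into enrichment. Whether such linear-combination
fits are best done on occupations or on displacement histograms is an
open choice; occupations on the shared grid are used here. Only the
two-component case is exercised; the nonspecific PAPA background is not
modeled as its own component.

## Ensemble intensity analytics

Sawtooth traces are raw per-frame pixel sums (no background subtraction),
averaged frame-by-frame across cells. The response to a pulse at frame p
is `mean(trace[p+1 .. p+w_post]) − mean(trace[p−w_pre .. p])` with 10-frame
windows by default — the window length balances Poisson averaging against
re-shelving decay and is configurable. `skip_first` drops the first pulse
of each colour in a movie to avoid the initial shelving transient of
short protocols. An optional `detrend` mode fits a line to the pre-window
and subtracts its extrapolation under the post window: the plain
difference estimator is biased wherever the baseline decays appreciably
between the two windows (most visibly right after a saturating
reactivation train, and in null controls where the true step is zero),
and the detrended estimator removes that first-order bias. The PAPA/DR
ratio is the mean green increase over the mean violet increase; it is
invariant to overall gain. Rate fits of ratio vs. green pulse duration go
through the origin (`y = ax`), inverse-variance weighted when errors are
given, with an uncentered R².

Fractional reactivation from the five-phase kinetics assay is
`(i5 − i3)/(i1 − i3)` on the three probe-phase mean intensities — the
recovered fraction of the shelving-induced drop — fitted to
`A(1 − exp(−kN))` over the violet frame count N. With competing
shelving/bleaching rates the plateau A approximates the shelvable
fraction; the approximation is exact only when every molecule leaves the
bright state during the shelving phase, and the simulated design
(400 × 7 ms red frames at the default rates) reaches A ≈ 0.10–0.11 for a
true shelvable fraction of 0.10.

## FLIM-FRET

Donor lifetimes are maximum-likelihood fits of a record-truncated
mono-exponential to TCSPC histograms (multinomial likelihood per bin, no
instrument-response deconvolution — a deliberate simplification valid for
the synthetic decays used here, not for real TCSPC hardware). Fits from
fewer than 50 photons are flagged unreliable; standard errors come from
the observed Fisher information. Nuclear masks are Otsu thresholds
keeping the largest connected component; the mean nuclear lifetime is
unweighted by default with a photon-weighted option. FRET efficiency is
`E = 1 − τ/τ₀` with τ₀ measured from donor-only samples and taken as an
exact input (its uncertainty is not propagated).

## Validation studies and problem sizes

`papa_spt.experiments` defines the canonical simulated studies run by the
test suite and by `scripts/acceptance.py`. Problem sizes were chosen to
resolve each effect comfortably on one CPU in seconds to ~1 minute: 2,000
trajectories (mean length 8 frames) for two-state recovery and spectrum
shape; 10,000 molecules over ten 1,002-frame cycles for the two-component
mixture pipeline; 50,000 molecules for the linear-regime dose series
(green pulses 0.5–7 ms at k·dose ≤ 0.05) and the occlusion contrast;
30,000 for the sender-dependence null and the reactivation kinetics
series (N = 1–64 violet frames); ~10⁵ jumps for displacement-moment
checks; 10⁵ photons for lifetime recovery. The null-control study uses a
20 s pre-bleach (vs. 10 s elsewhere) so that the non-reactivatable bright
background, whose nonlinear decay otherwise leaks curvature into the
green-step statistic, is fully gone before probing.

All generators are bit-reproducible given (parameters, seed); every
stochastic stage of the pipeline records its seed, and pipeline manifests
record SHA-256 hashes of all artifacts so cached stages are re-used only
when config, upstream results, and on-disk files all match.

## Known limitations

* Dataset-specific quantities from real imaging (cell-count-dependent
  p-values, enrichment factors of particular constructs, measured FRET
  efficiencies) depend on the original data and are covered only by
  directional properties here.
* The two-state motion model has no defocalization and no photon-count
  dependence of localization precision; absolute bound fractions from
  real data will differ.
* The classifier's clipping rule and the 30-frame window are conventions;
  results are insensitive to the exact window in simulation but this was
  not tuned against real data.
* The unmixing assumes exactly two components and clean single-component
  references; contamination of references propagates directly into the
  enrichment estimate.
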