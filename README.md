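# papa_spt

Simulation and analysis of **proximity-assisted photoactivation
single-particle tracking (PAPA-SPT)** experiments.

PAPA is a photophysical property of rhodamine dyes: a "receiver"
fluorophore (e.g. JFX650) that intense red light has shelved into a
reversible dark state can be reactivated by exciting a nearby "sender"
fluorophore (e.g. JF549) with green light, whereas violet light
reactivates the same dark state directly (**DR**), regardless of any
sender. In live cells this turns reactivation into an interaction
readout: label one protein with the sender and another with the receiver,
shelve, then alternate green and violet pulses while imaging in red. The
**PAPA/DR ratio** — mean fluorescence increase after green pulses divided
by that after violet pulses — reports sender–receiver proximity, and the
single-molecule trajectories that appear right after green pulses are
optically *enriched* for double-labeled complexes, so their diffusion
behaviour can be compared with the overall population.

The package is aimed at single-molecule microscopists and method
developers who want to design, simulate, and analyze PAPA-SPT experiments
with known ground truth. It provides:

* **`illumination`** — protocols in the field's bracket notation
  (`10 cycles of 250 R [2 ms], 1 V [7 ms], 500 R [2 ms], 1 G [7 ms],
  250 R [2 ms]`), frame/dose queries, post-pulse analysis windows;
* **`synthetic_data`** — per-molecule photophysics (shelving, bleaching,
  DR, sender-dependent PAPA, spontaneous recovery), two-state Brownian
  motion with localization error, camera movies, sawtooth intensity
  traces, TCSPC decays;
* **`tracking`** — spot detection and greedy nearest-neighbour linking
  for sparse movies; trajectory CSV I/O;
* **`classify`** — splitting trajectories into PAPA/DR post-pulse
  segments, count balancing, single-molecule persistence scoring;
* **`spectrum`** — fixed-grid diffusion-spectrum inference by MAP-EM on
  the jump likelihood `r² ~ Exp(4(DΔt + σ²))`, reduced two/three-state
  fits, fraction bound below 0.15 µm²/s;
* **`unmix`** — simplex-constrained decomposition of a spectrum over two
  single-component references and the PAPA-vs-DR fold enrichment;
* **`ensemble`** — sawtooth analytics: pulse responses, PAPA/DR ratio,
  linear rate fits vs. pulse duration, reactivation kinetics;
* **`flim`** — mono-exponential TCSPC lifetime fits and FRET efficiency
  `E = 1 − τ/τ₀`;
* **`cli` / `pipeline`** — a `papa-spt` command with `demo`, `run`,
  `simulate`, `track`, `classify`, `spectrum`, `unmix`, `ensemble`, and
  `flim` subcommands, plus manifest-based caching for reproducible runs.

See `docs/methods.md` for the models, estimators, and their assumptions.

## Worked example

The bundled demo simulates a defined two-component mixture — 1,500
free-diffusing molecules labeled with both sender and receiver, 1,500
chromatin-bound molecules with receiver only — under four illumination
cycles with alternating violet and green pulses, then tracks the analysis
through classification, diffusion spectra, and unmixing:

```bash
papa-spt demo --outdir papa_demo --seed 1
```

which ends by printing the unmixing report:

```json
{
  "f_papa": {
    "free_double": 0.7611165010830161,
    "bound_single": 0.2388834989169839
  },
  "f_dr": {
    "free_double": 0.5376658147765799,
    "bound_single": 0.46233418522342007
  },
  "ratio_papa": 3.1861409621579475,
  "ratio_dr": 1.1629376151727917,
  "ratio_papa_2sf": 3.2,
  "ratio_dr_2sf": 1.2,
  "enrichment": 2.739735064537012,
  "enrichment_1dp": 2.7
}
```

Reading it: DR (violet-reactivated) trajectories split roughly evenly
between the two species (54% / 46% — violet reactivation is blind to the
sender), while PAPA (green-reactivated) trajectories are dominated by the
double-labeled species (76% / 24%). The component ratio rises from ~1.2
among DR trajectories to ~3.2 among PAPA trajectories: a **2.7-fold
optical enrichment** of double-labeled molecules in this small demo run.
The output directory also contains the trajectory and spectrum CSVs, a
`report.json` with bound fractions per class, and a `manifest.json` with
seeds and artifact hashes; re-running the same command reuses cached
stages bit-identically.

The same calculation on the canonical published-style fractions is a
two-liner:

```python
>>> from papa_spt.unmix import MixtureFit, component_ratio, fold_enrichment
>>> papa, dr = MixtureFit(0.91, 0.09, 0.0), MixtureFit(0.53, 0.47, 0.0)
>>> component_ratio(dr), component_ratio(papa), fold_enrichment(papa, dr)
(1.1276595744680853, 10.111111111111112, 8.966457023060796)
```

— a DR ratio of ~1.1, a PAPA ratio of ~10, and an approximately ninefold
enrichment.

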