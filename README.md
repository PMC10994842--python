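# septatrack

Single-molecule analysis of bacterial divisome dynamics on the division
septum, for researchers doing vertical-cell (end-on) single-molecule imaging
of septal peptidoglycan synthases such as PBP2B or FtsW in *Bacillus
subtilis*.

When a dividing cell is stood upright in a micro-hole, its division ring
lies in a single focal plane and sparsely labelled synthase molecules appear
as diffraction-limited spots moving on a circle. `septatrack` turns such
time-lapse movies into quantitative motion and stoichiometry statistics:

* **ring geometry** — maximum-intensity projection, cytoplasmic background
  subtraction by morphological opening, sub-pixel circle fit (weighted
  Taubin + RANSAC over spot maxima + on-circle intensity refinement), and
  polar unwrapping into a time × ring-angle **radial kymograph**;
* **tracking** — Laplacian-of-Gaussian spot detection, greedy
  nearest-neighbour linking with gap closing (0.5 µm link distance, 5-frame
  gaps, tracks ≥ 10 frames), and automated partitioning of each track into
  **immobile / processive / fast** motion states by penalized
  piecewise-linear changepoint segmentation of arc position vs time;
* **population statistics** — speed histograms fitted by a sum of Gaussians
  with the immobile component's mean fixed at 0 nm/s (processive speed =
  mean of the non-zero component, 95% CI by case-resampling bootstrap), and
  time-averaged MSD fits to the anomalous-diffusion model
  `MSD(t) = 4 D_eff t^α`;
* **kinetics** — censoring-aware exponential lifetimes
  ⟨t_A⟩ = Σ observed time / # uncensored exits, competing transition rates
  `k_B = B / ⟨t_A⟩` (with `k_A = Σ k_X = 1/⟨t_A⟩`), state occupancies, and
  Eyring two-temperature rate ratios
  `k₁/k₂ = (T₁/T₂)·exp(−(ΔH‡/R)(1/T₁ − 1/T₂))`;
* **stoichiometry** — changepoint detection of discrete intensity halvings
  (subunit bleaching) and doublings (subunit arrival) in single-track
  intensity traces, and their per-track prevalence;
* **synthetic movies** — a first-class generator that encodes the same
  model the analysis assumes: a three-state semi-Markov chain (exponential
  dwells, competing exits incl. direction reversals and terminal
  bleaching/dissociation), processive motion at `±v/r` rad/s, fast-state
  2-D fractional Brownian motion with `MSD = 4 D_eff t^α`, PSF rendering
  with motion blur, Poisson shot noise and read noise, written as
  ImageJ-compatible 16-bit TIFF plus a ground-truth JSON sidecar. Condition
  presets encode measured operating points (untreated rich-media 30 °C:
  13.4 nm/s processive mean; FtsZ-treadmilling-arrested: 8.1 nm/s;
  transpeptidation/lipid-II blocked: no processive population).

Because every estimator can be scored against the generator's ground truth,
the whole pipeline is validated by parameter recovery without any external
data.

## Worked example

Simulate an untreated-condition movie, analyze it, and run a full
parameter-recovery check:

```
$ septatrack simulate --seed 1 --preset untreated_rich_30C \
      --n-molecules 8 --n-frames 120 --out demo
{ "tiff": "demo/movie.tif", "truth": "demo/movie.truth.json", ... }

$ septatrack analyze demo/movie.tif --out demo
{ "results": "demo/results.json", "n_tracks": 14 }

$ septatrack recover --seed 1 --preset untreated_rich_30C --n-tracks 400
{
 "preset": "untreated_rich_30C",
 "n_speeds": 637,
 "processive_mean_fit": 13.01,
 "processive_mean_truth": 13.4,
 "processive_mean_pass": true,
 "occupancy":        { "immobile": 0.379, "processive": 0.589, "fast": 0.032 },
 "occupancy_oracle": { "immobile": 0.380, "processive": 0.590, "fast": 0.030 },
 "occupancy_pass": true
}
```

The `analyze` step writes `results.json` (ring geometry, speed-mixture fit,
per-state lifetimes/rates, step fractions) plus `tracks.csv` and
`segments.csv`. The `recover` report compares re-estimated quantities with
the generating truth: here the fitted processive-population mean
(13.01 nm/s) recovers the preset truth (13.4 nm/s) within tolerance, and
the measured state occupancies match the semi-Markov chain's analytic
stationary occupancies.

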