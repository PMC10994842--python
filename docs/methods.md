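# Methods

## The motion model

A labelled synthase molecule on the septal ring is modelled as a three-state
semi-Markov process. Dwell times in each state are exponential with mean
τ_state; on leaving a state, a competing outcome is drawn from a fixed
categorical distribution. The states and their kinematics:

* **immobile** — ring angle θ held fixed (interpreted as a wall-bound,
  synthesis-inactive complex);
* **processive** — directed motion along the ring, dθ/dt = ±v/r with the
  episode speed v drawn once per episode from N(μ_v, σ_v) truncated to
  positive values. A `direction_flip` exit starts a new processive episode
  with the sign reversed and the speed redrawn;
* **fast** — slow subdiffusion, modelled as 2-D fractional Brownian motion
  in the (arc, radial) plane with Hurst exponent H = α/2 and amplitude
  chosen so the ensemble MSD equals 4·D_eff·t^α (2·D_eff·t^α per axis).
  fBm increments are generated by Davies–Harte circulant embedding, with a
  Cholesky factorization of the fGn covariance as fallback; this reproduces
  the target MSD exactly in expectation. Because diffusing molecules are
  observed at or outside the septal leading edge (the septum interior is
  occluded by the ingrowing cross-wall), inward radial excursions reflect
  at a boundary 100 nm inside the ring radius.

A `terminal` exit ends the trajectory (photobleaching or dissociation); a
trajectory still alive at the end of the observation window has its final
episode right-censored.

### Preset operating points

The `untreated_rich_30C` preset is the reference condition: processive
speed 13.4 nm/s, immobile lifetime 48 s, processive-exit fractions
{flip 0.29, →immobile 0.12, →fast 0.05, terminal 0.54}, initial/restart
state distribution {0.38, 0.59, 0.03}, D_eff = 6.5×10⁻³ µm²/s, α = 0.80,
ring radius 450 nm. `pc190723` and `ftsZ_G106S` (treadmilling perturbed)
lower the processive speed to 8.1 nm/s; `penicillinG` and `fosfomycin`
(synthesis blocked) remove the processive state entirely; `diffusive_only`
emits pure fBm tracks.

Several quantities the model needs are not constrained by measurement and
are package assumptions, all preset-overridable:

* σ_v = 4 nm/s (processive speed spread; consistent with the width of the
  measured speed histograms);
* τ_P = 40 s and τ_F = 10 s (processive and fast lifetimes);
* exit distributions for the immobile and fast states. The fast exits are
  set to {→immobile 0.30, →processive 0.20, terminal 0.50}; the immobile
  exits {→processive 0.2181, →fast 0.2335, terminal 0.5484} are then the
  (unique) solution making the embedded chain's stationary time occupancies
  equal the measured occupancies {0.38, 0.59, 0.03} given the lifetimes
  above, with terminal events restarting from the initial distribution;
* per-fluorophore bleach rate 0.005 s⁻¹ and photon budget 400
  counts/frame (spot SNR ≈ 8 over a 20-count cytoplasmic background),
  plausible for a bright rhodamine HaloTag ligand under HiLO illumination.

The long-run occupancy of the chain — visits-per-state × lifetime,
normalized, with π the stationary law of the embedded chain including
restart — is available analytically (`kinetics.semi_markov_occupancy`) and
serves as the oracle the simulated trajectories are tested against.

### Rendering

Frames are built as a smooth cytoplasmic disk (logistic edge at 1.35× the
ring radius) plus one isotropic Gaussian PSF per molecule (σ = 110 nm,
about the diffraction limit at ~580 nm emission), evaluated at 5 sub-frame
positions spread across the 0.5 s exposure within the 1 s frame interval to
approximate motion blur, followed by Poisson shot noise, additive Gaussian
read noise (2 counts rms) and 16-bit quantization. Pixel size defaults to
65 nm. Rendering is deterministic given (paths, optics, seed).

## Ring fitting

The circle is fitted on the background-subtracted maximum-intensity
projection. Sparse single-molecule rings are only partially covered, and a
naive fit can collapse onto one bright arc, so three candidate circles
compete: an intensity-weighted algebraic (Taubin) fit of supra-threshold
pixels; a RANSAC consensus over circles through triplets of spot-level
local maxima (maxima sit on the ridge of the true ring even when molecules
cluster); and a coarse grid search maximizing a robust (clipped) on-circle
intensity score. Radii below 250 nm — smaller than any real septum — are
excluded. The winner by weighted point-consensus is polished by Nelder-Mead
on the on-circle score inside a ±0.75 px trust region. On noiseless rings
the recovered geometry is accurate to ≲0.1 px; on sparse noisy movies the
mean radius error over seeds is ~0.3 px, with occasional poorly covered
rings (few molecules, one short arc) failing by more — the synthetic
analogue of fits a microscopist would reject on visual inspection.

Kymographs sample each frame by bilinear interpolation at 360 angular bins
(1°/bin), averaged over radii within ±100 nm of the fitted circle (at least
Nyquist for 65 nm pixels at typical radii). Angle 0 is the image +x axis,
counter-clockwise positive; origin rotation is a cyclic column permutation
and leaves every downstream statistic unchanged.

## Track segmentation

The paper-level workflow annotates kymographs manually; here the
segmentation is automated. For each track the unwrapped arc position (θ
unwrapped by the ±2π branch minimizing each step, times the ring radius) is
segmented by exact dynamic programming over piecewise-linear fits with a
BIC-style penalty (3·log n per changepoint, residuals scaled by a robust
per-step noise estimate from second differences) and a 5-frame minimum
segment. Segments classify as **fast** if the linear-fit residual RMS
exceeds 50 nm (one-frame fBm steps are ~160 nm), otherwise **immobile** if
|slope| ≤ 3 nm/s, otherwise **processive**. Adjacent same-state segments
merge unless they are opposite-sign processive runs, which record a
direction flip. The final segment is right-censored and its end scored
"terminal". On simulated untreated trajectories with 15 nm localization
noise this labels ≈97% of frames correctly and locates direction flips
within ±3 frames.

## Population statistics

Speed magnitudes (signed speeds would split the processive peak) are
histogrammed at 2 nm/s and fitted by weighted nonlinear least squares to a
sum of 2 or 3 Gaussians with the first mean pinned at exactly 0; the
number of components is user-chosen, mirroring the two-component fits used
when the processive population is abolished. The fit is multi-started from
the non-zero histogram mode and two quantiles; the processive mean is the
mean of the component nearest the non-zero mode, flagged degenerate when
its weight is < 0.05 or its mean lies within two bins of zero. The 95% CI
is a case-resampling percentile bootstrap (default 1000 replicates,
replicate refits warm-started from the full-sample fit; > 20% failed refits
raises a warning flag). Histogram bin width, weighting and replicate count
are declared assumptions, exposed in the API.

MSDs are time-averaged over all pair starts per lag (lags 1–10 s by
default, matching the ≥10-frame track-length cut), and `MSD = 4 D_eff t^α`
is fitted by n_pairs-weighted linear regression of log MSD on log lag —
exact on noiseless power laws; on 300 simulated 50-frame fBm tracks the
median recovered α is within 0.03 and median D_eff within 2% of truth.

## Kinetics

Lifetimes use the exponential MLE under right-censoring: total observed
time divided by the number of uncensored exits, s.e.m. = ⟨t⟩/√n_uncensored.
Terminal ends (bleach, dissociation, acquisition end) are right-censored
for the lifetime but counted as the "terminal" outcome in the transition
fractions — the same episode legitimately contributes to both summaries.
Rates follow from k_B = B/⟨t_A⟩; the identity Σ k_X = 1/⟨t_A⟩ holds by
construction and is asserted in tests. Occupancy s.e.m. uses a track-level
bootstrap. The Eyring two-temperature ratio is evaluated in its ΔS‡-free
form with R = 8.314 J/mol/K and kelvin inputs; it is verified by its exact
limits (T₁ = T₂ → 1, ΔH‡ = 0 → T₁/T₂, reciprocal symmetry) rather than
against any rounded narrative summary.

## Intensity steps

Traces are segmented by recursive binary splitting on the mean with a
Welch-t criterion (α = 0.001, Bonferroni-corrected over candidate split
points, minimum level length 5 frames); consecutive level means classify as
`drop_half` for post/pre ratios in [0.35, 0.65], `jump_double` in
[1.7, 2.3] — windows wide enough to absorb shot noise — and `other`
outside both. Prevalence is reported per track over "full" tracks (both
appearance and disappearance observed inside the acquisition), with Wilson
95% CIs. On flat SNR-10 traces the false-event rate is < 2%; halving recall
at SNR 5 with ≥10-frame levels exceeds 90%.

## What the synthetic data do and do not establish

The generator reproduces the statistical structure the estimators assume —
exponential dwells, per-episode constant speeds, fBm subdiffusion,
Gaussian PSF with Poisson/read noise — so passing recovery tests shows the
pipeline is correct and unbiased *under the model*. Real movies add
features the generator omits: uneven illumination, focus drift, moving cell
bodies, fluorophore blinking, chromatic offsets between channels, septa
tilted out of plane, and crossing tracks from multiple lanes (a lane-offset
option exists but is off by default). Recovery on synthetic data therefore
bounds estimator error, not experimental systematics.

## Problem sizes and numerical choices

Recovery analyses use 300–400 simulated trajectories (≥500 segments,
~10⁵ s aggregate for occupancy checks) — enough that Monte-Carlo spread sits
well inside the stated tolerances while a full test run stays interactive.
Degenerate inputs are handled explicitly: all-censored lifetime sets raise,
empty spot lists and event-free traces are valid, zero-MSD lags are
dropped, and ties in θ-unwrapping take the no-jump branch. Greedy linking
(rather than global assignment) is adequate at the sparse labelling
densities simulated here and is a documented limitation for dense data, as
is best-effort resolution of crossing tracks.
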