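# Methods

`rgctools` reimplements, as tested library code, the analysis chain used
to quantify retinal ganglion cell (RGC) function and photoreceptor
survival in retinas undergoing (and rescued from) rod degeneration:
reverse-correlation receptive-field estimation, repeat-trial noise and
mutual-information analysis, and automated outer-nuclear-layer (ONL)
nuclei counting. Because the multielectrode-array recordings such
analyses are normally run on are access-restricted, the package ships a
seeded linear–nonlinear–Poisson (LNP) simulator and a planted-nuclei
image generator that provide ground truth for every analysis; all
quantitative claims the test suite makes are closed loops between those
generators and the analyses.

## Stimulus

Binary checkerboard noise with contrast coded as {−1, +1}. Zero-mean
coding makes the spike-triggered average (STA) an unbiased estimate of
the linear receptive field; all downstream math assumes it. Standard
configurations: 150 µm squares at 66 ms refresh (scotopic/mesopic,
~1 / ~100 Rh*/rod/s) and 75 µm squares at 33 ms (photopic,
~10,000 Rh*/rod/s); repeated stimuli are a 10 s clip presented 100×.
Frames per clip use `floor(clip_ms / refresh_ms)`; a partial trailing
frame is dropped. Checker updates are i.i.d. fair coins from a seeded
PCG64 generator; the light level is metadata only — the simulator, not
the stimulus, changes response regime.

## LNP simulator

Each synthetic cell is space–time separable by construction:

* **Space**: elliptical Gaussian over the checker grid
  (σ_major, σ_minor in µm, arbitrary orientation), unit norm.
* **Time**: difference of two gamma cascades,
  `k(t) = c(t; τ_f) − w·c(t; τ_s)` with
  `c(t; τ) = (t/τ)^n exp(n(1 − t/τ))`, each peaking at `t = τ`. With
  `τ_f < τ_s` and `0 < w < 1` the kernel is biphasic with closed-form
  zero crossing `t₀ = (ln w + n ln(τ_f/τ_s)) / (n(1/τ_s − 1/τ_f))`,
  which is the analytic oracle for the time-to-zero tests. Defaults
  (τ_f = 55 ms, τ_s = 90 ms, n = 4, w = 0.45 → t₀ ≈ 98 ms) sit in the
  range of photopic mouse RGC kernels.
* **Nonlinearity**: saturating rectifier
  `r(g) = baseline + min(slope·(g − θ)₊, r_max)`. The full space–time
  kernel is normalized to unit Frobenius norm, so the generator signal
  `g` has unit variance under binary white noise and θ, slope are in
  generator-SD units (θ defaults to 0.4–0.9; slope 45–75 spk/s per SD;
  r_max 120–220 spk/s in population draws).
* **Spiking**: counts drawn in fine bins (default 1 ms, tiling frames
  exactly). For dispersion φ = 1 they are Poisson. For φ > 1 each bin's
  rate is multiplied by an independent gamma variate with mean 1 and
  variance (φ−1)/λ_bin, making the count variance exactly φ·mean in
  every bin (law of total variance). Because independent overdispersed
  counts add, any rebinning at or above the simulation resolution
  preserves the variance/mean ratio — this is why the measured 5-ms
  Fano-like ratio equals the configured φ. The multiplier leaves the
  mean rate, and therefore the STA, unbiased, matching the empirical
  picture of signal-dependent noise above the Poisson line with
  unchanged receptive fields. This gamma-mixed-Poisson choice is one
  admissible mechanism for that observation, not a biophysical claim.
  Spike times are jittered uniformly within their bin.

**Condition presets** (`WT`, `untreated`, `early`, `mid`, `late`)
scale a condition-independent base draw per cell index — so conditions
are matched draw for draw — with gain_scale (multiplies slope and
r_max), dispersion φ, and t₀_scale (multiplies both kernel time
constants): WT (1.0, φ=1, 1.0), untreated (0.45, 1.9, 1.05),
early (0.92, 1.05, 1.0), mid (0.88, 1.10, 1.0), late (0.62, 1.7, 1.12).
These are qualitative emulations of the observed trends across rescue
timepoints — late rescue leaves gain low, noise high, kernels slow —
chosen so WT sits at a variance/mean ratio of ~1 and ~20 bits/s and
untreated at ~1.9 and ~9 bits/s; they are **not** fits to any recorded
population, and no test asserts recorded values against them. Cells
carry retina, sex, age and cell-type labels (two kinetic archetypes) so
the statistics layer has real grouping structure.

## Receptive-field analysis

* **STA**: `kernel[ℓ]` is the mean stimulus frame ℓ frames before each
  spike's frame (half-open frame assignment; lag 0 = the spike's own
  frame). Spikes in the first `depth` frames are excluded so every
  window is complete. Default depth covers 500 ms (15 frames at 33 ms,
  8 at 66 ms).
* **Separability screen**: SVD of the (lag × space) unfolding;
  `variance_fraction = σ₁²/Σσᵢ²`. A cell is analyzed further iff the
  fraction is ≥ 0.60 **and** the temporal factor is biphasic. Signs are
  fixed so the spatial map's peak is positive; the temporal factor then
  carries polarity (dominant lobe positive = ON). The temporal factor
  has unit norm; all scale lives in the spatial map / nonlinearity.
* **Biphasic test**: an opposite-sign lobe at larger lag whose peak is
  at least 5% of the dominant lobe. The 5% floor is this package's
  choice (degenerate ripples below it have no stable zero crossing).
* **Time-to-zero**: linear interpolation between the bracketing samples
  of the dominant-to-undershoot sign change; lag ℓ is assigned time
  ℓ·refresh (the mean time-before-spike of that frame). The recovered
  t₀ converges to the analytic crossing as the refresh shrinks and is
  within one refresh interval at 33 ms.
* **Spatial fit**: least-squares elliptical 2-D Gaussian (amplitude,
  center, σ_major, σ_minor, angle, offset), moment-initialized, on maps
  whose checker (row, col) is centred at ((col+½)·square, (row+½)·square)
  µm. Cells with `fit_r2 < 0.5` are excluded with a reason code. The
  reported ellipse is the 2σ contour; the "effective diameter" is the
  geometric mean of its axis lengths (4·√(σ_maj·σ_min)). That geometric
  mean is a length, so the RF *area* is defined here as the area of the
  circle with that diameter, π·(d/2)²; the raw σs and angle are always
  reported alongside so any other convention can be computed.
* **Nonlinearity and gain**: generator signal = unit-Frobenius-norm
  rank-one filter convolved with the stimulus (so rescaling contrast
  while inversely rescaling the filter changes nothing); equal-count
  (quantile) bins, default 20, robust to the generator distribution's
  shape; gain = rate linearly interpolated at 50% of the maximum
  observed generator value. The x-axis reading of "50% of peak" (rather
  than 50% of peak *rate*) is adopted because the contrast-response
  function is plotted against the generator axis; the full binned curve
  is returned so the alternative is computable.
* **Exclusions**: every excluded cell carries a reason code
  (`non-separable`, `non-biphasic`, `bad-fit`, `no-spikes`).

A note on the rank-one variance fraction: for a noisy STA it equals
signal energy / (signal + noise energy), and the noise energy is
(number of kernel entries)/n_spikes. It therefore depends on grid size
and recording length, not only on the cell. The closure tests use a
compact 6×6 photopic patch and a long recording (~250k spikes) where
the fraction reaches ~0.995; at 20k spikes on the same grid the noise
floor alone holds it near 0.97 even for a perfectly separable cell.

## Repeat-trial fidelity

* **Noise**: spike counts per (repeat × 5 ms bin); across-repeat mean
  and unbiased (n−1) variance per bin, each averaged over bins; their
  ratio is 1 for Poisson responses and equals the configured φ for the
  simulator's overdispersed cells.
* **Mutual information (direct method)**: counts clipped to a binary
  alphabet (multiple spikes in a 4–6 ms bin are rare; the clip level is
  configurable and logged), tokenized into non-overlapping word-aligned
  words of 3–6 bins. `H(R)` is the plug-in entropy of word frequencies
  pooled over all slices and repeats; `H(R|S)` the mean over slices of
  the across-repeat word entropy; `I = (H(R) − H(R|S)) / word_duration`
  in bits/s. Plug-in entropies are used without extrapolation; an
  optional Miller–Madow-style correction exists in the bias analysis of
  the tests but is not applied by default. By concavity of entropy,
  I ≥ 0 always; for stimulus-independent responses I converges to the
  small-sample bias, approximately (|A|−1)/(2·n_repeats·ln 2) bits per
  word, which is the yardstick the shuffle tests use.
* **Word-parameter selection**: the (bin, word) grid 4–6 ms × 3–6 bins
  is scanned and the setting whose noise-entropy plug-in estimate is
  closest to its Ma (coincidence) bound −log₂Σp² is selected, ties to
  the smallest bin then the smallest word; the full grid is attached as
  a diagnostic so any other rule can be applied post hoc. Despite the
  customary "Ma Upper Bound" name, −log₂Σp² is the Rényi order-2
  entropy and **lower**-bounds Shannon entropy; selection uses
  proximity, not direction, and the property suite verifies
  Ma ≤ plug-in on arbitrary distributions.
* **Autocorrelograms**: pairwise spike-time differences within ±window,
  self-pairs excluded, normalized by n_spikes·bin to a conditional rate
  (flat at the mean rate for Poisson trains; zero inside a refractory
  period). **Cell-type clustering** standardizes RF metrics plus
  autocorrelogram features and runs seeded k-means with a silhouette
  diagnostic.

## Histology

The counting pipeline: (1) local contrast normalization — each pixel
centred and scaled by its window's mean and SD, computed with box sums;
the local z-score is mapped linearly from a fixed range (−2, 10) onto
0–255, so the standard 8-bit cutoff 104 (= 0.4 normalized) corresponds
to z ≈ 2.9, about three background SDs. The z-score is invariant to
affine intensity changes, making every downstream count invariant to
global gain/offset and insensitive to smooth shading. The window
(default 201 px ≈ 40 µm at 0.2 µm/px) must be several nucleus diameters
wide, or nuclei normalize themselves away. (2) Threshold at ≥ 104
(inclusive; the equivalent normalized cutoff 0.4·255 ≈ 102 is close but
104 is taken as the authoritative 8-bit value). (3) Connected
components (8-connectivity) with two rules: width = minor axis of the
moment-based component ellipse must be ≥ 2.1 µm, and the nearest
edge-to-edge distance between surviving components must be ≥ 1.05 µm —
both members of a violating pair are removed, and edge distance is
measured between pixel outlines (minimum pixel-centre distance minus
one pixel pitch). (4) Counts of detection centroids inside three
rectangles of exactly 1000 µm² spanning the band height, centred at
25%, 50%, 75% of the image width, averaged. (5) Survival fraction =
mean count / reference mean count, with a delta-method standard error
from per-region SEMs. Stacks are max-projected over up to 15 z-slices
on load. Instead of manual correction of out-of-focus nuclei, a
low-confidence flag is raised when components failing the width rule by
less than 20% exceed 10% of candidates.

The synthetic ONL generator plants elliptical nuclei with known
half-max geometry (valid: minor-axis FWHM 3.2–4.8 µm, mutual gaps
≥ 2 µm; invalid: sub-width FWHM 0.9–1.4 µm, or full-width nuclei
0.25–0.55 µm from a neighbor) and labels each by the stated rules.
Nuclei render as order-5 super-Gaussian (flat-top, sharp-edged)
profiles: plain Gaussian profiles at these sizes produce a saddle above
half max for any gap below ~1.5 µm, which would make the separation
rule untestable end to end; DAPI-stained nuclei do have sharp borders.
Width bookkeeping (FWHM) is independent of the profile order, and
`profile_order=1` recovers a Gaussian. Planted density is sparse
(~12 nuclei per 100 × 100 µm field) — far below a real ONL, where
nuclei violate the separation rule en masse and manual correction was
needed; the generator is a detector test surface, not a tissue model.
Sub-micron planted gaps sit at the pixel/optical resolution limit: in
a minority of rendered images a close pair merges into one component
instead of being removed as two, so the exactness of the width and
separation filters is asserted on binary maps with constructed
component geometry, and the renderer loop is held to the
recall/precision criterion on constraint-satisfying images.

## Statistics

Two-sided Kolmogorov–Smirnov tests compare metric distributions between
groups (exact p-values for n₁·n₂ ≤ 10⁴, verified against an exhaustive
label-permutation oracle at small n; asymptotic otherwise), with
Bonferroni correction over exactly the family of comparisons declared
in one run (the family is printed in the report). The mixed-effects
model fits `metric ~ condition (+ condition × sex + condition ×
cell_type)` with a REML random intercept per retina (statsmodels
MixedLM; the default optimizer chain is used — `method="lbfgs"` alone
returns spurious boundary fits on these designs). Fixed-effect p-values
default to a *t* reference with between-within degrees of freedom
(n_retinas − n_condition_levels): the condition varies between retinas,
so the effective sample size is the number of retinas, and Monte-Carlo
calibration at 5–10 retinas per condition puts this choice at a type-I
error of ~0.05 where the large-sample normal approximation (available
as `df_method="normal"`) inflates to ~0.13. Variance-component recovery
is validated against the realized variance of the planted intercepts.

## Pipeline and problem sizes

`run_pipeline` chains stimulus → simulation → receptive fields →
repeat-trial fidelity → condition summaries under one top-level seed;
re-running a config is bit-reproducible, and the JSON report records
seeds, versions and the comparison family. The demo configuration uses
a 10 × 10 photopic patch, ~16.5 min of noise (30,000 frames), 8 cells ×
2 retinas per condition and 100 repeats of a 10 s clip — sizes chosen
so a full five-condition run completes in about a minute on one core
while leaving every qualitative ordering (gain and information:
late < early ≈ mid ≈ WT; variance/mean: late and untreated > WT) stable
across seeds. `scripts/acceptance.py` re-runs all the closed-loop
checks from scratch at the same sizes.

## What passing tests do and do not show

The simulator produces exactly the response family the analyses assume
(rank-one kernels, static nonlinearity, conditionally independent
spiking) and the image generator produces isolated sharp-edged nuclei.
Passing tests therefore demonstrate the *estimators* are correct and
calibrated on data satisfying their assumptions — they do not show that
real degenerating retinas are LNP, that real STAs are separable (the
screen exists precisely because many are not), or that real ONL
sections are sparse. Known limitations: no spike-history or coupling
terms, no spontaneous late-degeneration oscillations, no stimulus
reconstruction, plug-in (unextrapolated) entropies, and a nuclei
counter validated only in the sparse regime.
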