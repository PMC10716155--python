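# rgctools

Analysis tools for retinal ganglion cell (RGC) physiology and retinal
histology, built for studies of photoreceptor degeneration and genetic
rescue: how well does the retina's output signal survive rod loss, and
how many photoreceptors remain?

The package is aimed at retinal electrophysiologists working with
multielectrode-array recordings under checkerboard-noise stimulation,
and ships a seeded synthetic-data layer (an LNP retina simulator and a
planted-nuclei image generator) so every analysis can be validated
against known ground truth without access to recordings.

## What it computes

**Receptive fields (reverse correlation).** Under binary white noise
the spike-triggered average estimates the linear receptive field. For
cells whose STA is space–time separable — at least 60% of its variance
captured by a rank-one factorization K(x, t) ≈ k_t(t)·k_s(x), with a
biphasic temporal filter — the package reports:

- *time-to-zero* of k_t (integration time),
- the 2σ ellipse of a 2-D Gaussian fit to k_s, with RF size taken as
  the area of the circle whose diameter is the geometric mean of the
  ellipse axes,
- the static nonlinearity (contrast-response function) from quantile
  bins of the generator signal g = K ∗ s, and *gain* = firing rate at
  50% of the peak generator value.

**Response fidelity (repeated stimuli).** From many repeats of the
same 10 s clip:

- signal-dependent noise: across-repeat spike-count variance vs mean in
  5 ms bins (variance/mean = 1 for a Poisson process; above 1 means
  excess noise),
- mutual information by the direct method,
  I(S; R) = (H(R) − H(R|S)) / T_word, over binary words of 3–6 bins of
  4–6 ms, the word parameters chosen per cell by proximity of the
  noise-entropy estimate to its Ma (coincidence) bound −log₂ Σp²,
- spike-train autocorrelograms and k-means cell-type clustering,
- selection of the top 10% most informative cells.

**Histology.** Automated outer-nuclear-layer nuclei counting:
integral-image local contrast normalization, binarization at the 8-bit
threshold 104, connected components constrained to width ≥ 2.1 µm and
neighbor edge distance ≥ 1.05 µm, counts in three 1000 µm² regions
(left/center/right) averaged per retina, and photoreceptor survival
fractions versus a reference count.

**Statistics.** Two-sided Kolmogorov–Smirnov group comparisons with
Bonferroni correction, and a linear mixed-effects model with a random
intercept per retina (plus sex and cell-type interaction terms) so
condition effects are not confounded by retina-to-retina variability.

The simulator's condition presets (`WT`, `untreated`, `early`, `mid`,
`late` rescue) qualitatively emulate the physiology of rescue timing —
later rescue leaves response gain low, noise high, and information rates
depressed — and provide the grouping structure (retina, sex, cell type)
the statistics need. See `docs/methods.md` for the model details and
every numerical convention.

## Worked example

Simulate one photopic cell, then recover its receptive field and gain:

```python
import rgctools as rt
from rgctools.receptive_fields import (
    fit_spatial_gaussian, time_to_zero, estimate_nonlinearity,
)

clip = rt.generate_checkerboard(n_frames=100_000, n_rows=6, n_cols=6,
                                square_size_um=75.0, refresh_ms=33.0, seed=0)
cell = rt.SyntheticCellParams(spatial_center_um=(225.0, 225.0),
                              spatial_sigma_um=(60.0, 50.0),
                              threshold=0.9, slope_spk_s=150.0)
train = rt.simulate_spike_train(cell, clip, seed=1)

sta = rt.compute_sta(train, clip, depth_frames=13)
rt.factorize_rank_one(sta)
print(f"{train.n_spikes} spikes, rank-one variance fraction "
      f"{sta.variance_fraction_rank1:.3f}, {sta.polarity} cell")

tm = time_to_zero(sta.temporal_filter, clip.refresh_ms)
rf = fit_spatial_gaussian(sta.spatial_map, clip.square_size_um)
cr = estimate_nonlinearity(train, clip, sta)
print(f"time-to-zero {tm.time_to_zero_ms:.1f} ms (truth {cell.t_zero_ms:.1f} ms)")
print(f"RF center ({rf.center_um[0]:.0f}, {rf.center_um[1]:.0f}) um, "
      f"area {rf.area_um2:.0f} um^2")
print(f"gain {cr.gain_spk_s:.1f} spk/s")
```

prints

```
48964 spikes, rank-one variance fraction 0.986, ON cell
time-to-zero 97.6 ms (truth 97.9 ms)
RF center (226, 225) um, area 39480 um^2
gain 134.8 spk/s
```

The STA passes the separability screen (0.986 ≥ 0.60), the recovered
zero crossing is within 0.3 ms of the simulator's closed-form 97.9 ms,
the RF center lands ~1 µm from the planted (225, 225), and the gain is
the rectifier's rate at half the peak generator value.

The full five-condition experiment — simulation, receptive fields,
noise, information, and KS/Bonferroni summaries — runs as one command:

```sh
rgctools pipeline run --seed 1 --out results/demo
```

which writes per-cell metric CSVs, a condition-comparison table and a
JSON report; in the report, late-rescue cells show lower gain and
information and a higher variance/mean ratio than wild-type, while
early/mid rescue sit near wild-type. Individual stages are also exposed
as subcommands: `rgctools stimgen`, `rgctools synth population`,
`rgctools synth onl-image`, `rgctools rfanalyze`, `rgctools fidelity`,
`rgctools onlcount`.

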