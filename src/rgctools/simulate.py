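"""Synthetic ground truth: an LNP retina simulator and planted-nuclei images.

Two generators back the test surface of the analysis modules:

1. A linear–nonlinear–Poisson (LNP) simulator with optional
   overdispersion. Each cell has a space–time separable receptive field
   (elliptical Gaussian in space, biphasic difference-of-gamma-cascades
   in time), a saturating rectifier nonlinearity, and conditionally
   Poisson or gamma-mixed-Poisson spiking with a configurable
   variance-to-mean ratio phi. Condition presets emulate, qualitatively,
   wild-type retinas and retinas rescued at progressively later stages
   of rod degeneration (lower gain, higher signal-dependent noise,
   slower kernels for the latest rescue); they are emulations of the
   observed trends, not fits to any recorded population.

2. A planted-nuclei generator for outer-nuclear-layer (ONL) histology
   cross-sections: bright sharp-edged elliptical nuclei on a dark
   noisy background, with a ground-truth table stating which nuclei
   satisfy the detection constraints (minimum width 2.1 um, neighbor
   edge distance at least 1.05 um).

All randomness flows through explicit seeds; there is no hidden global
state.

Overdispersion model
--------------------
Spiking is simulated in fine time bins (default 1 ms). For phi > 1 each
bin's rate is multiplied by an independent gamma variate with mean 1 and
variance ``(phi - 1) / lambda_bin``, giving a gamma-mixed Poisson count
with variance exactly ``phi * mean`` in every bin. Because independent
overdispersed counts add, the variance-to-mean ratio is preserved under
any rebinning coarser than the simulation resolution. This mechanism
raises count variance while leaving the mean rate — and therefore the
STA — unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .receptive_fields import SpikeTrain
from .stimulus import StimulusClip

__all__ = [
    "SyntheticCellParams",
    "ConditionPreset",
    "CONDITION_PRESETS",
    "Population",
    "SyntheticONLImage",
    "simulate_spike_train",
    "simulate_population",
    "generate_onl_image",
    "temporal_kernel",
    "zero_crossing_ms",
]


def temporal_kernel(
    t_ms: np.ndarray,
    tau_fast_ms: float,
    tau_slow_ms: float,
    n_stages: int,
    undershoot_weight: float,
) -> np.ndarray:
    """Biphasic difference-of-gamma-cascades kernel, as a function of
    time before the spike.

    ``k(t) = c(t; tau_f) - w * c(t; tau_s)`` with
    ``c(t; tau) = (t/tau)^n * exp(n * (1 - t/tau))``, so each cascade
    peaks at ``t = tau`` with value 1. With ``tau_f < tau_s`` and
    ``0 < w < 1`` the kernel has a dominant early lobe, a later
    opposite-sign undershoot, and a unique zero crossing between them.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0

    def cascade(tt: np.ndarray, tau: float) -> np.ndarray:
        x = tt / tau
        return x**n_stages * np.exp(n_stages * (1.0 - x))

    out[pos] = cascade(t[pos], tau_fast_ms) - undershoot_weight * cascade(
        t[pos], tau_slow_ms
    )
    return out


def zero_crossing_ms(
    tau_fast_ms: float, tau_slow_ms: float, n_stages: int, undershoot_weight: float
) -> float:
    """Closed-form zero crossing of :func:`temporal_kernel`.

    Setting the two cascades equal and solving gives
    ``t0 = (ln w + n ln(tau_f/tau_s)) / (n (1/tau_s - 1/tau_f))``.
    """
    num = math.log(undershoot_weight) + n_stages * math.log(tau_fast_ms / tau_slow_ms)
    den = n_stages * (1.0 / tau_slow_ms - 1.0 / tau_fast_ms)
    return num / den


@dataclass
class SyntheticCellParams:
    """Ground-truth parameters of one simulated RGC.

    The full space–time kernel is rank one by construction:
    ``K[lag, px] = temporal[lag] * spatial[px]``, normalized to unit
    Frobenius norm before use, so the generator signal has unit variance
    under binary white noise and the nonlinearity parameters are in
    generator-SD units.
    """

    spatial_center_um: tuple[float, float] = (600.0, 600.0)
    spatial_sigma_um: tuple[float, float] = (36.0, 30.0)  # (major, minor)
    spatial_angle_rad: float = 0.0
    polarity: str = "ON"
    tau_fast_ms: float = 55.0
    tau_slow_ms: float = 90.0
    n_stages: int = 4
    undershoot_weight: float = 0.45
    filter_support_ms: float = 400.0
    threshold: float = 0.6  # generator-SD units
    slope_spk_s: float = 60.0  # spk/s per generator-SD unit above threshold
    max_rate_spk_s: float = 200.0
    baseline_rate_spk_s: float = 0.5
    dispersion_phi: float = 1.0
    cell_id: str = "cell0"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dispersion_phi < 1.0:
            raise ValueError("dispersion_phi must be >= 1 (1 = Poisson)")
        if not self.tau_fast_ms < self.tau_slow_ms:
            raise ValueError("need tau_fast_ms < tau_slow_ms for a biphasic kernel")
        if not 0 < self.undershoot_weight < 1:
            raise ValueError("undershoot_weight must be in (0, 1)")
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")

    @property
    def t_zero_ms(self) -> float:
        """Analytic zero crossing of the temporal kernel."""
        return zero_crossing_ms(
            self.tau_fast_ms, self.tau_slow_ms, self.n_stages, self.undershoot_weight
        )

    @property
    def t_peak_ms(self) -> float:
        return self.tau_fast_ms

    def depth_frames(self, refresh_ms: float) -> int:
        return int(np.ceil(self.filter_support_ms / refresh_ms))

    def temporal_filter(self, refresh_ms: float) -> np.ndarray:
        """Discrete temporal filter sampled at lag times ``l * refresh_ms``,
        signed by polarity, unit Euclidean norm."""
        lags = np.arange(self.depth_frames(refresh_ms)) * refresh_ms
        k = temporal_kernel(
            lags, self.tau_fast_ms, self.tau_slow_ms,
            self.n_stages, self.undershoot_weight,
        )
        if self.polarity == "OFF":
            k = -k
        return k / np.linalg.norm(k)

    def spatial_map(self, clip: StimulusClip) -> np.ndarray:
        """Gaussian spatial weights on the checker grid, unit norm."""
        n_rows, n_cols = clip.shape
        sq = clip.square_size_um
        yy, xx = np.mgrid[0:n_rows, 0:n_cols].astype(float)
        x = (xx + 0.5) * sq - self.spatial_center_um[0]
        y = (yy + 0.5) * sq - self.spatial_center_um[1]
        ct, st = np.cos(self.spatial_angle_rad), np.sin(self.spatial_angle_rad)
        xr = x * ct + y * st
        yr = -x * st + y * ct
        s_maj, s_min = self.spatial_sigma_um
        m = np.exp(-0.5 * ((xr / s_maj) ** 2 + (yr / s_min) ** 2))
        return m / np.linalg.norm(m)

    def generator_signal(self, clip: StimulusClip) -> np.ndarray:
        """True generator signal per frame (zero-padded history at the
        start), for one pass through the clip."""
        proj = np.tensordot(
            clip.frames.astype(np.float64), self.spatial_map(clip),
            axes=([1, 2], [0, 1]),
        )
        return np.convolve(proj, self.temporal_filter(clip.refresh_ms))[: clip.n_frames]

    def rate_from_generator(self, g: np.ndarray) -> np.ndarray:
        """Saturating rectifier: baseline + min(slope*(g - theta)_+, max)."""
        drive = np.minimum(
            self.slope_spk_s * np.clip(g - self.threshold, 0.0, None),
            self.max_rate_spk_s,
        )
        return self.baseline_rate_spk_s + drive


def simulate_spike_train(
    params: SyntheticCellParams,
    clip: StimulusClip,
    seed: int,
    dt_ms: float = 1.0,
) -> SpikeTrain:
    """Simulate one cell's response to ``clip`` (including its repeats).

    The per-frame rate is expanded to fine bins of ~``dt_ms`` (rounded so
    bins tile frames exactly), counts are drawn per bin — conditionally
    Poisson for phi = 1, gamma-mixed Poisson with variance phi*mean for
    phi > 1 — and spike times are jittered uniformly within bins.

    Raises
    ------
    ValueError
        If the clip is shorter than the filter's temporal support.
    """
    depth = params.depth_frames(clip.refresh_ms)
    if clip.n_frames <= depth:
        raise ValueError(
            f"clip has {clip.n_frames} frames; filter support needs > {depth}"
        )
    rng = np.random.default_rng(seed)
    g = params.generator_signal(clip)
    rate = params.rate_from_generator(g)  # spk/s per frame
    if clip.n_repeats > 1:
        rate = np.tile(rate, clip.n_repeats)

    n_sub = max(1, int(round(clip.refresh_ms / dt_ms)))
    dt_s = clip.refresh_ms / n_sub / 1000.0
    lam = np.repeat(rate, n_sub) * dt_s

    phi = params.dispersion_phi
    if phi > 1.0:
        mult = np.ones_like(lam)
        pos = lam > 0
        shape = lam[pos] / (phi - 1.0)
        mult[pos] = rng.gamma(shape, (phi - 1.0) / lam[pos])
        counts = rng.poisson(mult * lam)
    else:
        counts = rng.poisson(lam)

    starts = np.arange(lam.size) * dt_s
    times = np.repeat(starts, counts) + rng.random(int(counts.sum())) * dt_s
    times.sort()
    duration = clip.total_duration_s
    times = times[times < duration]
    return SpikeTrain(
        spike_times_s=times,
        cell_id=params.cell_id,
        duration_s=duration,
        metadata=dict(params.metadata),
    )


@dataclass
class ConditionPreset:
    """Scaling knobs emulating one experimental condition.

    These are qualitative emulations of the trends seen across rescue
    timepoints (late rescue: lower gain, higher dispersion, slower
    kernels), not fits to recorded populations.
    """

    label: str
    age_months: float = 7.0
    gain_scale: float = 1.0  # multiplies slope and max rate
    dispersion_phi: float = 1.0
    t0_scale: float = 1.0  # multiplies both kernel time constants
    population_density_scale: float = 1.0


CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "WT": ConditionPreset("WT", gain_scale=1.0, dispersion_phi=1.0),
    "untreated": ConditionPreset(
        "untreated", gain_scale=0.45, dispersion_phi=1.9,
        t0_scale=1.05, population_density_scale=0.9,
    ),
    "early": ConditionPreset("early", gain_scale=0.92, dispersion_phi=1.05),
    "mid": ConditionPreset("mid", gain_scale=0.88, dispersion_phi=1.10),
    "late": ConditionPreset(
        "late", gain_scale=0.62, dispersion_phi=1.7,
        t0_scale=1.12, population_density_scale=0.95,
    ),
}

# two cell-type archetypes: kinetics + refractoriness differ
_ARCHETYPES = {
    "fast": dict(tau_fast_ms=45.0, tau_slow_ms=72.0, undershoot_weight=0.55),
    "slow": dict(tau_fast_ms=65.0, tau_slow_ms=110.0, undershoot_weight=0.35),
}


@dataclass
class Population:
    """Simulated trains plus the ground-truth parameter table."""

    trains: list[SpikeTrain]
    truth: pd.DataFrame
    params: list[SyntheticCellParams]
    clip: StimulusClip


def _draw_base_params(
    seed: int, cell_index: int, clip: StimulusClip
) -> SyntheticCellParams:
    """Condition-independent base draw for cell ``cell_index``: two cells
    with the same (seed, index) get identical base parameters, so preset
    scalings act on matched draws."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, cell_index]))
    n_rows, n_cols = clip.shape
    sq = clip.square_size_um
    margin = 0.25
    cx = rng.uniform(margin, 1 - margin) * n_cols * sq
    cy = rng.uniform(margin, 1 - margin) * n_rows * sq
    s_min = rng.uniform(26.0, 36.0)
    s_maj = s_min * rng.uniform(1.0, 1.3)
    arch = "fast" if cell_index % 2 == 0 else "slow"
    return SyntheticCellParams(
        spatial_center_um=(cx, cy),
        spatial_sigma_um=(s_maj, s_min),
        spatial_angle_rad=rng.uniform(0, np.pi),
        polarity="ON" if rng.random() < 0.5 else "OFF",
        threshold=rng.uniform(0.4, 0.8),
        slope_spk_s=rng.uniform(45.0, 75.0),
        max_rate_spk_s=rng.uniform(120.0, 220.0),
        baseline_rate_spk_s=rng.uniform(0.2, 1.0),
        metadata={"cell_type": arch},
        **_ARCHETYPES[arch],
    )


def simulate_population(
    presets: list[ConditionPreset],
    n_cells_per_condition: int,
    base_clip: StimulusClip,
    seed: int,
    n_retinas_per_condition: int = 2,
    simulate: bool = True,
    dt_ms: float = 1.0,
) -> Population:
    """Simulate a multi-condition population with grouping structure.

    Base cell parameters are drawn per cell index independently of
    condition; each preset's ``gain_scale``, ``dispersion_phi`` and
    ``t0_scale`` are then applied deterministically, so conditions are
    matched draw for draw. Cells carry ``retina_id`` (cycled over
    ``n_retinas_per_condition`` retinas), ``sex`` (one per retina) and
    ``cell_type`` labels so downstream mixed-effects contracts have real
    grouping structure.

    With ``simulate=False`` only the parameters and truth table are
    built (no spiking).
    """
    if not presets:
        raise ValueError("presets must be non-empty")
    if n_cells_per_condition < 1:
        raise ValueError("n_cells_per_condition must be >= 1")
    trains: list[SpikeTrain] = []
    all_params: list[SyntheticCellParams] = []
    rows = []
    for ci, preset in enumerate(presets):
        for i in range(n_cells_per_condition):
            base = _draw_base_params(seed, i, base_clip)
            retina = f"{preset.label}_r{i % n_retinas_per_condition}"
            sex = "F" if (i % n_retinas_per_condition) % 2 == 0 else "M"
            p = replace(
                base,
                tau_fast_ms=base.tau_fast_ms * preset.t0_scale,
                tau_slow_ms=base.tau_slow_ms * preset.t0_scale,
                slope_spk_s=base.slope_spk_s * preset.gain_scale,
                max_rate_spk_s=base.max_rate_spk_s * preset.gain_scale,
                dispersion_phi=preset.dispersion_phi,
                cell_id=f"{preset.label}_c{i:03d}",
                metadata={
                    "retina_id": retina,
                    "condition": preset.label,
                    "age_months": preset.age_months,
                    "sex": sex,
                    "cell_type": base.metadata["cell_type"],
                },
            )
            all_params.append(p)
            rows.append(
                {
                    "cell_id": p.cell_id,
                    "condition": preset.label,
                    "retina_id": retina,
                    "age_months": preset.age_months,
                    "sex": sex,
                    "cell_type": p.metadata["cell_type"],
                    "phi": p.dispersion_phi,
                    "max_rate_spk_s": p.max_rate_spk_s,
                    "slope_spk_s": p.slope_spk_s,
                    "threshold": p.threshold,
                    "t0_ms": p.t_zero_ms,
                    "center_x_um": p.spatial_center_um[0],
                    "center_y_um": p.spatial_center_um[1],
                    "sigma_major_um": p.spatial_sigma_um[0],
                    "sigma_minor_um": p.spatial_sigma_um[1],
                    "polarity": p.polarity,
                    "gain_scale": preset.gain_scale,
                }
            )
            if simulate:
                child = np.random.SeedSequence([seed, ci, i, 7]).generate_state(1)[0]
                trains.append(
                    simulate_spike_train(p, base_clip, int(child % 2**31), dt_ms=dt_ms)
                )
    return Population(
        trains=trains, truth=pd.DataFrame(rows), params=all_params, clip=base_clip
    )


# ---------------------------------------------------------------------------
# planted-nuclei ONL images
# ---------------------------------------------------------------------------

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class PlantedNucleus:
    center_um: tuple[float, float]  # (x, y)
    fwhm_um: tuple[float, float]  # (major, minor) full width at half max
    angle_rad: float
    amplitude: float
    passes_width: bool = True
    passes_separation: bool = True

    @property
    def width_um(self) -> float:
        """Detection-rule width: minor-axis full width at half max."""
        return self.fwhm_um[1]

    @property
    def passes(self) -> bool:
        return self.passes_width and self.passes_separation


@dataclass
class SyntheticONLImage:
    pixels: np.ndarray  # 2-D uint8
    scale_um_per_px: float
    truth: list[PlantedNucleus]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "x_um": n.center_um[0],
                    "y_um": n.center_um[1],
                    "width_um": n.width_um,
                    "passes_width": n.passes_width,
                    "passes_separation": n.passes_separation,
                    "passes": n.passes,
                }
                for n in self.truth
            ]
        )


def _ellipse_boundary(n: PlantedNucleus, k: int = 72) -> np.ndarray:
    """Points on the half-max outline of a planted nucleus, in um."""
    th = np.linspace(0, 2 * np.pi, k, endpoint=False)
    a, b = n.fwhm_um[0] / 2.0, n.fwhm_um[1] / 2.0
    ct, st = np.cos(n.angle_rad), np.sin(n.angle_rad)
    x = a * np.cos(th) * ct - b * np.sin(th) * st + n.center_um[0]
    y = a * np.cos(th) * st + b * np.sin(th) * ct + n.center_um[1]
    return np.column_stack([x, y])


def _edge_gap_um(a: PlantedNucleus, b: PlantedNucleus) -> float:
    """Nearest edge-to-edge distance between two half-max outlines."""
    pa, pb = _ellipse_boundary(a), _ellipse_boundary(b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return float(d.min())


def generate_onl_image(
    n_valid_nuclei: int,
    n_invalid_nuclei: int = 0,
    scale_um_per_px: float = 0.2,
    noise_sd: float = 8.0,
    seed: int = 0,
    image_shape_px: tuple[int, int] = (512, 512),
    invalid_kind: str = "narrow",
    background: float = 25.0,
    min_width_um: float = 2.1,
    min_separation_um: float = 1.05,
    profile_order: int = 5,
    max_tries: int = 2000,
) -> SyntheticONLImage:
    """Render an 8-bit ONL cross-section with planted elliptical nuclei.

    ``n_valid_nuclei`` nuclei satisfy the detection constraints with
    margin (minor-axis FWHM 3.2–4.8 um, mutual edge gaps >= 2 um).
    ``n_invalid_nuclei`` violate them: ``invalid_kind='narrow'`` plants
    sub-width nuclei (FWHM 0.9–1.4 um); ``invalid_kind='close'`` plants a
    full-width nucleus 0.25–0.55 um (half-max edge gap) from an existing valid one, which per
    the separation rule fails *both* members of the pair. Truth labels
    are computed from the planted geometry by the stated rules.

    Raises
    ------
    RuntimeError
        If a feasible packing is not found within ``max_tries`` draws.
    """
    rng = np.random.default_rng(seed)
    h_px, w_px = image_shape_px
    h_um, w_um = h_px * scale_um_per_px, w_px * scale_um_per_px
    nuclei: list[PlantedNucleus] = []

    def try_place(fwhm_min: float, fwhm_max: float, gap_min: float,
                  near: PlantedNucleus | None = None,
                  gap_range: tuple[float, float] | None = None) -> PlantedNucleus:
        for _ in range(max_tries):
            f_min = rng.uniform(fwhm_min, fwhm_max)
            f_maj = f_min * rng.uniform(1.0, 1.35)
            angle = rng.uniform(0, np.pi)
            margin = f_maj / 2 + 3.0
            if near is None:
                cx = rng.uniform(margin, w_um - margin)
                cy = rng.uniform(margin, h_um - margin)
            else:
                # walk outward from a neighbor until the edge gap lands
                # in the requested range
                gap_target = rng.uniform(*gap_range)
                direction = rng.uniform(0, 2 * np.pi)
                r = (near.fwhm_um[0] + f_maj) / 2 + gap_target
                cx = near.center_um[0] + r * np.cos(direction)
                cy = near.center_um[1] + r * np.sin(direction)
                if not (margin < cx < w_um - margin and margin < cy < h_um - margin):
                    continue
            cand = PlantedNucleus(
                (cx, cy), (f_maj, f_min), angle, rng.uniform(180, 230)
            )
            gaps = [_edge_gap_um(cand, o) for o in nuclei]
            if near is not None:
                g = _edge_gap_um(cand, near)
                if not (gap_range[0] <= g <= gap_range[1]):
                    continue
                others = [gg for o, gg in zip(nuclei, gaps) if o is not near]
                if others and min(others) < gap_min:
                    continue
            elif gaps and min(gaps) < gap_min:
                continue
            return cand
        raise RuntimeError("could not place nucleus; packing infeasible")

    for _ in range(n_valid_nuclei):
        nuclei.append(try_place(3.2, 4.8, gap_min=2.0))
    for _ in range(n_invalid_nuclei):
        if invalid_kind == "narrow":
            nuclei.append(try_place(0.9, 1.4, gap_min=2.0))
        elif invalid_kind == "close":
            if not any(n.passes_width for n in nuclei):
                raise ValueError("'close' invalid nuclei need a valid neighbor")
            valid = [n for n in nuclei if n.fwhm_um[1] >= min_width_um]
            near = valid[int(rng.integers(len(valid)))]
            nuclei.append(
                try_place(3.2, 4.8, gap_min=2.0, near=near, gap_range=(0.25, 0.55))
            )
        else:
            raise ValueError(f"unknown invalid_kind {invalid_kind!r}")

    # truth labels from the stated rules
    for n in nuclei:
        n.passes_width = n.width_um >= min_width_um
    for i, n in enumerate(nuclei):
        n.passes_separation = all(
            _edge_gap_um(n, o) >= min_separation_um
            for j, o in enumerate(nuclei)
            if j != i
        )

    # render: super-Gaussian ellipses (flat interior, steep edge -- DAPI
    # nuclei have fairly sharp borders; profile_order=1 recovers a plain
    # Gaussian). Scale chosen so the half-max contour matches fwhm_um.
    q = profile_order
    half_scale = (2.0 * math.log(2.0)) ** (1.0 / (2 * q))
    yy, xx = np.mgrid[0:h_px, 0:w_px].astype(float)
    x_um = (xx + 0.5) * scale_um_per_px
    y_um = (yy + 0.5) * scale_um_per_px
    img = np.full((h_px, w_px), background, dtype=float)
    for n in nuclei:
        s_maj = n.fwhm_um[0] / 2.0 / half_scale
        s_min = n.fwhm_um[1] / 2.0 / half_scale
        ct, st = np.cos(n.angle_rad), np.sin(n.angle_rad)
        dx, dy = x_um - n.center_um[0], y_um - n.center_um[1]
        xr = dx * ct + dy * st
        yr = -dx * st + dy * ct
        u = (xr / s_maj) ** 2 + (yr / s_min) ** 2
        img += n.amplitude * np.exp(-0.5 * u**q)
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticONLImage(pixels=pixels, scale_um_per_px=scale_um_per_px, truth=nuclei)
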