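"""Reverse-correlation receptive-field analysis.

Under binary white-noise stimulation the spike-triggered average (STA)
— the mean stimulus preceding a spike — estimates the linear component
of a retinal ganglion cell's spatiotemporal receptive field. This module
computes the STA, screens cells for space–time separability (a rank-one
kernel), and derives the standard physiology metrics:

* temporal integration: time-to-zero of the biphasic temporal filter
* spatial extent: 2-sigma ellipse of a fitted 2-D Gaussian, with the
  receptive-field "size" taken as the area of a circle whose diameter
  is the geometric mean of the ellipse's major and minor axes
* response gain: spike rate of the static nonlinearity evaluated at
  50% of the peak generator-signal value

Cells are included in spatial/temporal summaries only when at least 60%
of the STA variance is captured by a rank-one factorization and the
temporal filter is biphasic (a well-defined zero crossing is required
for the time-to-zero). Excluded cells carry a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from .stimulus import StimulusClip

__all__ = [
    "SpikeTrain",
    "STAResult",
    "TemporalMetrics",
    "SpatialRF",
    "ContrastResponse",
    "compute_sta",
    "factorize_rank_one",
    "is_biphasic",
    "time_to_zero",
    "fit_spatial_gaussian",
    "estimate_nonlinearity",
    "analyze_cell",
    "SEPARABILITY_THRESHOLD",
    "BIPHASIC_LOBE_FRACTION",
]

#: Minimum fraction of STA variance a rank-one factorization must capture
#: for a cell to count as space-time separable.
SEPARABILITY_THRESHOLD = 0.60

#: Minimum magnitude of the secondary (opposite-sign) lobe relative to the
#: dominant lobe for a temporal filter to count as biphasic.
BIPHASIC_LOBE_FRACTION = 0.05


@dataclass
class SpikeTrain:
    """Sorted spike times for one cell, with experiment metadata."""

    spike_times_s: np.ndarray
    cell_id: str
    duration_s: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times_s must be 1-D")
        if t.size and (np.any(np.diff(t) < 0)):
            raise ValueError("spike times must be sorted ascending")
        if t.size and (t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("spike times must lie within [0, duration_s]")
        self.spike_times_s = t

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size

    @property
    def mean_rate_spk_s(self) -> float:
        return self.n_spikes / self.duration_s


@dataclass
class STAResult:
    """Spike-triggered average and its rank-one factorization."""

    kernel: np.ndarray  # (lag, row, col); lag 0 = frame containing the spike
    n_spikes: int
    depth_frames: int
    refresh_ms: float
    square_size_um: float
    variance_fraction_rank1: float | None = None
    temporal_filter: np.ndarray | None = None  # unit norm
    spatial_map: np.ndarray | None = None  # carries the kernel scale
    is_separable: bool | None = None
    polarity: str | None = None  # "ON" | "OFF"


@dataclass
class TemporalMetrics:
    time_to_zero_ms: float
    peak_time_ms: float
    biphasic_index: float  # |undershoot| / |dominant peak|


@dataclass
class SpatialRF:
    center_um: tuple[float, float]
    sigma_um: tuple[float, float]  # (sigma_major, sigma_minor)
    angle_rad: float  # orientation of the major axis, mod pi
    effective_diameter_um: float  # geometric mean of 2-sigma axis lengths
    area_um2: float  # pi * (effective_diameter / 2)**2
    fit_r2: float


@dataclass
class ContrastResponse:
    generator_bin_centers: np.ndarray
    mean_rate_spk_s: np.ndarray
    gain_spk_s: float  # rate interpolated at 50% of peak generator value
    peak_rate_spk_s: float


def _spike_frames(spikes: SpikeTrain, clip: StimulusClip) -> np.ndarray:
    """Frame index on screen at each spike time (half-open intervals)."""
    return np.floor(spikes.spike_times_s * 1000.0 / clip.refresh_ms).astype(np.int64)


def compute_sta(
    spikes: SpikeTrain, clip: StimulusClip, depth_frames: int | None = None
) -> STAResult:
    """Spike-triggered average over ``depth_frames`` of stimulus history.

    ``kernel[lag]`` is the mean, over all usable spikes, of the stimulus
    frame ``lag`` frames before the frame in which the spike occurred
    (lag 0 = the spike's own frame). Spikes in the first ``depth_frames``
    frames are excluded so that every averaged window is complete.

    The default depth covers 500 ms of history (15 frames at 33 ms
    refresh, 8 at 66 ms).

    Raises
    ------
    ValueError
        If ``clip`` is a repeated clip, or no usable spikes remain.
    """
    if clip.n_repeats != 1:
        raise ValueError("STA requires non-repeated noise; got a repeat clip")
    if depth_frames is None:
        depth_frames = max(1, int(round(500.0 / clip.refresh_ms)))
    if depth_frames < 1 or depth_frames >= clip.n_frames:
        raise ValueError("depth_frames must be in [1, n_frames)")

    frames64 = clip.frames.astype(np.float64)
    spike_fr = _spike_frames(spikes, clip)
    spike_fr = spike_fr[(spike_fr >= depth_frames) & (spike_fr < clip.n_frames)]
    if spike_fr.size == 0:
        raise ValueError("no usable spikes after excluding the first depth_frames")

    counts = np.bincount(spike_fr, minlength=clip.n_frames).astype(np.float64)
    n_usable = counts.sum()
    n = clip.n_frames
    kernel = np.empty((depth_frames,) + clip.shape)
    c = counts[depth_frames:]
    for lag in range(depth_frames):
        # frames[f - lag] for f in [depth_frames, n)
        kernel[lag] = np.tensordot(c, frames64[depth_frames - lag : n - lag], axes=1)
    kernel /= n_usable
    return STAResult(
        kernel=kernel,
        n_spikes=int(n_usable),
        depth_frames=depth_frames,
        refresh_ms=clip.refresh_ms,
        square_size_um=clip.square_size_um,
    )


def factorize_rank_one(sta: STAResult) -> STAResult:
    """Best rank-one (space x time) approximation of the STA, via SVD.

    Unfolds the kernel to (lag, space), takes the leading singular triple,
    and records ``variance_fraction_rank1 = s1^2 / sum(s_i^2)``. The
    temporal factor is stored with unit Euclidean norm; the spatial map
    carries all the scale. Signs are fixed so the spatial map's
    largest-magnitude entry is positive; the temporal filter's dominant
    lobe is then positive for ON cells and negative for OFF cells.

    ``is_separable`` is set to ``variance_fraction >= 0.60 AND the
    temporal factor is biphasic``.
    """
    kernel = sta.kernel
    if not np.any(kernel):
        raise ValueError("all-zero STA kernel cannot be factorized")
    depth = kernel.shape[0]
    unfolded = kernel.reshape(depth, -1)
    u, s, vt = np.linalg.svd(unfolded, full_matrices=False)
    variance_fraction = float(s[0] ** 2 / np.sum(s**2))
    temporal = u[:, 0]
    spatial = s[0] * vt[0].reshape(kernel.shape[1:])
    # sign convention: spatial peak positive
    peak = spatial.flat[np.argmax(np.abs(spatial))]
    if peak < 0:
        temporal = -temporal
        spatial = -spatial
    dominant = temporal[np.argmax(np.abs(temporal))]
    sta.variance_fraction_rank1 = variance_fraction
    sta.temporal_filter = temporal
    sta.spatial_map = spatial
    sta.polarity = "ON" if dominant > 0 else "OFF"
    sta.is_separable = bool(
        variance_fraction >= SEPARABILITY_THRESHOLD and is_biphasic(temporal)
    )
    return sta


def _dominant_and_undershoot(filt: np.ndarray) -> tuple[int, int | None]:
    """Indices of the dominant lobe and of the opposite-sign lobe at
    larger lag (further back in time), or None if absent."""
    i_dom = int(np.argmax(np.abs(filt)))
    s = np.sign(filt[i_dom])
    tail = filt[i_dom + 1 :]
    opposite = -s * tail
    if opposite.size == 0 or np.max(opposite) <= 0:
        return i_dom, None
    return i_dom, i_dom + 1 + int(np.argmax(opposite))


def is_biphasic(temporal_filter: np.ndarray) -> bool:
    """True iff the filter has a dominant lobe followed (at larger lag)
    by an opposite-sign lobe whose peak magnitude is at least 5% of the
    dominant lobe's. Polarity-invariant; False for degenerate input."""
    filt = np.asarray(temporal_filter, dtype=float)
    if filt.size < 2 or not np.any(filt):
        return False
    i_dom, i_und = _dominant_and_undershoot(filt)
    if i_und is None:
        return False
    return bool(np.abs(filt[i_und]) >= BIPHASIC_LOBE_FRACTION * np.abs(filt[i_dom]))


def time_to_zero(temporal_filter: np.ndarray, refresh_ms: float) -> TemporalMetrics:
    """Time from the spike back to the filter's zero crossing.

    The crossing between the dominant lobe and the subsequent
    opposite-sign lobe is located by linear interpolation between the
    two bracketing samples; lag ``l`` is assigned time ``l * refresh_ms``
    (the average time before the spike of the stimulus frame ``l``
    frames back). Invariant to positive rescaling of the filter.

    Raises
    ------
    ValueError
        If the filter is not biphasic (no zero crossing to report).
    """
    filt = np.asarray(temporal_filter, dtype=float)
    if not is_biphasic(filt):
        raise ValueError("temporal filter has no well-defined zero crossing")
    i_dom, i_und = _dominant_and_undershoot(filt)
    s = np.sign(filt[i_dom])
    crossing = None
    for j in range(i_dom + 1, i_und + 1):
        if filt[j] == 0.0:
            crossing = float(j)
            break
        if np.sign(filt[j]) == -s:
            # crossing between j-1 and j
            crossing = (j - 1) + filt[j - 1] / (filt[j - 1] - filt[j])
            break
    assert crossing is not None  # guaranteed by is_biphasic
    peak_time = i_dom * refresh_ms
    return TemporalMetrics(
        time_to_zero_ms=float(crossing * refresh_ms),
        peak_time_ms=float(peak_time),
        biphasic_index=float(abs(filt[i_und]) / abs(filt[i_dom])),
    )


def _gauss2d(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    amp, x0, y0, sx, sy, theta, offset = params
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + offset


def fit_spatial_gaussian(
    spatial_map: np.ndarray, square_size_um: float
) -> SpatialRF:
    """Least-squares elliptical 2-D Gaussian fit of the spatial map.

    Checker (row, col) is centred at ``((col + 0.5) * square, (row + 0.5)
    * square)`` micrometers, origin at the top-left checker. The map's
    sign is flipped if its peak is negative (OFF cells) so the fit always
    chases a positive bump. Initialization is moment-based.

    Size conventions: the reported ellipse is the 2-sigma contour
    (semi-axes ``2*sigma``); ``effective_diameter_um`` is the geometric
    mean of its major and minor axis lengths (``4*sqrt(s_maj*s_min)``)
    and ``area_um2 = pi * (effective_diameter/2)**2``, the area of the
    circle with that diameter.

    Raises
    ------
    ValueError
        If the fit fails to converge or explains less than half the map
        variance (``fit_r2 < 0.5``); such cells are excluded upstream.
    """
    z = np.asarray(spatial_map, dtype=float)
    n_rows, n_cols = z.shape
    peak = z.flat[np.argmax(np.abs(z))]
    if peak == 0:
        raise ValueError("flat spatial map")
    if peak < 0:
        z = -z

    yy, xx = np.mgrid[0:n_rows, 0:n_cols].astype(float)
    x = (xx + 0.5) * square_size_um
    y = (yy + 0.5) * square_size_um

    # moment-based initialization from the positive part
    w = np.clip(z - np.median(z), 0, None)
    wsum = w.sum()
    x0 = float((w * x).sum() / wsum)
    y0 = float((w * y).sum() / wsum)
    var_x = float((w * (x - x0) ** 2).sum() / wsum)
    var_y = float((w * (y - y0) ** 2).sum() / wsum)
    s0 = max(np.sqrt(max(var_x, var_y, 1e-6)), 0.25 * square_size_um)
    p0 = np.array([z.max(), x0, y0, s0, s0, 0.0, float(np.median(z))])

    lo = [0, x.min() - square_size_um, y.min() - square_size_um,
          1e-2 * square_size_um, 1e-2 * square_size_um, -np.pi, -np.inf]
    hi = [np.inf, x.max() + square_size_um, y.max() + square_size_um,
          n_cols * square_size_um, n_rows * square_size_um, np.pi, np.inf]
    res = least_squares(
        lambda p: (_gauss2d(p, x, y) - z).ravel(), p0, bounds=(lo, hi)
    )
    if not res.success:
        raise ValueError("2-D Gaussian fit failed to converge")
    amp, x0, y0, sx, sy, theta, offset = res.x
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < 0.5:
        raise ValueError(f"poor spatial fit (r2={r2:.2f} < 0.5)")

    if sx >= sy:
        s_maj, s_min, angle = sx, sy, theta
    else:
        s_maj, s_min, angle = sy, sx, theta + np.pi / 2
    angle = float(np.mod(angle, np.pi))
    eff_diam = 4.0 * np.sqrt(s_maj * s_min)
    return SpatialRF(
        center_um=(float(x0), float(y0)),
        sigma_um=(float(s_maj), float(s_min)),
        angle_rad=angle,
        effective_diameter_um=float(eff_diam),
        area_um2=float(np.pi * (eff_diam / 2.0) ** 2),
        fit_r2=float(r2),
    )


def generator_signal(sta: STAResult, clip: StimulusClip) -> np.ndarray:
    """Generator signal per frame: the unit-Frobenius-norm rank-one
    kernel convolved with the stimulus. Frames with incomplete history
    (the first ``depth_frames``) are omitted; the returned array aligns
    with frames ``depth_frames .. n_frames-1``."""
    if sta.temporal_filter is None or sta.spatial_map is None:
        raise ValueError("run factorize_rank_one first")
    depth = sta.depth_frames
    spatial = sta.spatial_map / np.linalg.norm(sta.spatial_map)
    temporal = sta.temporal_filter / np.linalg.norm(sta.temporal_filter)
    proj = np.tensordot(clip.frames.astype(np.float64), spatial, axes=([1, 2], [0, 1]))
    full = np.convolve(proj, temporal)[: clip.n_frames]
    return full[depth:]


def estimate_nonlinearity(
    spikes: SpikeTrain,
    clip: StimulusClip,
    sta: STAResult,
    n_bins: int = 20,
) -> ContrastResponse:
    """Static nonlinearity (contrast-response function) and gain.

    The generator signal is the convolution of the unit-norm rank-one
    filter with the stimulus; its values are partitioned into ``n_bins``
    equal-count (quantile) bins and the mean spike rate computed per bin.
    Gain is the rate linearly interpolated at 50% of the maximum observed
    generator value. Because the filter is unit-norm, rescaling stimulus
    contrast while inversely rescaling the filter leaves the generator
    signal, and hence the gain, unchanged.

    Raises
    ------
    ValueError
        If ``n_bins < 4`` or the STA has not been factorized.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    depth = sta.depth_frames
    g = generator_signal(sta, clip)

    spike_fr = _spike_frames(spikes, clip)
    spike_fr = spike_fr[(spike_fr >= depth) & (spike_fr < clip.n_frames)]
    counts = np.bincount(spike_fr - depth, minlength=g.size).astype(float)
    rate = counts / (clip.refresh_ms / 1000.0)

    order = np.argsort(g, kind="stable")
    splits = np.array_split(order, n_bins)
    centers = np.array([g[idx].mean() for idx in splits])
    rates = np.array([rate[idx].mean() for idx in splits])
    half_peak_g = 0.5 * g.max()
    gain = float(np.interp(half_peak_g, centers, rates))
    return ContrastResponse(
        generator_bin_centers=centers,
        mean_rate_spk_s=rates,
        gain_spk_s=gain,
        peak_rate_spk_s=float(rates.max()),
    )


def analyze_cell(
    spikes: SpikeTrain,
    clip: StimulusClip,
    depth_frames: int | None = None,
    n_bins: int = 20,
) -> dict[str, Any]:
    """Full single-cell receptive-field analysis with exclusion bookkeeping.

    Returns a flat dict of metrics (one tidy CSV row). Cells failing the
    separability screen, the biphasic requirement, or the spatial fit get
    ``exclude_reason`` set ('non-separable', 'non-biphasic', 'bad-fit',
    'no-spikes') and NaN metrics for the affected quantities.
    """
    row: dict[str, Any] = {
        "cell_id": spikes.cell_id,
        **{k: spikes.metadata.get(k) for k in
           ("retina_id", "condition", "age_months", "sex", "cell_type")},
        "n_spikes": np.nan,
        "variance_fraction": np.nan,
        "polarity": None,
        "t0_ms": np.nan,
        "area_um2": np.nan,
        "center_x_um": np.nan,
        "center_y_um": np.nan,
        "gain_spk_s": np.nan,
        "exclude_reason": None,
    }
    try:
        sta = compute_sta(spikes, clip, depth_frames)
    except ValueError:
        row["exclude_reason"] = "no-spikes"
        return row
    row["n_spikes"] = sta.n_spikes
    factorize_rank_one(sta)
    row["variance_fraction"] = sta.variance_fraction_rank1
    row["polarity"] = sta.polarity
    if sta.variance_fraction_rank1 < SEPARABILITY_THRESHOLD:
        row["exclude_reason"] = "non-separable"
        return row
    if not is_biphasic(sta.temporal_filter):
        row["exclude_reason"] = "non-biphasic"
        return row
    tm = time_to_zero(sta.temporal_filter, sta.refresh_ms)
    row["t0_ms"] = tm.time_to_zero_ms
    try:
        rf = fit_spatial_gaussian(sta.spatial_map, sta.square_size_um)
        row["area_um2"] = rf.area_um2
        row["center_x_um"], row["center_y_um"] = rf.center_um
    except ValueError:
        row["exclude_reason"] = "bad-fit"
    cr = estimate_nonlinearity(spikes, clip, sta, n_bins=n_bins)
    row["gain_spk_s"] = cr.gain_spk_s
    return row
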