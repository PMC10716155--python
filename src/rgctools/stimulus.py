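"""Binary checkerboard stimuli and repeated clips.

Checkerboard noise is the workhorse stimulus of reverse-correlation
experiments on the retina: each square ("checker") flips independently
between dark and bright on every refresh, so the stimulus is white in
space and time and the spike-triggered average is an unbiased estimate
of the linear receptive field.

Contrast is coded as {-1, +1} (zero mean), never {0, 1}: all downstream
reverse-correlation math assumes a zero-mean stimulus.

Typical configurations, as used on mouse retina:

* scotopic / mesopic (~1 / ~100 Rh*/rod/s): 150 um squares, 66 ms refresh
* photopic (~10,000 Rh*/rod/s): 75 um squares, 33 ms refresh

with repeated stimuli built as a 10 s clip presented 100 times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StimulusClip",
    "generate_checkerboard",
    "make_repeat_clip",
    "save_clip",
    "load_clip",
]


@dataclass
class StimulusClip:
    """A checkerboard movie plus its presentation geometry.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, n_rows, n_cols), int8
        Contrast values, every element exactly -1 or +1.
    square_size_um : float
        Side length of one checker in micrometers on the retina.
    refresh_ms : float
        Duration each frame is displayed, in milliseconds.
    light_level_rh : float
        Mean light level tag in Rh*/rod/s. Metadata only: the simulator,
        not the stimulus, changes the response regime.
    seed : int
        Seed of the generator that produced ``frames``.
    n_repeats : int
        Number of times the clip is presented back to back (1 for
        non-repeated noise).
    """

    frames: np.ndarray
    square_size_um: float
    refresh_ms: float
    light_level_rh: float = 10_000.0
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int8)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_rows, n_cols)")
        if self.refresh_ms <= 0:
            raise ValueError("refresh_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) checker grid."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        """Duration of a single presentation of the clip, in seconds."""
        return self.n_frames * self.refresh_ms / 1000.0

    @property
    def total_duration_s(self) -> float:
        """Total presented duration including repeats, in seconds."""
        return self.duration_s * self.n_repeats

    def frame_at(self, t_s: float) -> int:
        """Index of the frame on screen at time ``t_s`` (half-open frames).

        For repeated clips the index wraps modulo the clip length.
        """
        idx = int(np.floor(t_s * 1000.0 / self.refresh_ms))
        return idx % self.n_frames if self.n_repeats > 1 else idx


def generate_checkerboard(
    n_frames: int,
    n_rows: int,
    n_cols: int,
    square_size_um: float = 75.0,
    refresh_ms: float = 33.0,
    seed: int = 0,
    light_level_rh: float = 10_000.0,
) -> StimulusClip:
    """Generate binary checkerboard noise.

    Every checker on every frame is drawn independently and equiprobably
    from {-1, +1} using ``numpy.random.default_rng(seed)``; the same
    (seed, geometry) always reproduces the frames bit-exactly.

    Raises
    ------
    ValueError
        If any dimension is < 1 or ``refresh_ms`` <= 0.
    """
    if n_frames < 1 or n_rows < 1 or n_cols < 1:
        raise ValueError("n_frames, n_rows and n_cols must all be >= 1")
    if refresh_ms <= 0:
        raise ValueError("refresh_ms must be positive")
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 2, size=(n_frames, n_rows, n_cols), dtype=np.int8)
    frames = (2 * frames - 1).astype(np.int8)
    return StimulusClip(
        frames=frames,
        square_size_um=float(square_size_um),
        refresh_ms=float(refresh_ms),
        light_level_rh=float(light_level_rh),
        seed=int(seed),
        n_repeats=1,
    )


def make_repeat_clip(
    clip: StimulusClip, clip_duration_s: float, n_repeats: int
) -> StimulusClip:
    """Cut the first ``clip_duration_s`` of ``clip`` and flag it as repeated.

    The number of frames per repeat is ``floor(clip_duration_s * 1000 /
    refresh_ms)``; a partial trailing frame is dropped. The total
    presented duration is ``clip_duration_s_actual * n_repeats``.

    Raises
    ------
    ValueError
        If the source clip is shorter than ``clip_duration_s`` or
        ``n_repeats`` < 1.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n_frames = int(np.floor(clip_duration_s * 1000.0 / clip.refresh_ms))
    if n_frames < 1:
        raise ValueError("clip_duration_s shorter than one frame")
    if n_frames > clip.n_frames:
        raise ValueError(
            f"source clip has {clip.n_frames} frames, "
            f"{n_frames} needed for {clip_duration_s} s"
        )
    return replace(clip, frames=clip.frames[:n_frames], n_repeats=int(n_repeats))


def save_clip(clip: StimulusClip, path: str | Path) -> None:
    """Write a clip as a compressed ``.npz`` plus a JSON sidecar.

    ``path`` should end in ``.npz``; the sidecar gets a ``.json`` suffix.
    """
    path = Path(path)
    np.savez_compressed(path, frames=clip.frames)
    meta = {
        "square_size_um": clip.square_size_um,
        "refresh_ms": clip.refresh_ms,
        "light_level_rh": clip.light_level_rh,
        "seed": clip.seed,
        "n_repeats": clip.n_repeats,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_clip(path: str | Path) -> StimulusClip:
    """Load a clip written by :func:`save_clip`."""
    path = Path(path)
    frames = np.load(path)["frames"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return StimulusClip(frames=frames, **meta)
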