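"""Shared fixtures: simulated cells reused across test modules.

The expensive LNP simulations are session-scoped so the receptive-field
closure and repeat-trial analyses run them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import rgctools as rt


@pytest.fixture(scope="session")
def closure():
    """A long single-cell recording plus its full STA analysis.

    The checker grid is a compact photopic patch around one cell so the
    STA kernel is dominated by signal; the recording is long enough
    (~150k spikes) for the rank-one factorization to approach its
    noise-free limit.
    """
    clip = rt.generate_checkerboard(250_000, 6, 6, 75.0, 33.0, seed=5)
    params = rt.SyntheticCellParams(
        spatial_center_um=(225.0, 225.0),
        spatial_sigma_um=(60.0, 50.0),
        threshold=0.9,
        slope_spk_s=300.0,
        max_rate_spk_s=600.0,
        baseline_rate_spk_s=0.2,
    )
    train = rt.simulate_spike_train(params, clip, seed=6)
    sta = rt.compute_sta(train, clip, depth_frames=13)
    rt.factorize_rank_one(sta)
    return {"clip": clip, "params": params, "train": train, "sta": sta}


@pytest.fixture(scope="session")
def repeat_runs():
    """One cell simulated at dispersion phi in {1, 1.5, 2.5} over 100
    repeats of a 10 s checkerboard clip."""
    clip = rt.generate_checkerboard(400, 10, 10, 75.0, 33.0, seed=7)
    repeat = rt.make_repeat_clip(clip, 10.0, 100)
    runs = {}
    for phi in (1.0, 1.5, 2.5):
        params = rt.SyntheticCellParams(
            spatial_center_um=(375.0, 375.0),
            spatial_sigma_um=(60.0, 50.0),
            threshold=0.6,
            slope_spk_s=60.0,
            max_rate_spk_s=200.0,
            baseline_rate_spk_s=0.5,
            dispersion_phi=phi,
        )
        runs[phi] = rt.simulate_spike_train(params, repeat, seed=int(10 * phi))
    return {"repeat": repeat, "runs": runs}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
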