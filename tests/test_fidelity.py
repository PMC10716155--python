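"""Noise statistics, direct-method information, autocorrelograms, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rgctools as rt
from rgctools.fidelity import (
    InfoResult,
    autocorrelogram,
    cluster_cell_types,
    count_matrix,
    direct_info,
    ma_bound,
    plugin_entropy,
    select_word_params,
    top_informative,
    variance_mean,
)
from rgctools.receptive_fields import SpikeTrain


def _repeat_clip(duration_s=10.0, n_repeats=100, refresh=33.0):
    clip = rt.generate_checkerboard(
        int(duration_s * 1000 / refresh) + 2, 2, 2, 75.0, refresh, seed=0
    )
    return rt.make_repeat_clip(clip, duration_s, n_repeats)


class TestCountMatrix:
    def test_shape_for_paper_configuration(self):
        """10 s clip, 100 repeats, 5 ms bins -> 100 x 2000 matrix."""
        rep = _repeat_clip()
        train = SpikeTrain(np.array([1.0, 500.0]), "c", rep.total_duration_s)
        cm = count_matrix(train, rep, 5.0)
        assert cm.shape == (100, 1999)  # floor(9.999 s / 5 ms) per repeat

    def test_exact_shape_with_round_clip(self):
        clip = rt.generate_checkerboard(1000, 2, 2, 75.0, 10.0, seed=0)
        rep = rt.make_repeat_clip(clip, 10.0, 100)
        train = SpikeTrain(np.array([]), "c", rep.total_duration_s)
        assert count_matrix(train, rep, 5.0).shape == (100, 2000)

    def test_conservation_of_spikes(self, rng):
        rep = _repeat_clip(duration_s=5.0, n_repeats=10)
        t = np.sort(rng.uniform(0, rep.total_duration_s, 500))
        train = SpikeTrain(t, "c", rep.total_duration_s)
        cm = count_matrix(train, rep, 5.0)
        # spikes in dropped trailing bins are the only losses
        assert 490 <= cm.sum() <= 500

    def test_empty_train_all_zero(self):
        rep = _repeat_clip(duration_s=2.0, n_repeats=3)
        cm = count_matrix(SpikeTrain(np.array([]), "c", 6.0), rep, 5.0)
        assert cm.sum() == 0

    def test_nonpositive_bin_raises(self):
        rep = _repeat_clip(duration_s=2.0, n_repeats=3)
        with pytest.raises(ValueError):
            count_matrix(SpikeTrain(np.array([]), "c", 6.0), rep, 0.0)


class TestVarianceMean:
    def test_identical_repeats_zero_variance(self):
        counts = np.tile([1, 0, 2, 0, 1], (10, 1))
        ns = variance_mean(counts)
        assert ns.variance_count == 0.0
        assert ns.ratio == 0.0

    def test_phi_one_cell_in_poisson_band(self, repeat_runs):
        cm = count_matrix(repeat_runs["runs"][1.0], repeat_runs["repeat"], 5.0)
        assert 0.9 < variance_mean(cm).ratio < 1.1

    def test_phi_25_within_ten_percent(self, repeat_runs):
        cm = count_matrix(repeat_runs["runs"][2.5], repeat_runs["repeat"], 5.0)
        assert abs(variance_mean(cm).ratio - 2.5) / 2.5 < 0.10

    def test_ratio_monotone_in_phi(self, repeat_runs):
        ratios = [
            variance_mean(count_matrix(tr, repeat_runs["repeat"], 5.0)).ratio
            for phi, tr in sorted(repeat_runs["runs"].items())
        ]
        assert ratios == sorted(ratios)

    def test_zero_spikes_flagged_undefined(self):
        ns = variance_mean(np.zeros((5, 20), dtype=int))
        assert ns.undefined

    def test_single_repeat_raises(self):
        with pytest.raises(ValueError):
            variance_mean(np.ones((1, 10)))


class TestMaBound:
    def test_uniform_equals_log2k(self):
        assert ma_bound(np.full(8, 1 / 8)) == pytest.approx(3.0, abs=1e-12)

    def test_degenerate_is_zero(self):
        assert ma_bound([1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        assert ma_bound([0.5, 0.25, 0.25]) == pytest.approx(
            -np.log2(0.375), abs=1e-9
        )
        assert ma_bound([0.5, 0.25, 0.25]) <= 1.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ma_bound([])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(deadline=None, max_examples=200)
    def test_never_exceeds_shannon_entropy(self, weights):
        p = np.array(weights) / np.sum(weights)
        shannon = -np.sum(p * np.log2(p))
        assert ma_bound(p) <= shannon + 1e-9


class TestDirectInfo:
    def test_deterministic_channel(self):
        counts = np.tile([1, 0, 0, 1, 0, 1], (6, 1))
        r = direct_info(counts, 5.0, 3)
        assert r.noise_entropy_bits_per_word == 0.0
        assert r.info_bits_per_s == pytest.approx(
            r.total_entropy_bits_per_word / 0.015
        )

    def test_hand_enumerated_slice_distributions(self):
        """Slice 0 deterministic word (1,0); slice 1 splits 50/50 between
        (0,0) and (1,1): H(R|S) = 0.5 bits, H(R) = 1.5 bits by direct
        summation over {0.5, 0.25, 0.25}."""
        counts = np.array(
            [[1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 1, 1], [1, 0, 1, 1]]
        )
        r = direct_info(counts, 5.0, 2)
        assert r.noise_entropy_bits_per_word == pytest.approx(0.5, abs=1e-12)
        assert r.total_entropy_bits_per_word == pytest.approx(1.5, abs=1e-12)
        assert r.info_bits_per_s == pytest.approx(1.0 / 0.010, abs=1e-9)
        assert r.ma_bound_bits_per_word == pytest.approx(
            -np.log2(0.375), abs=1e-9
        )

    def test_shuffled_counts_within_bias_bound(self, rng):
        """Stimulus-independent responses: I stays below the small-sample
        plug-in bias bound (|A|-1)/(2N ln2) per word."""
        n_rep, n_bins, word = 150, 600, 3
        counts = rng.poisson(0.5, size=(n_rep, n_bins))
        r = direct_info(counts, 5.0, word)
        # the plug-in I converges to the bias itself, so allow 1.5x for
        # realization noise and higher-order terms
        bias_bits_per_word = (2**word - 1) / (2 * n_rep * np.log(2))
        assert 0 <= r.info_bits_per_s <= 1.5 * bias_bits_per_word / (word * 0.005)

    def test_counts_clipped_to_binary_alphabet(self):
        burst = np.tile([3, 0], (4, 2))  # clips to word (1,0)
        single = np.tile([1, 0], (4, 2))
        a = direct_info(burst, 5.0, 2)
        b = direct_info(single, 5.0, 2)
        assert a.total_entropy_bits_per_word == b.total_entropy_bits_per_word

    def test_fewer_than_two_repeats_raises(self):
        with pytest.raises(ValueError):
            direct_info(np.ones((1, 10), dtype=int), 5.0, 2)


class TestSelectWordParams:
    def test_single_setting_grid_returned(self, repeat_runs):
        r = select_word_params(
            repeat_runs["runs"][1.0], repeat_runs["repeat"], (5.0,), (3,)
        )
        assert (r.bin_ms, r.word_bins) == (5.0, 3)
        assert len(r.selection_diagnostics) == 1

    def test_deterministic_tie_breaks_to_smallest_setting(self):
        rep = _repeat_clip(duration_s=2.0, n_repeats=4)
        # identical response in every repeat, offsets off the bin lattice
        base = np.sort(np.random.default_rng(3).uniform(0.001, 1.9, 40))
        t = np.concatenate([base + k * rep.duration_s for k in range(4)])
        train = SpikeTrain(np.sort(t), "c", rep.total_duration_s)
        r = select_word_params(train, rep, (4.0, 5.0, 6.0), (3, 4))
        assert r.noise_entropy_bits_per_word == 0.0
        assert (r.bin_ms, r.word_bins) == (4.0, 3)

    def test_grid_reported_as_diagnostics(self, repeat_runs):
        r = select_word_params(
            repeat_runs["runs"][1.0], repeat_runs["repeat"], (4.0, 6.0), (3, 4)
        )
        assert len(r.selection_diagnostics) == 4
        assert r.noise_ma_gap_bits == pytest.approx(
            r.selection_diagnostics.noise_ma_gap_bits.min(), abs=1e-12
        )

    def test_coarser_bins_do_not_increase_entropy_rate(self, repeat_runs):
        """Data-processing sanity: H(R) per unit time at 6 ms bins never
        exceeds that at 4 ms bins on the same train."""
        rates = {}
        for bin_ms in (4.0, 6.0):
            cm = count_matrix(repeat_runs["runs"][1.0], repeat_runs["repeat"], bin_ms)
            r = direct_info(cm, bin_ms, 4)
            rates[bin_ms] = r.total_entropy_bits_per_word / (4 * bin_ms / 1000)
        assert rates[6.0] <= rates[4.0] + 1e-9

    def test_empty_grid_raises(self, repeat_runs):
        with pytest.raises(ValueError):
            select_word_params(
                repeat_runs["runs"][1.0], repeat_runs["repeat"], (), (3,)
            )


class TestTopInformative:
    @staticmethod
    def _cells(rates):
        return [
            InfoResult(1, 0, r, 5.0, 3, 1, 0, cell_id=f"c{i:03d}")
            for i, r in enumerate(rates)
        ]

    def test_top_ten_percent_of_hundred(self, rng):
        cells = self._cells(rng.uniform(0, 30, size=100))
        top = top_informative(cells, 0.10)
        assert len(top) == 10
        cutoff = min(c.info_bits_per_s for c in top)
        assert sum(c.info_bits_per_s > cutoff for c in cells) < 10

    def test_fraction_one_returns_all(self):
        cells = self._cells([1, 2, 3])
        assert len(top_informative(cells, 1.0)) == 3

    def test_ties_break_by_cell_id(self):
        cells = self._cells([5.0] * 20)
        top = top_informative(cells, 0.10)
        assert [c.cell_id for c in top] == ["c000", "c001"]

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError):
            top_informative(self._cells([1, 2]), 0.0)


class TestAutocorrelogram:
    def test_poisson_train_flat_at_rate(self, rng):
        lam, T = 40.0, 200.0
        n = rng.poisson(lam * T)
        train = SpikeTrain(np.sort(rng.uniform(0, T, n)), "c", T)
        ac = autocorrelogram(train, window_ms=50.0, bin_ms=5.0)
        assert np.all(np.abs(ac.rate_spk_s - lam) < 5 * np.sqrt(lam / (0.005 * n)))

    def test_refractory_period_empty_at_short_lags(self, rng):
        t = np.cumsum(0.004 + rng.exponential(0.02, size=3000))
        train = SpikeTrain(t, "c", float(t[-1] + 1))
        ac = autocorrelogram(train, window_ms=20.0, bin_ms=1.0)
        short = np.abs(ac.lags_ms) < 4.0
        assert ac.rate_spk_s[short].sum() == 0

    def test_time_reversal_invariance(self, rng):
        t = np.sort(rng.uniform(0, 50, 800))
        fwd = SpikeTrain(t, "c", 50.0)
        rev = SpikeTrain(np.sort(50.0 - t), "c", 50.0)
        a = autocorrelogram(fwd, 40.0, 2.0)
        b = autocorrelogram(rev, 40.0, 2.0)
        np.testing.assert_allclose(a.rate_spk_s, b.rate_spk_s)

    def test_symmetry(self, rng):
        t = np.sort(rng.uniform(0, 20, 300))
        ac = autocorrelogram(SpikeTrain(t, "c", 20.0), 30.0, 3.0)
        np.testing.assert_allclose(ac.rate_spk_s, ac.rate_spk_s[::-1])

    def test_single_spike_raises(self):
        with pytest.raises(ValueError):
            autocorrelogram(SpikeTrain(np.array([1.0]), "c", 2.0), 50.0, 1.0)


class TestClusterCellTypes:
    def test_single_cluster(self, rng):
        labels, sil = cluster_cell_types(rng.normal(size=(10, 3)), k=1)
        assert set(labels) == {0}
        assert np.isnan(sil)

    def test_two_archetypes_perfectly_recovered(self, rng):
        """Cells with well-separated kinetics and autocorrelation shape
        cluster to the ground-truth partition (adjusted agreement 1)."""
        from sklearn.metrics import adjusted_rand_score

        a = np.column_stack([rng.normal(80, 3, 20), rng.normal(0.2, 0.03, 20)])
        b = np.column_stack([rng.normal(130, 3, 20), rng.normal(0.6, 0.03, 20)])
        x = np.vstack([a, b])
        truth = np.array([0] * 20 + [1] * 20)
        labels, sil = cluster_cell_types(x, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert sil > 0.5

    def test_order_invariance(self, rng):
        # three separated feature blobs; the optimum is unambiguous
        x = np.vstack([rng.normal(c, 0.2, size=(10, 4)) for c in (0.0, 4.0, 8.0)])
        labels, _ = cluster_cell_types(x, k=3, seed=1)
        perm = rng.permutation(30)
        labels_p, _ = cluster_cell_types(x[perm], k=3, seed=1)
        # same partition up to label names
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_bad_k_raises(self, rng):
        with pytest.raises(ValueError):
            cluster_cell_types(rng.normal(size=(5, 2)), k=0)


def test_plugin_entropy_uniform():
    assert plugin_entropy(np.arange(16)) == pytest.approx(4.0)
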