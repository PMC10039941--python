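import numpy as np
import pytest

import stsca
from stsca.core import offset_count_table
from stsca.stsca import (
    apply_whitening,
    compute_stsca,
    compute_stsca_with_noise,
    fit_whitening,
    randomize_spike_times,
)


def kernel_on_lag_grid(kernel, result):
    ax = result.axes
    xi, psi = np.meshgrid(ax.spatial_lags_mm, ax.spatial_lags_mm, indexing="xy")
    return stsca.eval_kernel(
        kernel, xi[:, :, None], psi[:, :, None], ax.temporal_lags_s[None, None, :]
    )


class TestComputeStsca:
    def test_single_spike_identity(self, utah):
        rng = np.random.default_rng(0)
        fs = 500.0
        rec = stsca.Recording(rng.standard_normal((96, 300)), fs, utah.channel_ids)
        ch = utah.channel_at(5, 5)
        spikes = stsca.SpikeTrain([ch], [150], fs)
        res = compute_stsca(rec, spikes, utah, window_s=0.1)
        assert set(np.unique(res.counts)) <= {0, 1}
        w1 = utah.grid_side - 1
        for row_idx, cid in enumerate(utah.channel_ids):
            r, c = utah.position(cid)
            got = res.values[r - 5 + w1, c - 5 + w1, :]
            assert np.array_equal(got, rec.signals[row_idx, 100:201])

    def test_constant_lfp_counts_match_offset_table(self, full10):
        fs = 100.0
        n_ch = full10.n_channels
        rec = stsca.Recording(np.ones((n_ch, 500)), fs, full10.channel_ids)
        # one spike on every channel, spread in time
        idx = 50 + np.arange(n_ch) * 4
        spikes = stsca.SpikeTrain(full10.channel_ids, idx, fs)
        res = compute_stsca(rec, spikes, full10, window_s=0.1)
        table = offset_count_table(full10)
        for k in range(res.counts.shape[2]):
            assert np.array_equal(res.counts[:, :, k], table)
        defined = res.counts > 0
        assert np.allclose(res.values[defined], 1.0)
        assert np.all(np.isnan(res.values[~defined]))

    def test_exact_kernel_recovery(self, exact_sinc_fixture):
        res = exact_sinc_fixture["result"]
        k = kernel_on_lag_grid(exact_sinc_fixture["kernel"], res)
        d = res.counts > 0
        assert np.allclose(res.values[d], k[d], rtol=1e-10, atol=1e-10)

    def test_marginal_identity(self, exact_sinc_fixture):
        res = exact_sinc_fixture["result"]
        rec = exact_sinc_fixture["rec"]
        spikes = exact_sinc_fixture["spikes"]
        sta = stsca.compute_sta(
            stsca.array_mean_lfp(rec), rec.fs_hz, spikes.times_s, window_s=0.08
        )
        d = res.counts > 0
        num = np.where(d, res.values * res.counts, 0.0).sum(axis=(0, 1))
        den = res.counts.sum(axis=(0, 1))
        assert np.allclose(num / den, sta.values, rtol=1e-10)

    def test_origin_trace_is_own_channel_sta(self, exact_sinc_fixture):
        res = exact_sinc_fixture["result"]
        rec = exact_sinc_fixture["rec"]
        spikes = exact_sinc_fixture["spikes"]
        half = 40  # window_s=0.08 at 500 Hz
        rows = rec.channel_index(spikes.channel_ids)
        segs = [
            rec.signals[r, i - half : i + half + 1]
            for r, i in zip(rows, spikes.sample_indices)
            if half <= i < rec.n_samples - half
        ]
        assert np.allclose(res.origin_trace, np.mean(segs, axis=0), rtol=1e-10)

    def test_counts_tau_invariant(self, noisy_sinc_fixture):
        counts = noisy_sinc_fixture["result"].counts
        assert np.all(counts == counts[:, :, :1])

    def test_permutation_invariance(self, utah):
        rng = np.random.default_rng(4)
        fs = 200.0
        rec = stsca.Recording(rng.standard_normal((96, 2000)), fs, utah.channel_ids)
        idx = np.sort(rng.choice(np.arange(100, 1900), 30, replace=False))
        ch = rng.choice(utah.channel_ids, 30)
        a = compute_stsca(rec, stsca.SpikeTrain(ch, idx, fs), utah, 0.1)
        perm = rng.permutation(30)
        # rebuild from a permuted event list (subset() re-sorts internally)
        b = compute_stsca(
            rec, stsca.SpikeTrain(ch, idx, fs).subset(perm), utah, 0.1
        )
        assert np.allclose(a.values, b.values, equal_nan=True)
        assert np.array_equal(a.counts, b.counts)

    def test_spike_on_unknown_channel_raises(self, utah):
        rec = stsca.Recording(np.zeros((96, 500)), 500.0, utah.channel_ids)
        spikes = stsca.SpikeTrain([12345], [250], 500.0)
        with pytest.raises(KeyError):
            compute_stsca(rec, spikes, utah, 0.1)

    def test_zero_retained_raises(self, utah):
        rec = stsca.Recording(np.zeros((96, 500)), 500.0, utah.channel_ids)
        spikes = stsca.SpikeTrain([5], [2], 500.0)
        with pytest.raises(ValueError):
            compute_stsca(rec, spikes, utah, 0.1)

    def test_masked_samples_excluded(self, utah):
        rng = np.random.default_rng(6)
        fs = 100.0
        sig = rng.standard_normal((96, 400))
        mask = np.ones((96, 400), bool)
        mask[10, :] = False  # one dead channel
        rec = stsca.Recording(sig, fs, utah.channel_ids, exclusion_mask=mask)
        ch = utah.channel_at(5, 5)
        spikes = stsca.SpikeTrain([ch], [200], fs)
        res = compute_stsca(rec, spikes, utah, 0.1)
        dead_r, dead_c = utah.position(utah.channel_ids[10])
        w1 = utah.grid_side - 1
        assert np.all(res.counts[dead_r - 5 + w1, dead_c - 5 + w1, :] == 0)

    def test_noisy_parameter_recovery(self, noisy_sinc_fixture):
        # with noise SD = kernel peak, ~1000 spikes the angle-averaged
        # estimate must correlate > 0.95 with the true kernel
        res = noisy_sinc_fixture["result"]
        kernel = noisy_sinc_fixture["kernel"]
        assert res.n_spikes >= 900
        rad = stsca.radial_reduce(res, tau_window_s=0.035)
        r_grid, t_grid = np.meshgrid(
            rad.r_bin_centers_mm, rad.temporal_lags_s, indexing="ij"
        )
        true = stsca.eval_kernel(kernel, r_grid, 0.0, t_grid)
        d = rad.counts > 0
        r = np.corrcoef(rad.values[d], true[d])[0, 1]
        assert r > 0.95


class TestRandomizeSpikeTimes:
    def test_counts_preserved(self, noisy_sinc_fixture):
        spikes = noisy_sinc_fixture["spikes"]
        rand = randomize_spike_times(spikes, 60.0, seed=3)
        assert rand.counts_per_channel() == spikes.counts_per_channel()

    def test_seed_reproducible(self, noisy_sinc_fixture):
        spikes = noisy_sinc_fixture["spikes"]
        a = randomize_spike_times(spikes, 60.0, seed=11)
        b = randomize_spike_times(spikes, 60.0, seed=11)
        assert np.array_equal(a.sample_indices, b.sample_indices)
        assert np.array_equal(a.channel_ids, b.channel_ids)
        c = randomize_spike_times(spikes, 60.0, seed=12)
        assert not np.array_equal(a.sample_indices, c.sample_indices)

    def test_duration_shorter_than_spikes_rejected(self):
        spikes = stsca.SpikeTrain([0], [5000], 1000.0)
        with pytest.raises(ValueError):
            randomize_spike_times(spikes, 1.0, seed=0)

    def test_control_destroys_pattern(self, noisy_sinc_fixture, utah):
        rec = noisy_sinc_fixture["rec"]
        spikes = noisy_sinc_fixture["spikes"]
        res = noisy_sinc_fixture["result"]
        rand = randomize_spike_times(spikes, rec.duration_s, seed=2)
        ctrl, _ = compute_stsca_with_noise(rec, rand, utah, window_s=0.1)
        m_obs = stsca.spatial_map(res, 0.035)
        m_ctl = stsca.spatial_map(ctrl, 0.035)
        # compare over reliably sampled cells (>= 20 contributions)
        reliable = res.counts[:, :, 0] >= 20
        peak_obs = np.nanmax(np.abs(np.where(reliable, m_obs, np.nan)))
        peak_ctl = np.nanmax(np.abs(np.where(reliable, m_ctl, np.nan)))
        assert peak_ctl < 0.2 * peak_obs


class TestWhitening:
    def test_uncorrelated_unit_variance_gives_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 20_000))
        rec = stsca.Recording(x, 1000.0, np.arange(8))
        model = fit_whitening(rec)
        assert np.allclose(model.w_matrix, np.eye(8), atol=0.05)

    def test_spd_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((12, 12))
        cov = a @ a.T + 12 * np.eye(12)
        x = np.linalg.cholesky(cov) @ rng.standard_normal((12, 8000))
        rec = stsca.Recording(x, 1000.0, np.arange(12))
        model = fit_whitening(rec)
        sample_cov = np.cov(x, ddof=1)
        assert np.max(np.abs(model.w_matrix @ sample_cov @ model.w_matrix.T - np.eye(12))) < 1e-8

    def test_w_symmetric(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 5000)) * np.array([1, 2, 3, 1, 2, 3])[:, None]
        model = fit_whitening(stsca.Recording(x, 1000.0, np.arange(6)))
        assert np.max(np.abs(model.w_matrix - model.w_matrix.T)) < 1e-10

    def test_whitened_covariance_identity(self):
        rng = np.random.default_rng(3)
        mix = rng.standard_normal((10, 10))
        x = mix @ rng.standard_normal((10, 10_000)) + 5.0
        rec = stsca.Recording(x, 1000.0, np.arange(10))
        out = apply_whitening(rec, fit_whitening(rec))
        assert np.allclose(np.cov(out.signals, ddof=1), np.eye(10), atol=1e-8)

    def test_identity_model_mean_removal(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((4, 100)) + 3.0
        rec = stsca.Recording(x, 1000.0, np.arange(4))
        model = stsca.WhiteningModel(
            w_matrix=np.eye(4),
            eigenvalues=np.ones(4),
            mean_vector=x.mean(axis=1),
            channel_ids=np.arange(4),
        )
        out = apply_whitening(rec, model)
        assert np.allclose(out.signals, x - x.mean(axis=1, keepdims=True))

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        rec = stsca.Recording(rng.standard_normal((4, 500)), 1000.0, np.arange(4))
        model = fit_whitening(rec)
        other = stsca.Recording(rng.standard_normal((4, 500)), 1000.0, np.arange(4) + 10)
        with pytest.raises(ValueError):
            apply_whitening(other, model)

    def test_rank_deficient_rejected(self):
        x = np.ones((4, 500)) * np.arange(500)  # identical channels
        rec = stsca.Recording(x, 1000.0, np.arange(4))
        with pytest.raises(np.linalg.LinAlgError):
            fit_whitening(rec)
        model = fit_whitening(rec, ridge=1e-3)  # ridge rescues the fit
        assert np.all(np.isfinite(model.w_matrix))

    def test_literal_eigenvalue_power_option(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((5, 4000)) * np.array([1, 2, 3, 4, 5])[:, None]
        rec = stsca.Recording(x, 1000.0, np.arange(5))
        zca = fit_whitening(rec)
        inv = fit_whitening(rec, eigenvalue_power=-1.0)
        cov = np.cov(x, ddof=1)
        assert np.allclose(inv.w_matrix @ cov, np.eye(5), atol=1e-8)
        assert not np.allclose(zca.w_matrix, inv.w_matrix)

    def test_too_few_samples_rejected(self):
        rec = stsca.Recording(np.zeros((10, 8)), 1000.0, np.arange(10))
        with pytest.raises(ValueError):
            fit_whitening(rec)
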