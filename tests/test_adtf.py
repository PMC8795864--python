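"""Spectral transfer, ADTF normalization, band integration, baseline logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tvnet
from tvnet import adtf as A
from tvnet.tvmvar import TVMVARModel, kalman_fit


def model_from_coeffs(coeffs_t, dt=1 / 128, labels=None):
    """Wrap a (T, P, n, n) coefficient trajectory as a fitted model."""
    n_t, order, n, _ = coeffs_t.shape
    labels = labels or tuple(f"ch{i}" for i in range(n))
    return TVMVARModel(
        coeffs=coeffs_t, innovation_cov=np.tile(np.eye(n), (n_t, 1, 1)),
        estimated=np.ones(n_t, dtype=bool), order=order, uc=1e-3, dt=dt,
        channel_labels=labels, t0_index=0)


class TestSpectralTransfer:
    def test_uncoupled_system_has_diagonal_transfer(self):
        coeffs = np.zeros((3, 1, 2, 2))
        coeffs[:, 0] = 0.5 * np.eye(2)
        st_ = A.spectral_transfer(model_from_coeffs(coeffs),
                                  A.band_frequencies(), np.arange(3))
        off = st_.H[:, :, ~np.eye(2, dtype=bool)]
        assert np.all(off == 0)
        assert not st_.flagged.any()

    def test_zero_coefficients_give_identity_transfer(self):
        coeffs = np.zeros((2, 1, 3, 3))
        st_ = A.spectral_transfer(model_from_coeffs(coeffs),
                                  A.band_frequencies(), np.arange(2))
        np.testing.assert_allclose(st_.H, np.broadcast_to(np.eye(3), st_.H.shape))

    def test_single_edge_matches_closed_form(self):
        # order-1, lower-triangular A: H_21 = a*e / ((1-d1*e)(1-d2*e))
        d1, d2, a, dt = 0.5, 0.6, 0.4, 1 / 128
        coeffs = np.array([[[[d1, 0.0], [a, d2]]]])
        freqs = A.band_frequencies()
        st_ = A.spectral_transfer(model_from_coeffs(coeffs, dt), freqs, np.array([0]))
        e = np.exp(-2j * np.pi * freqs * dt)
        expected = np.abs(a * e / ((1 - d1 * e) * (1 - d2 * e)))
        np.testing.assert_allclose(np.abs(st_.H[0, :, 1, 0]), expected, rtol=1e-10)

    def test_frequencies_outside_nyquist_rejected(self):
        coeffs = np.zeros((1, 1, 2, 2))
        with pytest.raises(ValueError, match="Hz"):
            A.spectral_transfer(model_from_coeffs(coeffs), np.array([70.0]),
                                np.array([0]))


class TestNormalization:
    def make_transfer(self, h):
        n_t, n_f = h.shape[:2]
        return A.SpectralTransfer(
            H=h, freqs=np.arange(n_f) + 3.0, times_ms=np.arange(n_t, dtype=float),
            flagged=np.zeros((n_t, n_f), dtype=bool),
            channel_labels=tuple(f"c{i}" for i in range(h.shape[2])))

    def test_identity_transfer_gives_identity_influence(self):
        h = np.broadcast_to(np.eye(3, dtype=complex), (2, 4, 3, 3)).copy()
        g = A.adtf_normalized(self.make_transfer(h))
        np.testing.assert_allclose(g.gamma2, np.broadcast_to(np.eye(3), g.gamma2.shape))

    def test_sink_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(3, 5, 4, 4)) + 1j * rng.normal(size=(3, 5, 4, 4))
        g = A.adtf_normalized(self.make_transfer(h))
        np.testing.assert_allclose(g.gamma2.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(g.gamma2 >= 0)

    def test_equal_magnitudes_split_evenly(self):
        h = np.array([[[[0.0, 1.0], [1.0 + 0j, 1.0]]]])
        g = A.adtf_normalized(self.make_transfer(h))
        assert np.isclose(g.gamma2[0, 0, 1, 0], 0.5)
        assert np.isclose(g.gamma2[0, 0, 1, 1], 0.5)

    def test_zero_row_flagged(self):
        h = np.ones((1, 2, 2, 2), dtype=complex)
        h[0, 1, 0, :] = 0
        g = A.adtf_normalized(self.make_transfer(h))
        assert g.flagged[0, 1]
        assert not g.flagged[0, 0]


def make_gamma(gamma2, freqs=None):
    n_t, n_f = gamma2.shape[:2]
    return A.ADTFMatrix(
        gamma2=gamma2, freqs=freqs if freqs is not None else np.arange(n_f) + 3.0,
        times_ms=np.arange(n_t, dtype=float),
        flagged=np.zeros((n_t, n_f), dtype=bool),
        channel_labels=tuple(f"c{i}" for i in range(gamma2.shape[2])))


class TestBandIntegration:
    def test_constant_band_average_is_constant(self):
        g = make_gamma(np.full((2, 6, 3, 3), 0.3))
        band = A.band_integrate(g, 3, 8)
        np.testing.assert_allclose(band.theta2, 0.3)

    def test_identity_influence_stays_identity(self):
        g = make_gamma(np.broadcast_to(np.eye(2), (3, 5, 2, 2)).copy())
        band = A.band_integrate(g, 3, 7)
        np.testing.assert_allclose(band.theta2, np.broadcast_to(np.eye(2), (3, 2, 2)))

    def test_linear_ramp_averages_to_bin_mean(self):
        n_f = 10
        ramp = np.linspace(0, 1, n_f)
        gamma2 = np.zeros((1, n_f, 2, 2))
        gamma2[0, :, 0, 1] = ramp
        band = A.band_integrate(make_gamma(gamma2), 3, 12)
        assert np.isclose(band.theta2[0, 0, 1], ramp.mean())  # summation oracle

    def test_empty_band_rejected(self):
        g = make_gamma(np.full((1, 4, 2, 2), 0.25))
        with pytest.raises(ValueError, match="bins"):
            A.band_integrate(g, 40, 50)

    def test_excess_flagged_points_fail_loudly(self):
        g = make_gamma(np.full((10, 4, 2, 2), 0.25))
        g.flagged[:, :2] = True
        with pytest.raises(RuntimeError, match="singular"):
            A.band_integrate(g, 3, 6)


class TestSegmentAverage:
    def band(self, value, times=3):
        return A.BandADTF(theta2=np.full((times, 2, 2), value), f1=3, f2=30,
                          times_ms=np.arange(times, dtype=float),
                          channel_labels=("a", "b"))

    def test_identical_segments_average_to_themselves(self):
        out = tvnet.segment_average([self.band(0.2), self.band(0.2)])
        np.testing.assert_allclose(out.theta2, 0.2)

    def test_two_segment_mean(self):
        out = tvnet.segment_average([self.band(0.2), self.band(0.4)])
        np.testing.assert_allclose(out.theta2, 0.3)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            tvnet.segment_average([self.band(0.2, times=3), self.band(0.2, times=4)])


class TestBaseline:
    def band_with_times(self, theta, times_ms):
        return A.BandADTF(theta2=theta, f1=3, f2=30,
                          times_ms=np.asarray(times_ms, dtype=float),
                          channel_labels=("a", "b"))

    def baseline_times(self):
        # the default grid: 40 samples at 128 Hz starting nearest -360 ms
        return (np.arange(-46, -6)) / 128 * 1e3

    def test_constant_baseline_recovered(self):
        t = self.baseline_times()
        base = A.baseline_stats(self.band_with_times(np.full((40, 2, 2), 0.37), t))
        np.testing.assert_allclose(base.mean_theta2, 0.37)
        assert base.n_timepoints == 40

    def test_wrong_point_count_is_explicit_failure(self):
        t = self.baseline_times()[:-1]
        with pytest.raises(ValueError, match="40"):
            A.baseline_stats(self.band_with_times(np.full((39, 2, 2), 0.3), t))

    def test_linear_trend_averages_to_midpoint(self):
        t = self.baseline_times()
        theta = np.zeros((40, 2, 2))
        theta[:, 0, 1] = np.linspace(0.1, 0.5, 40)
        base = A.baseline_stats(self.band_with_times(theta, t))
        assert np.isclose(base.mean_theta2[0, 1], 0.3)

    def test_post_equal_to_baseline_corrects_to_zero(self):
        t = self.baseline_times()
        band = self.band_with_times(np.full((40, 2, 2), 0.4), t)
        base = A.baseline_stats(band)
        corr = A.baseline_correct(band, base)
        np.testing.assert_allclose(corr.values, 0.0, atol=1e-15)

    def test_drop_from_baseline_is_negative(self):
        t = self.baseline_times()
        base = A.baseline_stats(self.band_with_times(np.full((40, 2, 2), 0.4), t))
        post = A.BandADTF(theta2=np.full((5, 2, 2), 0.1), f1=3, f2=30,
                          times_ms=np.arange(5, dtype=float), channel_labels=("a", "b"))
        corr = A.baseline_correct(post, base)
        np.testing.assert_allclose(corr.values, -0.3)

    def test_channel_mismatch_rejected(self):
        t = self.baseline_times()
        base = A.baseline_stats(self.band_with_times(np.full((40, 2, 2), 0.4), t))
        post = A.BandADTF(theta2=np.full((5, 3, 3), 0.1), f1=3, f2=30,
                          times_ms=np.arange(5, dtype=float),
                          channel_labels=("a", "b", "c"))
        with pytest.raises(ValueError, match="channel"):
            A.baseline_correct(post, base)


class TestGrids:
    def test_default_grid_counts(self):
        base = A.make_time_grid(128, 128.0, *A.BASELINE_GRID, n_samples=384)
        post = A.make_time_grid(128, 128.0, *A.POST_GRID, n_samples=384)
        assert base.n_points == 40
        assert post.n_points == 246
        assert -360 <= base.times_ms[0] and base.times_ms[-1] <= -40
        assert 60 <= post.times_ms[0] and post.times_ms[-1] <= 2000

    def test_grid_exceeding_segment_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            A.make_time_grid(128, 128.0, 60.0, 300, n_samples=384)

    def test_band_has_28_bins(self):
        assert A.band_frequencies().size == 28


class TestDirectionality:
    def test_unidirectional_coupling_yields_asymmetric_influence(self):
        truth = tvnet.make_tv_system(2, couplings=[tvnet.Coupling(0, 1, 0.5)],
                                     order=1, diag=0.5, window_ms=(0.0, 4000.0))
        ep = tvnet.simulate_segments(truth, 30, fs=128, seed=8)
        freqs = A.band_frequencies()
        fwd, rev = [], []
        for s in range(ep.n_segments):
            seg = tvnet.EpochSet(ep.data[s:s + 1], ep.dt, ep.t0_index,
                                 ep.channel_labels)
            model = kalman_fit(seg, 1, 1e-3)
            idx = np.arange(200, ep.n_samples)
            h, _ = A._transfer_from_coeffs(model.coeffs[idx], ep.dt, freqs)
            g = h.real ** 2 + h.imag ** 2
            g /= g.sum(axis=-1, keepdims=True)
            th = g.mean(axis=1)
            fwd.append(th[:, 1, 0].mean())
            rev.append(th[:, 0, 1].mean())
        assert np.mean(fwd) / np.mean(rev) > 3

    def test_planted_drop_turns_corrected_negative(self, control_results,
                                                   control_sessions):
        res = control_results[0]
        labels = list(res.corrected.channel_labels)
        weakened = control_sessions[0].truth.weakened_edges()
        for src, snk in weakened:
            vals = res.corrected.values[:, labels.index(snk), labels.index(src)]
            assert (vals < 0).mean() >= 0.8


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_normalization_invariant_on_random_fitted_models(seed):
    """Any fitted trajectory yields row sums of one and Theta2 in [0, 1]."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 5))
    w = float(rng.uniform(-0.5, 0.5))
    truth = tvnet.make_tv_system(n, couplings=[tvnet.Coupling(0, n - 1, w)],
                                 order=1, diag=float(rng.uniform(0.1, 0.7)),
                                 window_ms=(0.0, 3000.0))
    ep = tvnet.simulate_segments(truth, 1, fs=128, seed=seed)
    model = kalman_fit(ep, 1, 1e-3)
    idx = np.arange(model.order, ep.n_samples, 10)
    st_ = A.spectral_transfer(model, A.band_frequencies(), idx)
    g = A.adtf_normalized(st_)
    assert np.all(np.abs(g.gamma2.sum(axis=-1) - 1) < 1e-9)
    band = A.band_integrate(g)
    assert np.all(band.theta2 >= 0) and np.all(band.theta2 <= 1 + 1e-12)
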