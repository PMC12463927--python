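"""MVAR fitting, spectral transfer, DTF normalization, surrogate nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdtf.connectivity import (IllConditionedTransferError, MVARModel,
                                 SingularFitError, dtf, dtf_mean, fit_mvar,
                                 frequency_grid, observed_dtf_mean,
                                 phase_randomize, rank_index,
                                 select_order_bic, simulate_mvar,
                                 surrogate_threshold, threshold_network,
                                 transfer_function)
from eegdtf.spectral import Band

A1_3CH = np.array([[0.4, 0.1, 0.0], [0.3, 0.3, 0.0], [0.0, 0.2, 0.2]])
A2_3CH = np.array([[-0.3, 0.0, 0.0], [0.0, -0.25, 0.1], [0.15, 0.0, -0.2]])


def _random_stable_mvar2(k, rng, radius=0.9):
    """Random MVAR(2) rescaled until its companion spectral radius < radius."""
    coeffs = [rng.normal(0, 0.3 / np.sqrt(k), (k, k)) for _ in range(2)]
    for _ in range(50):
        m = MVARModel(order=2, coeffs=coeffs, resid_cov=np.eye(k), n_samples_used=1)
        r = m.companion_spectral_radius()
        if r < radius:
            return coeffs
        coeffs = [a * (radius / r) ** (i + 1) for i, a in enumerate(coeffs, start=0)]
    raise RuntimeError("could not stabilize")


class TestFitMVAR:
    def test_parameter_recovery_mvar2(self):
        """Coefficients of a known stable 3-channel MVAR(2) recovered within
        +-0.1 on average over 50 seeds (1250 samples each)."""
        errs = []
        for seed in range(50):
            X = simulate_mvar([A1_3CH, A2_3CH], 1250, np.random.default_rng(seed))
            f = fit_mvar(X, 2)
            errs.append(max(np.abs(f.coeffs[0] - A1_3CH).max(),
                            np.abs(f.coeffs[1] - A2_3CH).max()))
        assert np.mean(errs) < 0.1

    def test_white_noise_coefficients_small(self):
        X = np.random.default_rng(0).standard_normal((3, 1250))
        f = fit_mvar(X, 2)
        assert np.abs(np.hstack(f.coeffs)).max() < 0.1

    def test_matches_statsmodels_var(self):
        """Independent cross-check: OLS coefficients agree with the
        statsmodels VAR estimator (no intercept) on the same data."""
        from statsmodels.tsa.api import VAR
        X = simulate_mvar([A1_3CH, A2_3CH], 2000, np.random.default_rng(4))
        ours = fit_mvar(X, 2)
        theirs = VAR(X.T).fit(2, trend="n").coefs  # (p, k, k)
        np.testing.assert_allclose(np.stack(ours.coeffs), theirs, atol=1e-6)

    def test_invalid_order_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mvar(rng.standard_normal((3, 100)), 0)

    def test_nonfinite_input_rejected(self):
        X = np.full((3, 100), np.nan)
        with pytest.raises(ValueError):
            fit_mvar(X, 2)

    def test_rank_deficient_raises_singular(self, rng):
        x = rng.standard_normal(500)
        X = np.vstack([x, x])  # duplicated channel
        with pytest.raises(SingularFitError):
            fit_mvar(X, 2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mvar(rng.standard_normal((5, 12)), 2)


class TestOrderSelection:
    def test_mvar2_selects_order_2(self):
        hits = 0
        for seed in range(50):
            X = simulate_mvar([A1_3CH, A2_3CH], 1250, np.random.default_rng(seed))
            hits += select_order_bic(X, range(1, 7)) == 2
        assert hits >= 45  # >= 90% of runs

    def test_white_noise_prefers_order_1(self):
        from collections import Counter
        sel = Counter(
            select_order_bic(np.random.default_rng(100 + s).standard_normal((3, 1250)),
                             range(1, 7))
            for s in range(20)
        )
        assert sel.most_common(1)[0][0] == 1

    def test_single_candidate(self, rng):
        X = rng.standard_normal((3, 500))
        assert select_order_bic(X, [2]) == 2

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            select_order_bic(rng.standard_normal((3, 500)), [])


class TestTransferFunction:
    def test_zero_coefficients_identity(self):
        m = MVARModel(order=1, coeffs=[np.zeros((3, 3))],
                      resid_cov=np.eye(3), n_samples_used=10)
        H = transfer_function(m, frequency_grid(), 250.0)
        np.testing.assert_allclose(
            H.H, np.broadcast_to(np.eye(3) + 0j, H.H.shape), atol=1e-14)

    def test_triangular_structure_preserved(self):
        """Channel 1 drives 2 with no reverse: H_12(f)=0 at every f."""
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        m = MVARModel(order=1, coeffs=[A], resid_cov=np.eye(2), n_samples_used=10)
        H = transfer_function(m, frequency_grid(), 250.0)
        assert np.abs(H.H[:, 0, 1]).max() < 1e-14

    def test_ar1_closed_form_spectrum(self):
        """1-channel AR(1), a=0.5: |H(f)|^2 = 1/|1-0.5 e^{-i2pif/fs}|^2."""
        fs = 250.0
        m = MVARModel(order=1, coeffs=[np.array([[0.5]])],
                      resid_cov=np.eye(1), n_samples_used=10)
        freqs = frequency_grid()
        H = transfer_function(m, freqs, fs)
        expected = 1.0 / np.abs(1 - 0.5 * np.exp(-2j * np.pi * freqs / fs)) ** 2
        np.testing.assert_allclose(np.abs(H.H[:, 0, 0]) ** 2, expected, rtol=1e-12)

    def test_unstable_pole_on_grid_rejected(self):
        # a=1 puts a unit-root singularity at f=0; grid touching 0 must fail
        m = MVARModel(order=1, coeffs=[np.array([[1.0]])],
                      resid_cov=np.eye(1), n_samples_used=10)
        with pytest.raises(IllConditionedTransferError):
            transfer_function(m, np.array([0.0]), 250.0)


class TestDTF:
    def test_identity_transfer_gives_identity_dtf(self):
        H = np.broadcast_to(np.eye(4) + 0j, (10, 4, 4))
        g = dtf(H)
        np.testing.assert_allclose(g, np.broadcast_to(np.eye(4), (10, 4, 4)))

    def test_triangular_direction_recovered(self):
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        m = MVARModel(order=1, coeffs=[A], resid_cov=np.eye(2), n_samples_used=10)
        g = dtf(transfer_function(m, frequency_grid(), 250.0))
        assert np.all(g[:, 0, 1] == 0)  # no flow 2 -> 1
        assert np.all(g[:, 1, 0] > 0)   # flow 1 -> 2

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_rows_sum_to_one(self, seed, k):
        """Normalization: sum_j gamma2[i, j](f) = 1 for every target i and
        frequency, on random stable MVAR(2) models."""
        rng = np.random.default_rng(seed)
        coeffs = _random_stable_mvar2(k, rng)
        m = MVARModel(order=2, coeffs=coeffs, resid_cov=np.eye(k), n_samples_used=10)
        g = dtf(transfer_function(m, frequency_grid(), 250.0))
        assert np.abs(g.sum(axis=-1) - 1).max() < 1e-10

    def test_estimated_dtf_converges_to_analytic(self):
        """Oracle equivalence: DTF from a 5000-sample fit matches the DTF
        computed from the true coefficients (max abs error < 0.05)."""
        A = np.array([[0.5, 0.0], [0.4, 0.5]])
        truth = MVARModel(order=1, coeffs=[A], resid_cov=np.eye(2), n_samples_used=1)
        freqs = frequency_grid()
        g_true = dtf(transfer_function(truth, freqs, 250.0))
        X = simulate_mvar([A], 5000, np.random.default_rng(17))
        g_est = dtf(transfer_function(fit_mvar(X, 1), freqs, 250.0))
        assert np.abs(g_est - g_true).max() < 0.05
        assert g_est[:, 0, 1].max() < 0.02  # structurally-zero reverse edge


class TestDTFMean:
    BAND = Band("alpha", 8.0, 13.0)
    FREQS = frequency_grid()

    def test_constant_gamma2(self):
        g = np.full((len(self.FREQS), 3, 3), 0.25)
        np.testing.assert_allclose(dtf_mean(g, self.FREQS, self.BAND), 0.25)

    def test_single_bin_band_identity(self):
        g = np.random.default_rng(0).uniform(size=(len(self.FREQS), 2, 2))
        narrow = Band("one", 10.0, 10.5)  # half-open: exactly the 10 Hz bin
        idx = int(np.where(self.FREQS == 10.0)[0][0])
        np.testing.assert_allclose(dtf_mean(g, self.FREQS, narrow), g[idx])

    def test_two_epoch_average(self):
        g = np.stack([np.full((len(self.FREQS), 2, 2), 0.2),
                      np.full((len(self.FREQS), 2, 2), 0.4)])
        np.testing.assert_allclose(dtf_mean(g, self.FREQS, self.BAND), 0.3)

    def test_empty_band_rejected(self):
        g = np.zeros((len(self.FREQS), 2, 2))
        with pytest.raises(ValueError):
            dtf_mean(g, self.FREQS, Band("none", 40.0, 45.0))


class TestPhaseRandomize:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.standard_normal((4, 1001))  # odd length
        y = phase_randomize(x, rng)
        np.testing.assert_allclose(np.abs(np.fft.rfft(y, axis=-1)),
                                   np.abs(np.fft.rfft(x, axis=-1)), rtol=1e-8)

    def test_even_length_real_output(self, rng):
        x = rng.standard_normal((2, 1250))
        y = phase_randomize(x, rng)
        assert y.dtype.kind == "f"
        np.testing.assert_allclose(np.abs(np.fft.rfft(y)), np.abs(np.fft.rfft(x)),
                                   rtol=1e-8)

    def test_constant_signal_unchanged(self, rng):
        x = np.full((2, 100), 4.2)
        np.testing.assert_allclose(phase_randomize(x, rng), x, atol=1e-10)

    def test_cross_channel_correlation_destroyed(self, rng):
        """A strongly coupled pair loses its lagged correlation after
        independent per-channel randomization (|r| < 0.1 averaged over 100
        surrogates)."""
        src = rng.standard_normal(2000)
        tgt = np.zeros_like(src)
        tgt[2:] = 0.9 * src[:-2]
        tgt += 0.1 * rng.standard_normal(2000)
        X = np.vstack([src, tgt])
        rs = []
        for _ in range(100):
            Y = phase_randomize(X, rng)
            rs.append(np.corrcoef(Y[0][:-2], Y[1][2:])[0, 1])
        assert np.mean(np.abs(rs)) < 0.1

    def test_nonfinite_rejected(self, rng):
        with pytest.raises(ValueError):
            phase_randomize(np.array([[1.0, np.inf]]), rng)


class TestSurrogateThreshold:
    def test_rank_indices(self):
        assert rank_index(1000, 0.05) == 950
        assert rank_index(100, 0.05) == 95
        assert rank_index(200, 0.05) == 190

    def test_thresholds_in_unit_interval_and_monotone(self, rng):
        eps = rng.standard_normal((3, 4, 250))
        null = surrogate_threshold(eps, [Band("alpha", 8, 13)], order=2,
                                   n_surrogates=30, rng=rng, sample_rate=125.0)
        thr = null.thresholds["alpha"]
        assert np.all((thr >= 0) & (thr <= 1))
        d = null.distributions["alpha"]
        assert np.all(np.diff(d, axis=0) >= 0)  # sorted distributions

    def test_too_few_surrogates_rejected(self, rng):
        eps = rng.standard_normal((2, 3, 250))
        with pytest.raises(ValueError):
            surrogate_threshold(eps, [Band("alpha", 8, 13)], n_surrogates=10,
                                rng=rng, sample_rate=125.0)

    def test_determinism_under_seeded_rng(self):
        eps = np.random.default_rng(3).standard_normal((2, 4, 250))
        kw = dict(order=2, n_surrogates=25, sample_rate=125.0)
        n1 = surrogate_threshold(eps, [Band("alpha", 8, 13)],
                                 rng=np.random.default_rng(5), **kw)
        n2 = surrogate_threshold(eps, [Band("alpha", 8, 13)],
                                 rng=np.random.default_rng(5), **kw)
        np.testing.assert_array_equal(n1.thresholds["alpha"], n2.thresholds["alpha"])


class TestThresholdNetwork:
    def test_above_threshold_retained(self):
        out = threshold_network(np.array([[0.0, 0.30], [0.10, 0.0]]),
                                np.array([[0.0, 0.25], [0.25, 0.0]]))
        assert out[0, 1] == 0.30
        assert out[1, 0] == 0.0

    def test_below_threshold_zeroed(self):
        out = threshold_network(np.full((3, 3), 0.20), np.full((3, 3), 0.25))
        np.testing.assert_array_equal(out, 0.0)

    def test_tie_goes_to_zero(self):
        out = threshold_network(np.full((2, 2), 0.25), np.full((2, 2), 0.25))
        np.testing.assert_array_equal(out, 0.0)

    def test_diagonal_always_zero(self):
        out = threshold_network(np.full((3, 3), 0.9), np.zeros((3, 3)))
        assert np.all(np.diag(out) == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            threshold_network(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDirectionRecovery:
    def test_injected_coupling_direction(self, rng):
        """A single lagged coupling 1 -> 2 in white noise yields a dominant
        DTF edge in the correct direction."""
        n = 2500
        src = rng.standard_normal(n)
        tgt = np.zeros(n)
        tgt[2:] = 0.6 * src[:-2]
        tgt += rng.standard_normal(n)
        other = rng.standard_normal(n)
        eps = np.stack([np.vstack([src, tgt, other])])
        obs = observed_dtf_mean(eps, [Band("alpha", 8, 13)], order=2,
                                sample_rate=250.0)["alpha"]
        assert obs[1, 0] > 5 * obs[0, 1]  # flow 1->2 dominates reverse
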