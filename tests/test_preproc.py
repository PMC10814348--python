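"""Preprocessing chain: covariance, prewhitening, combination, phasing,
HOSVD denoising, and AUC maps."""

import numpy as np
import pytest
from scipy import stats

from hp13c.containers import (
    AcquisitionParams,
    BolusParams,
    KineticParams,
    MetaboliteSeries,
    NoiseModel,
    RawDynamic,
)
from hp13c.preproc import (
    auc_maps,
    combine_channels,
    estimate_noise_covariance,
    hosvd_denoise,
    phase_correct,
    prewhiten,
)
from hp13c.synth import default_coil_profiles, simulate_two_site, synthesize_multichannel


def _raw_noise_only(cov, n_frames, vol=(4, 5, 5), scale=1.0, seed=0):
    """RawDynamic whose every frame is pure correlated noise."""
    n_ch = cov.shape[0]
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    data = {}
    for m in ("pyr", "lac", "bic"):
        w = rng.standard_normal((n_ch, n_frames) + vol + (2,)) @ np.array([1, 1j])
        w *= np.sqrt(0.5)
        data[m] = np.einsum("ij,j...->i...", L, w) * scale
    acq = AcquisitionParams(n_timepoints=n_frames)
    return RawDynamic(data=data, acq=acq, noise_frames=list(range(n_frames)))


class TestNoiseCovariance:
    def test_white_noise_recovers_identity(self):
        raw = _raw_noise_only(np.eye(3, dtype=complex), n_frames=20)
        est = estimate_noise_covariance(raw).channel_covariance
        assert np.linalg.norm(est - np.eye(3)) / np.linalg.norm(np.eye(3)) < 0.05

    def test_known_covariance_recovered_within_5pct(self):
        """Monte-Carlo oracle: [[1, .5], [.5, 1]] at ~1e5 samples."""
        cov = np.array([[1.0, 0.5], [0.5, 1.0]], dtype=complex)
        raw = _raw_noise_only(cov, n_frames=20, vol=(10, 14, 14), seed=3)
        est = estimate_noise_covariance(raw).channel_covariance
        np.testing.assert_allclose(est, cov, atol=0.05)

    def test_duplicated_channel_regularized_to_pd(self):
        """A duplicated channel yields a singular sample covariance; the
        estimate must still come back positive-definite."""
        raw = _raw_noise_only(np.eye(2, dtype=complex), n_frames=20)
        for m in raw.data:
            raw.data[m][1] = raw.data[m][0]
        est = estimate_noise_covariance(raw)
        assert np.all(np.linalg.eigvalsh(est.channel_covariance) > 0)
        est.cholesky()  # must not raise

    def test_no_noise_frames_is_error(self):
        raw = _raw_noise_only(np.eye(2, dtype=complex), n_frames=20)
        raw.noise_frames = []
        with pytest.raises(ValueError):
            estimate_noise_covariance(raw)


class TestPrewhiten:
    def test_identity_covariance_leaves_data_unchanged(self):
        raw = _raw_noise_only(np.eye(3, dtype=complex), n_frames=6)
        out = prewhiten(raw, NoiseModel(np.eye(3, dtype=complex)))
        np.testing.assert_allclose(out.data["pyr"], raw.data["pyr"])

    def test_diagonal_covariance_scales_channels(self):
        raw = _raw_noise_only(np.eye(2, dtype=complex), n_frames=6)
        out = prewhiten(raw, NoiseModel(np.diag([4.0, 1.0]).astype(complex)))
        np.testing.assert_allclose(out.data["lac"][0], raw.data["lac"][0] / 2.0)
        np.testing.assert_allclose(out.data["lac"][1], raw.data["lac"][1])

    def test_random_spd_covariance_whitens_noise(self, rng):
        """After prewhitening, the re-estimated covariance of the noise
        samples is the identity within Monte-Carlo tolerance."""
        a = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
        cov = a @ a.conj().T + 0.5 * np.eye(3)
        raw = _raw_noise_only(cov, n_frames=20, vol=(10, 14, 14), seed=9)
        white = prewhiten(raw, NoiseModel(cov))
        est = estimate_noise_covariance(white).channel_covariance
        np.testing.assert_allclose(est, np.eye(3), atol=0.05)

    def test_dimension_mismatch_rejected(self):
        raw = _raw_noise_only(np.eye(2, dtype=complex), n_frames=6)
        with pytest.raises(ValueError):
            prewhiten(raw, NoiseModel(np.eye(4, dtype=complex)))


def _noiseless_raw(n_ch=2, vol=(2, 3, 3), acq=None):
    acq = acq or AcquisitionParams()
    kp = KineticParams()
    kp.k_pl = np.full(vol, 0.015)
    kp.k_pb = np.full(vol, 0.003)
    series = simulate_two_site(BolusParams(), kp, acq)
    profiles = default_coil_profiles(n_ch, vol, seed=0)
    raw = synthesize_multichannel(
        series, profiles, NoiseModel(np.eye(n_ch, dtype=complex), noise_scale=0.0), 0
    )
    return series, profiles, raw


class TestCombineChannels:
    def test_single_channel_returns_that_channel_up_to_phase(self):
        series, profiles, raw = _noiseless_raw(n_ch=1)
        out = combine_channels(raw)
        np.testing.assert_allclose(np.abs(out.pyr), np.abs(raw.data["pyr"][0]), atol=1e-12)

    def test_zero_sensitivity_channel_gets_zero_weight(self):
        series, profiles, raw = _noiseless_raw(n_ch=2)
        raw.data = {m: a.copy() for m, a in raw.data.items()}
        for m in raw.data:
            raw.data[m][1] = 0.0
        out2 = combine_channels(raw)
        _, _, raw1 = _noiseless_raw(n_ch=1)
        out1 = combine_channels(raw1)
        # combining with a dead channel changes nothing but the profile set
        np.testing.assert_allclose(np.abs(out2.pyr), np.abs(raw.data["pyr"][0]), atol=1e-12)

    def test_all_zero_pyruvate_voxel_flagged(self):
        series, profiles, raw = _noiseless_raw(n_ch=2)
        raw.data = {m: a.copy() for m, a in raw.data.items()}
        for m in raw.data:
            raw.data[m][:, :, 0, 0, 0] = 0.0
        out = combine_channels(raw)
        assert out.invalid_mask[0, 0, 0]
        assert np.all(out.pyr[:, 0, 0, 0] == 0)

    def test_global_complex_scalar_invariance(self):
        """Scaling every channel by one complex scalar leaves the combined
        magnitude unchanged (weights renormalize)."""
        series, profiles, raw = _noiseless_raw(n_ch=3)
        scaled = RawDynamic(
            data={m: (0.5 + 0.8j) * a for m, a in raw.data.items()},
            acq=raw.acq, noise_frames=raw.noise_frames,
            appended_noise_frame=raw.appended_noise_frame,
        )
        a = np.abs(combine_channels(raw).pyr)
        b = np.abs(combine_channels(scaled).pyr)
        np.testing.assert_allclose(b, np.abs(0.5 + 0.8j) * a, rtol=1e-10)

    def test_matched_filter_snr_gain(self):
        """Two equal-sensitivity channels with independent unit noise:
        combined SNR approaches sqrt(2) x single-channel SNR."""
        rng = np.random.default_rng(11)
        acq = AcquisitionParams(n_timepoints=20)
        vol = (6, 10, 10)
        sig = np.zeros((20,) + vol)
        sig[2:] = 5.0  # strong constant signal after 2 noise frames
        series = MetaboliteSeries(pyr=sig, lac=sig * 0.2, bic=sig * 0.05,
                                  time=acq.time_axis(), acq=acq)
        profiles = np.ones((2,) + vol, dtype=complex)
        raw = synthesize_multichannel(
            series, profiles, NoiseModel(np.eye(2, dtype=complex), noise_scale=1.0),
            seed=4,
        )
        combined = combine_channels(raw)
        single = raw.data["pyr"][0]
        snr_single = np.abs(single[10]).mean() / np.real(single[0]).std()
        snr_comb = np.abs(combined.pyr[10]).mean() / np.real(combined.pyr[0]).std()
        assert snr_comb / snr_single == pytest.approx(np.sqrt(2), rel=0.12)


class TestPhaseCorrect:
    def test_constant_phase_recovers_magnitude(self):
        series, _, raw = _noiseless_raw(n_ch=1)
        combined = combine_channels(raw)
        rotated = MetaboliteSeries(
            pyr=combined.pyr * np.exp(1j * np.pi / 4),
            lac=combined.lac * np.exp(1j * np.pi / 4),
            bic=combined.bic * np.exp(1j * np.pi / 4),
            time=combined.time, acq=combined.acq, noise_sd=combined.noise_sd,
        )
        out = phase_correct(rotated)
        np.testing.assert_allclose(out.pyr, np.abs(combined.pyr), atol=1e-10)

    def test_noiseless_forward_voxel_real_nonnegative(self):
        series, _, raw = _noiseless_raw(n_ch=3)
        out = phase_correct(combine_channels(raw))
        assert np.all(out.pyr >= -1e-12)
        assert np.all(out.lac >= -1e-12)

    def test_phased_noise_real_channel_gaussian(self):
        """Zero-order phasing rotates circular noise; the real channel of
        noise samples stays zero-mean Gaussian."""
        cov = np.eye(2, dtype=complex)
        raw = _raw_noise_only(cov, n_frames=20, vol=(4, 6, 6), seed=21)
        # add signal so the peak-phase estimate is defined
        sig = np.zeros((2, 20, 4, 6, 6), dtype=complex)
        sig[:, 5:] = 3.0
        raw.data["pyr"] = raw.data["pyr"] + sig
        raw.noise_frames = [0, 1, 2]
        out = phase_correct(combine_channels(raw))
        noise_vals = out.lac[:3].ravel()
        assert abs(noise_vals.mean()) < 0.05
        assert stats.shapiro(noise_vals[:500]).pvalue > 0.01


class TestHOSVD:
    def _series(self, data5):
        acq = AcquisitionParams(n_timepoints=data5.shape[1])
        return MetaboliteSeries(
            pyr=data5[0], lac=data5[1], bic=data5[2],
            time=acq.time_axis(), acq=acq, noise_sd=1.0,
        )

    def test_full_rank_is_identity(self, rng):
        data = rng.standard_normal((3, 6, 4, 5, 5))
        s = self._series(data)
        out = hosvd_denoise(s, (3, 6, 4, 5, 5))
        np.testing.assert_allclose(out.stack(), data, atol=1e-10)

    def test_exact_rank1_recovered_by_rank1_truncation(self, rng):
        vecs = [rng.standard_normal(n) for n in (3, 6, 4, 5, 5)]
        data = np.einsum("a,b,c,d,e->abcde", *vecs)
        out = hosvd_denoise(self._series(data), (1, 1, 1, 1, 1))
        np.testing.assert_allclose(out.stack(), data, atol=1e-12)

    def test_denoising_reduces_residual_on_low_rank_data(self, rng):
        """Rank-2 tensor + noise at SNR ~5: truncated reconstruction is
        strictly closer to the ground truth than the noisy input."""
        truth = sum(
            np.einsum("a,b,c,d,e->abcde", *[rng.standard_normal(n) for n in (3, 8, 4, 6, 6)])
            for _ in range(2)
        )
        sigma = np.abs(truth).mean() / 5.0
        noisy = truth + rng.normal(0, sigma, truth.shape)
        out = hosvd_denoise(self._series(noisy), (2, 2, 2, 2, 2))
        res_before = np.linalg.norm(noisy - truth)
        res_after = np.linalg.norm(out.stack() - truth)
        assert res_after < res_before

    def test_truncation_error_monotone_in_rank(self, rng):
        data = rng.standard_normal((3, 6, 4, 5, 5))
        s = self._series(data)
        errs = [
            np.linalg.norm(hosvd_denoise(s, (3, r, 4, 5, 5)).stack() - data)
            for r in (2, 3, 4, 5, 6)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_rank_exceeding_dimension_rejected(self, rng):
        s = self._series(rng.standard_normal((3, 6, 4, 5, 5)))
        with pytest.raises(ValueError):
            hosvd_denoise(s, (4, 6, 4, 5, 5))


class TestAUC:
    def _series(self, pyr, noise_sd=1.0):
        acq = AcquisitionParams(n_timepoints=pyr.shape[0])
        return MetaboliteSeries(
            pyr=pyr, lac=pyr * 0.1, bic=pyr * 0.02,
            time=acq.time_axis(), acq=acq, noise_sd=noise_sd,
        )

    def test_constant_signal_auc(self):
        pyr = np.full((20, 1, 1, 1), 3.0)
        maps = auc_maps(self._series(pyr))
        assert maps.auc["pyr"][0, 0, 0] == pytest.approx(60.0)

    def test_zero_voxel_masked_out(self):
        pyr = np.zeros((20, 1, 2, 1))
        pyr[:, 0, 1, 0] = 10.0
        maps = auc_maps(self._series(pyr))
        assert not maps.mask["pyr"][0, 0, 0]
        assert maps.mask["pyr"][0, 1, 0]

    def test_snr_exactly_at_threshold_excluded(self):
        """Strict inequality: AUC SNR == 5.0 does not survive the mask."""
        n = 16
        pyr = np.zeros((n, 1, 1, 2))
        pyr[:, 0, 0, 0] = 5.0 * np.sqrt(n) / n  # AUC = 5*sqrt(n) -> SNR exactly 5
        pyr[:, 0, 0, 1] = 5.0 * np.sqrt(n) / n * 1.01
        maps = auc_maps(self._series(pyr, noise_sd=1.0), snr_threshold=5.0)
        assert maps.snr["pyr"][0, 0, 0] == pytest.approx(5.0)
        assert not maps.mask["pyr"][0, 0, 0]
        assert maps.mask["pyr"][0, 0, 1]

    def test_missing_noise_estimate_is_error(self):
        pyr = np.ones((20, 1, 1, 1))
        s = self._series(pyr)
        s.noise_sd = None
        with pytest.raises(ValueError):
            auc_maps(s)
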