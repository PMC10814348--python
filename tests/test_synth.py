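"""Synthetic generators: phantom geometry, bolus, forward model, multichannel."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import gammainc, gamma as gamma_fn

from hp13c.containers import (
    AcquisitionParams,
    BolusParams,
    KineticParams,
    MetaboliteSeries,
    NoiseModel,
)
from hp13c.synth import (
    default_coil_profiles,
    make_phantom,
    simulate_bolus,
    simulate_two_site,
    synthesize_multichannel,
)


class TestPhantom:
    def test_brain_mask_mirror_symmetric(self):
        ph = make_phantom((16, 16, 8), seed=1)
        assert np.array_equal(ph.brain_mask, ph.brain_mask[:, :, ::-1])

    def test_deterministic_for_fixed_seed(self):
        a, b = make_phantom((8, 16, 16), 7), make_phantom((8, 16, 16), 7)
        for name in ("brain_mask", "nawm_mask", "gm_mask", "t2_lesion_mask", "tumor_mask"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_lesion_reflection_lies_inside_brain(self):
        """Reflecting the left-hemisphere lesion indices across the column
        midplane lands inside the right hemisphere of the brain mask."""
        ph = make_phantom((8, 16, 16), seed=3)
        nc = ph.shape[2]
        idx = np.argwhere(ph.t2_lesion_mask)
        assert len(idx) > 0
        mid = (nc - 1) / 2
        assert np.all(idx[:, 2] < mid)  # lesion lateralized left
        reflected = idx.copy()
        reflected[:, 2] = nc - 1 - idx[:, 2]
        assert np.all(reflected[:, 2] > mid)
        assert ph.brain_mask[tuple(reflected.T)].all()

    def test_masks_nested_and_disjoint(self):
        ph = make_phantom((8, 16, 16), seed=2)
        for name in ("nawm_mask", "gm_mask", "t2_lesion_mask", "tumor_mask"):
            assert not np.any(getattr(ph, name) & ~ph.brain_mask)
        assert not np.any(ph.nawm_mask & ph.t2_lesion_mask)

    @pytest.mark.parametrize("shape", [(4, 16, 16), (8, 16, 7), (16, 16)])
    def test_degenerate_shape_rejected(self, shape):
        with pytest.raises(ValueError):
            make_phantom(shape, seed=0)


class TestBolus:
    def test_zero_amplitude_gives_zero_trace(self):
        t = np.linspace(0, 60, 100)
        assert np.all(simulate_bolus(BolusParams(amplitude=0.0), t) == 0)

    def test_zero_before_arrival_and_nonnegative(self):
        b = BolusParams(arrival_time=5.0)
        t = np.linspace(0, 60, 601)
        u = simulate_bolus(b, t)
        assert np.all(u[t < 5.0] == 0)
        assert np.all(u >= 0)

    def test_peak_at_arrival_plus_alpha_beta(self):
        """Calculus oracle: d/dt x^a exp(-x/b) = 0 at x = a*b."""
        b = BolusParams(arrival_time=4.0, alpha=2.5, beta=3.5)
        t = np.linspace(0, 80, 800001)
        u = simulate_bolus(b, t)
        assert t[np.argmax(u)] == pytest.approx(4.0 + 2.5 * 3.5, abs=1e-3)
        assert u.max() == pytest.approx(b.amplitude, rel=1e-9)

    def test_amplitude_linearity(self):
        t = np.linspace(0, 60, 200)
        u1 = simulate_bolus(BolusParams(amplitude=1.0), t)
        u2 = simulate_bolus(BolusParams(amplitude=2.0), t)
        np.testing.assert_allclose(u2, 2 * u1)

    def test_empty_grid(self):
        assert simulate_bolus(BolusParams(), np.array([])).size == 0

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_bolus(BolusParams(), np.array([3.0, 1.0]))


class TestTwoSite:
    def test_zero_kpl_gives_zero_lactate(self, acq, bolus):
        kp = KineticParams(k_pl=0.0, k_pb=0.003)
        s = simulate_two_site(bolus, kp, acq)
        assert np.all(s.lac == 0)
        assert s.bic.max() > 0

    def test_linear_lactate_growth_limit(self):
        """With T1 -> inf, negligible flips, and constant prescribed
        pyruvate P0, lactate grows as k_PL * P0 * t."""
        eps = 1e-6
        acq = AcquisitionParams(
            n_timepoints=20, temporal_resolution=3.0, acquisition_delay=0.0,
            flip_pyr=eps, flip_lac=eps, flip_bic=eps,
        )
        kp = KineticParams(k_pl=0.015, k_pb=0.0, t1_pyr=1e12, t1_lac=1e12, t1_bic=1e12)
        p0 = 2.0
        pmag = np.full(20, p0)
        s = simulate_two_site(pmag, kp, acq)
        lac_mag = s.lac / np.sin(np.deg2rad(eps))
        expected = 0.015 * p0 * acq.time_axis()
        np.testing.assert_allclose(lac_mag, expected, rtol=1e-6, atol=1e-9)

    def test_matches_matrix_exponential_oracle(self, rng):
        """Homogeneous evolution (initial state, no input) against a
        scipy.linalg.expm propagation with per-frame RF losses; 100
        random parameter draws."""
        for _ in range(100):
            kpl, kpb = rng.uniform(0, 0.05, 2)
            t1 = rng.uniform(5, 60, 3)
            flips = rng.uniform(5, 45, 3)
            dt = rng.uniform(1, 4)
            acq = AcquisitionParams(
                n_timepoints=8, temporal_resolution=dt, acquisition_delay=0.0,
                flip_pyr=flips[0], flip_lac=flips[1], flip_bic=flips[2],
            )
            kp = KineticParams(k_pl=kpl, k_pb=kpb, t1_pyr=t1[0], t1_lac=t1[1], t1_bic=t1[2])
            init = rng.uniform(0.1, 2, 3)
            s = simulate_two_site(BolusParams(amplitude=0.0), kp, acq, initial=tuple(init))

            a_mat = np.array(
                [
                    [-(1 / t1[0] + kpl + kpb), 0, 0],
                    [kpl, -1 / t1[1], 0],
                    [kpb, 0, -1 / t1[2]],
                ]
            )
            prop = expm(a_mat * dt)
            m = init.copy()
            sin_a, cos_a = np.sin(np.deg2rad(flips)), np.cos(np.deg2rad(flips))
            ref = np.zeros((8, 3))
            for i in range(8):
                ref[i] = m * sin_a
                m = prop @ (m * cos_a)
            sim = np.stack([s.pyr, s.lac, s.bic], axis=1)
            np.testing.assert_allclose(sim, ref, rtol=1e-8, atol=1e-14)

    def test_mass_balance_analytic_limit(self):
        """No relaxation, no RF loss: terminal lactate equals
        k_PL/(k_PL+k_PB) of the bolus mass already cleared from the
        pyruvate pool."""
        eps = 1e-6
        acq = AcquisitionParams(
            n_timepoints=1200, temporal_resolution=0.05, acquisition_delay=0.0,
            flip_pyr=eps, flip_lac=eps, flip_bic=eps,
        )
        kp = KineticParams(k_pl=0.015, k_pb=0.003, t1_pyr=1e12, t1_lac=1e12, t1_bic=1e12)
        b = BolusParams(arrival_time=4.0, alpha=2.5, beta=3.5, amplitude=1.0)
        s = simulate_two_site(b, kp, acq, substeps_per_frame=60)
        sin_eps = np.sin(np.deg2rad(eps))
        p_end, l_end, b_end = s.pyr[-1] / sin_eps, s.lac[-1] / sin_eps, s.bic[-1] / sin_eps
        t_end = acq.time_axis()[-1]
        peak = (b.alpha * b.beta) ** b.alpha * np.exp(-b.alpha)
        int_u = (
            b.amplitude / peak * b.beta ** (b.alpha + 1)
            * gamma_fn(b.alpha + 1) * gammainc(b.alpha + 1, (t_end - b.arrival_time) / b.beta)
        )
        kappa = kp.k_pl + kp.k_pb
        assert l_end == pytest.approx(kp.k_pl * (int_u - p_end) / kappa, rel=1e-6)
        assert l_end / b_end == pytest.approx(kp.k_pl / kp.k_pb, rel=1e-9)

    def test_negative_rates_rejected(self, acq, bolus):
        kp = KineticParams()
        kp.k_pl = np.array(-0.01)
        with pytest.raises(ValueError):
            simulate_two_site(bolus, kp, acq)

    def test_volume_rates_broadcast(self, acq, bolus):
        kp = KineticParams()
        kp.k_pl = np.array([[0.01, 0.02]])
        kp.k_pb = np.array([[0.003, 0.003]])
        s = simulate_two_site(bolus, kp, acq)
        assert s.lac.shape == (20, 1, 2)
        assert s.lac[:, 0, 1].max() > s.lac[:, 0, 0].max()


class TestMultichannel:
    def _series(self, acq, noise_free=True):
        kp = KineticParams()
        kp.k_pl = np.full((2, 3, 3), 0.015)
        kp.k_pb = np.full((2, 3, 3), 0.003)
        return simulate_two_site(BolusParams(), kp, acq)

    def test_zero_noise_is_profile_times_signal(self, acq):
        s = self._series(acq)
        profiles = default_coil_profiles(4, (2, 3, 3), seed=0)
        noise = NoiseModel(np.eye(4, dtype=complex), noise_scale=0.0)
        raw = synthesize_multichannel(s, profiles, noise, seed=0)
        expected = np.einsum("czyx,tzyx->ctzyx", profiles, s.pyr)
        np.testing.assert_allclose(raw.data["pyr"][:, : acq.n_timepoints], expected)

    def test_channel_count_mismatch_rejected(self, acq):
        s = self._series(acq)
        profiles = default_coil_profiles(4, (2, 3, 3), seed=0)
        with pytest.raises(ValueError):
            synthesize_multichannel(s, profiles, NoiseModel(np.eye(3, dtype=complex)), 0)

    def test_non_positive_definite_covariance_rejected(self, acq):
        s = self._series(acq)
        profiles = default_coil_profiles(2, (2, 3, 3), seed=0)
        bad = NoiseModel(np.array([[1.0, 1.0], [1.0, 1.0]], dtype=complex))
        with pytest.raises(ValueError):
            synthesize_multichannel(s, profiles, bad, 0)

    def test_empirical_covariance_matches_input(self):
        """Law of large numbers: the sample covariance of the generated
        noise (~2e4 signal-free samples) recovers the requested channel
        covariance within sampling error."""
        acq = AcquisitionParams(n_timepoints=12)
        vol = (6, 10, 10)
        zeros = np.zeros((12,) + vol)
        series = MetaboliteSeries(pyr=zeros, lac=zeros, bic=zeros,
                                  time=acq.time_axis(), acq=acq)
        profiles = np.ones((2,) + vol, dtype=complex)
        cov = np.array([[1.0, 0.4 + 0.2j], [0.4 - 0.2j, 1.5]])
        raw = synthesize_multichannel(series, profiles, NoiseModel(cov, noise_scale=1.0), seed=5)
        x = np.concatenate(
            [raw.data[m][:, f].reshape(2, -1) for m in ("pyr", "lac", "bic") for f in raw.noise_frames],
            axis=1,
        )
        assert x.shape[1] >= 1e4
        est = (x @ x.conj().T) / x.shape[1]
        np.testing.assert_allclose(est, cov, atol=0.05)

    def test_seeds_differ_but_signal_identical(self, acq):
        s = self._series(acq)
        profiles = default_coil_profiles(2, (2, 3, 3), seed=0)
        nm = NoiseModel(np.eye(2, dtype=complex), noise_scale=0.5)
        r1 = synthesize_multichannel(s, profiles, nm, seed=1)
        r2 = synthesize_multichannel(s, profiles, nm, seed=2)
        assert not np.allclose(r1.data["pyr"], r2.data["pyr"])
        # expectation identical: difference is pure zero-mean noise
        diff = (r1.data["pyr"] - r2.data["pyr"]).ravel()
        assert abs(diff.mean()) < 0.02

    def test_noise_frames_designated(self, acq):
        """Pre-arrival frames (before the 4-s bolus) are signal-free and
        flagged for covariance estimation."""
        s = self._series(acq)
        profiles = default_coil_profiles(2, (2, 3, 3), seed=0)
        raw = synthesize_multichannel(s, profiles, NoiseModel(np.eye(2, dtype=complex)), 0)
        assert raw.noise_frames and not raw.appended_noise_frame
        stacked = s.stack()
        for f in raw.noise_frames:
            assert np.all(stacked[:, f] == 0)
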