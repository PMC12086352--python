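"""Time-domain prior-knowledge fitting: phase correction, recovery,
CRLB calibration, and SNR."""
import copy
import math

import numpy as np
import pytest

from xemrsi.config import AcquisitionConfig, HeterogeneityConfig
from xemrsi.fitting import (NoiseEstimate, PeakPrior, PriorKnowledge,
                            estimate_noise, fit_voxel, fit_volume,
                            optimize_prior, phase_correct, snr)
from xemrsi.recon import reconstruct
from xemrsi.sampling import build_spherical_pattern
from xemrsi.synthetic import (Peak, generate_phantom, set_amplitudes_for_snr,
                              simulate_acquisition, simulate_fid)


def three_peak_fid(acq, fio2=0.40, noise_sd=0.0, seed=0, n=None):
    from xemrsi.synthetic import SPECTRAL_DEFAULTS

    p = SPECTRAL_DEFAULTS[fio2]
    peaks = [
        Peak(1.0, p["cs_gas"], p["lw_gas"], flip_deg=0.1,
             t2star_s=p["gas_t2star_ms"] / 1000),
        Peak(0.012, p["cs_mem"], p["lw_mem"], shape="voigt", flip_deg=10.0),
        Peak(0.012 * p["rbc_m"], p["cs_rbc"], p["lw_rbc"], flip_deg=10.0),
    ]
    return simulate_fid(peaks, acq, n_samples=n, noise_sd=noise_sd, seed=seed)


class TestPhaseCorrect:
    def test_already_phased_fid_gives_zero_phase(self, acq):
        fid = three_peak_fid(acq)
        _, phi0, tau = phase_correct(fid, acq)
        assert abs(phi0) < 0.05 and tau == pytest.approx(0.0, abs=1e-7)

    def test_recovers_applied_zero_order_phase(self, acq):
        fid = three_peak_fid(acq)
        _, phi0, _ = phase_correct(fid * np.exp(1j * 0.7), acq)
        assert phi0 == pytest.approx(0.7, abs=0.01)

    def test_recovers_two_sample_delay(self, acq):
        fid = three_peak_fid(acq, n=90)
        delayed = np.concatenate([np.zeros(2, complex), fid[:86]])
        _, _, tau = phase_correct(delayed, acq)
        assert tau == pytest.approx(2 * acq.dwell_s, abs=0.3 * acq.dwell_s)

    def test_correction_invertible(self, acq):
        fid = three_peak_fid(acq) * np.exp(1j * 1.1)
        corrected, phi0, tau = phase_correct(fid, acq)
        n = len(fid)
        freq = np.fft.fftfreq(n, d=acq.dwell_s)
        S = np.fft.fft(corrected * np.exp(1j * phi0), norm="ortho")
        back = np.fft.ifft(S * np.exp(-2j * math.pi * freq * tau), norm="ortho")
        np.testing.assert_allclose(back, fid, atol=1e-12)

    def test_all_zero_fid_degenerate(self, acq):
        c, phi0, tau = phase_correct(np.zeros(88, complex), acq)
        assert phi0 == 0.0 and tau == 0.0 and not np.any(c)


class TestOptimizePrior:
    def test_fixed_point_when_prior_matches_signal(self, acq):
        prior = PriorKnowledge.default(0.40)
        fid = three_peak_fid(acq)
        new = optimize_prior(fid, prior, acq)
        assert new.optimized and new.warning is None
        for k in prior.peaks:
            assert new.peaks[k].cs_init_ppm == pytest.approx(
                prior.peaks[k].cs_init_ppm, abs=1e-3
            )
            assert new.peaks[k].cs_bounds_ppm == prior.peaks[k].cs_bounds_ppm

    def test_shifted_rbc_moves_initial_value(self, acq):
        from xemrsi.synthetic import SPECTRAL_DEFAULTS

        p = SPECTRAL_DEFAULTS[0.40]
        peaks = [
            Peak(1.0, p["cs_gas"], p["lw_gas"], flip_deg=0.1),
            Peak(0.012, p["cs_mem"], p["lw_mem"], shape="voigt", flip_deg=10.0),
            Peak(0.012 * 0.275, p["cs_rbc"] + 1.0, p["lw_rbc"], flip_deg=10.0),
        ]
        fid = simulate_fid(peaks, acq)
        new = optimize_prior(fid, PriorKnowledge.default(0.40), acq)
        assert new.peaks["rbc"].cs_init_ppm == pytest.approx(209.80, abs=0.05)

    def test_pure_noise_flags_warning_and_keeps_prior(self, acq):
        rng = np.random.default_rng(0)
        fid = rng.normal(0, 1, 88) + 1j * rng.normal(0, 1, 88)
        prior = PriorKnowledge.default(0.40)
        new = optimize_prior(fid, prior, acq)
        assert new.warning is not None
        assert new.peaks["rbc"].cs_init_ppm == prior.peaks["rbc"].cs_init_ppm


class TestFitVoxel:
    def test_noiseless_single_lorentzian_recovery(self, acq):
        prior = PriorKnowledge(peaks={
            "rbc": PeakPrior("rbc", "lorentzian", 207.5, (202.0, 212.0),
                             100.0, (5.0, 300.0), amp_init=0.5),
        })
        fid = simulate_fid([Peak(1.0, 206.81, 80.0, flip_deg=90.0, t2star_s=1e9)],
                           acq)
        vf = fit_voxel(fid, prior, acq)
        assert vf.cs_ppm["rbc"] == pytest.approx(206.81, abs=1e-3)
        assert vf.lw_hz["rbc"] == pytest.approx(80.0, abs=0.1)

    @pytest.mark.parametrize("cs_true,lw_true", [(205.0, 30.0), (206.81, 80.0),
                                                 (209.5, 200.0)])
    def test_recovery_across_prior_range(self, acq, cs_true, lw_true):
        """Noiseless recovery over a grid spanning the prior bounds."""
        prior = PriorKnowledge(peaks={
            "rbc": PeakPrior("rbc", "lorentzian", 207.5, (202.0, 212.0),
                             100.0, (5.0, 300.0), amp_init=0.5),
        })
        fid = simulate_fid([Peak(1.0, cs_true, lw_true, flip_deg=90.0,
                                 t2star_s=1e9)], acq)
        vf = fit_voxel(fid, prior, acq)
        assert vf.cs_ppm["rbc"] == pytest.approx(cs_true, abs=1e-3)
        assert vf.lw_hz["rbc"] == pytest.approx(lw_true, abs=0.1)

    def test_noiseless_three_peak_recovery(self, acq):
        fid = three_peak_fid(acq, 0.40)
        vf = fit_voxel(fid, PriorKnowledge.default(0.40), acq)
        assert vf.cs_ppm["rbc"] == pytest.approx(208.80, abs=1e-3)
        assert vf.cs_ppm["mem"] == pytest.approx(196.97, abs=1e-3)
        assert vf.lw_hz["mem"] == pytest.approx(67.0, abs=0.1)

    def test_phase_equivariance(self, acq):
        """A global FID rotation changes only the reported phase."""
        fid = three_peak_fid(acq, 0.40)
        a = fit_voxel(fid, PriorKnowledge.default(0.40), acq)
        b = fit_voxel(fid * np.exp(1j * 0.9), PriorKnowledge.default(0.40), acq)
        for k in a.amp:
            assert b.amp[k] == pytest.approx(a.amp[k], rel=1e-4)
            assert b.cs_ppm[k] == pytest.approx(a.cs_ppm[k], abs=1e-4)
            # the Voigt width split is weakly conditioned, so allow a
            # little optimizer termination noise on the FWHM
            assert b.lw_hz[k] == pytest.approx(a.lw_hz[k], abs=0.05)
        assert (b.phase0 - a.phase0) == pytest.approx(0.9, abs=1e-3)

    def test_pure_noise_voxel_small_amps_large_crlb(self, acq):
        rng = np.random.default_rng(1)
        sd = 1e-3
        fid = rng.normal(0, sd, 88) + 1j * rng.normal(0, sd, 88)
        vf = fit_voxel(fid, PriorKnowledge.default(0.40), acq,
                       noise=NoiseEstimate(sd=sd * math.sqrt(88 / 256)))
        # amplitudes comparable to noise, relative uncertainty enormous
        for k in ("mem", "rbc"):
            assert vf.amp[k] < 20 * sd
            assert vf.crlb[f"{k}_amp"] > 0.1 * max(vf.amp[k], 1e-12)

    def test_residual_never_exceeds_initial(self, acq):
        """Monotone optimizer contract, noisy case."""
        prior = PriorKnowledge.default(0.40)
        fid = three_peak_fid(acq, 0.40, noise_sd=2e-4, seed=3)
        vf = fit_voxel(fid, prior, acq)
        from xemrsi.fitting import _model_and_parts, _stack, _x0_bounds

        x0, _ = _x0_bounds(prior)
        m0, _ = _model_and_parts(x0, acq.time_axis(88), prior, acq)
        r0 = np.linalg.norm(_stack(m0) - _stack(fid))
        assert vf.residual_norm <= r0 + 1e-12

    def test_linewidths_respect_prior_bounds(self, acq):
        prior = PriorKnowledge.default(0.40)
        fid = three_peak_fid(acq, 0.40, noise_sd=5e-4, seed=9)
        vf = fit_voxel(fid, prior, acq)
        assert 1.0 <= vf.lw_hz["gas"] <= 50.0
        for k in ("mem", "rbc"):
            lo, hi = prior.peaks[k].lw_bounds_hz
            assert vf.lw_hz[k] <= 1.7 * hi  # Voigt FWHM of two bounded widths

    def test_monte_carlo_recovery_unbiased(self, acq):
        """Three-peak fits at the 40% cohort parameters and SNR: the mean
        recovered RBC shift over 100 noise seeds is unbiased within 2 SE."""
        raw_rbc = 0.012 * 0.275 * math.sin(math.radians(10)) \
            * math.exp(-acq.te_ms / 1000 * math.pi * 71)
        sigma_spec = raw_rbc / 5.0          # RBC SNR 5 at 40% FiO2
        sigma_t = sigma_spec / math.sqrt(acq.n_spectral / acq.n_spectral_zf)
        prior = PriorKnowledge.default(0.40)
        cs = []
        for s in range(100):
            fid = three_peak_fid(acq, 0.40, noise_sd=sigma_t, seed=s)
            vf = fit_voxel(fid, prior, acq)
            cs.append(vf.cs_ppm["rbc"])
        cs = np.array(cs)
        se = cs.std(ddof=1) / math.sqrt(len(cs))
        assert abs(cs.mean() - 208.80) < 2 * se + 1e-9


class TestCRLB:
    def base_prior(self):
        return PriorKnowledge(peaks={
            "rbc": PeakPrior("rbc", "lorentzian", 206.81, (202.0, 212.0),
                             80.0, (5.0, 300.0), amp_init=1.0),
        })

    def test_crlb_scales_linearly_with_noise(self, acq):
        fid = simulate_fid([Peak(1.0, 206.81, 80.0, flip_deg=90.0,
                                 t2star_s=1e9)], acq)
        vf1 = fit_voxel(fid, self.base_prior(), acq, noise=NoiseEstimate(sd=1e-3))
        vf2 = fit_voxel(fid, self.base_prior(), acq, noise=NoiseEstimate(sd=2e-3))
        for name in vf1.crlb:
            assert vf2.crlb[name] == pytest.approx(2 * vf1.crlb[name], rel=1e-9)
        vf0 = fit_voxel(fid, self.base_prior(), acq, noise=NoiseEstimate(sd=1e-12))
        assert vf0.crlb["rbc_amp"] < 1e-9

    def test_crlb_matches_monte_carlo_sd(self, acq):
        """Single-Lorentzian amplitude CRLB vs Monte-Carlo estimator SD at
        SNR 30 (500 replicates, within 15%)."""
        amp_true = 1.0
        sigma_spec = amp_true / 30.0
        sigma_t = sigma_spec / math.sqrt(acq.n_spectral / acq.n_spectral_zf)
        fid0 = simulate_fid([Peak(amp_true, 206.81, 80.0, flip_deg=90.0,
                                  t2star_s=1e9)], acq)
        vf0 = fit_voxel(fid0, self.base_prior(), acq,
                        noise=NoiseEstimate(sd=sigma_spec))
        rng = np.random.default_rng(42)
        est = {"amp": [], "cs": [], "lwl": []}
        for _ in range(500):
            fid = fid0 + rng.normal(0, sigma_t, 88) + 1j * rng.normal(0, sigma_t, 88)
            vf = fit_voxel(fid, self.base_prior(), acq)
            est["amp"].append(vf.amp["rbc"])
            est["cs"].append(vf.cs_ppm["rbc"])
            est["lwl"].append(vf.lw_hz["rbc"])
        for name, vals in est.items():
            mc_sd = np.std(vals, ddof=1)
            assert vf0.crlb[f"rbc_{name}"] == pytest.approx(mc_sd, rel=0.15)


class TestSNR:
    def test_snr_targets_recovered(self, acq_small, pattern_small):
        """A volume generated at the 100% cohort SNR targets yields
        measured SNRs within 20%."""
        ph = generate_phantom(acq_small.matrix, 1.00, HeterogeneityConfig.none(),
                              seed=0)
        sigma = 5e-4
        targets = {"gas": 36.0, "mem": 28.0, "rbc": 8.0}
        ph = set_amplitudes_for_snr(ph, acq_small, pattern_small, targets, sigma)
        ksp = simulate_acquisition(ph, acq_small, pattern_small, sigma, seed=1)
        img = reconstruct(ksp)
        fits = fit_volume(img, PriorKnowledge.default(1.00), acq_small)
        measured = snr(fits)
        for k, target in targets.items():
            assert measured[k] == pytest.approx(target, rel=0.20)

    def test_noiseless_snr_flagged_infinite(self, noiseless_fits_small):
        _, fits = noiseless_fits_small
        vals = snr(fits, noise=NoiseEstimate(sd=0.0))
        assert all(np.isinf(v) for v in vals.values())

    def test_doubling_amplitudes_doubles_snr(self, noiseless_fits_small):
        _, fits = noiseless_fits_small
        ref = snr(fits, noise=NoiseEstimate(sd=1e-4))
        boosted = copy.deepcopy(fits)
        for k in boosted.amp:
            boosted.amp[k] = boosted.amp[k] * 2
        out = snr(boosted, noise=NoiseEstimate(sd=1e-4))
        for k in ref:
            assert out[k] == pytest.approx(2 * ref[k], rel=1e-9)

    def test_noise_window_overlapping_peak_rejected(self, noiseless_fits_small):
        img, _ = noiseless_fits_small
        with pytest.raises(ValueError, match="overlaps"):
            estimate_noise(img, window_ppm=(150.0, 250.0))
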