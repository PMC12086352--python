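"""Phantom generation, FID/k-space simulation, blood gas, ventilation."""
import math

import numpy as np
import pytest

from xemrsi.config import AcquisitionConfig, HeterogeneityConfig
from xemrsi.sampling import build_spherical_pattern
from xemrsi.synthetic import (BLOOD_GAS_DEFAULTS, LOBE_LABELS, Peak,
                              generate_phantom, phantom_voxel_fids,
                              simulate_acquisition, simulate_blood_gas,
                              simulate_fid, simulate_ventilation,
                              spectral_noise_sd)


class TestGeneratePhantom:
    def test_zero_heterogeneity_gives_printed_means(self, acq):
        ph = generate_phantom((28, 28, 6), 0.40, HeterogeneityConfig.none(), seed=3)
        lung = ph.lung_mask
        assert np.all(ph.maps["cs_rbc"][lung] == pytest.approx(208.80))
        assert np.all(ph.maps["cs_mem"][lung] == pytest.approx(196.97))
        assert np.all(ph.maps["lw_rbc"][lung] == pytest.approx(71.0))

    @pytest.mark.parametrize("fio2,rbc_m", [(0.40, 0.275), (1.00, 0.330)])
    def test_default_amplitude_ratios(self, fio2, rbc_m):
        ph = generate_phantom((16, 16, 6), fio2, HeterogeneityConfig.none(), seed=1)
        lung = ph.lung_mask
        ratio = ph.maps["amp_rbc"][lung] / ph.maps["amp_mem"][lung]
        assert np.allclose(ratio, rbc_m)
        mg = ph.maps["amp_mem"][lung] / ph.maps["amp_gas"][lung]
        assert np.allclose(mg, 0.012)

    def test_invariants(self):
        ph = generate_phantom((16, 16, 6), 1.00, None, seed=9)
        assert np.all(ph.maps["amp_rbc"] >= 0)
        assert np.all(ph.maps["lw_mem"] > 0)
        # lobe labels only inside lung; dissolved amplitude zero outside
        assert np.all((ph.lobe_labels > 0) == ph.lung_mask)
        assert np.all(ph.maps["amp_mem"][~ph.lung_mask] == 0)
        assert np.all(ph.maps["amp_rbc"][~ph.lung_mask] == 0)
        assert set(np.unique(ph.lobe_labels)) == set(range(7))

    def test_seed_reproducibility_bit_for_bit(self):
        a = generate_phantom((16, 16, 6), 0.40, None, seed=5)
        b = generate_phantom((16, 16, 6), 0.40, None, seed=5)
        for k in a.maps:
            np.testing.assert_array_equal(a.maps[k], b.maps[k])
        c = generate_phantom((16, 16, 6), 0.40, None, seed=6)
        assert not np.array_equal(a.maps["cs_rbc"], c.maps["cs_rbc"])

    def test_pao2_coupling_moves_rbc_shift(self):
        lo = generate_phantom((16, 16, 6), 0.40, HeterogeneityConfig.none(),
                              seed=1, pao2=100.0)
        hi = generate_phantom((16, 16, 6), 0.40, HeterogeneityConfig.none(),
                              seed=1, pao2=300.0)
        d = (hi.maps["cs_rbc"][hi.lung_mask].mean()
             - lo.maps["cs_rbc"][lo.lung_mask].mean())
        assert d == pytest.approx(200.0 * (206.81 - 208.80) / (386.13 - 181.74),
                                  rel=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate geometry"):
            generate_phantom((3, 16, 6), 0.40, None, seed=0)

    def test_unknown_lobe_scheme_rejected(self):
        with pytest.raises(ValueError, match="lobe scheme"):
            generate_phantom((16, 16, 6), 0.40, None, seed=0, lobe_scheme="human5")

    def test_unknown_fio2_needs_overrides(self):
        with pytest.raises(KeyError, match="spectral defaults"):
            generate_phantom((16, 16, 6), 0.21, None, seed=0)


class TestSimulateFid:
    def test_single_lorentzian_magnitude_is_exponential(self, acq):
        pk = Peak(2.0, 100.0, 40.0, flip_deg=90.0, t2star_s=1e9)
        fid = simulate_fid([pk], acq)
        t = acq.time_axis()
        np.testing.assert_allclose(np.abs(fid), 2.0 * np.exp(-math.pi * 40.0 * t),
                                   rtol=1e-12)

    def test_two_peak_spectrum_maxima_at_configured_ppm(self, acq):
        peaks = [Peak(1.0, 0.0, 20.0, flip_deg=90.0, t2star_s=1e9),
                 Peak(1.0, 197.0, 20.0, flip_deg=90.0, t2star_s=1e9)]
        fid = simulate_fid(peaks, acq, n_samples=512)
        # brute-force scan of a densely zero-filled spectrum
        spec = np.abs(np.fft.fftshift(np.fft.fft(fid, n=16384)))
        ppm = np.fft.fftshift(np.fft.fftfreq(16384, d=acq.dwell_s)) / acq.f0_mhz
        half = ppm > 100
        assert ppm[~half][np.argmax(spec[~half])] == pytest.approx(0.0, abs=0.05)
        assert ppm[half][np.argmax(spec[half])] == pytest.approx(197.0, abs=0.05)

    def test_flip_angle_amplitude_scaling(self, acq):
        lo = simulate_fid([Peak(1.0, 0.0, 5.0, flip_deg=0.1, t2star_s=1e9)], acq)
        hi = simulate_fid([Peak(1.0, 0.0, 5.0, flip_deg=10.0, t2star_s=1e9)], acq)
        ratio = abs(lo[0]) / abs(hi[0])
        assert ratio == pytest.approx(math.sin(math.radians(0.1))
                                      / math.sin(math.radians(10.0)))
        assert ratio == pytest.approx(1 / 99.5, rel=1e-3)

    def test_negative_noise_rejected(self, acq):
        with pytest.raises(ValueError):
            simulate_fid([Peak(1.0, 0.0, 5.0)], acq, noise_sd=-1.0)


class TestSimulateAcquisition:
    def test_single_voxel_constant_k_magnitude(self, acq_small, pattern_small):
        ph = generate_phantom(acq_small.matrix, 0.40, HeterogeneityConfig.none(),
                              seed=0)
        keep = np.zeros(ph.grid, dtype=bool)
        keep[8, 8, 3] = True
        for c in ("gas", "mem", "rbc"):
            ph.maps[f"amp_{c}"][~keep] = 0.0
        ksp = simulate_acquisition(ph, acq_small, pattern_small, 0.0, seed=0)
        mags = np.abs(ksp.fids)
        assert np.allclose(mags, mags[0], rtol=1e-9)

    def test_uniform_phantom_energy_at_dc(self, acq_small, pattern_small):
        ph = generate_phantom(acq_small.matrix, 0.40, HeterogeneityConfig.none(),
                              seed=0)
        ph.lung_mask[:] = True
        for c in ("gas", "mem", "rbc"):
            ph.maps[f"amp_{c}"][:] = ph.maps[f"amp_{c}"].max()
        ksp = simulate_acquisition(ph, acq_small, pattern_small, 0.0, seed=0)
        e = np.sum(np.abs(ksp.fids) ** 2, axis=1)
        dc = np.argwhere((ksp.locations == 0).all(axis=1))[0, 0]
        off = np.delete(e, dc)
        assert e[dc] > 1e6 * off.mean()

    def test_empty_pattern_rejected(self, acq_small, pattern_small,
                                    uniform_phantom_small):
        empty = type(pattern_small)(pattern_small.locations[:1],
                                    pattern_small.matrix)
        empty.locations = empty.locations[:0]
        with pytest.raises(ValueError, match="empty"):
            simulate_acquisition(uniform_phantom_small, acq_small, empty, 0.0, 0)

    def test_noise_reproducible(self, acq_small, pattern_small,
                                uniform_phantom_small):
        a = simulate_acquisition(uniform_phantom_small, acq_small, pattern_small,
                                 1e-4, seed=11)
        b = simulate_acquisition(uniform_phantom_small, acq_small, pattern_small,
                                 1e-4, seed=11)
        np.testing.assert_array_equal(a.fids, b.fids)

    def test_spectral_noise_prediction(self, acq_small, pattern_small):
        """Analytic noise propagation matches an empirical pure-noise recon."""
        from xemrsi.recon import reconstruct

        ph = generate_phantom(acq_small.matrix, 0.40, HeterogeneityConfig.none(),
                              seed=0)
        for c in ("gas", "mem", "rbc"):
            ph.maps[f"amp_{c}"][:] = 0.0
        sigma = 1e-3
        ksp = simulate_acquisition(ph, acq_small, pattern_small, sigma, seed=2)
        img = reconstruct(ksp)
        pred = spectral_noise_sd(sigma, acq_small, pattern_small)
        assert img.spectra.real.std() == pytest.approx(pred, rel=0.02)


class TestBloodGas:
    def test_cohort_means_match_defaults(self):
        recs = simulate_blood_gas(400, (0.40, 1.00), seed=1)
        for level, expected_mu, expected_sd in ((0.40, 181.74, 11.22),
                                                (1.00, 386.13, 31.65)):
            vals = np.array([r.pao2_mmHg for r in recs if r.fio2 == level])
            se = expected_sd / math.sqrt(len(vals))
            assert abs(vals.mean() - expected_mu) < 3 * se

    def test_empirical_sd_matches_table(self):
        recs = simulate_blood_gas(10000, (0.40,), seed=7)
        vals = np.array([r.pao2_mmHg for r in recs])
        assert vals.std(ddof=1) == pytest.approx(11.22, rel=0.05)

    def test_zero_sd_gives_identical_animals(self):
        ov = {0.40: {k: (mu, 0.0) for k, (mu, sd) in BLOOD_GAS_DEFAULTS[0.40].items()}}
        recs = simulate_blood_gas(5, (0.40,), seed=3, overrides=ov)
        assert len({r.pao2_mmHg for r in recs}) == 1

    def test_unknown_level_needs_overrides(self):
        with pytest.raises(KeyError):
            simulate_blood_gas(2, (0.21,), seed=0)

    def test_so2_in_physiological_range(self):
        recs = simulate_blood_gas(50, (0.40, 1.00), seed=4)
        assert all(0.9 < r.so2 <= 1.0 for r in recs)


class TestVentilation:
    def test_defect_fraction_recovered_by_threshold(self):
        vent, tcv = simulate_ventilation((40, 40, 10), defect_frac=0.08, seed=5)
        vv = (vent >= 0.1 * vent.max()) & tcv
        vdp = 1 - vv.sum() / tcv.sum()
        assert vdp == pytest.approx(0.08, abs=0.015)

    def test_zero_defect(self):
        vent, tcv = simulate_ventilation((30, 30, 8), defect_frac=0.0, seed=5)
        assert ((vent >= 0.1 * vent.max()) & tcv).sum() == tcv.sum()


def test_phantom_voxel_fids_match_single_fid(acq_small, uniform_phantom_small):
    """Vectorized volume synthesis agrees with the scalar FID model."""
    ph = uniform_phantom_small
    vox = phantom_voxel_fids(ph, acq_small)
    i, j, k = np.argwhere(ph.lung_mask)[0]
    peaks = []
    for comp, shape in (("gas", "lorentzian"), ("mem", "voigt"), ("rbc", "lorentzian")):
        peaks.append(Peak(
            amp=ph.maps[f"amp_{comp}"][i, j, k],
            cs_ppm=ph.maps[f"cs_{comp}"][i, j, k],
            lw_hz=ph.maps[f"lw_{comp}"][i, j, k],
            shape=shape,
            flip_deg=ph.flip_deg(comp, acq_small),
            t2star_s=float(ph.t2star_s(comp)[i, j, k]),
        ))
    fid = simulate_fid(peaks, acq_small)
    np.testing.assert_allclose(vox[i, j, k], fid, rtol=1e-10)
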