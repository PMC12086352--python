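# xemrsi

Dissolved-phase hyperpolarized ¹²⁹Xe MR spectroscopic imaging (MRSI) of
the lung, as a fully simulated, tested analysis pipeline.

Inhaled hyperpolarized ¹²⁹Xe dissolves in lung tissue and plasma
("membrane", ~197 ppm downfield of the gas resonance) and in red blood
cells (RBC, ~207–209 ppm at 35.3 MHz). The RBC resonance is sensitive
to hemoglobin oxygenation: in the porcine lung its chemical shift
*decreases* and its linewidth *increases* with arterial oxygen partial
pressure (paO₂). This package implements the full analysis chain that
turns a 3D MRSI acquisition into regional gas-exchange and oxygenation
maps, together with a synthetic-data generator that emulates a
mechanically ventilated porcine cohort at FiO₂ 40% and 100%, so every
stage is testable without scanner data:

1. **Trajectory & reconstruction** — spherical-undersampled 3D
   Cartesian k-space (28×28×6 matrix, 2416 excitations, center-out
   shell ordering), its point-spread function, and zero-filled Fourier
   reconstruction (spectral zero-fill 88→256 samples, spatial ×2).
2. **Spectral fitting** — AMARES-style prior-knowledge time-domain
   least squares per voxel: gas and RBC Lorentzian, membrane Voigt, one
   shared zero-order phase, dead-time (first-order phase) folded into
   the model time axis, Cramér–Rao lower bounds, and SNR against the
   noise floor measured at −150 to −250 ppm.
3. **Quantitative maps** — flip-angle (0.1° gas vs 10° dissolved) and
   exp(TE/T2*) amplitude corrections, masking at 0.6× the mean gas
   amplitude, ratio / shift / linewidth / RBC−membrane difference maps.
4. **Oxygen models** — simple linear calibration
   RBC_cs = −0.01 ppm/mmHg · paO₂ + intercept (inverted for voxelwise
   paO₂ maps), multiple linear regression with a shift×linewidth
   interaction, a logarithmic alternative, the exponential
   shift–saturation model δ(sO₂) = α·exp(β·sO₂) + δ₀, and Hill-type
   oxygen–hemoglobin dissociation curves (human and porcine).
5. **Ventilation & regional statistics** — ventilation defect
   percentage VDP = (1 − VV/TCV)·100, six porcine lobes
   (R1–R4, L1–L2), paired t-tests between oxygen levels, and two-way
   ANOVA (region × oxygen, with interaction) on lobe-level animal means.

## Worked example

Simulate one animal at 100% FiO₂, acquire, reconstruct, fit and map:

```python
import numpy as np
from xemrsi import (AcquisitionConfig, HeterogeneityConfig, PriorKnowledge,
                    build_spherical_pattern, fit_volume, generate_phantom,
                    kspace_noise_for_snr, make_maps, reconstruct,
                    simulate_acquisition)

acq = AcquisitionConfig(spatial_zf=1)          # 28x28x6, 20 kHz, TR 7.4 ms
pattern = build_spherical_pattern(acq.matrix)  # 2416 excitations
phantom = generate_phantom(acq.matrix, fio2=1.00,
                           heterogeneity=HeterogeneityConfig.none(), seed=5)
noise = kspace_noise_for_snr(phantom, acq, pattern, target_snr=8.0)  # RBC SNR 8
ksp = simulate_acquisition(phantom, acq, pattern, noise, seed=7)
img = reconstruct(ksp)
fits = fit_volume(img, PriorKnowledge.default(1.00), acq)
maps = make_maps(fits, acq, t2star_ms={"gas": phantom.gas_t2star_ms})
print(round(np.nanmean(maps.maps["cs_rbc"]), 2),
      round(np.nanmean(maps.maps["cs_diff"]), 2), dict(
      (k, round(v, 1)) for k, v in maps.snr.items()))
```

prints

```
206.8 9.89 {'gas': 21.1, 'mem': 24.3, 'rbc': 8.0}
```

i.e. the masked whole-lung RBC shift (206.8 ppm) and RBC−membrane
difference (9.89 ppm) recover the generator's 100%-FiO₂ cohort values,
and the measured RBC SNR matches the calibrated target of 8.

The numbered scripts under `analysis/` run the larger studies and print
their findings (protocol arithmetic; the full 4-animal × 2-FiO₂
experiment with calibration fits, ANOVA tables and VDP; oxygen-model
comparisons; replicated recovery validation). For example
`analysis/02_run_experiment.py` reports a whole-lung RBC shift of
208.84 ppm at 40% vs 206.83 ppm at 100% FiO₂ (paired p = 0.004), an
RBC:membrane ratio rising from 0.281 to 0.335, and an SLR calibration
slope of −0.0106 ppm/mmHg (R² = 0.99), mirroring the in-vivo cohort
this simulation is parameterized from.

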