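# Methods

This note documents the models, defaults, numerical choices and known
limitations of the `xemrsi` pipeline.

## Acquisition model

The acquisition is a 3D Cartesian MRSI protocol expressed as data
(`AcquisitionConfig`): matrix 28×28×6 over a 40×40×20 cm³ FOV, 88
complex FID samples per excitation at 20 kHz bandwidth, TR 7.4 ms,
reference frequency 35.3 MHz (so 1 ppm = 35.3 Hz), a spectrally
tailored excitation giving 10° on the dissolved resonances and 0.1° on
gas, and 20 initial 30° dummy scans. Derived quantities come from this
one object: spectral resolution 20 000/256 = 78.125 Hz = 2.213 ppm per
bin after zero-filling, scan time = excitations × TR = 17.88 s, dummy
saturation residual cos(30°)²⁰ = 5.63%, nominal reconstructed voxel
7.14 mm in-plane after the ×2 spatial zero-fill.

### Spherical trajectory and the boundary rule

Sampled locations are the centered Cartesian indices
(even axes span [−N/2, N/2−1], DC at 0) whose normalized radius
r = ‖(kᵢ/(Nᵢ/2))‖ lies inside the unit ellipsoid, ordered center-out by
radius with deterministic tie-breaks. The discrete radii form shells;
the default `"shell"` boundary rule keeps every complete shell up to
and including the first shell strictly beyond r = 1, i.e. a
shell-ordered trajectory rounds the nominal boundary outward to a
complete shell rather than truncating mid-shell. On 28×28×6 the
inclusive rule (r ≤ 1) gives 2400 points and the first outer shell
(r² = 1765/1764) adds 16, reproducing the protocol's 2416 excitations
exactly; the `"inclusive"` and `"strict"` rules are available as
alternatives. Both kz conventions (the asymmetric [−3, 2] range is the
default) are supported through the centered-index convention.

### Reconstruction

Gridding places each FID at its k-space index (unsampled points stay
zero — no density compensation or iterative recovery), the grid is
zero-padded in k-space by the spatial zero-fill factor, and an
orthonormal inverse FFT per time point yields voxel FIDs; voxel spectra
follow from spectral zero-filling (88→256) and an orthonormal FFT.
Orthonormal transforms make Parseval checks scale-free; voxel FIDs are
additionally rescaled by √(N_zf/N) so amplitudes do not depend on the
zero-fill factor. With full Cartesian sampling the
simulate→reconstruct chain is the identity to ~1e−15 relative error.

## Signal model and synthetic cohort

Each voxel holds three compartments: gas (≈0.06–0.10 ppm; the gas peak
is referenced to the transmit frequency and need not sit exactly at 0),
membrane (≈196.9 ppm, Voigt) and RBC (207–209 ppm, Lorentzian). The
noiseless FID is

    s(t) = Σₚ Aₚ · sin(flipₚ) · exp(−TE/T2*ₚ) · exp(i φₚ) · exp(2πi fₚ t) · envₚ(t)

with env the exponential decay exp(−π·lw·t) for Lorentzian peaks times
a Gaussian factor exp(−(π·lw_G·t)²/(4 ln 2)) for the Voigt peak. The
Voigt FWHM is reported with the Olivero–Longbothum approximation
0.5346·l + √(0.2166·l² + g²); the generator splits a target membrane
FWHM into equal Lorentzian and Gaussian components. TE defaults to
0.3 ms (half the 0.6 ms excitation pulse). The T2* used in the
exp(−TE/T2*) amplitude factor is the gas-reservoir decay time for gas
(14.10 ms at FiO₂ 0.40, 9.08 ms at 1.00) and 1/(π·lw) for the dissolved
peaks; the gas FID decay *during* the readout follows its fitted
linewidth (5–6 Hz), since the reservoir decay and the spectral
linewidth are distinct processes.

FiO₂-conditional cohort defaults (means): shifts gas 0.06/0.10, mem
196.97/196.91, RBC 208.80/206.81 ppm; linewidths gas 5/6, mem 67/71,
RBC 71/80 Hz; ratios M:Gas 0.012 at both levels, RBC:M 0.275/0.330;
SNR levels gas 33/36, mem 25/28, RBC 5/8. When a per-animal paO₂ is
supplied, the RBC shift and linewidth means move along the two-point
cohort slopes (−0.009736 ppm/mmHg, +0.04403 Hz/mmHg).

Heterogeneity is layered as: (a) between-animal offsets of the
whole-lung means, at the cohort SDs (e.g. RBC shift ±0.17/±0.36 ppm);
membrane and RBC shift offsets are drawn with correlation 0.6 because
the cohort SD of their *difference* (0.19–0.26 ppm) is well below the
value independent draws would give (~0.43 ppm); amplitude-ratio
spreads are ±8.3% (M:Gas) and ±3.6% (RBC:M) relative; (b) additive
lobe offsets over the six porcine lobes (defaults ±0.5 ppm shifts,
±8 Hz linewidths, ±20% amplitudes — the study reports strong regional
effects but no functional form, so these are round numbers of the
observed order); (c) a linear anterior–posterior gradient (gravity-
dependent perfusion is the physiological motivation; the form is a
modeling choice); (d) within-lobe voxel noise with documented,
deliberately arbitrary defaults (±0.05 ppm, ±2 Hz, ±5%), since no
voxel-level variance is reported for any metric. Lung geometry is two
ellipsoids partitioned into R1–R4/L1–L2 by cranio-caudal and medial
cuts.

Noise is complex white Gaussian per k-space sample (SD per component).
With orthonormal transforms, the spectral-domain component SD is
σ_spec = σ_k·√(N_pattern/N_matrix)·√(88/256), verified empirically in
the tests; `kspace_noise_for_snr` inverts this to hit a target
per-peak SNR, RBC SNR 8 being the default calibration anchor (the
cohort's printed per-peak SNRs and amplitude ratios are not exactly
mutually consistent, so one anchor must be chosen; RBC is the limiting
and scientifically central peak). An alternative amplitude mode
rescales the three compartments to hit all three SNR targets at once.

Arterial blood gas records are normal draws around the cohort
means/SDs per oxygen level (paO₂ 181.74 ± 11.22 and
386.13 ± 31.65 mmHg, plus pH, pCO₂, hematocrit, hemoglobin); sO₂
follows from the porcine Hill curve.

## Spectral fitting

Fitting is time-domain bounded nonlinear least squares on the stacked
real/imaginary residuals (`scipy.optimize.least_squares`, trust-region
reflective, analytic Jacobian, single deterministic start) — the
appropriate domain for heavily truncated short-T2* FIDs. Parameters:
per peak amplitude (≥0), shift (±5 ppm box around the prior initial),
Lorentzian width (bounds 1–50 Hz gas, 5–300 Hz dissolved) plus a
Gaussian width for the membrane Voigt peak, and one shared zero-order
phase. The prior's starting amplitudes, shifts and phase are first
refined on the masked mean FID (high SNR); a mean FID with no
detectable signal leaves the prior unchanged with a warning flag.

**Dead-time (first-order phase).** The transmit–receive delay is a
hardware constant, so it is estimated once from the mean FID — by
maximizing the magnitude of the spectrum's continuous-time inverse
transform over a delay grid with local refinement, with a 5% monotone
penalty across the search window to break the near-ties that multi-peak
beat patterns create — and then folded into the model's time axis
(t → t + τ) for every voxel fit. Two designs were measured and
rejected: per-voxel delay estimation (the one-sided search rectifies
noise and biased the recovered RBC shift by ~0.12 ppm at RBC SNR 8),
and correcting the data by fractional-sample FFT interpolation (the
gas component has not decayed by the end of the 88-sample FID, so
circular interpolation rings across the whole record, inflating fitted
widths). The standalone `phase_correct` still returns a corrected FID
for inspection and round-trip tests.

**Uncertainty and SNR.** CRLBs are √diag(F⁻¹) with
F = JᵀJ/σ_t² evaluated at the fitted parameters, σ_t the time-domain
per-component noise SD; they match Monte-Carlo estimator SDs within
15% at SNR 30. The noise SD is measured on the real spectrum in the
−150 to −250 ppm window as the *median* over voxels of the per-voxel
window SD — strong-signal voxels leak truncation ringing into the
window and would inflate a pooled SD by ~20–30%, while the background
majority pins the median to the true floor. SNR is the volume-mean
fitted amplitude over that SD (per-voxel maps available).

## Maps and summaries

Corrected amplitude = raw × exp(TE/T2*) / sin(flip). The analysis mask
keeps voxels with gas amplitude ≥ 0.6 × the mean gas amplitude, the
mean taken over voxels with converged fits (not the full FOV, whose
empty background would drag the mean down). Ratio, shift, linewidth
and RBC−membrane difference maps are NaN outside the mask and wherever
a denominator vanishes; NaN voxels serialize as NaN in NIfTI and are
excluded from every statistic. Whole-lung summary ratios are computed
as ratios of masked-mean corrected amplitudes rather than means of the
voxel-wise ratio maps: Monte-Carlo measurement at the cohort RBC SNR
of 8 shows the voxel-wise nonlinear-LS amplitudes carry a +1–3%
noise-induced bias (amplitude–linewidth coupling) that largely cancels
when amplitudes are pooled before dividing. Summaries are computed per
volume and then averaged across animals, matching the paired n = 4
design; voxel pooling across animals is never used.

## Oxygen models

Calibration fits use animal-level points (whole-lung mean RBC shift or
linewidth joined to that animal's arterial paO₂; 4 animals × 2 levels
= 8 points). SLR is OLS of the spectral parameter on paO₂; paO₂ maps
invert the *unrounded* fitted calibration — the printed rounded
coefficients (an interaction term printed to one significant figure)
are useless numerically and are kept only as rounding-validation
constants in the tests. MLR regresses paO₂ on shift, linewidth and
their product, with t-based two-sided coefficient p-values (df = n−k).
The logarithmic model cs = a·ln(paO₂) + b is OLS in the transformed
predictor; over the hyperoxic study range (≈180–390 mmHg) it deviates
from the linear fit by <0.2 ppm. The exponential saturation model
δ(sO₂) = α·exp(β·sO₂) + δ₀ ships with the human whole-blood defaults
(α = 9.3·10⁻⁴ ppm, β = 8.62, δ₀ = 20.4 ppm, increasing direction) and
a nonlinear fitter for porcine-direction (decreasing) data. The ODC is
a Hill curve sO₂ = paO₂ⁿ/(paO₂ⁿ + P50ⁿ) with literature defaults
(human P50 26.8 mmHg, n 2.7; porcine P50 34.0 mmHg, n 2.8, citations
in code); above 150 mmHg the species curves differ by <0.01.

## Ventilation and regional statistics

VDP = (1 − VV/TCV)·100 with the ventilated volume (10%-of-max
threshold) intersected with the anatomical cavity mask first, so VDP
cannot go negative when ventilation bleeds outside the cavity. Regional
tables hold per-lobe mean/SD/count within the analysis mask; empty
lobes yield flagged rows rather than errors. The paired t-test flags
zero-variance differences explicitly. The two-way ANOVA
(region × oxygen with interaction) uses the closed-form balanced
decomposition — cross-checked against statsmodels OLS — and falls back
to statsmodels partial (type II) sums of squares under imbalance; a
single observation per cell raises (interaction untestable), and a
zero-residual (noiseless) design is flagged degenerate. No multiplicity
correction is applied, matching the study design. Observations are
lobe-level animal means.

## Problem sizes and validation

The replicated recovery study (`xemrsi.validation.rbc_recovery_study`,
also the basis of `scripts/acceptance.py`) simulates one animal per
replicate: spatially homogeneous lungs with between-animal spread at
the 100%-FiO₂ defaults, 28×28×6 acquisition on the 2416-point
trajectory at RBC SNR 8, reconstruction without spatial zero-fill
(display interpolation adds no information, only 8× more voxel fits),
~780 voxel fits per replicate, 100 replicates. The mean masked RBC
shift recovers the generator value to ~0.01 ppm; per-replicate
whole-lung values scatter with the between-animal SD (±0.36 ppm), so
the replicate set behaves like a large simulated cohort.

## Known limitations

- Voxel-wise nonlinear amplitude estimates at RBC SNR ≤ 8 are biased
  at the few-percent level (measured; see Maps); linewidths share the
  coupling. This is a property of the estimator at the study's SNR,
  not removable by bounds, and motivates the pooled-ratio summary.
- The PSF of the spherically truncated trajectory blurs mask edges;
  edge voxels carry reduced amplitude (~2–3% on the masked mean), which
  cancels in ratios but not in absolute amplitudes.
- No B0 inhomogeneity, eddy currents, motion, cardiac signal, flow, or
  RF-pulse profile effects; flip angles are config constants.
- The generator's regional structure (additive lobe offsets + linear
  gradient) is a deliberately simple stand-in for real regional
  physiology; passing regional tests demonstrates correctness of the
  statistics, not realism of porcine lungs.
- Perfusion maps are accepted as external inputs to the regional
  module only; no DCE quantification is performed.
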