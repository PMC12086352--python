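"""Synthetic ground truth: lung phantoms, FIDs, k-space, and blood gas.

The generator emulates a mechanically ventilated pig imaged at two
inspired-oxygen levels.  Three spectral compartments are modelled per
voxel — gas near 0 ppm, membrane (lung tissue / plasma) near 197 ppm and
RBC near 207-209 ppm at 35.3 MHz — with FiO2-conditional default means
for amplitude ratios, chemical shifts and linewidths, lobe-wise regional
offsets, a gravity-dependent anterior-posterior gradient, and arterial
blood-gas records drawn around the cohort means.

All randomness flows through one seeded numpy Generator per call.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import AcquisitionConfig, HeterogeneityConfig
from .lineshape import gauss_decay, lorentz_decay, t2star_from_lw, voigt_equal_split
from .oxygen import PORCINE_ODC, odc
from .recon import KSpaceMRSI

__all__ = [
    "SPECTRAL_DEFAULTS",
    "BLOOD_GAS_DEFAULTS",
    "LOBE_LABELS",
    "CS_SLOPE_PPM_PER_MMHG",
    "LW_SLOPE_HZ_PER_MMHG",
    "Peak",
    "PhantomTruth",
    "BloodGasRecord",
    "generate_phantom",
    "simulate_fid",
    "phantom_voxel_fids",
    "simulate_acquisition",
    "simulate_blood_gas",
    "simulate_ventilation",
    "kspace_noise_for_snr",
    "set_amplitudes_for_snr",
    "spectral_noise_sd",
]

# FiO2-conditional cohort means: chemical shifts (ppm, gas-referenced),
# linewidths (FWHM Hz), amplitude ratios, gas-reservoir decay time, and
# the cohort SNR levels observed at each oxygen level.
SPECTRAL_DEFAULTS: dict[float, dict] = {
    0.40: dict(
        cs_gas=0.06, cs_mem=196.97, cs_rbc=208.80,
        lw_gas=5.0, lw_mem=67.0, lw_rbc=71.0,
        m_gas=0.012, rbc_m=0.275,
        gas_t2star_ms=14.10,
        snr=dict(gas=33.0, mem=25.0, rbc=5.0),
    ),
    1.00: dict(
        cs_gas=0.10, cs_mem=196.91, cs_rbc=206.81,
        lw_gas=6.0, lw_mem=71.0, lw_rbc=80.0,
        m_gas=0.012, rbc_m=0.330,
        gas_t2star_ms=9.08,
        snr=dict(gas=36.0, mem=28.0, rbc=8.0),
    ),
}

PAO2_LEVEL_MEANS = {0.40: 181.74, 1.00: 386.13}

# Two-point slopes implied by the cohort means at the two oxygen levels;
# used to couple per-animal paO2 draws to the RBC spectral parameters.
CS_SLOPE_PPM_PER_MMHG = (206.81 - 208.80) / (386.13 - 181.74)
LW_SLOPE_HZ_PER_MMHG = (80.0 - 71.0) / (386.13 - 181.74)

# Arterial blood gas cohort means +- SD at each oxygen level.
BLOOD_GAS_DEFAULTS: dict[float, dict] = {
    0.40: dict(pao2_mmHg=(181.74, 11.22), pco2_mmHg=(44.03, 1.58),
               ph=(7.49, 0.01), hct=(0.3013, 0.0345), hb_mmol_l=(6.10, 0.70)),
    1.00: dict(pao2_mmHg=(386.13, 31.65), pco2_mmHg=(42.90, 3.15),
               ph=(7.49, 0.02), hct=(0.2930, 0.0301), hb_mmol_l=(5.93, 0.63)),
}

LOBE_LABELS = {1: "R1", 2: "R2", 3: "R3", 4: "R4", 5: "L1", 6: "L2"}
_COMPARTMENTS = ("gas", "mem", "rbc")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class Peak:
    """One spectral component of a voxel FID.

    ``amp`` is the underlying magnetization amplitude (a.u.); the raw
    signal amplitude is amp * sin(flip) * exp(-TE/T2*).  ``lw_hz`` is the
    FWHM of the full line shape; for Voigt peaks it is split into equal
    Lorentzian and Gaussian components unless ``lw_gauss_hz`` is given.
    """

    amp: float
    cs_ppm: float
    lw_hz: float
    shape: str = "lorentzian"
    phase: float = 0.0
    flip_deg: float | None = None
    t2star_s: float | None = None
    lw_gauss_hz: float | None = None

    def components(self) -> tuple[float, float]:
        """(Lorentzian FWHM, Gaussian FWHM) in Hz."""
        if self.shape == "lorentzian":
            return self.lw_hz, 0.0
        if self.shape != "voigt":
            raise ValueError(f"unknown line shape {self.shape!r}")
        if self.lw_gauss_hz is not None:
            return self.lw_hz, self.lw_gauss_hz
        w = float(voigt_equal_split(self.lw_hz))
        return w, w


@dataclass
class BloodGasRecord:
    animal: str
    fio2: float
    pao2_mmHg: float
    pco2_mmHg: float
    ph: float
    so2: float
    hct: float
    hb_mmol_l: float

    def __post_init__(self) -> None:
        if self.pao2_mmHg <= 0:
            raise ValueError("paO2 must be positive")
        if not 0 <= self.so2 <= 1.1:
            raise ValueError("sO2 outside [0, 1.1]")


@dataclass
class PhantomTruth:
    """Voxel-wise ground truth for one animal at one oxygen level.

    ``maps`` holds per-voxel parameter volumes: amp_{gas,mem,rbc} (a.u.
    magnetization), cs_* (ppm), lw_* (FWHM Hz), phase (rad).  Membrane is
    Voigt (equal-split convention), gas and RBC Lorentzian.
    """

    grid: tuple[int, int, int]
    fio2: float
    maps: dict = field(default_factory=dict)
    lung_mask: np.ndarray | None = None
    lobe_labels: np.ndarray | None = None
    label_map: dict = field(default_factory=lambda: dict(LOBE_LABELS))
    pao2_mmHg: float | None = None
    so2: float | None = None
    gas_t2star_ms: float = 14.10
    animal: str = "sim"
    meta: dict = field(default_factory=dict)

    def t2star_s(self, comp: str) -> np.ndarray:
        """Amplitude-correction T2* per voxel (s): the gas reservoir decay
        time for gas, 1/(pi*lw) for the dissolved compartments."""
        if comp == "gas":
            return np.full(self.grid, self.gas_t2star_ms / 1000.0)
        return t2star_from_lw(np.maximum(self.maps[f"lw_{comp}"], 1e-6))

    def flip_deg(self, comp: str, acq: AcquisitionConfig) -> float:
        return acq.flip_gas_deg if comp == "gas" else acq.flip_dissolved_deg

    def raw_amp(self, comp: str, acq: AcquisitionConfig) -> np.ndarray:
        """Expected fitted (raw) amplitude: amp * sin(flip) * exp(-TE/T2*)."""
        flip = math.radians(self.flip_deg(comp, acq))
        te = acq.te_ms / 1000.0
        return self.maps[f"amp_{comp}"] * math.sin(flip) * np.exp(-te / self.t2star_s(comp))

    def truth_maps(self) -> dict:
        """Quantitative truth maps on the phantom grid (NaN outside lung)."""
        m = self.maps
        with np.errstate(divide="ignore", invalid="ignore"):
            out = {
                "m_gas": m["amp_mem"] / m["amp_gas"],
                "rbc_gas": m["amp_rbc"] / m["amp_gas"],
                "rbc_m": m["amp_rbc"] / m["amp_mem"],
                "cs_gas": m["cs_gas"], "cs_mem": m["cs_mem"], "cs_rbc": m["cs_rbc"],
                "lw_gas": m["lw_gas"], "lw_mem": m["lw_mem"], "lw_rbc": m["lw_rbc"],
                "cs_diff": m["cs_rbc"] - m["cs_mem"],
            }
        for k, v in out.items():
            v = np.array(v, dtype=float)
            v[~self.lung_mask] = np.nan
            out[k] = v
        return out


def _lung_geometry(grid: tuple[int, int, int]):
    """Two ellipsoidal lungs and a six-lobe porcine partition.

    Axes: x = right-left, y = cranial-caudal, z = anterior-posterior.
    """
    nx, ny, nz = grid
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    semi = (0.17 * nx, 0.32 * ny, 0.36 * nz)
    masks = {}
    for side, cx in (("R", (nx - 1) / 2.0 - 0.22 * nx), ("L", (nx - 1) / 2.0 + 0.22 * nx)):
        r2 = (((x - cx) / semi[0]) ** 2 + ((y - cy) / semi[1]) ** 2
              + ((z - cz) / semi[2]) ** 2)
        masks[side] = r2 <= 1.0
    lung = masks["R"] | masks["L"]

    labels = np.zeros(grid, dtype=np.int16)
    yr = (y - (cy - semi[1])) / (2 * semi[1])  # 0 cranial -> 1 caudal
    right, left = masks["R"], masks["L"]
    labels[right & (yr < 0.33)] = 1                                  # R1
    labels[right & (yr >= 0.33) & (yr < 0.60)] = 2                    # R2
    medial = x >= ((nx - 1) / 2.0 - 0.22 * nx)
    labels[right & (yr >= 0.60) & ~medial] = 3                        # R3
    labels[right & (yr >= 0.60) & medial] = 4                         # R4 accessory
    labels[left & (yr < 0.45)] = 5                                    # L1
    labels[left & (yr >= 0.45)] = 6                                   # L2
    return lung, labels


_METRIC_TO_MAP = {
    "gas_cs_ppm": ("cs_gas", "add"), "mem_cs_ppm": ("cs_mem", "add"),
    "rbc_cs_ppm": ("cs_rbc", "add"), "gas_lw_hz": ("lw_gas", "add"),
    "mem_lw_hz": ("lw_mem", "add"), "rbc_lw_hz": ("lw_rbc", "add"),
    "gas_amp_rel": ("amp_gas", "mul"), "mem_amp_rel": ("amp_mem", "mul"),
    "rbc_amp_rel": ("amp_rbc", "mul"),
}


def generate_phantom(
    grid: tuple[int, int, int] = (28, 28, 6),
    fio2: float = 0.40,
    heterogeneity: HeterogeneityConfig | None = None,
    seed: int | np.random.Generator = 0,
    pao2: float | None = None,
    lobe_scheme: str = "porcine6",
    spectral_overrides: dict | None = None,
    animal: str = "sim",
) -> PhantomTruth:
    """Generate a voxel-wise ground-truth phantom.

    Compartment parameters are drawn around the FiO2-conditional cohort
    means with between-animal offsets (``animal_sd``), additive lobe
    offsets, a linear anterior-posterior gradient, and within-lobe voxel
    noise, all from ``heterogeneity``.  If ``pao2`` is given, the RBC
    shift and linewidth means are moved along the cohort two-point slopes
    so that the spectral truth is coupled to the blood gas.
    """
    grid = tuple(int(g) for g in grid)
    if any(g < 4 for g in grid):
        raise ValueError("degenerate geometry: every grid dimension must be >= 4")
    if lobe_scheme != "porcine6":
        raise ValueError(f"unknown lobe scheme {lobe_scheme!r}")
    level = round(float(fio2), 2)
    if spectral_overrides is None and level not in SPECTRAL_DEFAULTS:
        raise KeyError(
            f"no spectral defaults for FiO2={fio2}; pass spectral_overrides"
        )
    par = dict(SPECTRAL_DEFAULTS.get(level, {}))
    if spectral_overrides:
        par.update(spectral_overrides)
    het = HeterogeneityConfig.default() if heterogeneity is None else heterogeneity
    rng = _rng(seed)

    lung, labels = _lung_geometry(grid)

    so2 = None
    if pao2 is not None:
        dp = pao2 - PAO2_LEVEL_MEANS.get(level, pao2)
        par = dict(par)
        par["cs_rbc"] = par["cs_rbc"] + CS_SLOPE_PPM_PER_MMHG * dp
        par["lw_rbc"] = par["lw_rbc"] + LW_SLOPE_HZ_PER_MMHG * dp
        so2 = float(odc(pao2, PORCINE_ODC))

    # between-animal offsets on the whole-lung means; membrane and RBC
    # shifts are drawn with correlation cs_animal_corr so the spread of
    # their difference matches the cohort statistics
    animal_off = {
        metric: rng.normal(0.0, sd) if sd > 0 else 0.0
        for metric, sd in het.animal_sd.items()
    }
    rho = getattr(het, "cs_animal_corr", 0.0)
    sd_m = het.animal_sd.get("mem_cs_ppm", 0.0)
    sd_r = het.animal_sd.get("rbc_cs_ppm", 0.0)
    if rho and sd_m > 0 and sd_r > 0:
        z = rng.normal(0.0, 1.0, 3)
        animal_off["mem_cs_ppm"] = sd_m * (
            math.sqrt(rho) * z[0] + math.sqrt(1 - rho) * z[1]
        )
        animal_off["rbc_cs_ppm"] = sd_r * (
            math.sqrt(rho) * z[0] + math.sqrt(1 - rho) * z[2]
        )
    # relative perturbations of the amplitude ratios themselves
    par = dict(par)
    par["m_gas"] = par["m_gas"] * max(
        1.0 + animal_off.pop("m_gas_ratio_rel", 0.0), 0.0
    )
    par["rbc_m"] = par["rbc_m"] * max(
        1.0 + animal_off.pop("rbc_m_ratio_rel", 0.0), 0.0
    )

    amp_gas = 1.0
    amp_mem = par["m_gas"] * amp_gas
    amp_rbc = par["rbc_m"] * amp_mem
    base = {
        "amp_gas": amp_gas, "amp_mem": amp_mem, "amp_rbc": amp_rbc,
        "cs_gas": par["cs_gas"], "cs_mem": par["cs_mem"], "cs_rbc": par["cs_rbc"],
        "lw_gas": par["lw_gas"], "lw_mem": par["lw_mem"], "lw_rbc": par["lw_rbc"],
    }

    nz = grid[2]
    zc = (np.arange(nz) - (nz - 1) / 2.0) / max(nz - 1, 1)  # -0.5 .. 0.5, A -> P
    zvol = np.broadcast_to(zc[None, None, :], grid)

    maps: dict[str, np.ndarray] = {}
    for metric, (map_name, kind) in _METRIC_TO_MAP.items():
        field_ = np.zeros(grid)
        field_ += animal_off.get(metric, 0.0)
        for lab, name in LOBE_LABELS.items():
            off = het.lobe_offsets.get(metric, {}).get(name, 0.0)
            if off:
                field_[labels == lab] += off
        grad = het.ap_gradient.get(metric, 0.0)
        if grad:
            field_ = field_ + grad * zvol
        sd = het.voxel_sd.get(metric, 0.0)
        if sd > 0:
            field_ = field_ + rng.normal(0.0, sd, size=grid)
        if kind == "add":
            vol = base[map_name] + field_
        else:
            vol = base[map_name] * np.maximum(1.0 + field_, 0.0)
        maps[map_name] = vol

    for comp in _COMPARTMENTS:
        maps[f"amp_{comp}"] = np.clip(maps[f"amp_{comp}"], 0.0, None)
        maps[f"lw_{comp}"] = np.clip(maps[f"lw_{comp}"], 0.5, None)
        maps[f"amp_{comp}"][~lung] = 0.0
    maps["phase"] = np.zeros(grid)

    return PhantomTruth(
        grid=grid, fio2=float(fio2), maps=maps, lung_mask=lung,
        lobe_labels=labels, pao2_mmHg=pao2, so2=so2,
        gas_t2star_ms=par.get("gas_t2star_ms", 14.10), animal=animal,
        meta={"level_defaults": {k: v for k, v in par.items() if k != "snr"}},
    )


def simulate_fid(
    peaks: list[Peak],
    acq: AcquisitionConfig,
    n_samples: int | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one complex FID as a sum of decaying complex exponentials.

    Each peak contributes amp*sin(flip)*exp(-TE/T2*)*exp(i*phase)
    * exp(2*pi*i*f*t) * decay(t), with f = cs_ppm * f0 and decay the
    Lorentzian exponential (times a Gaussian factor for Voigt peaks).
    Complex white noise with per-component SD ``noise_sd`` is added.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = acq.n_spectral if n_samples is None else int(n_samples)
    if n < 1:
        raise ValueError("n_samples must be >= 1")
    t = acq.time_axis(n)
    fid = np.zeros(n, dtype=complex)
    te = acq.te_ms / 1000.0
    for pk in peaks:
        fl, fg = pk.components()
        flip = pk.flip_deg if pk.flip_deg is not None else acq.flip_dissolved_deg
        t2 = pk.t2star_s if pk.t2star_s is not None else float(t2star_from_lw(pk.lw_hz))
        a = pk.amp * math.sin(math.radians(flip)) * math.exp(-te / t2)
        osc = np.exp(1j * (pk.phase + 2 * math.pi * pk.cs_ppm * acq.hz_per_ppm * t))
        env = lorentz_decay(t, fl)
        if fg > 0:
            env = env * gauss_decay(t, fg)
        fid += a * osc * env
    if noise_sd > 0:
        rng = _rng(seed)
        fid = fid + rng.normal(0, noise_sd, n) + 1j * rng.normal(0, noise_sd, n)
    return fid


def phantom_voxel_fids(phantom: PhantomTruth, acq: AcquisitionConfig) -> np.ndarray:
    """Noiseless per-voxel FIDs (nx, ny, nz, n_spectral) for a phantom."""
    t = acq.time_axis()
    te = acq.te_ms / 1000.0
    grid = phantom.grid
    out = np.zeros(grid + (len(t),), dtype=complex)
    mask = phantom.lung_mask
    idx = np.nonzero(mask)
    for comp in _COMPARTMENTS:
        amp = phantom.raw_amp(comp, acq)[idx]
        cs = phantom.maps[f"cs_{comp}"][idx]
        lw = phantom.maps[f"lw_{comp}"][idx]
        phase = phantom.maps["phase"][idx]
        f_hz = cs * acq.hz_per_ppm
        osc = np.exp(1j * (phase[:, None] + 2 * math.pi * f_hz[:, None] * t[None, :]))
        if comp == "mem":
            w = voigt_equal_split(lw)
            env = lorentz_decay(t, w) * gauss_decay(t, w)
        else:
            env = lorentz_decay(t, lw)
        out[idx] += amp[:, None] * osc * env
    return out


def simulate_acquisition(
    phantom: PhantomTruth,
    acq: AcquisitionConfig,
    pattern,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> KSpaceMRSI:
    """Sample the phantom's k-space on a trajectory, adding complex noise.

    Each stored FID is the orthonormal 3D DFT of the noiseless voxel FID
    array evaluated at the sampled location, plus independent complex
    white noise of per-component SD ``noise_sd``.
    """
    if len(pattern) == 0:
        raise ValueError("empty sampling pattern")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if tuple(pattern.matrix) != tuple(phantom.grid):
        raise ValueError("pattern matrix does not match the phantom grid")
    vox = phantom_voxel_fids(phantom, acq)
    ksp = np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(vox, axes=(0, 1, 2)), axes=(0, 1, 2), norm="ortho"),
        axes=(0, 1, 2),
    )
    centers = np.array([m // 2 for m in phantom.grid])
    ix, iy, iz = (pattern.locations + centers).T
    fids = ksp[ix, iy, iz]
    if noise_sd > 0:
        rng = _rng(seed)
        fids = fids + rng.normal(0, noise_sd, fids.shape) + 1j * rng.normal(
            0, noise_sd, fids.shape
        )
    return KSpaceMRSI(locations=pattern.locations.copy(), fids=fids, acq=acq)


def spectral_noise_sd(kspace_noise_sd: float, acq: AcquisitionConfig, pattern) -> float:
    """Per-component noise SD in the reconstructed voxel spectra implied by
    k-space noise of per-component SD ``kspace_noise_sd``.

    With the orthonormal convention and the zero-fill amplitude rescale,
    voxel-FID noise SD is sigma_k * sqrt(N_pattern / N_matrix); spectral
    zero-filling from n to n_zf samples scales it by sqrt(n / n_zf).
    """
    n_grid = int(np.prod(acq.matrix))
    return (
        kspace_noise_sd
        * math.sqrt(len(pattern) / n_grid)
        * math.sqrt(acq.n_spectral / acq.n_spectral_zf)
    )


def kspace_noise_for_snr(
    phantom: PhantomTruth,
    acq: AcquisitionConfig,
    pattern,
    target_snr: float,
    peak: str = "rbc",
) -> float:
    """k-space noise SD that yields the target per-peak SNR, defined as the
    lung-mean raw fitted amplitude over the spectral noise SD."""
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    a = float(np.mean(phantom.raw_amp(peak, acq)[phantom.lung_mask]))
    sigma_spec = a / target_snr
    n_grid = int(np.prod(acq.matrix))
    return sigma_spec / (
        math.sqrt(len(pattern) / n_grid) * math.sqrt(acq.n_spectral / acq.n_spectral_zf)
    )


def set_amplitudes_for_snr(
    phantom: PhantomTruth,
    acq: AcquisitionConfig,
    pattern,
    snr_targets: dict,
    kspace_noise_sd: float,
) -> PhantomTruth:
    """Rescale each compartment's amplitude map so the expected per-peak
    SNRs equal ``snr_targets`` at the given k-space noise level.

    The observed cohort SNRs and amplitude ratios are not exactly mutually
    consistent; this mode privileges the SNR targets.
    """
    sigma_spec = spectral_noise_sd(kspace_noise_sd, acq, pattern)
    for comp, target in snr_targets.items():
        cur = float(np.mean(phantom.raw_amp(comp, acq)[phantom.lung_mask]))
        if cur <= 0:
            raise ValueError(f"compartment {comp} has zero amplitude in the lung")
        phantom.maps[f"amp_{comp}"] = phantom.maps[f"amp_{comp}"] * (
            target * sigma_spec / cur
        )
    return phantom


def simulate_blood_gas(
    n_animals: int,
    fio2_levels=(0.40, 1.00),
    seed: int | np.random.Generator = 0,
    overrides: dict | None = None,
) -> list[BloodGasRecord]:
    """Draw per-animal arterial blood-gas records at each oxygen level.

    Values are normal draws around the cohort means/SDs; sO2 is derived
    from the drawn paO2 through the porcine Hill ODC.  ``overrides`` maps
    FiO2 level -> {field: (mean, sd)} and is required for levels without
    built-in defaults.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = _rng(seed)
    records = []
    for level in fio2_levels:
        key = round(float(level), 2)
        params = dict(BLOOD_GAS_DEFAULTS.get(key, {}))
        if overrides and key in overrides:
            params.update(overrides[key])
        if not params:
            raise KeyError(f"no blood-gas defaults for FiO2={level}; pass overrides")
        for i in range(n_animals):
            draw = {
                name: float(rng.normal(mu, sd)) if sd > 0 else float(mu)
                for name, (mu, sd) in params.items()
            }
            draw["pao2_mmHg"] = max(draw["pao2_mmHg"], 1.0)
            records.append(
                BloodGasRecord(
                    animal=f"pig{i + 1}",
                    fio2=float(level),
                    so2=float(odc(draw["pao2_mmHg"], PORCINE_ODC)),
                    **draw,
                )
            )
    return records


def simulate_ventilation(
    grid: tuple[int, int, int] = (56, 56, 12),
    defect_frac: float = 0.069,
    seed: int | np.random.Generator = 0,
    smooth_vox: float = 1.5,
):
    """Synthetic ventilation volume and anatomical lung-cavity mask.

    Ventilated intensity is a smooth positive field inside the anatomical
    mask; a spatially coherent ``defect_frac`` of the cavity is set near
    zero so that a 10%-of-max threshold recovers it as defect.
    Returns ``(ventilation volume, tcv mask)``.
    """
    if not 0 <= defect_frac < 1:
        raise ValueError("defect_frac must be in [0, 1)")
    rng = _rng(seed)
    lung, _ = _lung_geometry(grid)
    vent = np.zeros(grid)
    texture = ndimage.gaussian_filter(rng.normal(0, 1, grid), smooth_vox)
    vent[lung] = 1.0 + 0.15 * texture[lung]
    vent = np.clip(vent, 0.0, None)
    if defect_frac > 0:
        fieldv = ndimage.gaussian_filter(rng.normal(0, 1, grid), smooth_vox)
        vals = fieldv[lung]
        cut = np.quantile(vals, defect_frac)
        defect = lung & (fieldv <= cut)
        vent[defect] *= 0.02
    return vent, lung
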