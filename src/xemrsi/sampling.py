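"""Spherical-undersampled Cartesian k-space trajectory and its PSF.

The trajectory samples the Cartesian grid points inside an ellipsoid
inscribed in the acquisition matrix, ordered center-out by normalized
radius.  Even-sized axes use the centered index range [-N/2, N/2-1] with
DC at index 0; the normalized radius of index k on an axis of size N is
k/(N/2), so the nominal boundary is |r| = 1 (+-0.5 periods/voxel).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig

__all__ = [
    "SamplingPattern",
    "build_spherical_pattern",
    "dummy_scan_residual",
    "spectral_axis",
    "point_spread_function",
    "scan_duration_s",
]

BOUNDARY_RULES = ("shell", "inclusive", "strict")


@dataclass
class SamplingPattern:
    """Ordered list of centered 3D k-space indices.

    ``locations`` is an (N, 3) int array; ordering is center-out by
    normalized radius with ties broken lexicographically by
    (|kz|, |ky|, |kx|) then by sign.
    """

    locations: np.ndarray
    matrix: tuple[int, int, int]
    ordering: str = "center-out"
    boundary_rule: str = "shell"

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=int)
        if self.locations.ndim != 2 or self.locations.shape[1] != 3:
            raise ValueError("locations must be (N, 3)")
        lo = np.array([-(m // 2) for m in self.matrix])
        hi = np.array([(m - 1) // 2 for m in self.matrix])
        if np.any(self.locations < lo) or np.any(self.locations > hi):
            raise ValueError("locations outside the matrix bounds")
        if len(np.unique(self.locations, axis=0)) != len(self.locations):
            raise ValueError("duplicate k-space locations")

    def __len__(self) -> int:
        return len(self.locations)

    def normalized_radius(self) -> np.ndarray:
        semi = np.array([m / 2.0 for m in self.matrix])
        return np.sqrt(np.sum((self.locations / semi) ** 2, axis=1))


def _centered_grid(matrix: tuple[int, int, int]):
    axes = [np.arange(-(m // 2), (m + 1) // 2) for m in matrix]
    return np.meshgrid(*axes, indexing="ij")


def build_spherical_pattern(
    matrix: tuple[int, int, int] = (28, 28, 6),
    boundary_rule: str = "shell",
) -> SamplingPattern:
    """Build the center-out spherical (ellipsoidal) Cartesian pattern.

    Boundary rules, with r the normalized radius:

    - ``"strict"``:    r < 1
    - ``"inclusive"``: r <= 1
    - ``"shell"`` (default): all complete discrete-radius shells up to and
      including the first shell strictly beyond r = 1.  The discrete shell
      structure never places a shell exactly on the continuous boundary in
      general, so a shell-ordered center-out trajectory rounds the
      boundary outward to the nearest complete shell; on the default
      28x28x6 matrix this rule yields exactly 2416 excitations.
    """
    if any(m <= 0 for m in matrix):
        raise ValueError("matrix dimensions must be positive")
    if boundary_rule not in BOUNDARY_RULES:
        raise ValueError(f"unknown boundary rule {boundary_rule!r}")

    KX, KY, KZ = _centered_grid(matrix)
    semi = [m / 2.0 for m in matrix]
    r2 = (KX / semi[0]) ** 2 + (KY / semi[1]) ** 2 + (KZ / semi[2]) ** 2
    r2 = np.round(r2, 12)  # collapse float fuzz so shells are exact ties

    if boundary_rule == "strict":
        keep = r2 < 1.0
    elif boundary_rule == "inclusive":
        keep = r2 <= 1.0
    else:  # shell
        shells = np.unique(r2)
        outer = shells[shells > 1.0]
        cutoff = outer[0] if outer.size else shells[-1]
        keep = r2 <= cutoff

    kx, ky, kz = KX[keep], KY[keep], KZ[keep]
    rad = r2[keep]
    order = np.lexsort(
        (
            np.sign(kx), np.sign(ky), np.sign(kz),
            np.abs(kx), np.abs(ky), np.abs(kz),
            rad,
        )
    )
    locs = np.stack([kx, ky, kz], axis=1)[order]
    return SamplingPattern(locs, tuple(matrix), boundary_rule=boundary_rule)


def dummy_scan_residual(n_dummies: int, flip_deg: float) -> float:
    """Longitudinal magnetization fraction surviving ``n_dummies`` ideal
    excitations of ``flip_deg`` degrees: cos(flip)^n."""
    if n_dummies < 0:
        raise ValueError("n_dummies must be >= 0")
    return math.cos(math.radians(flip_deg)) ** n_dummies


def spectral_axis(acq: AcquisitionConfig) -> np.ndarray:
    """Chemical-shift axis (ppm) of the zero-filled spectrum.

    Per-bin spacing is bandwidth / n_spectral_zf in Hz, divided by the
    reference frequency in MHz for ppm; the axis is centered on 0 ppm
    (the nominal transmit frequency) and increasing.
    """
    freq_hz = np.fft.fftshift(np.fft.fftfreq(acq.n_spectral_zf, d=acq.dwell_s))
    return freq_hz / acq.hz_per_ppm


def point_spread_function(
    pattern: SamplingPattern,
    matrix: tuple[int, int, int] | None = None,
    oversample: int = 1,
) -> np.ndarray:
    """Magnitude PSF of a binary sampling mask, peak-normalized to 1.

    The PSF is the inverse DFT of the sampling mask, evaluated on a grid
    ``oversample`` times finer than the matrix (by zero-padding k-space).
    """
    matrix = tuple(matrix or pattern.matrix)
    if len(pattern) == 0:
        raise ValueError("empty sampling pattern")
    shape = tuple(m * oversample for m in matrix)
    mask = np.zeros(shape)
    idx = tuple(
        pattern.locations[:, i] + shape[i] // 2 for i in range(3)
    )  # centered -> array indices on the padded grid
    mask[idx] = 1.0
    psf = np.abs(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(mask), norm="ortho")))
    return psf / psf.max()


def scan_duration_s(pattern: SamplingPattern, acq: AcquisitionConfig, *, round_to_s: bool = True) -> float:
    """Total acquisition time: pattern size x TR (dummy scans excluded)."""
    t = len(pattern) * acq.tr_ms / 1000.0
    return float(round(t)) if round_to_s else t
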