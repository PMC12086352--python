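"""Cartesian MRSI reconstruction with spatial and spectral zero-filling.

Sampled FIDs are gridded onto the centered Cartesian matrix (unsampled
locations stay zero), the grid is zero-padded in k-space by the spatial
zero-fill factor, and an orthonormal inverse 3D FFT per time point gives
voxel FIDs.  Each voxel FID is then zero-filled to the spectral target
length and Fourier transformed to a spectrum with a calibrated ppm axis.

The orthonormal convention makes Parseval checks scale-free; voxel FIDs
are additionally rescaled by sqrt(N_zf / N) so that voxel amplitudes are
independent of the zero-fill factor and directly comparable to the
per-voxel amplitudes that generated the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig
from .sampling import spectral_axis

__all__ = ["KSpaceMRSI", "SpectralImage", "reconstruct", "voxel_spectra"]


@dataclass
class KSpaceMRSI:
    """Sampled k-space: one FID per sampled Cartesian location.

    ``locations`` are centered integer indices (DC at 0, even axes span
    [-N/2, N/2-1]); ``fids`` is (N, n_samples) complex.
    """

    locations: np.ndarray
    fids: np.ndarray
    acq: AcquisitionConfig

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=int)
        self.fids = np.asarray(self.fids, dtype=complex)
        if self.fids.ndim != 2 or len(self.fids) != len(self.locations):
            raise ValueError("fids must be (N, n_samples) matching locations")


@dataclass
class SpectralImage:
    """Reconstructed spatial-spectral image.

    ``spectra`` is complex (x, y, z, n_spectral_zf); ``voxel_fids`` keeps
    the un-zero-filled time-domain data (x, y, z, n_spectral) for
    time-domain fitting.
    """

    spectra: np.ndarray
    voxel_fids: np.ndarray
    ppm: np.ndarray
    acq: AcquisitionConfig
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.spectra.shape[:3]


def _grid_kspace(ksp: KSpaceMRSI) -> np.ndarray:
    acq = ksp.acq
    nx, ny, nz = acq.matrix
    lo = np.array([-(m // 2) for m in acq.matrix])
    hi = np.array([(m - 1) // 2 for m in acq.matrix])
    if np.any(ksp.locations < lo) or np.any(ksp.locations > hi):
        raise ValueError("k-space location outside the acquisition matrix")
    if len(np.unique(ksp.locations, axis=0)) != len(ksp.locations):
        raise ValueError("duplicate k-space locations")
    grid = np.zeros((nx, ny, nz, ksp.fids.shape[1]), dtype=complex)
    ix, iy, iz = (ksp.locations + np.array([nx // 2, ny // 2, nz // 2])).T
    grid[ix, iy, iz] = ksp.fids
    return grid


def reconstruct(ksp: KSpaceMRSI, acq: AcquisitionConfig | None = None) -> SpectralImage:
    """Zero-filled Cartesian reconstruction of sampled MRSI k-space."""
    acq = acq or ksp.acq
    if ksp.fids.shape[1] != acq.n_spectral:
        raise ValueError("FID length does not match acquired spectral samples")
    grid = _grid_kspace(ksp)
    nx, ny, nz = acq.matrix
    zx, zy, zz = acq.zf_matrix

    big = np.zeros((zx, zy, zz, grid.shape[3]), dtype=complex)
    big[
        zx // 2 - nx // 2 : zx // 2 + (nx + 1) // 2,
        zy // 2 - ny // 2 : zy // 2 + (ny + 1) // 2,
        zz // 2 - nz // 2 : zz // 2 + (nz + 1) // 2,
    ] = grid

    img = np.fft.ifftn(
        np.fft.ifftshift(big, axes=(0, 1, 2)), axes=(0, 1, 2), norm="ortho"
    )
    img = np.fft.fftshift(img, axes=(0, 1, 2))
    # keep voxel amplitudes independent of the spatial zero-fill factor
    img *= np.sqrt((zx * zy * zz) / (nx * ny * nz))

    spectra = voxel_spectra(img, acq)
    return SpectralImage(
        spectra=spectra,
        voxel_fids=img,
        ppm=spectral_axis(acq),
        acq=acq,
        meta={"n_sampled": len(ksp.locations)},
    )


def voxel_spectra(voxel_fids: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    """Spectra of voxel FIDs: zero-fill to the spectral target, orthonormal
    FFT, fftshift so the axis matches :func:`xemrsi.sampling.spectral_axis`."""
    pad = acq.n_spectral_zf - voxel_fids.shape[-1]
    if pad < 0:
        raise ValueError("FID longer than the spectral zero-fill target")
    fids = np.pad(voxel_fids, [(0, 0)] * (voxel_fids.ndim - 1) + [(0, pad)])
    return np.fft.fftshift(np.fft.fft(fids, axis=-1, norm="ortho"), axes=-1)
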