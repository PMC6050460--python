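"""Gaussian point-spread-function model and separable convolution engine.

Scanner resolution is described by a per-axis Gaussian FWHM in millimetres
(:class:`PSFModel`).  The discrete realisation is a separable per-axis kernel
(:class:`Kernel`) built for a specific voxel size: each axis tap vector is a
Gaussian sampled at integer voxel offsets, truncated at +/-4 sigma (minimum
half-width one voxel) and renormalised to sum to one, so smoothed binary
masks stay in [0, 1].  ``fwhm = 0`` on an axis denotes the identity (delta)
PSF for that axis.

Convolution uses zero-padding outside the grid — the physical statement that
there is no activity outside the field of view.  All partial-volume divisions
downstream happen inside tissue where the padding influence is bounded by the
smoothed-mask thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import Image3D

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PSFModel:
    """Per-axis Gaussian FWHM in mm; (0, 0, 0) is the delta PSF."""

    fwhm_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.fwhm_mm) != 3:
            raise ValueError("fwhm_mm must have three components")
        if any(f < 0 for f in self.fwhm_mm):
            raise ValueError("FWHM must be nonnegative")

    @classmethod
    def isotropic(cls, fwhm_mm: float) -> "PSFModel":
        return cls(fwhm_mm=(fwhm_mm, fwhm_mm, fwhm_mm))

    @property
    def is_delta(self) -> bool:
        return all(f == 0 for f in self.fwhm_mm)


def sigma_from_fwhm(fwhm_mm: float) -> float:
    """sigma = FWHM / (2 sqrt(2 ln 2))."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    return fwhm_mm / FWHM_PER_SIGMA


@dataclass(frozen=True)
class Kernel:
    """Separable per-axis 1-D tap vectors in voxel units.

    Each axis vector is symmetric, nonnegative, odd-length and sums to one
    (within 1e-12).
    """

    taps: tuple[np.ndarray, np.ndarray, np.ndarray]
    truncation_sigmas: float

    def __post_init__(self) -> None:
        for t in self.taps:
            if t.ndim != 1 or t.size % 2 != 1:
                raise ValueError("axis taps must be odd-length 1-D vectors")
            if np.any(t < 0):
                raise ValueError("negative kernel weight")
            if abs(t.sum() - 1.0) > 1e-12:
                raise ValueError("axis taps must sum to 1")
            if not np.allclose(t, t[::-1], rtol=0, atol=1e-15):
                raise ValueError("axis taps must be symmetric")

    @property
    def is_delta(self) -> bool:
        return all(t.size == 1 for t in self.taps)


def make_kernel(
    psf: PSFModel,
    voxel_size_mm: tuple[float, float, float],
    truncation_sigmas: float = 4.0,
) -> Kernel:
    """Discrete separable Gaussian for a given grid.

    Per axis: sigma_vox = sigma_mm / voxel_size; taps are the Gaussian
    density at integer offsets out to ``truncation_sigmas`` * sigma_vox
    (at least one voxel), renormalised after truncation.  A zero-FWHM axis
    yields the single tap [1].
    """
    if any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel sizes must be positive")
    taps = []
    for fwhm, vsize in zip(psf.fwhm_mm, voxel_size_mm):
        if fwhm == 0:
            taps.append(np.ones(1))
            continue
        sigma_vox = sigma_from_fwhm(fwhm) / vsize
        half = max(1, int(np.ceil(truncation_sigmas * sigma_vox)))
        x = np.arange(-half, half + 1, dtype=np.float64)
        w = np.exp(-0.5 * (x / sigma_vox) ** 2)
        taps.append(w / w.sum())
    return Kernel(taps=tuple(taps), truncation_sigmas=truncation_sigmas)


def convolve_array(data: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Separable zero-padded convolution of a 3-D array."""
    if data.ndim != 3:
        raise ValueError("expected a 3-D array")
    out = np.asarray(data, dtype=np.float64)
    if kernel.is_delta:
        return out.copy()
    for axis, taps in enumerate(kernel.taps):
        if taps.size == 1:
            out = out * taps[0]
        else:
            out = ndimage.convolve1d(out, taps, axis=axis, mode="constant", cval=0.0)
    return out


def convolve(img: Image3D, kernel: Kernel) -> Image3D:
    """Convolve an image; the delta kernel returns a bitwise-equal copy."""
    return img.with_data(convolve_array(img.data, kernel))


def smooth_mask(mask: Image3D, psf: PSFModel) -> np.ndarray:
    """PSF-smoothed binary mask as a float array in [0, 1]."""
    kernel = make_kernel(psf, mask.voxel_size_mm)
    return convolve_array(mask.data.astype(np.float64), kernel)
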