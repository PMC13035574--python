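"""Spectral preprocessing: median smoothing, SNV normalization, cropping.

The pipeline order is fixed: median filter along the spectral axis, then
per-pixel standard-normal-variate (SNV) normalization, then cropping to
the 520-1000 nm working range that excludes the noisy short-wavelength
bands.  SNV removes multiplicative scatter differences between pixels;
it is applied before the crop (see PreprocessConfig), with the order
exposed in the config for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _nd_median

from .hsi_io import HyperCube

__all__ = [
    "PreprocessConfig",
    "median_filter_spectrum",
    "snv_normalize",
    "crop_wavelengths",
    "preprocess_cube",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Spectral preprocessing parameters.

    median_kernel : odd window length of the spectral median filter
    snv_epsilon   : SD floor below which a spectrum is mapped to zero
    crop_lo, crop_hi : closed wavelength interval retained, in nm
    snv_before_crop : apply SNV to the full spectrum before cropping
        (the default) or to the cropped spectrum
    """

    median_kernel: int = 5
    snv_epsilon: float = 1e-8
    crop_lo: float = 520.0
    crop_hi: float = 1000.0
    snv_before_crop: bool = True

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 1")
        if self.snv_epsilon <= 0:
            raise ValueError("snv_epsilon must be > 0")
        if not self.crop_lo < self.crop_hi:
            raise ValueError("crop_lo must be < crop_hi")


def median_filter_spectrum(spectrum: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Median-smooth one spectrum (or an array of spectra along the last
    axis) with reflect padding at the ends."""
    if kernel % 2 == 0:
        raise ValueError("median kernel must be odd")
    x = np.asarray(spectrum, dtype=np.float64)
    if kernel == 1:
        return x.copy()
    if kernel > x.shape[-1]:
        raise ValueError("median kernel longer than the spectrum")
    size = (1,) * (x.ndim - 1) + (kernel,)
    return _nd_median(x, size=size, mode="reflect")


def snv_normalize(spectrum: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Standard normal variate: center and scale each spectrum to zero mean
    and unit sample SD (ddof=1).  Spectra with SD below ``epsilon`` (for
    example fully shadowed pixels) map to all-zero rather than raising.

    Works on a single spectrum or any array whose last axis is spectral.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs spectra of length >= 2")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    degenerate = sd < epsilon
    safe_sd = np.where(degenerate, 1.0, sd)
    out = (x - mean) / safe_sd
    if degenerate.any():
        out = np.where(degenerate, 0.0, out)
    return out


def crop_wavelengths(cube: HyperCube, lo: float = 520.0, hi: float = 1000.0) -> HyperCube:
    """Keep exactly the bands with lo <= lambda <= hi (closed interval)."""
    sel = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    return HyperCube(cube.reflectance[:, :, sel], cube.wavelengths[sel], cube.patient_id)


def preprocess_cube(cube: HyperCube, config: PreprocessConfig | None = None) -> HyperCube:
    """Full spectral pipeline: median filter, SNV, crop (order fixed by
    ``config.snv_before_crop``; default SNV first).

    The returned cube holds signed SNV scores, so it relaxes the
    non-negativity invariant of raw reflectance cubes.
    """
    config = config or PreprocessConfig()
    data = median_filter_spectrum(cube.reflectance, config.median_kernel)
    wl = cube.wavelengths
    if config.snv_before_crop:
        data = snv_normalize(data, config.snv_epsilon)
        sel = (wl >= config.crop_lo) & (wl <= config.crop_hi)
        if not sel.any():
            raise ValueError(f"no bands inside [{config.crop_lo}, {config.crop_hi}] nm")
        data, wl = data[:, :, sel], wl[sel]
    else:
        sel = (wl >= config.crop_lo) & (wl <= config.crop_hi)
        if not sel.any():
            raise ValueError(f"no bands inside [{config.crop_lo}, {config.crop_hi}] nm")
        data, wl = data[:, :, sel], wl[sel]
        data = snv_normalize(data, config.snv_epsilon)
    return _SNVCube(data, wl, cube.patient_id)


class _SNVCube(HyperCube):
    """HyperCube variant holding signed SNV scores (skips the >= 0 check)."""

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.wavelengths.size != self.reflectance.shape[2]:
            raise ValueError("wavelength/band mismatch")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite values after preprocessing")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
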