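"""Spectral-residual (SR) fixation-prediction saliency.

The SR map of a single-channel image I is built entirely in the Fourier
domain: with F the 2-D DFT,

    A(f) = |F(I)|            amplitude spectrum
    P(f) = phase(F(I))       phase spectrum
    L(f) = log(A(f) + eps)   log amplitude
    R(f) = L(f) - h_n * L(f) spectral residual (h_n a small mean filter)
    SR(x) = |F^-1(exp(R + jP))|^2

Flat, predictable spectral structure is removed by the local average, so
the back-transform highlights the "unexpected" part of the image - small
high-contrast blobs such as a stained cell on a bright smear background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from .imaging import minmax01

#: Added inside the log so that zero amplitudes (flat images) stay finite.
LOG_EPS = 1e-8


@dataclass(frozen=True)
class SRComponents:
    """Intermediate spectra of the spectral-residual computation."""

    amplitude: np.ndarray      # A(f) >= 0
    phase: np.ndarray          # P(f), radians
    log_amplitude: np.ndarray  # L(f)
    residual: np.ndarray       # R(f)
    raw_map: np.ndarray        # |F^-1(exp(R + jP))|^2, unsmoothed


def _validate_gray(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D field, got shape {gray.shape}")
    if gray.shape[0] < 8 or gray.shape[1] < 8:
        raise ValueError(f"field too small: {gray.shape} (minimum 8x8)")
    if not np.isfinite(gray).all():
        raise ValueError("field contains non-finite values")
    return gray


def sr_components(gray: np.ndarray, avg_kernel_side: int = 3) -> SRComponents:
    """Compute all intermediate spectra and the raw (unsmoothed) SR map."""
    gray = _validate_gray(gray)
    if avg_kernel_side < 1:
        raise ValueError("avg_kernel_side must be >= 1")
    spectrum = np.fft.fft2(gray)
    amplitude = np.abs(spectrum)
    phase = np.angle(spectrum)
    log_amplitude = np.log(amplitude + LOG_EPS)
    # h_n: mean filter over the log-amplitude spectrum, edge-replicated.
    local_avg = uniform_filter(log_amplitude, size=avg_kernel_side, mode="nearest")
    residual = log_amplitude - local_avg
    back = np.fft.ifft2(np.exp(residual + 1j * phase))
    raw_map = np.abs(back) ** 2
    return SRComponents(amplitude, phase, log_amplitude, residual, raw_map)


def spectral_residual(
    gray: np.ndarray,
    avg_kernel_side: int = 3,
    smooth_sigma: float = 2.5,
    normalize: bool = True,
) -> np.ndarray:
    """Spectral-residual saliency map of a single-channel image.

    Parameters
    ----------
    gray:
        2-D field, at least 8x8, finite values (typically luminance in [0,1]).
    avg_kernel_side:
        Side of the square mean filter applied to the log-amplitude spectrum.
    smooth_sigma:
        Sigma (pixels) of an optional Gaussian smoothing of the back-projected
        map; 0 disables it.  Smoothing stabilises the top-n pixel selection
        downstream.
    normalize:
        Min-max normalize the result to [0, 1] (a constant map becomes zeros).

    Returns
    -------
    The saliency map, same shape as ``gray``.

    Notes
    -----
    A constant input has no spectral structure and returns an all-zero map
    directly.  (Pushing it through the formula would turn every
    zero-amplitude frequency into residual 0, i.e. amplitude 1 after the
    exponential, fabricating a phantom blob at the origin.)
    """
    gray = _validate_gray(gray)
    if gray.max() - gray.min() <= 0.0:
        return np.zeros_like(gray)
    out = sr_components(gray, avg_kernel_side).raw_map
    if smooth_sigma > 0:
        out = gaussian_filter(out, sigma=smooth_sigma, mode="nearest")
    if normalize:
        out, _ = minmax01(out)
    return out
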