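"""Centred discrete Fourier transforms.

All k-space indexing in the package places DC at index ``n // 2`` on every
axis.  The helpers below wrap ``numpy.fft`` with the fftshift bookkeeping so
that image-space and k-space arrays share that convention, and the forward /
inverse pair is unitary up to the usual 1/N factor of ``numpy.fft``.
"""

from __future__ import annotations

import numpy as np


def cfft(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centred forward FFT along one axis (DC at ``n // 2``)."""
    return np.fft.fftshift(np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis), axes=axis)


def icfft(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Centred inverse FFT along one axis."""
    return np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis), axes=axis)


def cfft2(x: np.ndarray, axes=(-2, -1)) -> np.ndarray:
    """Centred 2D forward FFT."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)


def icfft2(x: np.ndarray, axes=(-2, -1)) -> np.ndarray:
    """Centred 2D inverse FFT."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes)


def cdft_matrix(n: int) -> np.ndarray:
    """Dense centred DFT matrix (rows = k indices, DC at ``n // 2``).

    Used by tests as an O(N^2) oracle for the FFT-based path; kept in the
    package so the oracle and the implementation agree on conventions.
    """
    k = np.arange(n) - n // 2
    x = np.arange(n) - n // 2
    return np.exp(-2j * np.pi * np.outer(k, x) / n)
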