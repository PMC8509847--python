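"""Stationary (undecimated) discrete wavelet decomposition into frequency bands.

BOLD region time courses are split into four detail bands plus a coarse
approximation with a 4-level stationary DWT (``db4``). The undecimated
transform keeps every band series at the input length and is translation
invariant, so band-limited connectivity can be computed sample-for-sample
on the original sampling grid.

Implementation: each detail band is reconstructed through its zero-phase
analysis+synthesis transfer function

    B_j(w) = |G(2^{j-1} w)|^2 / 2 * prod_{l<j} |H(2^{l-1} w)|^2 / 2

where (H, G) are the DFTs of the orthonormal scaling/wavelet filter pair.
Because |H(w)|^2 + |G(w)|^2 = 2 for orthonormal wavelets, the band transfer
functions and the approximation sum to one exactly, giving perfect
reconstruction, and circular (periodic) convolution makes the transform
exactly shift equivariant. The result is numerically identical to running
``pywt.swt`` and inverting each level separately, but works for any input
length.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pywt

MIN_VOLUMES = 32  # minimum series length for a stable 4-level db4 transform

__all__ = [
    "BandSet",
    "band_frequency_ranges",
    "band_transfer_functions",
    "swt_band_reconstructions",
    "sdwt_decompose",
    "MIN_VOLUMES",
]


@dataclass
class BandSet:
    """Per-band detail reconstructions of a regions x volumes matrix.

    ``bands[j]`` holds the level-(j+1) detail series (finest first); each has
    the same shape as the input. ``band_ranges`` maps levels to nominal
    frequency intervals in Hz, finest band first.
    """

    bands: list[np.ndarray]
    approximation: np.ndarray
    band_ranges: list[tuple[float, float]]
    tr: float
    wavelet: str = "db4"
    levels: int = 4
    mode: str = "periodic"
    region_labels: list[str] | None = None
    subject_id: str | None = None
    session: str | None = None

    def reconstruct(self) -> np.ndarray:
        """Sum of all detail bands plus the approximation."""
        return sum(self.bands) + self.approximation

    def band(self, band_index: int) -> np.ndarray:
        """Detail series for 1-based ``band_index`` (1 = finest, highest band)."""
        if not 1 <= band_index <= self.levels:
            raise ValueError(f"band_index must be in 1..{self.levels}, got {band_index}")
        return self.bands[band_index - 1]


def band_frequency_ranges(tr: float, levels: int = 4) -> list[tuple[float, float]]:
    """Nominal (low, high) Hz range of each wavelet detail level.

    Level j of a dyadic wavelet decomposition of a signal sampled every
    ``tr`` seconds covers (fN / 2^j, fN / 2^(j-1)) with fN = 1 / (2 tr).
    For tr = 2 s and 4 levels this gives 0.125-0.25, 0.0625-0.125,
    0.03125-0.0625 and 0.015625-0.03125 Hz.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    nyquist = 1.0 / (2.0 * tr)
    return [(nyquist / 2 ** j, nyquist / 2 ** (j - 1)) for j in range(1, levels + 1)]


@functools.lru_cache(maxsize=64)
def band_transfer_functions(
    n_samples: int, levels: int = 4, wavelet: str = "db4"
) -> tuple[tuple[np.ndarray, ...], np.ndarray]:
    """Real non-negative rfft-grid transfer functions (details, approximation).

    The detail functions plus the approximation sum to one on every
    frequency bin (exactly, up to float roundoff).
    """
    wav = pywt.Wavelet(wavelet)
    h = np.asarray(wav.dec_lo, dtype=float)
    g = np.asarray(wav.dec_hi, dtype=float)
    freqs = np.arange(n_samples // 2 + 1)
    taps = np.arange(len(h))
    details = []
    carry = np.ones(n_samples // 2 + 1)
    for j in range(1, levels + 1):
        upsample = 2 ** (j - 1)
        phase = np.exp(-2j * np.pi * np.outer(freqs, upsample * taps) / n_samples)
        low = phase @ h
        high = phase @ g
        details.append((np.abs(high) ** 2 / 2.0) * carry)
        carry = carry * (np.abs(low) ** 2 / 2.0)
    return tuple(d for d in details), carry


def swt_band_reconstructions(
    data: np.ndarray,
    levels: int = 4,
    wavelet: str = "db4",
    mode: str = "periodic",
) -> tuple[list[np.ndarray], np.ndarray]:
    """Detail reconstructions (finest first) and approximation of each row.

    ``mode`` selects the boundary treatment: ``periodic`` (circular, exact
    shift equivariance) or ``symmetric`` (whole-signal mirror extension,
    then periodic on the doubled signal; still perfectly reconstructing).
    """
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    n = arr.shape[-1]
    if n < MIN_VOLUMES:
        raise ValueError(
            f"series has {n} samples; at least {MIN_VOLUMES} are required "
            f"for a {levels}-level {wavelet} stationary transform"
        )
    if mode == "symmetric":
        ext = np.concatenate([arr, arr[..., ::-1]], axis=-1)
        det_ext, approx_ext = swt_band_reconstructions(ext, levels, wavelet, "periodic")
        return [d[..., :n] for d in det_ext], approx_ext[..., :n]
    if mode != "periodic":
        raise ValueError(f"unknown boundary mode {mode!r}")
    det_tf, approx_tf = band_transfer_functions(n, levels, wavelet)
    spectrum = np.fft.rfft(arr, axis=-1)
    details = [np.fft.irfft(spectrum * tf, n, axis=-1) for tf in det_tf]
    approx = np.fft.irfft(spectrum * approx_tf, n, axis=-1)
    if np.asarray(data).ndim == 1:
        return [d[0] for d in details], approx[0]
    return details, approx


def sdwt_decompose(ts, levels: int = 4, wavelet: str = "db4", mode: str = "periodic") -> BandSet:
    """Decompose a :class:`~fbandnet.prep.RoiTimeseries` into wavelet bands."""
    details, approx = swt_band_reconstructions(ts.data, levels, wavelet, mode)
    return BandSet(
        bands=list(details),
        approximation=approx,
        band_ranges=band_frequency_ranges(ts.tr, levels),
        tr=ts.tr,
        wavelet=wavelet,
        levels=levels,
        mode=mode,
        region_labels=list(ts.region_labels),
        subject_id=ts.subject_id,
        session=ts.session,
    )
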