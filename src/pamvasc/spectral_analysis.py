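"""Pixel-wise power spectra and the image-level spectral mean frequency.

The power spectrum of a photoacoustic A-line encodes the effective absorber
size: larger absorbers emit longer, lower-frequency pulses, so their
power-weighted mean frequency (spectral centroid) is lower.  This module
computes a per-pixel power spectral map with noise-robust spatial averaging
and reduces it to a single mean frequency per image.

Robustness rule: A-lines whose envelope maximum falls below a configurable
quantile of the image's envelope maxima (and any all-zero A-line) are treated
as background and excluded both from the sliding-window average and from the
image-level spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal.windows import hann

from .rf_preprocessing import RFVolume, ValidationError, hilbert_envelope

__all__ = [
    "SpectralMap",
    "MeanFrequencyResult",
    "power_spectral_map",
    "mean_frequency",
    "mean_frequency_of_volume",
]

DEFAULT_WINDOW_PX = 5
DEFAULT_NOISE_FLOOR_QUANTILE = 0.5


@dataclass(frozen=True)
class SpectralMap:
    """Per-pixel power spectra: ``power[bin, lateral, frame]``.

    ``included`` flags the pixels that passed the signal gate; excluded pixels
    carry zero power and do not contribute to :func:`mean_frequency`.
    """

    power: np.ndarray
    freq_axis_hz: np.ndarray
    included: np.ndarray

    def __post_init__(self) -> None:
        if self.power.ndim != 3:
            raise ValidationError("power must be 3D (bins, lateral, frame)")
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ValidationError("power must be finite and nonnegative")
        if np.any(np.diff(self.freq_axis_hz) <= 0):
            raise ValidationError("freq_axis_hz must be strictly increasing")


@dataclass(frozen=True)
class MeanFrequencyResult:
    mean_freq_hz: float
    n_pixels_used: int


def power_spectral_map(
    vol: RFVolume,
    window_px: int = DEFAULT_WINDOW_PX,
    noise_floor_quantile: float = DEFAULT_NOISE_FLOOR_QUANTILE,
) -> SpectralMap:
    """Sliding-window-averaged Hann periodogram per A-line.

    Each included A-line's one-sided periodogram (Hann window) is averaged
    over a ``window_px`` x ``window_px`` spatial neighborhood of *included*
    A-lines; excluded A-lines neither contribute to nor receive an average.

    Raises
    ------
    ValidationError
        If ``window_px`` is even, exceeds the lateral grid, or no A-line
        passes the signal gate ("no signal pixels").
    """
    n_t, n_lat, n_frm = vol.samples.shape
    if window_px < 1 or window_px % 2 == 0:
        raise ValidationError("window_px must be an odd positive integer")
    if window_px > n_lat or window_px > n_frm:
        raise ValidationError(
            f"window_px {window_px} larger than image ({n_lat}x{n_frm})"
        )
    if not 0.0 <= noise_floor_quantile < 1.0:
        raise ValidationError("noise_floor_quantile must be in [0, 1)")

    env_max = hilbert_envelope(vol).max(axis=0)  # (lateral, frame)
    gate = np.quantile(env_max, noise_floor_quantile)
    included = (env_max >= gate) & (env_max > 0)
    if not included.any():
        raise ValidationError("no signal pixels")

    win = hann(n_t, sym=False)
    spectra = np.abs(np.fft.rfft(vol.samples * win[:, None, None], axis=0)) ** 2
    spectra[:, ~included] = 0.0

    if window_px == 1:
        power = spectra
    else:
        # masked box average: sum(P * inc) / sum(inc) over the window
        size = (1, window_px, window_px)
        num = ndimage.uniform_filter(spectra, size=size, mode="constant")
        den = ndimage.uniform_filter(
            included.astype(np.float64)[None, :, :], size=size, mode="constant"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            power = np.where(den > 0, num / den, 0.0)
        power[:, ~included] = 0.0

    freq_axis = np.fft.rfftfreq(n_t, d=1.0 / vol.sampling_rate_hz)
    return SpectralMap(power=power, freq_axis_hz=freq_axis, included=included)


def mean_frequency(smap: SpectralMap) -> MeanFrequencyResult:
    """Average the included pixels' spectra, then take the power centroid."""
    n_used = int(smap.included.sum())
    if n_used == 0:
        raise ValidationError("no included pixels in spectral map")
    avg = smap.power[:, smap.included].mean(axis=1)
    total = avg.sum()
    if total <= 0:
        raise ValidationError("spectral map has zero total power")
    centroid = float((smap.freq_axis_hz * avg).sum() / total)
    return MeanFrequencyResult(mean_freq_hz=centroid, n_pixels_used=n_used)


def mean_frequency_of_volume(
    vol: RFVolume,
    window_px: int = DEFAULT_WINDOW_PX,
    noise_floor_quantile: float = DEFAULT_NOISE_FLOOR_QUANTILE,
) -> MeanFrequencyResult:
    """Convenience composition of the spectral map and its centroid."""
    return mean_frequency(power_spectral_map(vol, window_px, noise_floor_quantile))
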