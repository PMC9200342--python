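"""Continuous wavelet transform scaleograms for the deep model's image branch.

Each standardized bin sequence (48 time steps x 4 channels) is expanded into
a scales x time magnitude image per channel, stacking the four behavioural
channels as image channels of a single 2-D input. Defaults: Morlet wavelet,
integer scales 1..16.

Scaleograms are computed *after* per-fold standardisation so the image
branch sees a common scale across cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import SequenceTensor

DEFAULT_WAVELET = "morl"
DEFAULT_SCALES = tuple(range(1, 17))


@dataclass
class ScaleogramSet:
    """|CWT| magnitudes for a batch of sequences: (N, n_scales, target_len, 4)."""

    data: np.ndarray
    scales: tuple[float, ...]
    wavelet_name: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1] != len(self.scales):
            raise ValueError("data must have shape (N, n_scales, target_len, channels)")

    def __len__(self) -> int:
        return int(self.data.shape[0])


def _validate(scales, wavelet: str) -> np.ndarray:
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0 or np.any(scales <= 0):
        raise ValueError("scales must be non-empty and positive")
    try:
        pywt.ContinuousWavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet!r}") from exc
    return scales


def scaleogram(
    sequence: np.ndarray,
    scales=DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Channel-wise |CWT| of one (target_len, channels) sequence.

    Returns an ``(n_scales, target_len, channels)`` array of magnitudes.
    """
    scales = _validate(scales, wavelet)
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2:
        raise ValueError("sequence must be 2-D (time, channels)")
    if not np.all(np.isfinite(sequence)):
        raise ValueError("sequence contains non-finite values")
    coef, _ = pywt.cwt(sequence, scales, wavelet, axis=0)
    return np.abs(coef)


def batch_scaleograms(
    tensor: SequenceTensor | np.ndarray,
    scales=DEFAULT_SCALES,
    wavelet: str = DEFAULT_WAVELET,
) -> ScaleogramSet:
    """Scaleograms for every sequence in a batch, order preserved."""
    scales = _validate(scales, wavelet)
    data = tensor.data if isinstance(tensor, SequenceTensor) else np.asarray(tensor, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a (N, time, channels) batch")
    coef, _ = pywt.cwt(data, scales, wavelet, axis=1)
    # pywt puts the scale axis first: (n_scales, N, time, channels)
    out = np.abs(coef).transpose(1, 0, 2, 3)
    return ScaleogramSet(data=out, scales=tuple(float(s) for s in scales), wavelet_name=wavelet)
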