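"""Feature extraction from ensemble heartbeats.

Two frequency-domain feature sets, chosen because fiducial/time-domain
measurements are unreliable on noisy off-the-person signals:

- ``DCT``: the leading coefficients of an orthonormal type-II discrete
  cosine transform, keeping the band [0, 40) Hz.  Coefficient k of a
  length-L transform at sampling rate fs represents frequency
  ``k * fs / (2 L)``, so the count kept is ``floor(2 * (L / fs) * 40)`` —
  52 coefficients for the canonical 0.65 s beat at 1 kHz.
- ``HAAR2``: the detail coefficients of the second level of a Haar wavelet
  decomposition (half-sample symmetric boundary extension, per-level output
  length ``floor((L + 1) / 2)``) — 163 coefficients for L = 650.

The Haar filter bank is implemented directly (the orthonormal pair
``(x0 + x1)/sqrt(2)``, ``(x0 - x1)/sqrt(2)`` on non-overlapping pairs);
lengths and values match the conventional symmetric-extension DWT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct as _dct

from wheelbeat.prepare import EnsembleHeartbeat

__all__ = ["FeatureVector", "dct_features", "haar_features",
           "dct_feature_count", "haar_level2_count", "haar_analysis"]

_SQRT2 = np.sqrt(2.0)


@dataclass
class FeatureVector:
    """Ordered real features extracted from one ensemble heartbeat."""

    values: np.ndarray
    scheme: str                # "DCT" | "HAAR2"
    source_length: int
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scheme not in ("DCT", "HAAR2"):
            raise ValueError("scheme must be DCT or HAAR2")


def dct_feature_count(length: int, fs: float, fmax: float = 40.0) -> int:
    """Number of DCT coefficients inside [0, fmax): floor(2 * (L/fs) * fmax).

    The division comes last so exact-integer cases (e.g. L=650, fs=1000 -> 52)
    are not perturbed by intermediate rounding.
    """
    return int(np.floor(2.0 * length * fmax / fs))


def dct_features(ens: EnsembleHeartbeat, fs: float, fmax: float = 40.0
                 ) -> FeatureVector:
    """Orthonormal DCT-II coefficients of the sub-``fmax`` band."""
    x = ens.samples
    if x.size < 2:
        raise ValueError("ensemble must have at least two samples")
    coeffs = _dct(x, type=2, norm="ortho")
    k = dct_feature_count(x.size, fs, fmax)
    k = max(min(k, x.size), 1)
    return FeatureVector(values=coeffs[:k], scheme="DCT",
                         source_length=x.size, fs=fs)


def _haar_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One level of the orthonormal Haar analysis filter bank.

    Odd-length inputs get a half-sample symmetric extension (last sample
    repeated), so the output length is floor((L + 1) / 2) at every level.
    """
    if x.size % 2:
        x = np.concatenate([x, x[-1:]])
    even = x[0::2]
    odd = x[1::2]
    approx = (even + odd) / _SQRT2
    detail = (even - odd) / _SQRT2
    return approx, detail


def haar_analysis(x: np.ndarray, levels: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Multi-level Haar decomposition; returns (approximation, [details])."""
    x = np.asarray(x, dtype=float)
    details = []
    for _ in range(levels):
        if x.size < 2:
            raise ValueError("signal too short for the requested Haar depth")
        x, d = _haar_step(x)
        details.append(d)
    return x, details


def haar_level2_count(length: int) -> int:
    """Level-2 detail length: floor((floor((L+1)/2) + 1) / 2)."""
    l1 = (length + 1) // 2
    return (l1 + 1) // 2


def haar_features(ens: EnsembleHeartbeat, fs: float = float("nan")
                  ) -> FeatureVector:
    """Second-level Haar detail coefficients of the ensemble heartbeat."""
    x = ens.samples
    if x.size < 4:
        raise ValueError("ensemble must have at least four samples")
    _, details = haar_analysis(x, levels=2)
    return FeatureVector(values=details[1], scheme="HAAR2",
                         source_length=x.size, fs=fs)
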