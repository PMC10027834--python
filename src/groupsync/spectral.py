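"""Spectral synchrony: team-averaged coherence and sum-normalized CSD.

Both metrics compare channels pairwise in the frequency domain using
Welch's averaged-periodogram estimates and then average over all unordered
pairs.  Coherence normalizes per frequency, so a strongly coherent but
low-amplitude band counts as much as a dominant one; the sum-normalized
cross-spectral density instead normalizes after summing across frequencies,
which weights frequencies by amplitude and is therefore less inflated by
broadband noise.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import signal

from .core import ParameterError, ValidationError, as_array

__all__ = ["team_coherence", "sum_normalized_csd"]

_TAPER_KW = dict(window="hann", detrend="constant")
_WELCH_KW = dict(**_TAPER_KW, return_onesided=True)


def _check(values: np.ndarray, nperseg: int) -> None:
    if values.shape[0] < 2:
        raise ValidationError("spectral metrics need >= 2 variables")
    if nperseg < 2:
        raise ParameterError(f"welch_segment_length must be >= 2, got {nperseg}")
    if nperseg > values.shape[1]:
        raise ParameterError(
            f"welch_segment_length {nperseg} exceeds series length "
            f"{values.shape[1]}; reduce the segment length"
        )


def team_coherence(
    series,
    welch_segment_length: int = 256,
    include_dc: bool = False,
) -> float:
    """Pairwise magnitude-squared coherence, averaged over frequencies then pairs.

    Welch settings: Hann taper, 50% overlap, constant detrend.  The DC bin is
    excluded by default (mean-centered channels make it degenerate).  Returns
    a value in [0, 1]; 1.0 when every pair is a duplicated signal.
    """
    values = as_array(series)
    _check(values, welch_segment_length)
    noverlap = welch_segment_length // 2
    pair_means = []
    for i, j in combinations(range(values.shape[0]), 2):
        f, cxy = signal.coherence(
            values[i], values[j], nperseg=welch_segment_length,
            noverlap=noverlap, **_TAPER_KW,
        )
        keep = slice(None) if include_dc else f > 0
        pair_means.append(cxy[keep].mean())
    return float(np.mean(pair_means))


def sum_normalized_csd(
    series,
    welch_segment_length: int = 256,
    include_dc: bool = False,
) -> float:
    """Sum over frequencies of |S_xy|^2, normalized by the sum of S_xx * S_yy.

    For each unordered pair the statistic is
    ``sum_f |S_xy(f)|^2 / sum_f S_xx(f) * S_yy(f)``, which lies in [0, 1]
    because the Welch estimates satisfy |S_xy|^2 <= S_xx * S_yy at every
    frequency (Cauchy-Schwarz over the averaged segments).  Pair values are
    averaged into one team score.
    """
    values = as_array(series)
    _check(values, welch_segment_length)
    noverlap = welch_segment_length // 2
    f, autos = signal.welch(
        values, nperseg=welch_segment_length, noverlap=noverlap, axis=-1, **_WELCH_KW
    )
    keep = slice(None) if include_dc else f > 0
    pair_values = []
    for i, j in combinations(range(values.shape[0]), 2):
        _, sxy = signal.csd(
            values[i], values[j], nperseg=welch_segment_length,
            noverlap=noverlap, **_WELCH_KW,
        )
        num = np.sum(np.abs(sxy[keep]) ** 2)
        den = np.sum(autos[i][keep] * autos[j][keep])
        pair_values.append(num / den)
    return float(np.mean(pair_values))
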