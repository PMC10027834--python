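"""Sliding-window evaluation of synchrony metrics.

Most metrics summarize a whole recording in one number; windowing recovers
a time-varying estimate by applying the metric independently to contiguous
slices.  Every window is treated as a standalone recording: tercile
boundaries, normalization, and spectral estimates are recomputed locally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import ParameterError, as_array

__all__ = ["WindowedResult", "apply_windowed"]


@dataclass
class WindowedResult:
    """Metric values per window; axis 0 of ``values`` indexes windows."""

    values: np.ndarray
    window_length: int
    step: int
    window_start_indices: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def reduce(self, how: str) -> np.ndarray:
        """Summarize across windows: 'max' or 'min' (entropy conventionally
        uses the minimum, the other metrics the maximum)."""
        if how == "max":
            return np.max(self.values, axis=0)
        if how == "min":
            return np.min(self.values, axis=0)
        raise ParameterError(f"unknown reducer {how!r}; use 'max' or 'min'")


def apply_windowed(
    series,
    metric: Callable[[np.ndarray], object],
    window_length: int,
    step: int | None = None,
    **metric_kwargs,
) -> WindowedResult:
    """Evaluate *metric* on each sliding window of the series.

    *metric* is any callable taking a (n_variables, window_length) array and
    returning a scalar or array (sample-level tests that need several
    recordings cannot be windowed).  Trailing samples not covered by a full
    window are dropped; ``step`` defaults to ``window_length`` (no overlap).
    The input is never modified.
    """
    values = as_array(series)
    n_t = values.shape[1]
    if window_length < 1 or window_length > n_t:
        raise ParameterError(
            f"window_length must be in [1, {n_t}], got {window_length}"
        )
    if step is None:
        step = window_length
    if step < 1:
        raise ParameterError(f"step must be >= 1, got {step}")
    starts = np.arange(0, n_t - window_length + 1, step)
    results = [
        metric(values[:, s : s + window_length], **metric_kwargs) for s in starts
    ]
    return WindowedResult(
        values=np.asarray(results),
        window_length=window_length,
        step=step,
        window_start_indices=starts,
    )
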