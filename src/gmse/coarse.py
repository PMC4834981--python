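"""Moment-based coarse-graining of a time series.

At scale factor ``tau`` the source series is divided into
non-overlapping, left-aligned segments of ``tau`` consecutive points (a
trailing remainder of fewer than ``tau`` points is discarded) and one
summary statistic — the mean, the unbiased sample variance (denominator
``tau - 1``) or the bias-adjusted sample skewness — is computed per
segment.  The variance-coarse-grained series is the signal's volatility
at that time scale.

A moving-window (stride-1) variant is provided for display purposes
only; the analysis pipeline always uses non-overlapping segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

__all__ = ["CoarseGrainedSeries", "coarse_grain", "rolling_moment",
           "MIN_SCALE", "MOMENTS"]

#: minimum scale at which each moment is estimable per segment
MIN_SCALE = {"mean": 1, "variance": 2, "skewness": 3}
MOMENTS = tuple(MIN_SCALE)


@dataclass
class CoarseGrainedSeries:
    """Per-segment moment values of a source series at one scale.

    ``values[k]`` is the moment of source points ``[k*scale, (k+1)*scale)``
    (0-based, half-open).  Units: source units for the mean, source units
    squared for the variance, dimensionless for skewness.
    """

    scale: int
    moment: str
    values: np.ndarray
    n_source: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_source // self.scale:
            raise ValueError("coarse-grained length must be floor(n_source/scale)")

    def __len__(self) -> int:
        return int(self.values.size)


def _validate(moment: str, scale: int, n: int, what: str = "scale") -> None:
    if moment not in MIN_SCALE:
        raise ValueError(f"unknown moment {moment!r}; choose from {MOMENTS}")
    if not (isinstance(scale, (int, np.integer)) and scale >= 1):
        raise ValueError(f"{what} must be a positive integer, got {scale!r}")
    if scale < MIN_SCALE[moment]:
        raise ValueError(
            f"moment {moment!r} requires {what} >= {MIN_SCALE[moment]}, got {scale}"
        )
    if n < scale:
        raise ValueError(
            f"series of length {n} is shorter than one segment of {scale}"
        )


def _segment_moment(segments: np.ndarray, moment: str) -> np.ndarray:
    # segments: (k, tau) array; statistic taken along axis 1
    if moment == "mean":
        return segments.mean(axis=1)
    if moment == "variance":
        return segments.var(axis=1, ddof=1)
    # bias-adjusted (Fisher-Pearson adjusted) sample skewness, the
    # convention of scipy.stats.skew(bias=False)
    return stats.skew(segments, axis=1, bias=False)


def coarse_grain(series: Sequence[float], scale: int,
                 moment: str = "mean") -> CoarseGrainedSeries:
    """Coarse-grain ``series`` at scale ``scale`` with the given moment.

    Examples
    --------
    >>> coarse_grain([0, 1, 0, 1, 0, 1], 2, "variance").values
    array([0.5, 0.5, 0.5])
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("input series must be one-dimensional")
    _validate(moment, scale, x.size)
    k = x.size // scale
    segments = x[: k * scale].reshape(k, scale)
    return CoarseGrainedSeries(scale=int(scale), moment=moment,
                               values=_segment_moment(segments, moment),
                               n_source=int(x.size))


def rolling_moment(series: Sequence[float], window: int,
                   moment: str = "variance") -> np.ndarray:
    """Stride-1 moving-window moment (display helper, length N-window+1).

    This reproduces the moving-window volatility display; it is never
    used to build the coarse-grained series fed to entropy estimation.
    """
    x = np.asarray(series, dtype=float)
    _validate(moment, window, x.size, what="window")
    return _segment_moment(sliding_window_view(x, window), moment)
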