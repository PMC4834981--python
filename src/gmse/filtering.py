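"""Moving-window artifact filter for RR-interval series.

Excludes artifacts, premature ventricular complexes and missed-beat
detections by comparing each interval with the local mean of its
neighbors: the central point of a moving window of length ``l`` is
excluded when it falls outside ``[(1-a)*m_c, (1+a)*m_c]``, where ``m_c``
is the mean of the other ``l-1`` window points and ``a`` a relative
tolerance.  Excluded beats are removed, never interpolated; surviving
intervals are concatenated in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .io import RRSeries

__all__ = ["FilterParams", "FilterReport", "filter_rr"]


@dataclass(frozen=True)
class FilterParams:
    """Window length ``l`` (odd, >= 3) and relative tolerance ``a`` (0 < a <= 1).

    Defaults l=41, a=0.2 are the values used for 24-h Holter RR series.
    """

    l: int = 41
    a: float = 0.2

    def __post_init__(self) -> None:
        if not (isinstance(self.l, (int, np.integer)) and self.l >= 3
                and self.l % 2 == 1):
            raise ValueError(f"window length l must be an odd integer >= 3, "
                             f"got {self.l!r}")
        if not (0 < self.a <= 1):
            raise ValueError(f"tolerance a must satisfy 0 < a <= 1, got {self.a!r}")

    @property
    def half(self) -> int:
        return (self.l - 1) // 2


@dataclass
class FilterReport:
    """Bookkeeping for one filter run: exclusions are 0-based indices
    into the input series."""

    n_input: int
    n_excluded: int
    excluded_indices: List[int] = field(default_factory=list)
    params: FilterParams = field(default_factory=FilterParams)
    edges: str = "truncated"
    n_passes: int = 1

    def __post_init__(self) -> None:
        if self.n_excluded != len(self.excluded_indices):
            raise ValueError("n_excluded must equal len(excluded_indices)")
        if self.n_excluded > self.n_input:
            raise ValueError("cannot exclude more points than supplied")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "excluded_indices": list(map(int, self.excluded_indices)),
            "l": self.params.l,
            "a": self.params.a,
            "edges": self.edges,
            "n_passes": self.n_passes,
        }


def _exclusion_mask(x: np.ndarray, params: FilterParams, edges: str) -> np.ndarray:
    """Single-pass exclusion decisions against the original values.

    Interior points use the full centered window of ``l`` points; under
    ``edges="truncated"`` the first/last ``(l-1)/2`` points use all
    available neighbors within the half-window, and are evaluated only
    when at least ``(l-1)/2`` neighbors exist.  ``edges="keep"`` never
    excludes edge points.
    """
    n = x.size
    h = params.half
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    win_sum = csum[hi] - csum[lo]
    count = hi - lo - 1  # neighbors, excluding the central point
    full = count == params.l - 1
    if edges == "truncated":
        evaluable = count >= h
    elif edges == "keep":
        evaluable = full
    else:
        raise ValueError(f"unknown edge policy {edges!r}")
    mean_excl = np.full(n, np.nan)
    np.divide(win_sum - x, count, out=mean_excl, where=count > 0)
    with np.errstate(invalid="ignore"):
        outside = (x < (1 - params.a) * mean_excl) | (x > (1 + params.a) * mean_excl)
    return outside & evaluable


def filter_rr(series: RRSeries, params: FilterParams = FilterParams(),
              edges: str = "truncated",
              iterate: bool = False) -> Tuple[RRSeries, FilterReport]:
    """Apply the moving-window outlier filter to an RR series.

    Decisions are made against the original series in a single
    deterministic pass (all window means computed from input values,
    excluded points removed afterwards).  ``iterate=True`` repeats
    passes on the survivors until no further point is excluded; reported
    indices always refer to the original input.

    Returns the filtered series (with the report attached) and the
    :class:`FilterReport`.
    """
    x = np.asarray(series.values, dtype=float)
    if x.size < 3:
        raise ValueError(
            f"series too short for filtering: {x.size} points, need >= 3"
        )
    orig_idx = np.arange(x.size)
    excluded: List[int] = []
    n_passes = 0
    while True:
        n_passes += 1
        mask = _exclusion_mask(x, params, edges)
        if not mask.any():
            break
        excluded.extend(orig_idx[mask].tolist())
        x = x[~mask]
        orig_idx = orig_idx[~mask]
        if not iterate:
            break
        if x.size < 3:
            break
    excluded.sort()
    report = FilterReport(n_input=len(series), n_excluded=len(excluded),
                          excluded_indices=excluded, params=params,
                          edges=edges, n_passes=n_passes)
    if x.size < 1:
        raise ValueError("filter excluded every point of the series")
    out = RRSeries(x, label=series.label, sampling_note=series.sampling_note,
                   filter_report=report)
    return out, report
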