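"""Sample entropy and quadratic sample entropy.

Sample entropy (SampEn) of a series of length N is -ln(A/B), where B is
the number of unordered pairs of distinct length-m templates whose
Chebyshev (maximum-coordinate) distance is strictly below the tolerance
r, A is the number of those same pairs still matching when the templates
are extended to length m+1, and both counts run over the same N-m
template start indices so that every template considered has an
extension.  Self-matches are excluded.  When no pairs match at either
length the estimate is undefined and flagged rather than raised.

Quadratic sample entropy (QSE) is SampEn + ln(2r): normalizing by the
tolerance window converts the conditional-probability estimate into a
density-like one, mitigating the dependence on r and the impact of
outliers on the tolerance.

Pair counting uses a k-d tree in the Chebyshev metric; the strict "< r"
criterion is realized exactly by querying at the largest float below r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

__all__ = ["EntropyParams", "EntropyEstimate", "resolve_r",
           "sample_entropy", "quadratic_sample_entropy"]

#: default tolerance (percent of the original series' SD) per coarse-graining
#: moment: variance-coarse-grained series have much smaller amplitudes than
#: mean-coarse-grained ones, hence the much smaller percentage.
DEFAULT_R_PERCENT = {"mean": 15.0, "variance": 0.5}

R_MODES = ("percent_of_sd", "fixed_absolute", "percent_of_reference_series")


@dataclass(frozen=True)
class EntropyParams:
    """Template length and tolerance-resolution rule for SampEn.

    ``r_mode``:

    - ``percent_of_sd`` — r = (r_value/100) * SD of the original
      (post-filter) series, resolved once and held constant across all
      scales;
    - ``fixed_absolute`` — r = r_value, in the (coarse-grained) series'
      own units;
    - ``percent_of_reference_series`` — as percent_of_sd but the caller
      designates the reference (e.g. one of the first variance
      coarse-grained series).
    """

    m: int = 2
    r_mode: str = "percent_of_sd"
    r_value: float = 0.5
    resolved_r: Optional[float] = None

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"template length m must be a positive integer, "
                             f"got {self.m!r}")
        if self.r_mode not in R_MODES:
            raise ValueError(f"unknown r_mode {self.r_mode!r}; choose from {R_MODES}")
        if not self.r_value > 0:
            raise ValueError(f"r_value must be positive, got {self.r_value!r}")
        if self.resolved_r is not None and not self.resolved_r > 0:
            raise ValueError(f"resolved_r must be positive, got {self.resolved_r!r}")


@dataclass(frozen=True)
class EntropyEstimate:
    """One SampEn (or QSE) estimate with its match counts.

    ``value`` is in nats; it is NaN (and ``defined`` False) when either
    pair count is zero.  ``matches_m`` is B, ``matches_m1`` is A.
    """

    value: float
    m: int
    r: float
    n_templates: int
    matches_m: int
    matches_m1: int

    @property
    def defined(self) -> bool:
        return self.matches_m > 0 and self.matches_m1 > 0


def resolve_r(reference: Sequence[float], params: EntropyParams) -> EntropyParams:
    """Resolve the absolute tolerance from ``params`` and a reference series.

    For the percent modes the reference is the series whose sample
    standard deviation (denominator n-1) anchors the tolerance: the
    original filtered series for ``percent_of_sd``, a caller-designated
    coarse-grained series for ``percent_of_reference_series``.  The
    returned params carry ``resolved_r``; the inputs are not mutated.
    """
    if params.r_mode == "fixed_absolute":
        return replace(params, resolved_r=float(params.r_value))
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError("reference series must have >= 2 points to resolve r")
    sd = float(np.std(ref, ddof=1))
    # an exactly-constant series can still show SD ~ eps*|mean| in floats
    if sd <= 4 * np.finfo(float).eps * float(np.max(np.abs(ref))):
        raise ValueError("tolerance resolves to zero (constant reference series)")
    r = (params.r_value / 100.0) * sd
    return replace(params, resolved_r=r)


def _count_pairs(points: np.ndarray, r: float) -> int:
    """Unordered template pairs at Chebyshev distance strictly below r."""
    r_strict = np.nextafter(r, 0.0)  # d <= r_strict  <=>  d < r in float64
    if r_strict <= 0:
        return 0
    tree = cKDTree(points)
    total = tree.count_neighbors(tree, r_strict, p=np.inf)
    return int(total - len(points)) // 2


def sample_entropy(x: Sequence[float], m: int = 2,
                   r: float = 0.2) -> EntropyEstimate:
    """Sample entropy of ``x`` with template length ``m`` and tolerance ``r``.

    Requires ``len(x) >= m + 2`` and finite values.  Returns a flagged
    undefined estimate (NaN value) when A or B is zero.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input series must be one-dimensional")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"template length m must be a positive integer, got {m!r}")
    if not r > 0:
        raise ValueError(f"tolerance r must be positive, got {r!r}")
    if x.size < m + 2:
        raise ValueError(
            f"series too short for SampEn: length {x.size}, need >= m + 2 = {m + 2}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    n_templates = x.size - m
    templates_m = sliding_window_view(x, m)[:n_templates]
    templates_m1 = sliding_window_view(x, m + 1)  # exactly n_templates rows
    b = _count_pairs(np.ascontiguousarray(templates_m), r)
    a = _count_pairs(np.ascontiguousarray(templates_m1), r) if b else 0
    value = (-math.log(a / b) + 0.0) if (a > 0 and b > 0) else float("nan")
    return EntropyEstimate(value=value, m=int(m), r=float(r),
                           n_templates=int(n_templates),
                           matches_m=b, matches_m1=a)


def quadratic_sample_entropy(x: Sequence[float], m: int = 2,
                             r: float = 0.2) -> EntropyEstimate:
    """Quadratic (tolerance-normalized) sample entropy: SampEn + ln(2r)."""
    est = sample_entropy(x, m=m, r=r)
    value = est.value + math.log(2 * est.r) if est.defined else float("nan")
    return replace(est, value=value)
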