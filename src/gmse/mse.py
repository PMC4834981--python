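"""Generalized multiscale entropy (MSE_n) orchestration.

The procedure: (1) divide the series into non-overlapping segments of
length tau, (2) summarize each segment with a selected moment to obtain
the coarse-grained series at scale tau, (3) estimate sample entropy of
each coarse-grained series with a single tolerance resolved from the
original series, and (4) sum the entropies over an inclusive scale range
into a complexity index.  MSE_mu uses the mean (the classical method);
MSE_sigma2 uses the unbiased per-segment variance and quantifies the
multiscale structure of the signal's volatility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .coarse import MIN_SCALE, coarse_grain
from .entropy import EntropyEstimate, EntropyParams, resolve_r, sample_entropy
from .io import RRSeries

__all__ = ["MSECurve", "ComplexityIndex", "mse_curve", "complexity_index",
           "DEFAULT_SCALES"]

#: default inclusive scale ranges: 10..100 for variance coarse-graining
#: (the complexity-index range used for 24-h Holter series), 1..20 for
#: exploratory mean coarse-graining.
DEFAULT_SCALES = {"variance": range(10, 101), "mean": range(1, 21),
                  "skewness": range(10, 101)}

#: below this many coarse-grained points the SampEn estimate is noisy
_SHORT_SERIES_WARN = 100


@dataclass
class MSECurve:
    """Scale -> entropy-estimate mapping for one series and one moment."""

    moment: str
    entries: Dict[int, EntropyEstimate]
    params: Optional[EntropyParams]
    source_label: str = "series"

    def __post_init__(self) -> None:
        scales = list(self.entries)
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("curve scales must be strictly increasing")

    @property
    def scales(self) -> List[int]:
        return list(self.entries)

    def values(self) -> np.ndarray:
        """Entropy values in scale order (NaN where undefined)."""
        return np.array([e.value for e in self.entries.values()])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ComplexityIndex:
    """Sum of entropies over an inclusive scale range, in nats."""

    value: float
    scale_min: int
    scale_max: int
    n_defined: int
    undefined_scales: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n_range = self.scale_max - self.scale_min + 1
        if self.n_defined + len(self.undefined_scales) != n_range:
            raise ValueError("defined + undefined scales must cover the range")


def _as_array_and_label(series) -> tuple:
    if isinstance(series, RRSeries):
        return np.asarray(series.values, dtype=float), series.label
    return np.asarray(series, dtype=float), "series"


def mse_curve(series: Union[RRSeries, Sequence[float]], moment: str = "variance",
              scales: Optional[Iterable[int]] = None,
              params: Optional[EntropyParams] = None,
              r_per_scale: bool = False) -> MSECurve:
    """Compute the MSE_n curve of a series over a range of scales.

    The tolerance is resolved once — from the input series for
    ``percent_of_sd`` — and reused at every scale, unless ``params``
    already carries ``resolved_r`` (e.g. fixed-absolute or
    reference-series modes) or the non-default ``r_per_scale`` variant is
    requested, in which case each scale's tolerance is the percentage of
    that coarse-grained series' own SD (recorded per entry).

    Undefined entropies (no template matches) are retained in the curve
    with their flag; policy for summing them is decided downstream by
    :func:`complexity_index`.
    """
    x, label = _as_array_and_label(series)
    if params is None:
        from .entropy import DEFAULT_R_PERCENT
        params = EntropyParams(m=2, r_mode="percent_of_sd",
                               r_value=DEFAULT_R_PERCENT.get(moment, 0.5))
    scales = list(scales) if scales is not None else list(DEFAULT_SCALES[moment])
    if not scales:
        raise ValueError("empty scale range")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")
    if scales[0] < MIN_SCALE[moment]:
        raise ValueError(
            f"moment {moment!r} requires scale >= {MIN_SCALE[moment]}, "
            f"got {scales[0]}"
        )
    scale_max = scales[-1]
    if x.size // scale_max < params.m + 2:
        feasible = x.size // (params.m + 2)
        raise ValueError(
            f"series of length {x.size} cannot support scale {scale_max} with "
            f"m={params.m}: floor(N/scale) >= m+2 requires scale <= {feasible}"
        )
    if x.size // scale_max < _SHORT_SERIES_WARN:
        warnings.warn(
            f"only {x.size // scale_max} coarse-grained points at scale "
            f"{scale_max}; entropy estimates may be unstable", stacklevel=2)

    if params.resolved_r is None and not r_per_scale:
        if params.r_mode == "percent_of_reference_series":
            raise ValueError(
                "percent_of_reference_series requires resolve_r() against the "
                "designated reference before calling mse_curve"
            )
        params = resolve_r(x, params)

    entries: Dict[int, EntropyEstimate] = {}
    for tau in scales:
        cg = coarse_grain(x, tau, moment).values
        if r_per_scale:
            r = resolve_r(cg, EntropyParams(m=params.m, r_mode="percent_of_sd",
                                            r_value=params.r_value)).resolved_r
        else:
            r = params.resolved_r
        entries[tau] = sample_entropy(cg, m=params.m, r=r)
    return MSECurve(moment=moment, entries=entries, params=params,
                    source_label=label)


def complexity_index(curve: MSECurve, scale_min: Optional[int] = None,
                     scale_max: Optional[int] = None,
                     policy: str = "strict") -> ComplexityIndex:
    """Sum the curve's entropies over the inclusive range [scale_min, scale_max].

    ``policy="strict"`` raises if any entry in range is undefined;
    ``policy="skip_undefined"`` sums the defined entries and records the
    skipped scales.
    """
    if policy not in ("strict", "skip_undefined"):
        raise ValueError(f"unknown policy {policy!r}")
    scales = curve.scales
    scale_min = scales[0] if scale_min is None else int(scale_min)
    scale_max = scales[-1] if scale_max is None else int(scale_max)
    if scale_min > scale_max:
        raise ValueError(f"scale_min {scale_min} exceeds scale_max {scale_max}")
    wanted = list(range(scale_min, scale_max + 1))
    missing = [s for s in wanted if s not in curve.entries]
    if missing:
        raise ValueError(f"curve does not cover scales {missing} in "
                         f"[{scale_min}, {scale_max}]")
    undefined = tuple(s for s in wanted if not curve.entries[s].defined)
    if undefined and policy == "strict":
        raise ValueError(
            f"entropy undefined at scales {list(undefined)}; use "
            f"policy='skip_undefined' to sum the remaining scales"
        )
    total = float(sum(curve.entries[s].value for s in wanted
                      if curve.entries[s].defined))
    return ComplexityIndex(value=total, scale_min=scale_min, scale_max=scale_max,
                           n_defined=len(wanted) - len(undefined),
                           undefined_scales=undefined)
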