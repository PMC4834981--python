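"""Model/Results interface for generalized multiscale entropy analysis.

:class:`MultiscaleEntropy` is built from a series (array, RRSeries or
DataFrame column) plus the analysis configuration; :meth:`fit` runs
artifact filtering (optional), tolerance resolution and the per-scale
entropy estimation, returning an :class:`MSEResults` carrying the curve,
the complexity index, the filter report and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .entropy import DEFAULT_R_PERCENT, EntropyParams, resolve_r
from .filtering import FilterParams, FilterReport, filter_rr
from .io import RRSeries
from .mse import (DEFAULT_SCALES, ComplexityIndex, MSECurve, complexity_index,
                  mse_curve)

__all__ = ["MultiscaleEntropy", "MSEResults"]


class MultiscaleEntropy:
    """Generalized multiscale entropy (MSE_n) model for one series.

    Parameters
    ----------
    endog : array-like, RRSeries
        The time series to analyze.  RR-interval series are in seconds.
    moment : {"variance", "mean", "skewness"}
        Moment used to coarse-grain; "variance" gives the volatility
        analysis MSE_sigma2, "mean" the classical MSE_mu.
    scales : iterable of int, optional
        Strictly increasing scale factors.  Defaults: 10..100 inclusive
        for variance, 1..20 for mean.
    m : int
        SampEn template length (default 2).
    r_mode, r_value
        Tolerance rule; default ``percent_of_sd`` with 0.5 (%) for
        variance coarse-graining and 15 (%) for mean.
    filter_params : FilterParams, optional
        When given, the RR artifact filter is applied before analysis.
    r_reference : array-like, optional
        Reference series for ``r_mode="percent_of_reference_series"``.

    Examples
    --------
    >>> from gmse import MultiscaleEntropy, synth
    >>> rr = synth.rr_like(20000, seed=1)
    >>> res = MultiscaleEntropy(rr, moment="variance").fit()
    >>> ci = res.complexity_index()
    """

    def __init__(self, endog: Union[Sequence[float], RRSeries],
                 moment: str = "variance",
                 scales: Optional[Iterable[int]] = None,
                 m: int = 2,
                 r_mode: str = "percent_of_sd",
                 r_value: Optional[float] = None,
                 r_per_scale: bool = False,
                 filter_params: Optional[FilterParams] = None,
                 filter_edges: str = "truncated",
                 r_reference: Optional[Sequence[float]] = None,
                 label: Optional[str] = None):
        if isinstance(endog, RRSeries):
            self.endog = endog
            self.label = label or endog.label
        else:
            arr = np.asarray(endog, dtype=float)
            self.endog = arr
            self.label = label or "series"
        self.moment = moment
        self.scales = list(scales) if scales is not None else \
            list(DEFAULT_SCALES[moment])
        if r_value is None:
            r_value = DEFAULT_R_PERCENT.get(moment, 0.5)
        self.entropy_params = EntropyParams(m=m, r_mode=r_mode, r_value=r_value)
        self.r_per_scale = r_per_scale
        self.filter_params = filter_params
        self.filter_edges = filter_edges
        self.r_reference = None if r_reference is None else \
            np.asarray(r_reference, dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, column: str,
                       **kwargs) -> "MultiscaleEntropy":
        """Build the model from one column of a DataFrame."""
        if column not in data.columns:
            raise KeyError(f"column {column!r} not in DataFrame")
        kwargs.setdefault("label", column)
        return cls(data[column].to_numpy(dtype=float), **kwargs)

    def fit(self) -> "MSEResults":
        """Run the pipeline: filter -> resolve r -> per-scale SampEn."""
        series = self.endog
        report: Optional[FilterReport] = None
        if self.filter_params is not None:
            rr = series if isinstance(series, RRSeries) else \
                RRSeries(series, label=self.label)
            series, report = filter_rr(rr, self.filter_params,
                                       edges=self.filter_edges)
        params = self.entropy_params
        if params.r_mode == "percent_of_reference_series":
            if self.r_reference is None:
                raise ValueError("r_mode='percent_of_reference_series' "
                                 "requires r_reference")
            params = resolve_r(self.r_reference, params)
        curve = mse_curve(series, moment=self.moment, scales=self.scales,
                          params=params, r_per_scale=self.r_per_scale)
        return MSEResults(self, curve, filter_report=report)


class MSEResults:
    """Results of a fitted :class:`MultiscaleEntropy` model."""

    def __init__(self, model: MultiscaleEntropy, curve: MSECurve,
                 filter_report: Optional[FilterReport] = None):
        self.model = model
        self.curve = curve
        self.filter_report = filter_report

    @property
    def entropies(self) -> np.ndarray:
        """Per-scale entropy values in scale order (NaN where undefined)."""
        return self.curve.values()

    @property
    def resolved_r(self) -> Optional[float]:
        return self.curve.params.resolved_r if self.curve.params else None

    def complexity_index(self, scale_min: Optional[int] = None,
                         scale_max: Optional[int] = None,
                         policy: str = "strict") -> ComplexityIndex:
        """Sum of entropies over the inclusive scale range (defaults: the
        fitted range)."""
        return complexity_index(self.curve, scale_min, scale_max, policy)

    def as_dataframe(self) -> pd.DataFrame:
        """Per-scale table: scale, entropy, tolerance and match counts."""
        rows = [{"scale": s, "entropy": e.value, "r": e.r,
                 "n_templates": e.n_templates, "matches_m": e.matches_m,
                 "matches_m1": e.matches_m1, "defined": e.defined}
                for s, e in self.curve.entries.items()]
        return pd.DataFrame(rows).set_index("scale")

    def summary(self) -> str:
        """Plain-text summary in the style of statistical model results."""
        scales = self.curve.scales
        try:
            ci = self.complexity_index(policy="skip_undefined")
        except ValueError:
            ci = None
        lines = [
            "Generalized Multiscale Entropy Results",
            "=" * 54,
            f"{'Series:':<28}{self.curve.source_label}",
            f"{'Coarse-graining moment:':<28}{self.curve.moment}",
            f"{'Scales:':<28}{scales[0]}..{scales[-1]} ({len(scales)} scales)",
            f"{'Template length m:':<28}{self.curve.params.m}",
            f"{'Tolerance mode:':<28}{self.curve.params.r_mode}",
            f"{'Resolved r:':<28}"
            f"{'per-scale' if self.resolved_r is None else f'{self.resolved_r:.6g}'}",
        ]
        if self.filter_report is not None:
            fr = self.filter_report
            lines.append(f"{'Filter (l, a):':<28}({fr.params.l}, {fr.params.a}) "
                         f"excluded {fr.n_excluded}/{fr.n_input}")
        if ci is not None:
            lines += [
                "-" * 54,
                f"{'Complexity index:':<28}{ci.value:.4f} nats "
                f"(scales {ci.scale_min}..{ci.scale_max})",
                f"{'Defined scales:':<28}{ci.n_defined}"
                + (f" (undefined: {list(ci.undefined_scales)})"
                   if ci.undefined_scales else ""),
            ]
        lines.append("=" * 54)
        lines.append(f"gmse {_version}")
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Plot entropy against scale factor (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.scales, self.entropies, marker="o", **kwargs)
        ax.set_xlabel("scale factor")
        ax.set_ylabel("sample entropy (nats)")
        ax.set_title(f"MSE ({self.curve.moment}) — {self.curve.source_label}")
        return ax
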