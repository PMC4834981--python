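"""Reading and writing RR-interval series and analysis results.

Plain-text formats only: RR series as one interval per line (or
``time<sep>interval`` pairs), multiscale-entropy curves as two-column
TSV, complexity indices as JSON.  No entropy logic lives here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .filtering import FilterReport
    from .mse import ComplexityIndex, MSECurve

__all__ = ["RRSeries", "read_rr", "write_rr", "write_curve", "read_curve",
           "write_index_json"]


@dataclass
class RRSeries:
    """An ordered sequence of cardiac interbeat (RR) intervals in seconds.

    Parameters
    ----------
    values : array-like
        Interbeat intervals, seconds.  Every value must be finite and
        strictly positive; at least one value is required.
    label : str
        Free-text identifier (file stem, subject id, ...).
    sampling_note : str, optional
        Provenance note, e.g. the sampling rate of the source ECG.
    filter_report : FilterReport, optional
        Attached by :func:`gmse.filtering.filter_rr` when the series is
        the output of artifact filtering.
    """

    values: np.ndarray
    label: str = "series"
    sampling_note: Optional[str] = None
    filter_report: Optional["FilterReport"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("RR series must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("empty series")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RR series contains non-finite values")
        if np.any(self.values <= 0):
            bad = int(np.argmax(self.values <= 0))
            raise ValueError(
                f"RR series contains non-positive interval at index {bad}: "
                f"{self.values[bad]!r}"
            )

    def __len__(self) -> int:
        return int(self.values.size)


def _parse_line(line: str, fmt: str, lineno: int) -> float:
    parts = line.replace(",", " ").split()
    try:
        if fmt == "one_column":
            if len(parts) != 1:
                raise ValueError
            return float(parts[0])
        elif fmt == "two_column_time_rr":
            if len(parts) != 2:
                raise ValueError
            return float(parts[1])
        raise ValueError(f"unknown format {fmt!r}")
    except ValueError:
        raise ValueError(
            f"parse error at line {lineno}: could not read {fmt} "
            f"record from {line!r}"
        ) from None


def read_rr(path, format: str = "one_column", units: str = "s",
            label: Optional[str] = None) -> RRSeries:
    """Read an RR-interval series from a plain-text file.

    One numeric interval per line; ``two_column_time_rr`` files carry a
    cumulative-time first column and the interval second (whitespace or
    comma separated).  Lines starting with ``#`` and blank lines are
    ignored.  ``units="ms"`` converts to seconds on ingest.
    """
    if format not in ("one_column", "two_column_time_rr"):
        raise ValueError(f"unknown format {format!r}")
    if units not in ("s", "ms"):
        raise ValueError(f"unknown units {units!r}")
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            v = _parse_line(line, format, lineno)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"validation error at line {lineno}: interval must be "
                    f"finite and positive, got {v!r}"
                )
            values.append(v)
    if not values:
        raise ValueError(f"empty series: {path}")
    arr = np.asarray(values, dtype=float)
    if units == "ms":
        arr = arr / 1000.0
    return RRSeries(arr, label=label or path.stem)


def write_rr(series: RRSeries, path) -> None:
    """Write an RR series as one interval per line (seconds)."""
    with open(path, "w") as fh:
        for v in series.values:
            fh.write(repr(float(v)) + "\n")


def _format_value(v: float, precision: Optional[int]) -> str:
    if precision is None:
        return repr(float(v))
    return f"{v:.{precision}g}"


def write_curve(curve: "MSECurve", path, precision: Optional[int] = None) -> None:
    """Write an MSE curve as two-column TSV ``scale<TAB>entropy``.

    Undefined entropies are written as the literal token ``NA``.  The
    default precision is the shortest representation that round-trips
    float64 exactly, so write→read→write is the identity; pass
    ``precision=15`` for fixed significant digits.
    """
    if not curve.entries:
        raise ValueError("empty curve")
    with open(path, "w") as fh:
        for scale, est in curve.entries.items():
            if est.defined:
                fh.write(f"{scale}\t{_format_value(est.value, precision)}\n")
            else:
                fh.write(f"{scale}\tNA\n")


def read_curve(path) -> "MSECurve":
    """Read a two-column TSV curve file written by :func:`write_curve`.

    Match counts are not stored in the TSV, so the reconstructed
    estimates carry values (and the NA flag) only.
    """
    from .entropy import EntropyEstimate
    from .mse import MSECurve

    entries = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"parse error at line {lineno}: {raw!r}")
            scale = int(parts[0])
            if parts[1] == "NA":
                est = EntropyEstimate(value=float("nan"), m=0, r=float("nan"),
                                      n_templates=0, matches_m=0, matches_m1=0)
            else:
                est = EntropyEstimate(value=float(parts[1]), m=0,
                                      r=float("nan"), n_templates=0,
                                      matches_m=1, matches_m1=1)
            entries[scale] = est
    if not entries:
        raise ValueError(f"empty curve: {path}")
    return MSECurve(moment="unknown", entries=entries, params=None,
                    source_label=Path(path).stem)


def write_index_json(index: "ComplexityIndex", path, label: str = "series",
                     extra: Optional[dict] = None) -> None:
    """Write a complexity-index summary as JSON."""
    payload = {
        "label": label,
        "scale_min": index.scale_min,
        "scale_max": index.scale_max,
        "n_scales_defined": index.n_defined,
        "undefined_scales": list(index.undefined_scales),
        "index": index.value,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
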