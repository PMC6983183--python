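"""Two-rule RR-interval pre-filter.

Rule 1 (range): intervals implausible during sleep — shorter than 300 ms or
longer than 1500 ms — are excluded (strict inequalities: exactly 300 ms and
exactly 1500 ms survive).

Rule 2 (running median): an interval deviating more than 20% from the median
of its up-to-ten preceding and ten following neighbours (computed on the
range-filtered series) is excluded.  Decisions are made against the input
series in a single pass — removals do not cascade into later neighbourhood
medians.  Edge beats use truncated neighbourhoods; beats with fewer than two
neighbours are kept.

Excluded beats leave timing gaps in the onset vector; downstream spectral
analysis interpolates across them.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rr_io import RRSeries


@dataclass
class FilterConfig:
    min_rr_ms: float = 300.0
    max_rr_ms: float = 1500.0
    rel_tol: float = 0.20
    half_width_beats: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_rr_ms < self.max_rr_ms:
            raise ValueError("need 0 < min_rr_ms < max_rr_ms")
        if not 0 < self.rel_tol < 1:
            raise ValueError("rel_tol must be in (0, 1)")
        if self.half_width_beats < 1:
            raise ValueError("half_width_beats must be >= 1")


@dataclass
class FilterReport:
    n_input: int
    n_removed_range: int
    n_removed_median: int
    n_output: int
    fraction_removed: float

    def __post_init__(self) -> None:
        if self.n_output != self.n_input - self.n_removed_range - self.n_removed_median:
            raise ValueError("inconsistent filter report counts")
        if not 0.0 <= self.fraction_removed <= 1.0:
            raise ValueError("fraction_removed must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_range": self.n_removed_range,
            "n_removed_median": self.n_removed_median,
            "n_output": self.n_output,
            "fraction_removed": self.fraction_removed,
        }


def apply_range_filter(series: RRSeries, config: FilterConfig | None = None
                       ) -> tuple[RRSeries, int]:
    """Drop intervals outside [min_rr_ms, max_rr_ms] (strict exclusion).

    Onsets of surviving beats are retained from the input, so gaps appear
    where beats were removed; the output carries ``filtered=True``.
    """
    config = config or FilterConfig()
    keep = (series.rr_ms >= config.min_rr_ms) & (series.rr_ms <= config.max_rr_ms)
    out = replace(
        series,
        onsets_s=series.onsets_s[keep],
        rr_ms=series.rr_ms[keep],
        filtered=True,
    )
    return out, int(series.n_beats - out.n_beats)


def _median_keep_mask(rr: np.ndarray, half_width: int, rel_tol: float) -> np.ndarray:
    """Keep-mask of the running-median rule, single pass against the input."""
    n = rr.size
    keep = np.ones(n, dtype=bool)
    if n < 2:
        return keep
    h = half_width
    if n >= 2 * h + 1:
        # interior beats: vectorised median over the 2h neighbours (centre excluded)
        win = np.lib.stride_tricks.sliding_window_view(rr, 2 * h + 1)
        neigh = np.concatenate([win[:, :h], win[:, h + 1:]], axis=1)
        med = np.median(neigh, axis=1)
        centre = rr[h:n - h]
        keep[h:n - h] = np.abs(centre - med) <= rel_tol * med
        edge_idx = list(range(h)) + list(range(n - h, n))
    else:
        edge_idx = list(range(n))
    for i in edge_idx:
        neigh = np.concatenate([rr[max(0, i - h):i], rr[i + 1:i + 1 + h]])
        if neigh.size < 2:
            continue  # too few neighbours for a meaningful median: keep
        med = float(np.median(neigh))
        if abs(rr[i] - med) > rel_tol * med:
            keep[i] = False
    return keep


def apply_median_filter(series: RRSeries, config: FilterConfig | None = None
                        ) -> tuple[RRSeries, int]:
    """Drop intervals deviating more than ``rel_tol`` from their running median.

    The median of beat *i* is taken over up to ``half_width_beats`` preceding
    and following beats of the input series (truncated at the record edges,
    centre excluded).  Series shorter than 2 beats are returned unchanged.
    """
    config = config or FilterConfig()
    if series.n_beats < 2:
        return replace(series, filtered=True), 0
    keep = _median_keep_mask(series.rr_ms, config.half_width_beats, config.rel_tol)
    out = replace(
        series,
        onsets_s=series.onsets_s[keep],
        rr_ms=series.rr_ms[keep],
        filtered=True,
    )
    return out, int(series.n_beats - out.n_beats)


def filter_rr(series: RRSeries, config: FilterConfig | None = None
              ) -> tuple[RRSeries, FilterReport]:
    """Apply the range rule then the running-median rule; report removals."""
    config = config or FilterConfig()
    ranged, n_range = apply_range_filter(series, config)
    out, n_median = apply_median_filter(ranged, config)
    n_in = series.n_beats
    report = FilterReport(
        n_input=n_in,
        n_removed_range=n_range,
        n_removed_median=n_median,
        n_output=out.n_beats,
        fraction_removed=(n_range + n_median) / n_in if n_in else 0.0,
    )
    return out, report
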