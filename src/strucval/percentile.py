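"""Percentile ranks of entry metrics against archive distributions.

Every slider metric carries two ranks: an absolute percentile against the
whole archive and a relative percentile against comparable entries — for
crystal structures a symmetric resolution window widened until it holds at
least 1,000 entries (or the whole archive when smaller), for NMR/EM the pool
of same-method entries. Higher percentile always means better; ties get
midrank weight 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .refdata import ArchiveStats, MetricRecord

__all__ = [
    "SliderScores",
    "SliderSet",
    "absolute_percentile",
    "relative_percentile",
    "slider_panel",
    "MIN_POOL",
    "WINDOW_START",
    "WINDOW_STEP",
]

MIN_POOL = 1000
WINDOW_START = 0.1
WINDOW_STEP = 0.1

# metrics meaningful per experimental method
_METHOD_METRICS = {
    "xray": ("Rfree", "clashscore", "rama_outlier_pct", "rotamer_outlier_pct", "rsrz_outlier_pct"),
    "nmr": ("clashscore", "rama_outlier_pct", "rotamer_outlier_pct"),
    "em": ("clashscore", "rama_outlier_pct", "rotamer_outlier_pct"),
    "other": ("clashscore", "rama_outlier_pct", "rotamer_outlier_pct"),
}


def _midrank_percentile(value: float, values: np.ndarray, direction: str = "lower") -> float:
    """100 * (n_worse + 0.5 * n_equal) / n_total, 'worse' per direction tag."""
    if values.size == 0:
        raise ValueError("empty distribution")
    if direction == "lower":
        n_worse = int((values > value).sum())
    else:
        n_worse = int((values < value).sum())
    n_equal = int((values == value).sum())
    return 100.0 * (n_worse + 0.5 * n_equal) / values.size


def absolute_percentile(value: float, records: Sequence[MetricRecord],
                        direction: str = "lower") -> float:
    """Percentile of `value` against the whole archive distribution."""
    return _midrank_percentile(value, np.array([r.value for r in records]), direction)


def relative_percentile(
    value: float,
    resolution: Optional[float],
    records: Sequence[MetricRecord],
    direction: str = "lower",
    method: str = "xray",
    min_pool: int = MIN_POOL,
    window_start: float = WINDOW_START,
    window_step: float = WINDOW_STEP,
) -> tuple[float, int, Optional[float]]:
    """Percentile against comparable entries.

    Crystal entries use a resolution window |res - query| <= w, with w grown
    from `window_start` in `window_step` increments until the pool holds
    min(min_pool, n_total) entries; other methods use all same-method
    records. Returns (percentile, pool size, window or None)."""
    if method == "xray" and resolution is not None:
        res = np.array([r.resolution if r.resolution is not None else np.inf
                        for r in records])
        vals = np.array([r.value for r in records])
        target = min(min_pool, len(records))
        w = window_start
        while True:
            sel = np.abs(res - resolution) <= w + 1e-12
            if int(sel.sum()) >= target:
                break
            w += window_step
        return _midrank_percentile(value, vals[sel], direction), int(sel.sum()), w
    pool = [r for r in records if r.method == method] or list(records)
    vals = np.array([r.value for r in pool])
    return _midrank_percentile(value, vals, direction), len(pool), None


@dataclass
class SliderScores:
    metric: str
    value: float
    absolute: float
    relative: float
    pool_size: int
    window: Optional[float]


@dataclass
class SliderSet:
    sliders: dict[str, SliderScores]
    omitted: dict[str, str]  # metric -> reason

    def __getitem__(self, metric: str) -> SliderScores:
        return self.sliders[metric]

    def __contains__(self, metric: str) -> bool:
        return metric in self.sliders


def slider_panel(
    entry_metrics: dict[str, Optional[float]],
    archive: ArchiveStats,
    method: str = "xray",
    resolution: Optional[float] = None,
    min_pool: int = MIN_POOL,
) -> SliderSet:
    """Build the percentile-slider panel for one entry.

    Metrics not applicable to the method, missing from the entry, or absent
    from the archive are omitted with a reason."""
    sliders: dict[str, SliderScores] = {}
    omitted: dict[str, str] = {}
    for metric in ("Rfree", "clashscore", "rama_outlier_pct",
                   "rotamer_outlier_pct", "rsrz_outlier_pct"):
        if metric not in _METHOD_METRICS.get(method, ()):
            omitted[metric] = f"not applicable to {method} entries"
            continue
        value = entry_metrics.get(metric)
        if value is None:
            omitted[metric] = "metric unavailable for this entry"
            continue
        records = archive.metrics.get(metric)
        if not records:
            omitted[metric] = "no archive distribution"
            continue
        direction = archive.directions.get(metric, "lower")
        abs_p = absolute_percentile(value, records, direction)
        rel_p, pool, window = relative_percentile(value, resolution, records,
                                                  direction, method, min_pool)
        sliders[metric] = SliderScores(metric, value, abs_p, rel_p, pool, window)
    return SliderSet(sliders=sliders, omitted=omitted)
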