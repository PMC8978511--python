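"""Pearson synchronicity between a mobility proxy and a reference series.

Used to check that an indirectly measured mobility series (e.g. daily
roaming-device counts aggregated over all counterpart countries) co-varies
with an independent reference (e.g. daily air-passenger arrivals).  Two
views are computed:

* global synchronicity rho_g — Pearson correlation over the full overlap;
* local synchronicity rho_l — Pearson correlation inside sliding windows of
  size W (step 1 day), summarised by mean and median per W.  Windows where
  either sub-series is constant have undefined correlation; they are
  excluded from the aggregates and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import align_series
from .errors import ConfigurationError

DEFAULT_WINDOWS = (5, 10, 15, 20, 25)

UNDEFINED = float("nan")


@dataclass
class WindowResult:
    """Sliding-window correlations for one window size."""

    window: int
    correlations: list[float]  # per start day; NaN where undefined
    mean: float
    median: float
    n_excluded: int
    unstable: bool = False  # window < 3 points


@dataclass
class SynchronyReport:
    rho_g: float
    windows: dict[int, WindowResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rho_g": self.rho_g,
            "local": {
                str(w): {
                    "mean": res.mean,
                    "median": res.median,
                    "n_windows": len(res.correlations),
                    "n_excluded": res.n_excluded,
                }
                for w, res in self.windows.items()
            },
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(stats.pearsonr(x, y).statistic)


def global_synchrony(x: pd.Series, y: pd.Series) -> float:
    """Pearson correlation of two date-indexed series over their full span.

    The series must cover identical date sets (AlignmentError otherwise);
    a constant series yields the NaN undefined marker.
    """
    xa, ya = align_series(x, y)
    return _pearson(xa, ya)


def local_synchrony(
    x: pd.Series,
    y: pd.Series,
    window_sizes=DEFAULT_WINDOWS,
) -> dict[int, WindowResult]:
    """Sliding-window (step 1) Pearson correlations for each window size.

    A window size equal to the series length reproduces the global value.
    Sizes below 3 are rejected: correlation on fewer than 3 points is not a
    stable quantity.
    """
    xa, ya = align_series(x, y)
    n = len(xa)
    out: dict[int, WindowResult] = {}
    for w in window_sizes:
        w = int(w)
        if w < 3:
            raise ConfigurationError(f"window size {w} < 3: correlation would be unstable")
        if w > n:
            raise ConfigurationError(f"window size {w} exceeds series length {n}")
        corrs = [_pearson(xa[t : t + w], ya[t : t + w]) for t in range(n - w + 1)]
        arr = np.asarray(corrs)
        defined = arr[~np.isnan(arr)]
        out[w] = WindowResult(
            window=w,
            correlations=corrs,
            mean=float(defined.mean()) if len(defined) else UNDEFINED,
            median=float(np.median(defined)) if len(defined) else UNDEFINED,
            n_excluded=int(np.isnan(arr).sum()),
        )
    return out


def synchrony_report(x: pd.Series, y: pd.Series, window_sizes=DEFAULT_WINDOWS) -> SynchronyReport:
    """Global + local synchronicity in one report."""
    return SynchronyReport(rho_g=global_synchrony(x, y), windows=local_synchrony(x, y, window_sizes))
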