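"""Binned climate summaries aligned with lineage-through-time curves.

A sea-level (or any palaeoclimate) time series is summarised over contiguous
1-Myr intervals — the first bin spanning 0-1 Ma — and merged with an LTT
curve so lineage accumulation can be read against the climate trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversification import LttCurve
from .io_formats import SeaLevelSeries

__all__ = ["BinnedSeries", "bin_time_series", "overlay_report"]


@dataclass(frozen=True)
class BinnedSeries:
    """Per-bin mean / sample s.d. / count over half-open bins [k*w, (k+1)*w)."""

    table: pd.DataFrame  # columns: start_ma, end_ma, mean, sd, count
    width: float

    def __len__(self) -> int:
        return len(self.table)


def bin_time_series(series: SeaLevelSeries, width: float = 1.0) -> BinnedSeries:
    """Bin a series into contiguous intervals of ``width`` Myr from 0.

    Bins are half-open ``[k*width, (k+1)*width)``; the standard deviation is
    the sample (n-1) form and is NaN (flagged by ``count``) for bins with a
    single point.  Empty bins within the covered range are kept with count 0.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.floor(series.ages.max() / width)) + 1
    idx = np.floor(series.ages / width).astype(int)
    rows = []
    for k in range(n_bins):
        vals = series.values[idx == k]
        rows.append(
            {
                "start_ma": k * width,
                "end_ma": (k + 1) * width,
                "mean": vals.mean() if vals.size else np.nan,
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                "count": int(vals.size),
            }
        )
    table = pd.DataFrame(rows)
    assert int(table["count"].sum()) == len(series)
    return BinnedSeries(table=table, width=width)


def overlay_report(ltt: LttCurve, binned: BinnedSeries) -> pd.DataFrame:
    """Join an LTT curve with binned climate values on bin midpoints.

    The lineage count is the step-function value at each bin midpoint; bins
    older than the root are dropped.  A disjoint age range produces an empty
    table and a warning.
    """
    mids = (binned.table["start_ma"] + binned.table["end_ma"]) / 2.0
    in_range = mids <= ltt.ages[0]
    populated = binned.table["count"] > 0
    if not (in_range & populated).any():
        warnings.warn(
            "climate bins and LTT curve cover disjoint age ranges",
            RuntimeWarning,
            stacklevel=2,
        )
        in_range &= False
    sub = binned.table[in_range]
    return pd.DataFrame(
        {
            "age_ma": mids[in_range],
            "lineages": [ltt.count_at(m) for m in mids[in_range]],
            "climate_mean": sub["mean"].to_numpy(),
            "climate_sd": sub["sd"].to_numpy(),
            "climate_n": sub["count"].to_numpy(),
        }
    ).reset_index(drop=True)
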