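"""Growing degree days from monthly temperature normals.

Cumulative annual GDD is the sum over 12 months of the average daily GDD
times a fixed month length (30.4 days).  Average daily GDD uses the
mean of the daily minimum and maximum temperatures relative to a base of
8 degrees C, with the minimum clamped up to the base and the maximum
clamped down to an upper threshold of 32 degrees C before averaging;
negative daily values are floored at zero during summation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


class MonthlyTemperature(NamedTuple):
    """Average daily minimum / maximum temperature for one month, in C."""

    t_min: float
    t_max: float


@dataclass(frozen=True)
class GddParams:
    """Base and threshold temperatures (C) and the per-month day count."""

    t_lower: float = 8.0
    t_upper: float = 32.0
    days_per_month: float = 30.4

    def __post_init__(self) -> None:
        if not self.t_lower < self.t_upper:
            raise ValueError("t_lower must be below t_upper")


DEFAULT_PARAMS = GddParams()


def daily_gdd(month: MonthlyTemperature, params: GddParams = DEFAULT_PARAMS) -> float:
    """Average daily degree days for a month: [(Tmax + Tmin)/2] - Tlower.

    Tmin is clamped up to the base temperature and Tmax down to the upper
    threshold before averaging; the result is floored at zero.
    """
    t_min, t_max = month
    if t_min > t_max:
        raise ValueError(f"t_min {t_min} exceeds t_max {t_max}")
    lo = max(float(t_min), params.t_lower)
    hi = min(float(t_max), params.t_upper)
    return max((hi + lo) / 2.0 - params.t_lower, 0.0)


def monthly_gdd(month: MonthlyTemperature, params: GddParams = DEFAULT_PARAMS) -> float:
    """Degree days accumulated over one month (daily value x 30.4 days)."""
    return daily_gdd(month, params) * params.days_per_month


def annual_gdd(months: Sequence[MonthlyTemperature], params: GddParams = DEFAULT_PARAMS) -> float:
    """Cumulative annual degree days: the sum of 12 monthly values."""
    if len(months) != 12:
        raise ValueError(f"expected 12 months, got {len(months)}")
    return float(sum(monthly_gdd(MonthlyTemperature(*m), params) for m in months))


def read_monthly_temperatures(path: str | Path) -> pd.DataFrame:
    """Read a delimited monthly temperature table.

    Columns: county_id, year, month (1-12), t_min, t_max (C).
    """
    df = pd.read_csv(path, dtype={"county_id": str})
    required = ["county_id", "year", "month", "t_min", "t_max"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"temperature file missing column(s): {missing}")
    return df[required]


def annual_gdd_table(temps: pd.DataFrame, params: GddParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Annual GDD per (county_id, year) from a monthly temperature table."""
    lo = np.maximum(temps["t_min"].to_numpy(float), params.t_lower)
    hi = np.minimum(temps["t_max"].to_numpy(float), params.t_upper)
    daily = np.maximum((hi + lo) / 2.0 - params.t_lower, 0.0)
    work = temps[["county_id", "year"]].copy()
    work["monthly"] = daily * params.days_per_month
    counts = work.groupby(["county_id", "year"]).size()
    if (counts != 12).any():
        bad = counts[counts != 12].index[0]
        raise ValueError(f"county-year {bad} does not have exactly 12 months")
    out = work.groupby(["county_id", "year"], as_index=False)["monthly"].sum()
    return out.rename(columns={"monthly": "gdd"})


def merge_gdd(panel, gdd_table: pd.DataFrame, *, scale: float = 1e-3):
    """Attach annual GDD to a panel as ``x_gdd``, in thousands of degree days.

    Returns a new panel; county-years missing from ``gdd_table`` raise.
    """
    out = panel.copy()
    merged = out.data.merge(gdd_table, on=["county_id", "year"], how="left")
    if merged["gdd"].isna().any():
        miss = merged.loc[merged["gdd"].isna(), ["county_id", "year"]].iloc[0]
        raise ValueError(f"no GDD value for county-year {tuple(miss)}")
    out.data["x_gdd"] = merged["gdd"].to_numpy(float) * scale
    return out
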