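"""Nonparametric rest-activity rhythm markers: L5, M10, RA, IV, IS.

L5/M10 are the mean level over the least-active 5 h / most-active 10 h
contiguous windows of the average daily profile (windows wrap past
midnight); RA = (M10 - L5)/(M10 + L5) is the scale-free day-night contrast.
IV (intradaily variability) is the normalised first-difference variance of
the hourly-binned record — about 2 for white noise, near 0 for a smooth
rhythm.  IS (interdaily stability) is the variance of the mean 24-h profile
relative to total variance — 1 when every day repeats exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wearable_io import MINUTES_PER_DAY, MinuteSeries

DEFAULT_BIN_MINUTES = 60

L5_WINDOW_MINUTES = 300
M10_WINDOW_MINUTES = 600


@dataclass(frozen=True)
class BinnedSeries:
    """A multi-day signal averaged into fixed clock-aligned bins."""

    bin_minutes: int
    values: np.ndarray  # length N = days * bins_per_day
    bins_per_day: int  # S

    @property
    def n_total(self) -> int:
        return len(self.values)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())

    @property
    def hourly_profile(self) -> np.ndarray:
        """Per-clock-bin mean across days (length S)."""
        return self.values.reshape(-1, self.bins_per_day).mean(axis=0)


@dataclass(frozen=True)
class NonparamMarkers:
    l5: float
    m10: float
    ra: float
    iv: float
    is_: float


def bin_series(series: MinuteSeries, bin_minutes: int = DEFAULT_BIN_MINUTES) -> BinnedSeries:
    if MINUTES_PER_DAY % bin_minutes != 0:
        raise ValueError("bin width must divide 1440")
    vals = series.values.reshape(-1, bin_minutes).mean(axis=1)
    return BinnedSeries(
        bin_minutes=bin_minutes,
        values=vals,
        bins_per_day=MINUTES_PER_DAY // bin_minutes,
    )


def mean_daily_profile(series: MinuteSeries) -> np.ndarray:
    """Average day: element m is the mean over days of minute-of-day m."""
    if series.n_days < 2:
        raise ValueError("need at least 2 whole days for a daily profile")
    return series.daily().mean(axis=0)


def _wrapping_window_means(profile: np.ndarray, width: int) -> np.ndarray:
    """Mean of every contiguous ``width``-minute window, wrapping past midnight."""
    ext = np.concatenate([profile, profile[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[width:] - csum[:-width]) / width


def l5_m10_ra(profile: np.ndarray) -> tuple[float, float, float]:
    """L5, M10 and relative amplitude from a 1440-point average day.

    Ties among equally extreme windows resolve to the earliest start.
    RA is NaN when M10 + L5 == 0 (an all-zero profile).
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) != MINUTES_PER_DAY:
        raise ValueError("profile must have 1440 points")
    l5 = float(_wrapping_window_means(profile, L5_WINDOW_MINUTES).min())
    m10 = float(_wrapping_window_means(profile, M10_WINDOW_MINUTES).max())
    denom = m10 + l5
    ra = (m10 - l5) / denom if denom != 0 else math.nan
    return l5, m10, ra


def intradaily_variability(binned: BinnedSeries) -> float:
    """IV = N * sum (Y_t - Y_{t-1})^2 / [(N-1) * sum (Y_t - Ybar)^2]."""
    y = binned.values
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 bins for IV")
    denom = (n - 1) * ((y - y.mean()) ** 2).sum()
    if denom == 0:
        return math.nan
    return float(n * (np.diff(y) ** 2).sum() / denom)


def interdaily_stability(binned: BinnedSeries) -> float:
    """IS = N * sum_h (xbar_h - xbar)^2 / [S * sum_i (x_i - xbar)^2]."""
    y = binned.values
    n = len(y)
    s = binned.bins_per_day
    if n < 2 * s:
        raise ValueError("need at least 2 whole days for IS")
    hourly = binned.hourly_profile
    denom = s * ((y - y.mean()) ** 2).sum()
    if denom == 0:
        return math.nan
    return float(n * ((hourly - y.mean()) ** 2).sum() / denom)


def compute_nonparametric_markers(
    series: MinuteSeries, bin_minutes: int = DEFAULT_BIN_MINUTES
) -> NonparamMarkers:
    """All five markers with the module defaults (profile-mode L5/M10, hourly IV/IS)."""
    profile = mean_daily_profile(series)
    l5, m10, ra = l5_m10_ra(profile)
    binned = bin_series(series, bin_minutes)
    return NonparamMarkers(
        l5=l5,
        m10=m10,
        ra=ra,
        iv=intradaily_variability(binned),
        is_=interdaily_stability(binned),
    )


def l5_m10_per_day(series: MinuteSeries) -> tuple[float, float]:
    """Alternative mode: L5/M10 computed per day then averaged across days."""
    daily = series.daily()
    l5s, m10s = [], []
    for day in daily:
        l5s.append(_wrapping_window_means(day, L5_WINDOW_MINUTES).min())
        m10s.append(_wrapping_window_means(day, M10_WINDOW_MINUTES).max())
    return float(np.mean(l5s)), float(np.mean(m10s))
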