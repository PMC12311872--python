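"""Nightly sleep summaries: midsleep time (MST) and total sleep time (TST).

MST is the clock midpoint of the main nocturnal sleep episode, reported in
minutes after midnight; TST is the episode duration in minutes.  Means and
SDs are taken across nights, with MST averaged circularly so that schedules
straddling midnight (23:50 vs 00:10) average to midnight rather than noon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wearable_io import MINUTES_PER_DAY, SleepEpisode

#: a night belongs to the window [18:00 of day d, 12:00 of day d+1)
NIGHT_WINDOW_START_HOUR = 18
NIGHT_WINDOW_END_HOUR = 12


@dataclass(frozen=True)
class SleepMarkers:
    mst_mean: float  # minutes after midnight, circular mean in [0, 1440)
    mst_sd: float  # minutes, circular dispersion
    tst_mean: float  # minutes
    tst_sd: float  # minutes
    n_nights: int


def main_sleep_per_night(episodes: list[SleepEpisode]) -> list[SleepEpisode]:
    """Keep one episode per night: the longest with midpoint in the night window.

    The night window runs from 18:00 to noon the next day, so daytime naps
    are discarded.  Nights with no episode are simply absent from the result.
    """
    by_night: dict[pd.Timestamp, SleepEpisode] = {}
    for ep in sorted(episodes, key=lambda e: e.onset):
        mid = ep.midpoint
        if mid.hour >= NIGHT_WINDOW_START_HOUR:
            night = mid.normalize()
        elif mid.hour < NIGHT_WINDOW_END_HOUR:
            night = mid.normalize() - pd.Timedelta(days=1)
        else:
            continue  # midpoint in the afternoon: a nap
        best = by_night.get(night)
        if best is None or ep.duration_minutes > best.duration_minutes:
            by_night[night] = ep
    return [by_night[k] for k in sorted(by_night)]


def _midpoint_minutes(ep: SleepEpisode) -> float:
    mid = ep.midpoint
    return (mid - mid.normalize()) / pd.Timedelta(minutes=1)


def circular_mean_minutes(minutes: np.ndarray) -> float:
    """Mean of clock times (minutes after midnight) on the 24-h circle."""
    ang = np.asarray(minutes, dtype=float) * 2 * np.pi / MINUTES_PER_DAY
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float(mean_ang * MINUTES_PER_DAY / (2 * np.pi) % MINUTES_PER_DAY)


def circular_sd_minutes(minutes: np.ndarray) -> float:
    """Sample SD of wrapped deviations from the circular mean, in minutes."""
    center = circular_mean_minutes(minutes)
    dev = (np.asarray(minutes, dtype=float) - center + MINUTES_PER_DAY / 2) % MINUTES_PER_DAY
    dev -= MINUTES_PER_DAY / 2
    return float(np.sqrt((dev**2).sum() / (len(dev) - 1)))


def compute_sleep_markers(nightly: list[SleepEpisode]) -> SleepMarkers:
    """MST/TST means and SDs across nightly main-sleep episodes."""
    if len(nightly) < 2:
        raise ValueError("insufficient nights: need at least 2 nightly episodes")
    mids = np.array([_midpoint_minutes(ep) for ep in nightly])
    durations = np.array([ep.duration_minutes for ep in nightly])
    return SleepMarkers(
        mst_mean=circular_mean_minutes(mids),
        mst_sd=circular_sd_minutes(mids),
        tst_mean=float(durations.mean()),
        tst_sd=float(durations.std(ddof=1)),
        n_nights=len(nightly),
    )
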