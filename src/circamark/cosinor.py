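"""Single-component cosinor analysis.

Fits Y(t) = M + A cos(2*pi*t/tau + phi) by ordinary least squares via the
linear reparameterisation Y = M + beta*cos(2*pi*t/tau) + gamma*sin(2*pi*t/tau),
yielding the MESOR M (rhythm-adjusted mean), amplitude A = sqrt(beta^2 +
gamma^2), and acrophase reported as the clock time of the fitted peak in
decimal hours.  The circadian quotient CQ = A/M is a scale-free measure of
rhythm strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wearable_io import MinuteSeries

DEFAULT_PERIOD_MINUTES = 1440.0

#: amplitudes below this fraction of the signal scale are treated as absent,
#: in which case the acrophase is undefined
_AMPLITUDE_EPS = 1e-9


@dataclass(frozen=True)
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_hours: float  # clock time of fitted peak in [0, 24); NaN if A == 0
    period_minutes: float
    cq: float  # amplitude / MESOR; NaN if MESOR <= 0
    rss: float  # residual sum of squares of the fit
    phi_radians: float  # raw phase of the cosine term, kept for diagnostics


def fit_cosinor(
    series: MinuteSeries | np.ndarray,
    period_minutes: float = DEFAULT_PERIOD_MINUTES,
) -> CosinorFit:
    """Least-squares cosinor fit at a fixed period (default 24 h).

    ``series`` may be a :class:`MinuteSeries` (heart rate already
    interpolated) or a bare array sampled at one-minute resolution starting
    at midnight.  The fit is computed on the pooled multi-day record.
    """
    y = series.values if isinstance(series, MinuteSeries) else np.asarray(series, float)
    if len(y) < period_minutes:
        raise ValueError("series must cover at least one full period")
    t = np.arange(len(y), dtype=float)
    w = 2 * np.pi * t / period_minutes
    design = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    amplitude = math.hypot(beta, gamma)
    resid = y - design @ coef
    rss = float(resid @ resid)

    scale = max(float(np.abs(y).max()), 1.0)
    if amplitude <= _AMPLITUDE_EPS * scale:
        amplitude = 0.0
        acrophase = math.nan
        phi = math.nan
    else:
        # Y = M + A*cos(w*t - theta) peaks at t = theta/w; phi = -theta
        theta = math.atan2(gamma, beta)
        phi = -theta
        t_peak = theta * period_minutes / (2 * np.pi) % period_minutes
        acrophase = t_peak / 60.0 % 24.0
    cq = amplitude / mesor if mesor > 0 else math.nan
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase_hours=acrophase,
        period_minutes=period_minutes,
        cq=cq,
        rss=rss,
        phi_radians=phi,
    )


def cosinor_predict(fit: CosinorFit, t_minutes: np.ndarray) -> np.ndarray:
    """Evaluate the fitted cosine at the given minute offsets."""
    if math.isnan(fit.phi_radians):
        return np.full_like(np.asarray(t_minutes, float), fit.mesor)
    w = 2 * np.pi * np.asarray(t_minutes, float) / fit.period_minutes
    return fit.mesor + fit.amplitude * np.cos(w + fit.phi_radians)
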