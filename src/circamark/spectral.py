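"""Morlet continuous wavelet transform energy profiles and CCE band markers.

The continuous wavelet circadian-rhythm energy (CCE) summarises a
minute-level signal by the total spectrogram energy at each central period:
the signal is z-scored, transformed with an analytic Morlet wavelet
(psi(t) = pi^(-1/4) * exp(i*omega0*t) * exp(-t^2/2), omega0 = 6) over a
logarithmic grid of central periods, and |W(a, b)|^2 is summed over time at
each scale.  The profile is normalised to unit total so band values are
dimensionless fractions of signal energy.  The marker bands are 69-80 min
(mid-frequency) and 900-1100 min (low-frequency), plus their ratio.

Implementation notes: coefficients use the L1 scale normalisation
(W(a,b) = (1/a) * integral x(t) psi*((t-b)/a) dt), which weights a sinusoid
of a given amplitude equally at every period; the transform is evaluated in
the Fourier domain with periodic boundary handling, and the time-summed
energy at each scale follows from Parseval's identity without materialising
the spectrogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .wearable_io import MinuteSeries

DEFAULT_OMEGA0 = 6.0
DEFAULT_PERIOD_MIN = 20.0
DEFAULT_PERIOD_MAX = 1500.0
#: 80 log-spaced periods: the coarsest grid of this span that keeps at least
#: three points inside each marker band (checked at import below)
DEFAULT_N_PERIODS = 80

MID_BAND_MINUTES = (69.0, 80.0)
LOW_BAND_MINUTES = (900.0, 1100.0)


def default_period_grid() -> np.ndarray:
    return np.geomspace(DEFAULT_PERIOD_MIN, DEFAULT_PERIOD_MAX, DEFAULT_N_PERIODS)


def morlet_fourier_factor(omega0: float) -> float:
    """Scale per unit Fourier period for the Morlet wavelet: a = factor * period."""
    return (omega0 + math.sqrt(2.0 + omega0**2)) / (4.0 * math.pi)


@dataclass(frozen=True)
class WaveletConfig:
    omega0: float = DEFAULT_OMEGA0
    periods: np.ndarray = field(default_factory=default_period_grid)
    normalize: bool = True  # z-score input and normalise profile to unit total
    exclude_coi: bool = False  # drop coefficients within one e-folding of the edges

    def __post_init__(self) -> None:
        p = np.asarray(self.periods, dtype=float)
        if p.ndim != 1 or len(p) < 2 or not np.all(np.diff(p) > 0):
            raise ValueError("period grid must be strictly increasing")
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        object.__setattr__(self, "periods", p)

    @property
    def scales(self) -> np.ndarray:
        return morlet_fourier_factor(self.omega0) * self.periods


@dataclass(frozen=True)
class EnergyProfile:
    periods: np.ndarray  # central periods in minutes
    energy: np.ndarray  # per-period time-summed |W|^2, >= 0
    total_energy: float  # pre-normalisation total

    def __post_init__(self) -> None:
        if np.any(self.energy < 0):
            raise ValueError("energy must be non-negative")


@dataclass(frozen=True)
class CceMarkers:
    mid_frequency: float  # band energy over 69-80 min central periods
    low_frequency: float  # band energy over 900-1100 min central periods
    mid_low_ratio: float  # mid / low, NaN when low == 0


def _morlet_hat(w: np.ndarray, omega0: float) -> np.ndarray:
    """Fourier transform of the Morlet mother wavelet at angular frequency w."""
    out = np.zeros_like(w)
    pos = w > 0  # analytic wavelet: negligible response at w <= 0
    out[pos] = math.pi**-0.25 * math.sqrt(2.0 * math.pi) * np.exp(
        -0.5 * (w[pos] - omega0) ** 2
    )
    return out


def _prepare_signal(series: MinuteSeries | np.ndarray, cfg: WaveletConfig) -> np.ndarray:
    x = series.values if isinstance(series, MinuteSeries) else np.asarray(series, float)
    n = len(x)
    if np.asarray(cfg.periods).max() > n / 2:
        raise ValueError("period unresolvable: grid exceeds half the record length")
    if cfg.normalize:
        sd = x.std()
        if sd == 0:
            raise ValueError("zero variance: cannot z-score a constant signal")
        x = (x - x.mean()) / sd
    return x


def cwt_coefficients(
    series: MinuteSeries | np.ndarray, cfg: WaveletConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full complex CWT matrix (periods x time), L1-normalised, periodic edges."""
    cfg = cfg or WaveletConfig()
    x = _prepare_signal(series, cfg)
    n = len(x)
    xhat = np.fft.fft(x)
    w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0)
    coeffs = np.empty((len(cfg.periods), n), dtype=complex)
    for i, a in enumerate(cfg.scales):
        coeffs[i] = np.fft.ifft(xhat * np.conj(_morlet_hat(a * w, cfg.omega0)))
    return cfg.periods, coeffs


def cwt_energy_profile(
    series: MinuteSeries | np.ndarray, cfg: WaveletConfig | None = None
) -> EnergyProfile:
    """Per-central-period CWT energy summed over time.

    With ``cfg.normalize`` the profile is divided by its total so that it
    sums to 1.  With ``cfg.exclude_coi`` coefficients within one wavelet
    e-folding (sqrt(2)*scale samples) of either record edge are omitted.
    """
    cfg = cfg or WaveletConfig()
    if cfg.exclude_coi:
        _, coeffs = cwt_coefficients(series, cfg)
        n = coeffs.shape[1]
        energy = np.empty(len(cfg.periods))
        for i, a in enumerate(cfg.scales):
            edge = min(int(math.ceil(math.sqrt(2.0) * a)), n // 2)
            energy[i] = np.abs(coeffs[i, edge : n - edge]) ** 2 @ np.ones(n - 2 * edge)
    else:
        x = _prepare_signal(series, cfg)
        n = len(x)
        power = np.abs(np.fft.fft(x)) ** 2
        w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0)
        # Parseval: sum_b |W(a, b)|^2 == (1/n) * sum_k |X_k|^2 |psi_hat(a w_k)|^2
        energy = np.array(
            [(power * _morlet_hat(a * w, cfg.omega0) ** 2).sum() / n for a in cfg.scales]
        )
    total = float(energy.sum())
    if cfg.normalize and total > 0:
        energy = energy / total
    return EnergyProfile(periods=cfg.periods, energy=energy, total_energy=total)


def _band_slice(periods: np.ndarray, band: tuple[float, float], name: str) -> np.ndarray:
    mask = (periods >= band[0]) & (periods <= band[1])
    if not mask.any():
        raise ValueError(f"band not covered by grid: {name} {band}")
    return mask


def compute_cce(profile: EnergyProfile) -> CceMarkers:
    """CCE band markers: energy summed at grid periods inside each band (inclusive)."""
    mid = float(profile.energy[_band_slice(profile.periods, MID_BAND_MINUTES, "mid")].sum())
    low = float(profile.energy[_band_slice(profile.periods, LOW_BAND_MINUTES, "low")].sum())
    ratio = mid / low if low > 0 else math.nan
    return CceMarkers(mid_frequency=mid, low_frequency=low, mid_low_ratio=ratio)


def band_scan(
    profiles: list[EnergyProfile],
    labels: list[str],
    test: str = "t",
) -> np.ndarray:
    """Two-sample test of per-period energy between groups.

    Returns an array of shape (n_periods, 2): central period and p-value.
    ``test`` is "t" (Welch) or "wilcoxon" (rank-sum).  Degenerate periods
    (zero variance in both groups) get a NaN p-value.
    """
    if test not in ("t", "wilcoxon"):
        raise ValueError("test must be 't' or 'wilcoxon'")
    labels_arr = np.asarray(labels)
    periods = profiles[0].periods
    mat = np.vstack([p.energy for p in profiles])
    case = mat[labels_arr == "case"]
    control = mat[labels_arr == "control"]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 participants per group")
    out = np.empty((len(periods), 2))
    out[:, 0] = periods
    for j in range(len(periods)):
        a, b = case[:, j], control[:, j]
        if a.std() == 0 and b.std() == 0:
            out[j, 1] = math.nan
            continue
        if test == "t":
            out[j, 1] = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            out[j, 1] = stats.ranksums(a, b).pvalue
    return out


def _assert_default_grid_covers_bands() -> None:
    grid = default_period_grid()
    for band in (MID_BAND_MINUTES, LOW_BAND_MINUTES):
        inside = ((grid >= band[0]) & (grid <= band[1])).sum()
        if inside < 3:
            raise AssertionError(
                f"default period grid has only {inside} points in band {band}"
            )


_assert_default_grid_covers_bands()


def dump_spectrogram(
    series: MinuteSeries | np.ndarray,
    path,
    cfg: WaveletConfig | None = None,
) -> None:
    """Write the |W(a, b)|^2 spectrogram as delimited text (periods x minutes).

    The first column holds the central period in minutes; remaining columns
    are squared coefficient magnitudes per minute.  Intended for external
    plotting; the marker pipeline never materialises this matrix.
    """
    periods, coeffs = cwt_coefficients(series, cfg)
    mat = np.column_stack([periods, np.abs(coeffs) ** 2])
    header = "period_minutes," + ",".join(f"t{i}" for i in range(coeffs.shape[1]))
    np.savetxt(path, mat, delimiter=",", header=header, comments="")
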