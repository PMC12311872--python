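"""Synthetic wearable cohorts with the structure the marker panel measures.

Each participant gets five weekdays (Monday-Friday) of minute-level heart
rate and step counts plus nightly sleep episodes.  Heart rate is a sum of a
24-h cosine (MESOR, amplitude, acrophase drawn per participant), ultradian
components near 70 and 1000 minutes with participant-random phases, a
nocturnal elevation tied to the sleep indicator, and AR(1) noise; device
nonwear appears as zero-coded bursts.  Steps are zero during sleep and
follow a bout-structured Poisson process with a daytime hump while awake.

Group contrasts are injected mechanistically — through component
amplitudes, MESOR shifts and nocturnal elevation, never by perturbing
markers directly — so recovering the published direction pattern (cases:
higher MESOR/L5 of heart rate, lower relative amplitude, attenuated 70-min
energy, relatively higher 900-1100-min energy, less regular activity) is a
genuine end-to-end test of the pipeline.  Default group means follow the
published cohort tables; between-participant spreads are the generator's
own calibration, sized so those contrasts are detectable at the reference
cohort size (88 cases / 184 controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .wearable_io import (
    MINUTES_PER_DAY,
    MinuteSeries,
    ParticipantRecord,
    SleepEpisode,
)

#: record start: a Monday, so the consecutive-weekday rule is met by design
DEFAULT_START = "2024-03-04"

#: mean of the daytime activity shape over typical waking hours; divides the
#: shape so that steps_day_rate is the mean awake stepping rate
_SHAPE_WAKING_MEAN = 0.62

#: steps bout process: two-state Markov chain transition probabilities
_P_IDLE_TO_ACTIVE = 0.08
_P_ACTIVE_TO_IDLE = 0.25


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one study group (defaults: control group)."""

    n: int = 184
    hr_mesor: float = 71.89  # bpm, group mean
    hr_mesor_sd: float = 4.5  # bpm, between-participant SD
    hr_circ_amplitude: float = 11.66  # bpm, 24-h component
    hr_acrophase: float = 14.97  # clock hours of the heart-rate peak
    hr_acrophase_sd: float = 1.2  # between-participant SD, hours
    amplitude_jitter_cv: float = 0.15  # lognormal CV of per-participant amplitudes
    ultradian_70min_amplitude: float = 3.0  # bpm
    lowfreq_1000min_amplitude: float = 1.5  # bpm
    noise_sd: float = 3.0  # bpm, stationary AR(1) SD
    ar1: float = 0.8  # minute-to-minute autocorrelation
    night_hr_elevation: float = 0.0  # bpm added while asleep
    steps_day_rate: float = 9.0  # steps/min, mean awake rate
    steps_day_cv: float = 0.15  # day-to-day lognormal CV of the activity rate
    mst_mean: float = 207.55  # minutes after midnight
    mst_sd: float = 40.0  # night-to-night SD, minutes
    tst_mean: float = 414.92  # minutes
    tst_sd: float = 80.0  # night-to-night SD, minutes
    missing_rate: float = 0.02  # fraction of minutes zero-coded
    missing_burst_minutes: float = 30.0  # mean nonwear burst length
    age_mean: float = 44.04
    age_sd: float = 6.48
    male_fraction: float = 0.152
    bmi_mean: float = 21.70
    bmi_sd: float = 2.08

    def __post_init__(self) -> None:
        non_negative = (
            self.hr_circ_amplitude,
            self.ultradian_70min_amplitude,
            self.lowfreq_1000min_amplitude,
            self.noise_sd,
            self.night_hr_elevation,
            self.steps_day_rate,
            self.steps_day_cv,
            self.mst_sd,
            self.tst_sd,
            self.hr_mesor_sd,
        )
        if any(v < 0 for v in non_negative):
            raise ValueError("amplitudes, rates and SDs must be non-negative")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")
        if not 0 <= self.missing_rate < 0.25:
            raise ValueError("missing_rate must stay below 0.25 (6-h rule headroom)")


def control_spec(**overrides) -> GroupSpec:
    return replace(GroupSpec(), **overrides) if overrides else GroupSpec()


def case_spec(**overrides) -> GroupSpec:
    """Case-group defaults: published direction pattern for the MetS group."""
    spec = GroupSpec(
        n=88,
        hr_mesor=75.05,
        hr_circ_amplitude=11.22,
        hr_acrophase=15.00,
        ultradian_70min_amplitude=2.4,  # attenuated mid-frequency energy
        lowfreq_1000min_amplitude=1.9,  # elevated low-frequency energy
        night_hr_elevation=1.5,  # raises nocturnal HR, hence L5, lowers RA
        steps_day_rate=7.8,
        steps_day_cv=0.35,  # less regular day-to-day activity -> lower IS
        mst_mean=207.08,
        mst_sd=45.0,
        tst_mean=410.70,
        tst_sd=84.0,
        age_mean=48.94,
        age_sd=6.92,
        male_fraction=0.5,
        bmi_mean=27.90,
        bmi_sd=2.94,
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class SimConfig:
    case: GroupSpec = field(default_factory=case_spec)
    control: GroupSpec = field(default_factory=control_spec)
    days: int = 5
    seed: int = 0
    start: str = DEFAULT_START

    def __post_init__(self) -> None:
        if self.days < 5:
            raise ValueError("need at least 5 days")
        if self.case.n < 2 or self.control.n < 2:
            raise ValueError("need at least 2 participants per group")
        if pd.Timestamp(self.start).dayofweek != 0:
            raise ValueError("cohort start must be a Monday")


def default_sim_config(seed: int = 0, **overrides) -> SimConfig:
    return SimConfig(seed=seed, **overrides)


def effect_free_config(n_case: int, n_control: int, seed: int = 0) -> SimConfig:
    """Null configuration: both groups drawn from the control spec."""
    return SimConfig(
        case=control_spec(n=n_case), control=control_spec(n=n_control), seed=seed
    )


def mf_attenuation_config(n_case: int, n_control: int, seed: int = 0) -> SimConfig:
    """Single-effect configuration: cases differ only in an attenuated
    70-minute ultradian component (the isolated mid-frequency condition)."""
    case = control_spec(n=n_case, ultradian_70min_amplitude=case_spec().ultradian_70min_amplitude)
    return SimConfig(case=case, control=control_spec(n=n_control), seed=seed)


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML mapping (case/control field overrides)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    case = case_spec(**raw.get("case", {}))
    control = control_spec(**raw.get("control", {}))
    return SimConfig(
        case=case,
        control=control,
        days=int(raw.get("days", 5)),
        seed=int(raw.get("seed", 0)),
        start=str(raw.get("start", DEFAULT_START)),
    )


# ---------------------------------------------------------------------------
# single participant
# ---------------------------------------------------------------------------


def _daytime_shape(minute_of_day: np.ndarray, peak_hour: float = 14.8) -> np.ndarray:
    """Smooth activity hump peaking mid-afternoon, zero near its antiphase."""
    return 0.5 * (1 + np.cos(2 * np.pi * (minute_of_day - peak_hour * 60) / MINUTES_PER_DAY))


def _sleep_episodes(
    spec: GroupSpec, rng: np.random.Generator, days: int, start: pd.Timestamp
) -> list[SleepEpisode]:
    episodes = []
    for night in range(days):
        mid = rng.normal(spec.mst_mean, spec.mst_sd)
        tst = float(np.clip(rng.normal(spec.tst_mean, spec.tst_sd), 180.0, 700.0))
        midnight = start + pd.Timedelta(days=night)
        onset = midnight + pd.Timedelta(minutes=round(mid - tst / 2))
        episodes.append(SleepEpisode(onset, onset + pd.Timedelta(minutes=round(tst))))
    return episodes


def _sleep_indicator(
    episodes: list[SleepEpisode], start: pd.Timestamp, n: int
) -> np.ndarray:
    ind = np.zeros(n)
    for ep in episodes:
        i0 = int((ep.onset - start) / pd.Timedelta(minutes=1))
        i1 = int((ep.offset - start) / pd.Timedelta(minutes=1))
        ind[max(i0, 0) : min(i1, n)] = 1.0
    return ind


def _missing_mask(
    spec: GroupSpec, rng: np.random.Generator, n: int
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if spec.missing_rate == 0:
        return mask
    n_bursts = rng.poisson(n * spec.missing_rate / spec.missing_burst_minutes)
    for _ in range(n_bursts):
        length = rng.geometric(1.0 / spec.missing_burst_minutes)
        start_idx = rng.integers(0, n)
        mask[start_idx : start_idx + length] = True
    return mask


def simulate_participant(
    spec: GroupSpec,
    seed: int | np.random.Generator,
    participant_id: str = "P000",
    group: str = "control",
    days: int = 5,
    start: str | pd.Timestamp = DEFAULT_START,
) -> ParticipantRecord:
    """Generate one participant record; all randomness flows from ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = pd.Timestamp(start)
    n = days * MINUTES_PER_DAY
    t = np.arange(n, dtype=float)
    minute_of_day = t % MINUTES_PER_DAY

    mesor = rng.normal(spec.hr_mesor, spec.hr_mesor_sd)
    jitter = rng.lognormal(mean=0.0, sigma=spec.amplitude_jitter_cv, size=3)
    a_circ = spec.hr_circ_amplitude * jitter[0]
    a_70 = spec.ultradian_70min_amplitude * jitter[1]
    a_1000 = spec.lowfreq_1000min_amplitude * jitter[2]
    acrophase_min = rng.normal(spec.hr_acrophase, spec.hr_acrophase_sd) * 60.0
    phase_70, phase_1000 = rng.uniform(0, 2 * np.pi, size=2)

    floor = mesor - a_circ - a_70 - a_1000 - 4 * spec.noise_sd
    if floor <= 0:
        raise ValueError("spec implies a non-positive heart-rate floor")

    episodes = _sleep_episodes(spec, rng, days, start)
    asleep = _sleep_indicator(episodes, start, n)

    innovations = rng.normal(0.0, spec.noise_sd * np.sqrt(1 - spec.ar1**2), size=n)
    noise = signal.lfilter([1.0], [1.0, -spec.ar1], innovations)

    hr = (
        mesor
        + a_circ * np.cos(2 * np.pi * (t - acrophase_min) / MINUTES_PER_DAY)
        + a_70 * np.cos(2 * np.pi * t / 70.0 + phase_70)
        + a_1000 * np.cos(2 * np.pi * t / 1000.0 + phase_1000)
        + spec.night_hr_elevation * asleep
        + noise
    )

    missing = _missing_mask(spec, rng, n)
    hr_values = np.where(missing, 0.0, hr)

    # day-level activity multiplier (mean 1): day-to-day irregularity
    day_mult = rng.lognormal(-0.5 * spec.steps_day_cv**2, spec.steps_day_cv, days)
    lam = (
        spec.steps_day_rate
        * np.repeat(day_mult, MINUTES_PER_DAY)
        * _daytime_shape(minute_of_day)
        / _SHAPE_WAKING_MEAN
    )
    active = np.empty(n, dtype=bool)
    state = rng.random() < 0.2
    stay = rng.random(n)
    for i in range(n):  # two-state bout chain
        if state:
            state = stay[i] >= _P_ACTIVE_TO_IDLE
        else:
            state = stay[i] < _P_IDLE_TO_ACTIVE
        active[i] = state
    pi_active = _P_IDLE_TO_ACTIVE / (_P_IDLE_TO_ACTIVE + _P_ACTIVE_TO_IDLE)
    steps = rng.poisson(lam * active / pi_active * (1.0 - asleep))

    return ParticipantRecord(
        participant_id=participant_id,
        hr=MinuteSeries(start=start, values=hr_values, missing=missing, kind="heart_rate"),
        steps=MinuteSeries(
            start=start,
            values=steps.astype(float),
            missing=np.zeros(n, dtype=bool),
            kind="steps",
        ),
        sleep=episodes,
        group=group,
        covariates={
            "age": round(float(rng.normal(spec.age_mean, spec.age_sd)), 1),
            "sex": "M" if rng.random() < spec.male_fraction else "F",
            "bmi": round(float(rng.normal(spec.bmi_mean, spec.bmi_sd)), 1),
        },
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Generate a full cohort; optionally write minute/sleep/manifest CSVs.

    Returns the in-memory records and the manifest.  With ``out_dir`` the
    exact file formats ``wearable_io`` reads are written; an existing
    manifest at the target path is an error (no silent overwrite).
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.case.n + cfg.control.n)
    records = []
    rows = []
    idx = 0
    for group, spec in (("case", cfg.case), ("control", cfg.control)):
        for _ in range(spec.n):
            pid = f"{group[0].upper()}{idx:04d}"
            rec = simulate_participant(
                spec,
                np.random.default_rng(seeds[idx]),
                participant_id=pid,
                group=group,
                days=cfg.days,
                start=cfg.start,
            )
            records.append(rec)
            rows.append(
                {
                    "participant_id": pid,
                    "minute_file": f"{pid}_minutes.csv",
                    "sleep_file": f"{pid}_sleep.csv",
                    "group": group,
                    **rec.covariates,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.csv"
        if manifest_path.exists():
            raise FileExistsError(f"output path collision: {manifest_path}")
        for rec, row in zip(records, rows):
            write_participant_files(rec, out_dir / row["minute_file"], out_dir / row["sleep_file"])
        manifest.to_csv(manifest_path, index=False)
    return records, manifest


def write_participant_files(
    rec: ParticipantRecord, minute_path: Path, sleep_path: Path
) -> None:
    """Write one participant in the delimited formats wearable_io reads."""
    hr_out = np.where(rec.hr.missing, 0, np.round(rec.hr.values)).astype(int)
    pd.DataFrame(
        {
            "timestamp": rec.hr.timestamps.strftime("%Y-%m-%dT%H:%M"),
            "heart_rate": hr_out,
            "steps": rec.steps.values.astype(int),
        }
    ).to_csv(minute_path, index=False)
    pd.DataFrame(
        {
            "onset": [ep.onset.strftime("%Y-%m-%dT%H:%M") for ep in rec.sleep],
            "offset": [ep.offset.strftime("%Y-%m-%dT%H:%M") for ep in rec.sleep],
        }
    ).to_csv(sleep_path, index=False)
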