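"""Assembly of the 26-marker sleep and circadian rhythm panel.

Per participant the panel holds: 4 sleep summaries (MST/TST mean and SD),
8 cosinor markers (MESOR, amplitude, acrophase, CQ for step count and heart
rate), 10 nonparametric markers (L5, M10, RA, IS, IV for both signals), the
SSA-based CARE on step count, and the 3 heart-rate CCE band markers.
Upstream failures (e.g. a constant signal) propagate as explicit NaNs with
a recorded reason — never as silent zeros.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import care, cosinor, nonparametric, sleep_markers, spectral
from .wearable_io import ParticipantRecord, interpolate_missing_hr

#: canonical marker order, matching the panel layout (sleep, cosinor,
#: nonparametric, dimension reduction, wavelet band energy)
MARKER_NAMES: tuple[str, ...] = (
    "MST_Mean",
    "MST_SD",
    "TST_Mean",
    "TST_SD",
    "MESOR_SC",
    "MESOR_HR",
    "Amplitude_SC",
    "Amplitude_HR",
    "Acrophase_SC",
    "Acrophase_HR",
    "CQ_SC",
    "CQ_HR",
    "L5_SC",
    "L5_HR",
    "M10_SC",
    "M10_HR",
    "RA_SC",
    "RA_HR",
    "IS_SC",
    "IS_HR",
    "IV_SC",
    "IV_HR",
    "SSA_CARE_SC",
    "CCE_MF_HR",
    "CCE_LF_HR",
    "CCE_Ratio_HR",
)


@dataclass(frozen=True)
class MarkerConfig:
    """Configuration bundle for the full panel."""

    wavelet: spectral.WaveletConfig = field(default_factory=spectral.WaveletConfig)
    ssa: care.SsaConfig = field(default_factory=care.SsaConfig)
    bin_minutes: int = nonparametric.DEFAULT_BIN_MINUTES
    cosinor_period_minutes: float = cosinor.DEFAULT_PERIOD_MINUTES

    def config_hash(self) -> str:
        payload = {
            "omega0": self.wavelet.omega0,
            "periods": list(np.asarray(self.wavelet.periods, float)),
            "normalize": self.wavelet.normalize,
            "exclude_coi": self.wavelet.exclude_coi,
            "ssa_window": self.ssa.window_length,
            "ssa_components": self.ssa.n_components,
            "ssa_threshold": self.ssa.period_threshold,
            "bin_minutes": self.bin_minutes,
            "cosinor_period": self.cosinor_period_minutes,
        }
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
        return digest.hexdigest()[:12]


@dataclass
class MarkerVector:
    """The named 26-marker panel for one participant."""

    participant_id: str
    group: str
    values: dict[str, float]
    notes: dict[str, str] = field(default_factory=dict)  # reasons for missing markers
    covariates: dict = field(default_factory=dict)
    config_hash: str = ""

    def __post_init__(self) -> None:
        if tuple(self.values) != MARKER_NAMES:
            raise ValueError("marker vector must contain exactly the 26 named markers")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.participant_id)


def _nan_block(names: list[str], values: dict, notes: dict, reason: str) -> None:
    for name in names:
        values[name] = math.nan
        notes[name] = reason


def compute_marker_vector(
    record: ParticipantRecord, config: MarkerConfig | None = None
) -> MarkerVector:
    """Compute all 26 markers for one (wear-eligible) participant.

    Fully deterministic: identical record and config give a bit-identical
    vector.  Any upstream error marks its block NaN with the reason and the
    vector is still returned.
    """
    config = config or MarkerConfig()
    values: dict[str, float] = {name: math.nan for name in MARKER_NAMES}
    notes: dict[str, str] = {}

    hr = interpolate_missing_hr(record.hr)
    sc = record.steps

    # sleep block
    try:
        nightly = sleep_markers.main_sleep_per_night(record.sleep)
        sm = sleep_markers.compute_sleep_markers(nightly)
        values.update(
            MST_Mean=sm.mst_mean, MST_SD=sm.mst_sd, TST_Mean=sm.tst_mean, TST_SD=sm.tst_sd
        )
    except ValueError as exc:
        _nan_block(["MST_Mean", "MST_SD", "TST_Mean", "TST_SD"], values, notes, str(exc))

    # cosinor block
    for sig, suffix in ((sc, "SC"), (hr, "HR")):
        try:
            fit = cosinor.fit_cosinor(sig, config.cosinor_period_minutes)
            values[f"MESOR_{suffix}"] = fit.mesor
            values[f"Amplitude_{suffix}"] = fit.amplitude
            values[f"Acrophase_{suffix}"] = fit.acrophase_hours
            values[f"CQ_{suffix}"] = fit.cq
            if math.isnan(fit.acrophase_hours):
                notes[f"Acrophase_{suffix}"] = "zero amplitude: acrophase undefined"
        except ValueError as exc:
            _nan_block(
                [f"{m}_{suffix}" for m in ("MESOR", "Amplitude", "Acrophase", "CQ")],
                values,
                notes,
                str(exc),
            )

    # nonparametric block
    for sig, suffix in ((sc, "SC"), (hr, "HR")):
        try:
            np_markers = nonparametric.compute_nonparametric_markers(sig, config.bin_minutes)
            values[f"L5_{suffix}"] = np_markers.l5
            values[f"M10_{suffix}"] = np_markers.m10
            values[f"RA_{suffix}"] = np_markers.ra
            values[f"IS_{suffix}"] = np_markers.is_
            values[f"IV_{suffix}"] = np_markers.iv
            for short, val in (("RA", np_markers.ra), ("IS", np_markers.is_), ("IV", np_markers.iv)):
                if math.isnan(val):
                    notes[f"{short}_{suffix}"] = "degenerate (constant or all-zero) signal"
        except ValueError as exc:
            _nan_block(
                [f"{m}_{suffix}" for m in ("L5", "M10", "RA", "IS", "IV")],
                values,
                notes,
                str(exc),
            )

    # dimension-reduction block (steps only)
    try:
        care_val = care.compute_care(sc, config.ssa)
        values["SSA_CARE_SC"] = care_val
        if math.isnan(care_val):
            notes["SSA_CARE_SC"] = "zero-variance step series"
    except ValueError as exc:
        _nan_block(["SSA_CARE_SC"], values, notes, str(exc))

    # wavelet band energy block (heart rate only)
    try:
        profile = spectral.cwt_energy_profile(hr, config.wavelet)
        cce = spectral.compute_cce(profile)
        values["CCE_MF_HR"] = cce.mid_frequency
        values["CCE_LF_HR"] = cce.low_frequency
        values["CCE_Ratio_HR"] = cce.mid_low_ratio
    except ValueError as exc:
        _nan_block(["CCE_MF_HR", "CCE_LF_HR", "CCE_Ratio_HR"], values, notes, str(exc))

    ordered = {name: values[name] for name in MARKER_NAMES}
    return MarkerVector(
        participant_id=record.participant_id,
        group=record.group,
        values=ordered,
        notes=notes,
        covariates=dict(record.covariates),
        config_hash=config.config_hash(),
    )


def marker_table(
    records: list[ParticipantRecord], config: MarkerConfig | None = None
) -> pd.DataFrame:
    """Markers x participants table with id, group and covariate columns."""
    config = config or MarkerConfig()
    rows = []
    for rec in records:
        vec = compute_marker_vector(rec, config)
        row = {"participant_id": vec.participant_id, "group": vec.group}
        row.update(vec.covariates)
        row.update(vec.values)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df["participant_id"].duplicated().any():
        raise ValueError("duplicated participant ids in cohort")
    return df
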