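"""Configuration objects for simulation, signal processing and pipeline runs.

All configuration is expressed as pydantic models so that invalid settings
(negative corner frequencies, SpO2 plateaus outside the physiological range,
a sampling rate too low for the configured heart rate) are rejected at
construction time, and so that a full pipeline configuration round-trips
losslessly through JSON.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

Activity = Literal["lying", "sitting", "standing", "walking", "cycling"]

#: Tie-break order for the dominant activity of a window: more movement-prone
#: labels win ties (walking > cycling > standing > sitting > lying).
ACTIVITY_SEVERITY: tuple[str, ...] = (
    "walking",
    "cycling",
    "standing",
    "sitting",
    "lying",
)

#: Default activity schedule of the patient protocol: lying, sitting and
#: standing for 3 min each, a 6-min walking test, then 3 min of cycling.
PATIENT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("lying", 180.0),
    ("sitting", 180.0),
    ("standing", 180.0),
    ("walking", 360.0),
    ("cycling", 180.0),
)

#: Default volunteer protocol: three oxygenation levels (normoxemia, mild and
#: severe hypoxemia); at each level the subject walks, sits, stands and lies
#: for 3 min each (12 min per level).
VOLUNTEER_SCHEDULE: tuple[tuple[str, float], ...] = tuple(
    (act, 180.0)
    for _level in range(3)
    for act in ("walking", "sitting", "standing", "lying")
)

PATIENT_PLATEAUS: tuple[tuple[float, float], ...] = (
    (95.0, 180.0),
    (94.0, 180.0),
    (93.0, 180.0),
    (87.0, 360.0),
    (85.0, 180.0),
)

VOLUNTEER_PLATEAUS: tuple[tuple[float, float], ...] = (
    (97.0, 720.0),
    (88.0, 720.0),
    (82.0, 720.0),
)


class SimulationConfig(BaseModel):
    """Parameters of the synthetic two-wavelength PPG cohort generator.

    The generator encodes the true SpO2 trajectory into the red/infrared
    pulsatile amplitude ratio through the inverse of the linear calibration
    ``SpO2 = a * ROS + b``, so the configured ``true_slope_a`` and
    ``true_intercept_b`` are the ground truth the downstream pipeline should
    recover.
    """

    protocol: Literal["volunteer_hypoxemia", "patient_daily_activity"] = (
        "patient_daily_activity"
    )
    sampling_rate_hz: float = 100.0
    #: Total duration; defaults to the protocol schedule length.
    duration_s: Optional[float] = None
    #: (SpO2 level %, duration s) plateaus; defaults depend on the protocol.
    spo2_plateaus: Optional[list[tuple[float, float]]] = None
    #: Activity schedule as (activity, duration s); defaults per protocol.
    activity_schedule: Optional[list[tuple[Activity, float]]] = None
    #: Duration of the linear SpO2 ramp joining consecutive plateaus.
    ramp_s: float = 30.0

    heart_rate_bpm: float = 70.0
    heart_rate_activity_offsets: dict[str, float] = Field(
        default_factory=lambda: {
            "lying": -5.0,
            "sitting": 0.0,
            "standing": 5.0,
            "walking": 25.0,
            "cycling": 20.0,
        }
    )

    #: Baseline pulsatile fraction (AC/DC) of the infrared channel.
    perfusion_ac_over_dc: float = 0.02
    #: Ground-truth calibration line SpO2 = a * ROS + b.
    true_slope_a: float = -26.8
    true_intercept_b: float = 116.9

    #: Motion-artefact event rate per minute, per activity.
    motion_rate_per_min: dict[str, float] = Field(
        default_factory=lambda: {
            "lying": 0.2,
            "sitting": 0.3,
            "standing": 0.5,
            "walking": 6.0,
            "cycling": 1.5,
        }
    )

    #: Optical DC levels of the two channels, arbitrary units.
    dc_level_ir: float = 1000.0
    dc_level_red: float = 800.0

    ambient_offset: float = 50.0
    ambient_drift_amplitude: float = 30.0
    mains_hz: float = 50.0
    mains_amplitude: float = 5.0
    sensor_noise_sd: float = 1.0

    #: Continuous reference oximeter noise (AR(1), stationary sd, % SpO2).
    reference_noise_sd: float = 0.4
    reference_ar1_phi: float = 0.8
    #: Arterial blood-gas SaO2 noise (independent, % SaO2).
    abga_noise_sd: float = 0.5

    #: Per-subject cohort jitter (set to 0 for identical subjects).
    jitter_perfusion_rel: float = 0.25
    jitter_heart_rate_bpm: float = 8.0
    jitter_plateau_pct: float = 1.5

    seed: int = 0

    def schedule(self) -> list[tuple[str, float]]:
        if self.activity_schedule is not None:
            return [(a, float(d)) for a, d in self.activity_schedule]
        if self.protocol == "patient_daily_activity":
            return [(a, d) for a, d in PATIENT_SCHEDULE]
        return [(a, d) for a, d in VOLUNTEER_SCHEDULE]

    def plateaus(self) -> list[tuple[float, float]]:
        if self.spo2_plateaus is not None:
            return [(float(l), float(d)) for l, d in self.spo2_plateaus]
        if self.protocol == "patient_daily_activity":
            return [(l, d) for l, d in PATIENT_PLATEAUS]
        return [(l, d) for l, d in VOLUNTEER_PLATEAUS]

    def total_duration_s(self) -> float:
        if self.duration_s is not None:
            return float(self.duration_s)
        return float(sum(d for _, d in self.schedule()))

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for level, dur in self.plateaus():
            if not 70.0 <= level <= 100.0:
                raise ValueError(
                    f"SpO2 plateau level {level} outside the supported "
                    "range [70, 100]"
                )
            if dur <= 0:
                raise ValueError("plateau durations must be positive")
        if self.true_slope_a >= 0:
            raise ValueError(
                "true_slope_a must be negative: higher ROS corresponds to "
                "lower SpO2"
            )
        max_hr = self.heart_rate_bpm + max(
            self.heart_rate_activity_offsets.values(), default=0.0
        ) + self.jitter_heart_rate_bpm
        if self.sampling_rate_hz < 4.0 * max_hr / 60.0:
            raise ValueError(
                "sampling_rate_hz must be at least 4x the maximum heart "
                f"rate frequency ({max_hr / 60.0:.2f} Hz)"
            )
        if self.ramp_s < 0:
            raise ValueError("ramp_s must be non-negative")
        if self.perfusion_ac_over_dc <= 0:
            raise ValueError("perfusion_ac_over_dc must be positive")
        return self


class ProcessingParams(BaseModel):
    """Parameters of the window-level ROS/SQI processing chain."""

    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 5.0
    filter_order: int = 4
    window_s: float = 40.0
    hop_s: float = 10.0
    min_beats_per_window: int = 20
    refractory_s: float = 0.33
    sqi_threshold_pct: float = 70.0
    #: Corner of the sub-cardiac band used to estimate the ambient gain.
    ambient_band_hz: float = 0.4

    @model_validator(mode="after")
    def _check(self) -> "ProcessingParams":
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("need 0 < bandpass_low_hz < bandpass_high_hz")
        if self.window_s <= 0 or self.hop_s <= 0:
            raise ValueError("window_s and hop_s must be positive")
        if not 0 <= self.sqi_threshold_pct <= 100:
            raise ValueError("sqi_threshold_pct must lie in [0, 100]")
        return self


class EvaluationParams(BaseModel):
    """Stable-reference filtering and reference-pairing parameters."""

    #: Maximum within-window reference SpO2 range (max - min, percentage
    #: points) for a window to count as having a stable reference.
    max_reference_range_pct: float = 2.0
    #: Maximum gap between a blood-gas sample and the centre of the nearest
    #: retained window for the two to be paired.
    abga_max_gap_s: float = 30.0


class PipelineConfig(BaseModel):
    """Full configuration of a simulate-process-calibrate-evaluate run."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    processing: ProcessingParams = Field(default_factory=ProcessingParams)
    evaluation: EvaluationParams = Field(default_factory=EvaluationParams)
    n_subjects: int = 15
    seed: int = 0
    output_dir: Optional[Path] = None
    log_level: str = "INFO"


def default_patient_config(**overrides) -> SimulationConfig:
    """The default patient daily-activity cohort configuration."""
    return SimulationConfig(protocol="patient_daily_activity", **overrides)


def default_volunteer_config(**overrides) -> SimulationConfig:
    """The default volunteer stepwise-hypoxemia cohort configuration."""
    return SimulationConfig(protocol="volunteer_hypoxemia", **overrides)


def calibration_recovery_config(**overrides) -> SimulationConfig:
    """Patient cohort with low sensor noise, for calibration-recovery runs.

    Same protocol and reference-device behaviour as the default patient
    cohort, but with reduced broadband sensor noise so that the accuracy of
    the recovered calibration line is limited by the method, not by the
    simulated front-end.
    """
    overrides.setdefault("sensor_noise_sd", 0.2)
    return SimulationConfig(protocol="patient_daily_activity", **overrides)
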