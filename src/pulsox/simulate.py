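"""Synthetic two-wavelength PPG cohort generator.

Generates everything the downstream pipeline needs so it is testable without
real recordings: ground-truth SpO2 / heart-rate / activity trajectories
following the study protocols, raw red + infrared + ambient optical channels,
motion artefacts concentrated where the activity is motion-prone, and noisy
reference devices (a continuous display-rounded pulse oximeter and sparse
arterial blood-gas samples).

The central construction: the red channel's relative pulsatile amplitude is
the infrared one scaled by the target ratio of signals, ``AC/DC(red) =
ROS * AC/DC(ir)`` with ``ROS = (SpO2 - b) / a``, so that a correct
processing chain recovers the configured calibration line exactly on clean
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig

__all__ = [
    "ArtefactEvent",
    "GroundTruth",
    "PpgRecording",
    "ReferenceSeries",
    "spo2_to_ros",
    "build_truth",
    "synthesize_recording",
    "simulate_references",
    "make_cohort",
    "pulse_waveform",
]


# --------------------------------------------------------------------------
# containers


@dataclass
class ArtefactEvent:
    """A single motion-artefact transient (shared by both optical channels)."""

    t_start_s: float
    duration_s: float
    amplitude_factor: float  # multiple of the pulsatile amplitude
    freq_hz: float


@dataclass
class GroundTruth:
    """Per-sample ground truth accompanying one synthetic recording."""

    time_s: np.ndarray
    spo2_true: np.ndarray
    heart_rate_true: np.ndarray
    activity: np.ndarray  # per-sample activity label
    artefact_mask: np.ndarray  # boolean, True inside artefact transients
    artefact_events: list[ArtefactEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class PpgRecording:
    """Raw multi-channel optical time series on a uniform grid."""

    subject_id: str
    sampling_rate_hz: float
    time_s: np.ndarray
    ppg_red: np.ndarray  # 660 nm
    ppg_ir: np.ndarray  # 940 nm
    ambient: np.ndarray
    activity: np.ndarray

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class ReferenceSeries:
    """Reference devices: continuous 1-Hz oximeter plus sparse blood gases."""

    time_s: np.ndarray
    spo2_ref: np.ndarray  # integer-% display convention
    heart_rate_ref: np.ndarray
    abga_times_s: np.ndarray
    sao2_abga: np.ndarray


# --------------------------------------------------------------------------
# calibration line inversion


def spo2_to_ros(spo2, a: float, b: float):
    """Invert the calibration line ``SpO2 = a * ROS + b``.

    Parameters
    ----------
    spo2 : float or array
        Saturation in percent.
    a, b : float
        Slope (% per unit ROS, negative) and intercept (%).

    Returns
    -------
    float or ndarray
        ``(spo2 - b) / a``.
    """
    if a == 0:
        raise ValueError("degenerate calibration: slope a must be nonzero")
    return (np.asarray(spo2, dtype=float) - b) / a


# --------------------------------------------------------------------------
# pulse waveform

# Asymmetric cardiac pulse: a fast systolic upstroke and a slower, smaller
# diastolic hump, built from two Gaussians per period and normalised to zero
# mean and unit peak-to-trough.
_PHASE_GRID = np.linspace(0.0, 1.0, 2049)[:-1]


def _raw_pulse(phase: np.ndarray) -> np.ndarray:
    out = np.zeros_like(phase)
    for centre, width, amp in ((0.20, 0.07, 1.0), (0.55, 0.14, 0.40)):
        for wrap in (-1.0, 0.0, 1.0):
            out += amp * np.exp(-0.5 * ((phase - centre + wrap) / width) ** 2)
    return out


_TEMPLATE = _raw_pulse(_PHASE_GRID)
_TEMPLATE = _TEMPLATE - _TEMPLATE.mean()
_TEMPLATE = _TEMPLATE / np.ptp(_TEMPLATE)


def pulse_waveform(phase) -> np.ndarray:
    """Periodic unit-peak-to-trough, zero-mean cardiac waveform.

    ``phase`` is in cardiac cycles; the waveform has period 1.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    return np.interp(phase, _PHASE_GRID, _TEMPLATE, period=1.0)


# --------------------------------------------------------------------------
# seeded stream handling

def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Three independent deterministic streams: truth, signal, reference."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


# --------------------------------------------------------------------------
# ground truth


def build_truth(config: SimulationConfig) -> GroundTruth:
    """Build the ground-truth SpO2 / heart-rate / activity trajectories.

    SpO2 follows the configured plateaus joined by linear ramps of
    ``config.ramp_s`` (the ramp eats into the beginning of the next
    plateau). The activity schedule follows the protocol; motion-artefact
    event times are drawn from a Poisson process whose rate depends on the
    activity. Fully determined by ``config.seed``.
    """
    fs = config.sampling_rate_hz
    total = config.total_duration_s()
    schedule = config.schedule()
    plateaus = config.plateaus()
    sched_total = sum(d for _, d in schedule)
    plat_total = sum(d for _, d in plateaus)
    if total < sched_total - 1e-9:
        raise ValueError(
            f"duration_s={total:g} s is shorter than the protocol's "
            f"activity schedule ({sched_total:g} s)"
        )
    if abs(total - plat_total) > 1e-6 or abs(total - sched_total) > 1e-6:
        raise ValueError(
            "total duration, activity schedule and SpO2 plateaus must agree: "
            f"duration={total:g}, schedule={sched_total:g}, "
            f"plateaus={plat_total:g} s"
        )
    if config.ramp_s >= min(d for _, d in plateaus):
        raise ValueError("ramp_s must be shorter than every plateau")

    rng, _, _ = _streams(config.seed)
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # SpO2: plateaus + linear transition ramps
    spo2 = np.empty(n)
    start = 0.0
    prev_level = plateaus[0][0]
    for i, (level, dur) in enumerate(plateaus):
        seg = (t >= start) & (t < start + dur)
        spo2[seg] = level
        if i > 0 and config.ramp_s > 0:
            ramp = (t >= start) & (t < start + config.ramp_s)
            spo2[ramp] = prev_level + (level - prev_level) * (
                (t[ramp] - start) / config.ramp_s
            )
        start += dur
        prev_level = level
    spo2[t >= start] = prev_level

    # activity labels
    activity = np.empty(n, dtype="<U10")
    start = 0.0
    for act, dur in schedule:
        activity[(t >= start) & (t < start + dur)] = act
        start += dur
    activity[t >= start] = schedule[-1][0]

    # heart rate: per-activity step profile, smoothed to avoid abrupt
    # inter-beat-interval jumps at stage boundaries
    hr = np.full(n, config.heart_rate_bpm)
    for act, off in config.heart_rate_activity_offsets.items():
        hr[activity == act] += off
    k = max(1, int(round(20.0 * fs)))
    kernel = np.ones(k) / k
    hr = np.convolve(np.pad(hr, (k // 2, k - 1 - k // 2), mode="edge"),
                     kernel, mode="valid")

    # motion artefacts: Poisson process per activity segment
    events: list[ArtefactEvent] = []
    mask = np.zeros(n, dtype=bool)
    start = 0.0
    for act, dur in schedule:
        rate = config.motion_rate_per_min.get(act, 0.0)
        n_ev = rng.poisson(rate * dur / 60.0) if rate > 0 else 0
        for t0 in np.sort(rng.uniform(start, start + dur, n_ev)):
            ev = ArtefactEvent(
                t_start_s=float(t0),
                duration_s=float(rng.uniform(0.5, 2.0)),
                amplitude_factor=float(rng.uniform(5.0, 20.0)),
                freq_hz=float(rng.uniform(1.0, 4.0)),
            )
            events.append(ev)
            i0 = int(np.ceil(ev.t_start_s * fs))
            i1 = min(n, int(np.ceil((ev.t_start_s + ev.duration_s) * fs)))
            mask[i0:i1] = True
        start += dur

    return GroundTruth(
        time_s=t,
        spo2_true=spo2,
        heart_rate_true=hr,
        activity=activity,
        artefact_mask=mask,
        artefact_events=events,
    )


# --------------------------------------------------------------------------
# optical synthesis


def synthesize_recording(
    truth: GroundTruth,
    config: SimulationConfig,
    subject_id: str = "S00",
) -> PpgRecording:
    """Render raw red / infrared / ambient channels from ground truth.

    Signal model per sample::

        ppg_ir  = DC_ir  * (1 + p * pulse(t))          + ambient(t) + noise
        ppg_red = DC_red * (1 + p * ROS(t) * pulse(t)) + ambient(t) + noise

    with ``pulse`` a unit peak-to-trough, zero-mean periodic waveform at the
    true heart rate, ``p`` the infrared AC/DC perfusion fraction and
    ``ROS(t) = (spo2_true - b) / a``. Motion artefacts add a damped
    oscillation, correlated across the two channels (shared mechanical
    origin), scaled to 5-20x the pulsatile amplitude. The ambient addend
    (offset + slow drift + mains) is identical in all three channels and is
    recorded as the ambient channel.
    """
    fs = config.sampling_rate_hz
    n = len(truth)
    if n == 0:
        raise ValueError("empty ground truth")
    t = truth.time_s

    _, rng, _ = _streams(config.seed)

    phase = np.cumsum(truth.heart_rate_true / 60.0) / fs
    pulse = pulse_waveform(phase)
    ros = spo2_to_ros(
        truth.spo2_true, config.true_slope_a, config.true_intercept_b
    )
    p = config.perfusion_ac_over_dc

    clean_ir = config.dc_level_ir * (1.0 + p * pulse)
    clean_red = config.dc_level_red * (1.0 + p * ros * pulse)

    drift = np.zeros(n)
    # phases drawn unconditionally to keep the stream layout stable
    phases = rng.uniform(0, 2 * np.pi, 2)
    if config.ambient_drift_amplitude > 0:
        drift = config.ambient_drift_amplitude * (
            0.7 * np.sin(2 * np.pi * 0.05 * t + phases[0])
            + 0.5 * np.sin(2 * np.pi * 0.11 * t + phases[1])
        )
    mains = config.mains_amplitude * np.sin(
        2 * np.pi * config.mains_hz * t + np.pi / 4
    )
    ambient = config.ambient_offset + drift + mains

    art_ir = np.zeros(n)
    art_red = np.zeros(n)
    for ev in truth.artefact_events:
        i0 = int(np.ceil(ev.t_start_s * fs))
        i1 = min(n, int(np.ceil((ev.t_start_s + ev.duration_s) * fs)))
        if i1 <= i0:
            continue
        tau = ev.duration_s / 3.0
        tt = t[i0:i1] - ev.t_start_s
        shape = np.exp(-tt / tau) * np.sin(2 * np.pi * ev.freq_hz * tt)
        art_ir[i0:i1] += ev.amplitude_factor * p * config.dc_level_ir * shape
        art_red[i0:i1] += ev.amplitude_factor * p * config.dc_level_red * shape

    noise_red = noise_ir = 0.0
    if config.sensor_noise_sd > 0:
        noise_ir = rng.normal(0.0, config.sensor_noise_sd, n)
        noise_red = rng.normal(0.0, config.sensor_noise_sd, n)

    return PpgRecording(
        subject_id=subject_id,
        sampling_rate_hz=fs,
        time_s=t,
        ppg_red=clean_red + art_red + ambient + noise_red,
        ppg_ir=clean_ir + art_ir + ambient + noise_ir,
        ambient=ambient,
        activity=truth.activity,
    )


# --------------------------------------------------------------------------
# reference devices


def simulate_references(
    truth: GroundTruth, config: SimulationConfig
) -> ReferenceSeries:
    """Simulate the reference devices paired with one recording.

    The continuous reference is ``spo2_true`` plus AR(1) noise (autocorrelated
    at 1 Hz, stationary sd ``reference_noise_sd``), rounded to integer
    percent the way commercial oximeter displays are. Blood-gas SaO2 samples
    are taken at rest (mid sitting stage) and during cycling, with
    independent Gaussian noise of sd ``abga_noise_sd``.
    """
    _, _, rng = _streams(config.seed)
    fs = config.sampling_rate_hz
    t_end = truth.time_s[-1]
    t_ref = np.arange(0.0, t_end + 1.0 / (2 * fs), 1.0)
    spo2_at = np.interp(t_ref, truth.time_s, truth.spo2_true)
    hr_at = np.interp(t_ref, truth.time_s, truth.heart_rate_true)

    m = t_ref.size
    noise = np.zeros(m)
    sd = config.reference_noise_sd
    if sd > 0:
        phi = config.reference_ar1_phi
        innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), m)
        noise[0] = rng.normal(0.0, sd)
        for k in range(1, m):
            noise[k] = phi * noise[k - 1] + innov[k]
    spo2_ref = np.round(np.clip(spo2_at + noise, 0.0, 100.0))
    hr_ref = np.round(hr_at + rng.normal(0.0, 1.0, m))

    # blood gases: mid-sitting (rest) and mid-cycling, when present
    abga_t = []
    start = 0.0
    for act, dur in config.schedule():
        if act in ("sitting", "cycling"):
            abga_t.append(start + dur / 2.0)
        start += dur
    abga_t = np.asarray(abga_t[:2], dtype=float)
    sao2 = np.interp(abga_t, truth.time_s, truth.spo2_true)
    if config.abga_noise_sd > 0 and abga_t.size:
        sao2 = sao2 + rng.normal(0.0, config.abga_noise_sd, abga_t.size)

    return ReferenceSeries(
        time_s=t_ref,
        spo2_ref=spo2_ref,
        heart_rate_ref=hr_ref,
        abga_times_s=abga_t,
        sao2_abga=np.clip(sao2, 0.0, 100.0),
    )


# --------------------------------------------------------------------------
# cohort


def make_cohort(
    n_subjects: int, config: SimulationConfig, seed: int
) -> list[tuple[PpgRecording, ReferenceSeries, GroundTruth]]:
    """Generate a cohort of subjects with per-subject physiological jitter.

    Each subject gets a seed derived deterministically from the master seed
    plus independent jitter on perfusion, resting heart rate and plateau
    levels, so subjects differ but the whole cohort is reproducible.
    """
    if n_subjects < 2:
        raise ValueError(
            "a cohort needs at least 2 subjects (leave-one-out calibration)"
        )
    master = np.random.SeedSequence(seed)
    jitter_rng = np.random.default_rng(master.spawn(1)[0])
    subject_seeds = [
        int(c.generate_state(1)[0] % (2**31))
        for c in np.random.SeedSequence(seed + 1).spawn(n_subjects)
    ]

    cohort = []
    for i in range(n_subjects):
        jp = config.jitter_perfusion_rel
        jh = config.jitter_heart_rate_bpm
        jl = config.jitter_plateau_pct
        perfusion = config.perfusion_ac_over_dc * (
            1.0 + jitter_rng.uniform(-jp, jp)
        )
        hr = config.heart_rate_bpm + jitter_rng.uniform(-jh, jh)
        plateaus = [
            (float(np.clip(level + jitter_rng.uniform(-jl, jl), 70.0, 100.0)),
             dur)
            for level, dur in config.plateaus()
        ]
        sub_cfg = config.model_copy(
            update={
                "perfusion_ac_over_dc": perfusion,
                "heart_rate_bpm": hr,
                "spo2_plateaus": plateaus,
                "seed": subject_seeds[i],
            }
        )
        subject_id = f"S{i + 1:02d}"
        truth = build_truth(sub_cfg)
        rec = synthesize_recording(truth, sub_cfg, subject_id=subject_id)
        ref = simulate_references(truth, sub_cfg)
        cohort.append((rec, ref, truth))
    return cohort
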