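"""Window-level PPG processing: from raw channels to ROS and SQI.

The chain mirrors a conventional transmission pulse-oximetry front end:

1. ambient-light correction by regressing the recorded ambient channel out
   of each optical channel (gain estimated on the sub-cardiac band),
2. AC extraction with a zero-phase fourth-order Butterworth band-pass,
3. beat detection on the infrared AC channel (adaptive amplitude threshold
   with a refractory period),
4. cardiac-gated ensemble averaging over sliding 40-s windows, giving the
   AC amplitude (peak-to-trough of the beat template) and the DC level
   (window mean of the ambient-corrected raw channel),
5. the ratio of signals ROS = (AC_red/DC_red) / (AC_ir/DC_ir), and
6. a signal-quality index (SQI, 0-100) from red/infrared template agreement
   and rhythm regularity; windows with SQI strictly below the threshold are
   rejected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .config import ACTIVITY_SEVERITY, ProcessingParams
from .simulate import PpgRecording

__all__ = [
    "WindowEstimate",
    "TooFewBeatsError",
    "correct_ambient",
    "extract_ac",
    "detect_beats",
    "cardiac_gated_average",
    "compute_ros",
    "compute_sqi",
    "classify_window",
    "process_recording",
]


class TooFewBeatsError(ValueError):
    """Raised when a window does not contain enough beats to average."""


@dataclass
class WindowEstimate:
    """Per-window AC/DC components, ROS, SQI and rejection bookkeeping.

    Windows are half-open ``[t_start_s, t_end_s)``. ``rejected`` is True
    iff ``rejection_reason != "none"``. ``spo2_est`` is filled in once a
    calibration model has been applied; ``ref_spo2_mean`` once a continuous
    reference has been attached.
    """

    subject_id: str
    t_start_s: float
    t_end_s: float
    ac_red: float
    dc_red: float
    ac_ir: float
    dc_ir: float
    ros: float
    sqi: float
    n_beats: int
    activity: str
    rejected: bool = False
    rejection_reason: str = "none"
    spo2_est: Optional[float] = None
    spo2_est_unclamped: Optional[float] = None
    ref_spo2_mean: Optional[float] = None

    @property
    def t_center_s(self) -> float:
        return 0.5 * (self.t_start_s + self.t_end_s)


# --------------------------------------------------------------------------
# ambient correction


def correct_ambient(
    channel: np.ndarray,
    ambient: np.ndarray,
    fs: float,
    band_hz: float = 0.4,
) -> np.ndarray:
    """Subtract the ambient-light contribution from an optical channel.

    The coupling gain ``g`` is estimated by least squares between the
    sub-cardiac (< ``band_hz``) components of the ambient channel and of the
    optical channel, which protects the cardiac band from over-subtraction;
    the full ambient series scaled by ``g`` is then subtracted.
    """
    channel = np.asarray(channel, dtype=float)
    ambient = np.asarray(ambient, dtype=float)
    if channel.shape != ambient.shape:
        raise ValueError(
            f"channel and ambient lengths differ: {channel.size} vs "
            f"{ambient.size}"
        )
    if not np.any(ambient != 0.0):
        return channel.copy()
    if np.ptp(ambient) == 0.0:
        # constant ambient: a pure offset, subtract at unit gain
        return channel - ambient
    sos = sps.butter(2, band_hz, btype="low", fs=fs, output="sos")
    amb_lp = sps.sosfiltfilt(sos, ambient)
    ch_lp = sps.sosfiltfilt(sos, channel)
    amb_f = amb_lp - amb_lp.mean()
    ch_f = ch_lp - ch_lp.mean()
    denom = float(amb_f @ amb_f)
    # guard against a numerically degenerate (near-constant) regressor
    if denom <= 1e-12 * ambient.size * float(np.mean(ambient**2)):
        return channel - ambient
    g = float(amb_f @ ch_f) / denom
    return channel - g * ambient


# --------------------------------------------------------------------------
# AC extraction


def extract_ac(
    x: np.ndarray, fs: float, params: ProcessingParams
) -> np.ndarray:
    """Band-pass the pulsatile (AC) component, zero phase.

    Fourth-order Butterworth applied forward-backward (``sosfiltfilt``), so
    the passband attenuation is small and beat timing is not shifted.
    """
    x = np.asarray(x, dtype=float)
    min_len = int(np.ceil(3.0 * fs / params.bandpass_low_hz))
    if x.size < min_len:
        raise ValueError(
            f"signal of {x.size} samples is shorter than three time "
            f"constants of the {params.bandpass_low_hz:g} Hz high-pass "
            f"corner ({min_len} samples at fs={fs:g})"
        )
    sos = sps.butter(
        params.filter_order,
        [params.bandpass_low_hz, params.bandpass_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    return sps.sosfiltfilt(sos, x)


# --------------------------------------------------------------------------
# beat detection


def _block_p90(x: np.ndarray, fs: float, block_s: float = 10.0) -> np.ndarray:
    """Per-sample rolling amplitude scale: 90th percentile of ``|x|`` over
    ~10-s blocks, linearly interpolated between block centres."""
    n = x.size
    block = max(1, int(round(block_s * fs)))
    n_blocks = max(1, int(np.ceil(n / block)))
    centres = np.empty(n_blocks)
    values = np.empty(n_blocks)
    for i in range(n_blocks):
        lo, hi = i * block, min(n, (i + 1) * block)
        centres[i] = 0.5 * (lo + hi - 1)
        values[i] = np.percentile(x[lo:hi], 90.0)
    return np.interp(np.arange(n), centres, values)


def detect_beats(
    ac_ir: np.ndarray, fs: float, params: ProcessingParams
) -> np.ndarray:
    """Detect beat fiducials (systolic peaks) on the band-passed IR channel.

    Local maxima separated by at least the refractory period, retained when
    they exceed 0.4x the local (10-s) 90th-percentile amplitude. Returns a
    strictly increasing integer index array; empty for flat input.
    """
    ac_ir = np.asarray(ac_ir, dtype=float)
    if ac_ir.size == 0 or np.all(ac_ir == ac_ir[0]):
        return np.array([], dtype=int)
    distance = max(1, int(round(params.refractory_s * fs)))
    peaks, _ = sps.find_peaks(ac_ir, distance=distance)
    if peaks.size == 0:
        return peaks
    env = _block_p90(np.abs(ac_ir), fs)
    return peaks[ac_ir[peaks] >= 0.4 * env[peaks]]


# --------------------------------------------------------------------------
# cardiac-gated ensemble averaging


def _segments(
    beats: np.ndarray, start: int, stop: int
) -> list[tuple[int, int]]:
    """Beat-to-beat segments whose endpoints both fall in [start, stop)."""
    inside = beats[(beats >= start) & (beats < stop)]
    return [(int(inside[i]), int(inside[i + 1])) for i in range(inside.size - 1)]


def _resample_segments(
    x: np.ndarray, segs: Sequence[tuple[int, int]], n_pts: int
) -> np.ndarray:
    """Resample each beat segment to ``n_pts`` samples (rows = beats)."""
    grid = np.linspace(0.0, 1.0, n_pts, endpoint=False)
    out = np.empty((len(segs), n_pts))
    for i, (s, e) in enumerate(segs):
        seg = x[s:e]
        out[i] = np.interp(
            grid, np.linspace(0.0, 1.0, seg.size, endpoint=False), seg
        )
    return out


def _template_points(segs: Sequence[tuple[int, int]]) -> int:
    return max(32, int(np.median([e - s for s, e in segs])))


def _screen_beats(beat_matrix: np.ndarray) -> np.ndarray:
    """Flag outlier beats before ensemble averaging.

    A beat is dropped when its rms deviation from the element-wise median
    template exceeds both 3x the median deviation (adaptive, so uniform
    broadband noise drops nothing) and 5% of the template's peak-to-trough
    (absolute floor, so identical clean beats drop nothing). This removes
    motion-artefact transients, which dwarf the pulse, from the average.
    """
    med = np.median(beat_matrix, axis=0)
    resid = np.sqrt(np.mean((beat_matrix - med) ** 2, axis=1))
    thr = max(3.0 * float(np.median(resid)), 0.05 * float(np.ptp(med)))
    keep = resid <= thr
    if not keep.any():
        keep = np.ones(beat_matrix.shape[0], dtype=bool)
    return keep


def _ensemble_template(
    x: np.ndarray, segs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Resample beat segments to a common length, screen outlier beats,
    and average the survivors."""
    mat = _resample_segments(np.asarray(x, dtype=float), segs,
                             _template_points(segs))
    return mat[_screen_beats(mat)].mean(axis=0)


def cardiac_gated_average(
    ac: np.ndarray,
    raw: np.ndarray,
    beats: np.ndarray,
    start: int,
    stop: int,
) -> tuple[float, float, int]:
    """Ensemble-average the beats of one window.

    Parameters
    ----------
    ac : ndarray
        Band-passed (AC) channel.
    raw : ndarray
        Ambient-corrected, unfiltered channel (source of the DC level).
    beats : ndarray
        Beat fiducial indices for the whole recording.
    start, stop : int
        Half-open sample range of the window.

    Returns
    -------
    (ac_amplitude, dc_level, n_beats)
        Peak-to-trough of the ensemble beat template, mean of the raw
        channel over the window, and the number of beat segments averaged.
    """
    segs = _segments(np.asarray(beats, dtype=int), start, stop)
    if not segs:
        raise TooFewBeatsError(
            f"no complete beats in window [{start}, {stop})"
        )
    mat = _resample_segments(
        np.asarray(ac, dtype=float), segs, _template_points(segs)
    )
    keep = _screen_beats(mat)
    template = mat[keep].mean(axis=0)
    dc_level = float(np.mean(np.asarray(raw, dtype=float)[start:stop]))
    return float(np.ptp(template)), dc_level, int(keep.sum())


# --------------------------------------------------------------------------
# ratio of signals


def compute_ros(
    ac_red: float, dc_red: float, ac_ir: float, dc_ir: float
) -> float:
    """Ratio of signals: ``(AC_red/DC_red) / (AC_ir/DC_ir)``.

    Dimensionless and invariant to a common rescaling of both components of
    either channel.
    """
    if dc_red <= 0 or dc_ir <= 0:
        raise ValueError("degenerate window: non-positive DC level")
    if ac_ir <= 0:
        raise ValueError("degenerate window: non-positive infrared AC")
    return (ac_red / dc_red) / (ac_ir / dc_ir)


# --------------------------------------------------------------------------
# signal quality


def compute_sqi(
    template_red: Optional[np.ndarray],
    template_ir: Optional[np.ndarray],
    ibis_s: Sequence[float],
) -> float:
    """Signal-quality index in [0, 100] for one window.

    The product of (a) the positive part of the Pearson correlation between
    the red and infrared ensemble beat templates (both channels see the same
    cardiac pulse, so disagreement indicates non-physiological content) and
    (b) the fraction of inter-beat intervals within +/-20% of the window
    median (rhythm regularity). Fewer than two beats scores 0.
    """
    ibis = np.asarray(ibis_s, dtype=float)
    if template_red is None or template_ir is None or ibis.size < 1:
        return 0.0
    tr = np.asarray(template_red, dtype=float)
    ti = np.asarray(template_ir, dtype=float)
    if tr.size != ti.size or tr.size < 2:
        return 0.0
    sr, si = tr.std(), ti.std()
    if sr == 0.0 or si == 0.0:
        rho = 0.0
    else:
        rho = float(np.corrcoef(tr, ti)[0, 1])
    med = float(np.median(ibis))
    if med <= 0:
        return 0.0
    reg = float(np.mean(np.abs(ibis - med) <= 0.2 * med))
    return float(np.clip(100.0 * max(0.0, rho) * reg, 0.0, 100.0))


# --------------------------------------------------------------------------
# window classification


def classify_window(
    sqi: float, n_beats: int, params: ProcessingParams
) -> str:
    """Rejection reason for a window: beat count first, then SQI.

    The SQI threshold is strict — a window at exactly the threshold is
    retained ("lower than" the threshold is unreliable).
    """
    if n_beats < params.min_beats_per_window:
        return "too_few_beats"
    if sqi < params.sqi_threshold_pct:
        return "low_sqi"
    return "none"


def _dominant_activity(labels: np.ndarray) -> str:
    counts = Counter(labels.tolist())
    best = max(counts.values())
    tied = [a for a, c in counts.items() if c == best]
    for act in ACTIVITY_SEVERITY:
        if act in tied:
            return act
    return tied[0]


# --------------------------------------------------------------------------
# full chain


def process_recording(
    rec: PpgRecording, params: ProcessingParams
) -> list[WindowEstimate]:
    """Run the full chain on one recording, returning per-window estimates.

    Sliding windows of ``params.window_s`` advanced by ``params.hop_s``,
    half-open in time. Returns an empty list for recordings shorter than
    one window.
    """
    fs = rec.sampling_rate_hz
    n = len(rec)
    win = int(round(params.window_s * fs))
    hop = int(round(params.hop_s * fs))
    if n < win:
        return []

    red = correct_ambient(rec.ppg_red, rec.ambient, fs, params.ambient_band_hz)
    ir = correct_ambient(rec.ppg_ir, rec.ambient, fs, params.ambient_band_hz)
    ac_red = extract_ac(red, fs, params)
    ac_ir = extract_ac(ir, fs, params)
    beats = detect_beats(ac_ir, fs, params)

    windows: list[WindowEstimate] = []
    for start in range(0, n - win + 1, hop):
        stop = start + win
        segs = _segments(beats, start, stop)
        dc_r = float(np.mean(red[start:stop]))
        dc_i = float(np.mean(ir[start:stop]))
        ac_r = ac_i = ros = np.nan
        sqi = 0.0
        n_beats = 0
        if segs:
            # screen outlier beats on the higher-SNR infrared channel and
            # average the same surviving beats in both channels, so the
            # amplitude ratio compares like with like
            n_pts = _template_points(segs)
            mat_i = _resample_segments(ac_ir, segs, n_pts)
            mat_r = _resample_segments(ac_red, segs, n_pts)
            keep = _screen_beats(mat_i)
            n_beats = int(keep.sum())
            tmpl_i = mat_i[keep].mean(axis=0)
            tmpl_r = mat_r[keep].mean(axis=0)
            ac_r = float(np.ptp(tmpl_r))
            ac_i = float(np.ptp(tmpl_i))
            # rhythm regularity is judged on all detected beats, screened
            # or not: an irregular rhythm is a quality problem
            ibis = [(e - s) / fs for s, e in segs]
            sqi = compute_sqi(tmpl_r, tmpl_i, ibis)
            if dc_r > 0 and dc_i > 0 and ac_i > 0:
                ros = compute_ros(ac_r, dc_r, ac_i, dc_i)
            else:
                sqi = 0.0  # degenerate optics: never retain the window
        reason = classify_window(sqi, n_beats, params)
        windows.append(
            WindowEstimate(
                subject_id=rec.subject_id,
                t_start_s=start / fs,
                t_end_s=stop / fs,
                ac_red=ac_r,
                dc_red=dc_r,
                ac_ir=ac_i,
                dc_ir=dc_i,
                ros=float(ros),
                sqi=sqi,
                n_beats=n_beats,
                activity=_dominant_activity(rec.activity[start:stop]),
                rejected=reason != "none",
                rejection_reason=reason,
            )
        )
    return windows
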