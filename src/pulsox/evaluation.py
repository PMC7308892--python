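"""Accuracy evaluation of calibrated SpO2 estimates against references.

Implements the performance surface used to validate pulse oximeters:
stable-reference filtering, rejection accounting, pairing against a
continuous reference oximeter or sparse arterial blood-gas samples, and the
ISO 80601-2-61-style statistics — bias (mean error), precision (sd of
error), accuracy root-mean-square error (A_RMS, which the standard requires
to be <= 4%), Pearson correlation and Bland-Altman limits of agreement —
with walking / stationary activity stratification.

Conventions: ``precision_sd`` uses the n-1 (sample) denominator; ``arms``
is the root of the *mean* squared error (n denominator), so
``arms**2 == bias**2 + (n-1)/n * precision_sd**2`` exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dsp import WindowEstimate
from .simulate import ReferenceSeries

__all__ = [
    "EvaluationReport",
    "RejectionSummary",
    "filter_stable_reference",
    "rejection_accounting",
    "pair_with_reference",
    "compute_accuracy_stats",
    "stratify",
    "format_table",
]

PAIR_COLUMNS = [
    "subject_id",
    "t_window",
    "spo2_est",
    "spo2_ref",
    "activity",
    "reference_kind",
]


@dataclass
class RejectionSummary:
    n_total: int
    n_retained: int
    rejection_rate_pct: float
    by_reason: dict[str, int] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Agreement statistics for one set of (estimate, reference) pairs."""

    n_pairs: int
    bias: float
    precision_sd: float
    arms: float
    pearson_r: float
    pearson_p: float
    bland_altman: tuple[float, float, float]  # (mean_diff, loa_low, loa_high)
    rejection_rate_pct: float = float("nan")
    rejection_by_reason: dict[str, int] = field(default_factory=dict)
    strata: dict[str, "EvaluationReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        def _clean(obj):
            if isinstance(obj, float) and math.isnan(obj):
                return None
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        kwargs.setdefault("indent", 2)
        return json.dumps(_clean(self.to_dict()), **kwargs)


# --------------------------------------------------------------------------
# stable-reference filtering


def _window_reference(
    ref: ReferenceSeries, t_start: float, t_end: float
) -> np.ndarray:
    sel = (ref.time_s >= t_start) & (ref.time_s < t_end)
    return np.asarray(ref.spo2_ref)[sel]


def filter_stable_reference(
    windows: list[WindowEstimate],
    ref: ReferenceSeries,
    max_range_pct: float = 2.0,
) -> list[WindowEstimate]:
    """Discard windows whose reference SpO2 was not stable.

    A window is flagged ``unstable_reference`` when the continuous-reference
    range (max - min) inside it exceeds ``max_range_pct`` percentage points,
    or when reference samples are missing from the window. Windows already
    rejected for signal reasons keep their original reason. The window-mean
    reference of surviving windows is cached on ``ref_spo2_mean``.
    """
    for w in windows:
        vals = _window_reference(ref, w.t_start_s, w.t_end_s)
        expected = int(math.floor(w.t_end_s - w.t_start_s))  # 1-Hz reference
        complete = vals.size >= expected and not np.any(np.isnan(vals))
        if complete:
            w.ref_spo2_mean = float(np.mean(vals))
        if w.rejected:
            continue
        if not complete or float(np.ptp(vals)) > max_range_pct:
            w.rejected = True
            w.rejection_reason = "unstable_reference"
    return windows


# --------------------------------------------------------------------------
# rejection accounting


def rejection_accounting(windows: list[WindowEstimate]) -> RejectionSummary:
    """Tally retained vs rejected windows and the per-reason breakdown."""
    n_total = len(windows)
    if n_total == 0:
        raise ValueError("rejection rate undefined: no windows")
    n_retained = sum(1 for w in windows if not w.rejected)
    by_reason: dict[str, int] = {}
    for w in windows:
        if w.rejected:
            by_reason[w.rejection_reason] = (
                by_reason.get(w.rejection_reason, 0) + 1
            )
    return RejectionSummary(
        n_total=n_total,
        n_retained=n_retained,
        rejection_rate_pct=100.0 * (n_total - n_retained) / n_total,
        by_reason=by_reason,
    )


# --------------------------------------------------------------------------
# pairing


def pair_with_reference(
    windows: list[WindowEstimate],
    ref: ReferenceSeries,
    kind: str = "continuous",
    max_gap_s: float = 30.0,
) -> pd.DataFrame:
    """Pair retained, calibrated windows with a reference.

    ``continuous``: each retained window against the window-mean continuous
    reference. ``abga``: each blood-gas sample against the nearest retained
    window whose centre lies within ``max_gap_s``; samples with no such
    window are dropped.
    """
    retained = [
        w for w in windows if not w.rejected and w.spo2_est is not None
    ]
    rows = []
    if kind == "continuous":
        for w in retained:
            ref_mean = w.ref_spo2_mean
            if ref_mean is None:
                vals = _window_reference(ref, w.t_start_s, w.t_end_s)
                if vals.size == 0:
                    continue
                ref_mean = float(np.mean(vals))
            rows.append(
                (w.subject_id, w.t_center_s, w.spo2_est, ref_mean,
                 w.activity, "continuous")
            )
    elif kind == "abga":
        centres = np.array([w.t_center_s for w in retained])
        for t_abga, sao2 in zip(ref.abga_times_s, ref.sao2_abga):
            if centres.size == 0:
                break
            j = int(np.argmin(np.abs(centres - t_abga)))
            if abs(centres[j] - t_abga) > max_gap_s:
                continue
            w = retained[j]
            rows.append(
                (w.subject_id, w.t_center_s, w.spo2_est, float(sao2),
                 w.activity, "abga")
            )
    else:
        raise ValueError(f"unknown reference kind: {kind!r}")
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


# --------------------------------------------------------------------------
# statistics


def compute_accuracy_stats(pairs: pd.DataFrame) -> EvaluationReport:
    """ISO-style agreement statistics for a set of paired measurements.

    ``bias`` is the mean of estimate minus reference; ``precision_sd`` its
    sample sd (n-1); ``arms`` the root-mean-square error; Bland-Altman
    limits are mean difference +/- 1.96 sd.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    d = pairs["spo2_est"].to_numpy(float) - pairs["spo2_ref"].to_numpy(float)
    n = d.size
    bias = float(d.mean())
    arms = float(np.sqrt(np.mean(d**2)))
    precision_sd = float(d.std(ddof=1)) if n > 1 else float("nan")

    r = p = float("nan")
    if n > 1:
        est = pairs["spo2_est"].to_numpy(float)
        ref = pairs["spo2_ref"].to_numpy(float)
        if np.ptp(est) == 0.0 or np.ptp(ref) == 0.0:
            warnings.warn(
                "Pearson r undefined: zero variance in one series",
                stacklevel=2,
            )
        else:
            r, p = (float(v) for v in stats.pearsonr(est, ref))

    sd_ba = float(d.std(ddof=1)) if n > 1 else 0.0
    ba = (bias, bias - 1.96 * sd_ba, bias + 1.96 * sd_ba)
    return EvaluationReport(
        n_pairs=int(n),
        bias=bias,
        precision_sd=precision_sd,
        arms=arms,
        pearson_r=r,
        pearson_p=p,
        bland_altman=ba,
    )


# --------------------------------------------------------------------------
# stratification


def _group_mask(pairs: pd.DataFrame, group: str) -> pd.Series:
    if group == "overall":
        return pd.Series(True, index=pairs.index)
    if group == "walking":
        return pairs["activity"] == "walking"
    if group == "stationary":
        return pairs["activity"] != "walking"
    raise ValueError(f"unknown group: {group!r}")


def stratify(
    pairs: pd.DataFrame,
    windows: list[WindowEstimate] | None = None,
) -> dict[str, EvaluationReport]:
    """Per-activity-group reports: overall, walking, stationary.

    Walking is the walking activity alone; stationary pools every other
    activity. Groups with no pairs are omitted. When the window list is
    supplied, each group's rejection rate is computed from that group's own
    windows (per-stratum denominator).
    """
    out: dict[str, EvaluationReport] = {}
    for group in ("overall", "walking", "stationary"):
        sub = pairs[_group_mask(pairs, group)]
        if len(sub) == 0:
            continue
        rep = compute_accuracy_stats(sub)
        if windows is not None:
            if group == "overall":
                wins = windows
            elif group == "walking":
                wins = [w for w in windows if w.activity == "walking"]
            else:
                wins = [w for w in windows if w.activity != "walking"]
            if wins:
                summ = rejection_accounting(wins)
                rep.rejection_rate_pct = summ.rejection_rate_pct
                rep.rejection_by_reason = summ.by_reason
        out[group] = rep
    return out


# --------------------------------------------------------------------------
# report writer


def _fmt(x: float, nd: int = 1) -> str:
    return "-" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.{nd}f}"


def format_table(strata: dict[str, EvaluationReport]) -> str:
    """Human-readable summary table (rounded for display only).

    Rows: error (bias and sd), Pearson r, A_RMS, rejection rate; columns:
    overall / walking / stationary.
    """
    groups = [g for g in ("overall", "walking", "stationary") if g in strata]
    header = ["", *[g.capitalize() for g in groups]]
    rows = [
        ["n pairs", *[str(strata[g].n_pairs) for g in groups]],
        [
            "Error (%)",
            *[
                f"{_fmt(strata[g].bias)} ({_fmt(strata[g].precision_sd)})"
                for g in groups
            ],
        ],
        ["r", *[_fmt(strata[g].pearson_r, 2) for g in groups]],
        ["A_RMS (%)", *[_fmt(strata[g].arms, 2) for g in groups]],
        [
            "Rejection Rate (%)",
            *[_fmt(strata[g].rejection_rate_pct) for g in groups],
        ],
    ]
    widths = [
        max(len(r[i]) for r in [header, *rows]) for i in range(len(header))
    ]
    lines = []
    for r in [header, *rows]:
        lines.append(
            "  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip()
        )
    return "\n".join(lines)
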