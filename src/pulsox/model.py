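"""Model/Results interface for the leave-one-out oximeter calibration.

`OximeterCalibration` is constructed from window-level (ROS, reference SpO2)
pairs — typically the retained windows of a processed cohort — and its
``fit()`` returns an `OximeterCalibrationResults` carrying the per-subject
leave-one-out lines, the coefficient summary across subjects, prediction,
and a text ``summary()``.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .calibration import (
    CohortCalibration,
    apply_calibration,
    loo_calibrate,
)
from .dsp import WindowEstimate

__all__ = ["OximeterCalibration", "OximeterCalibrationResults"]


class OximeterCalibration:
    """Leave-one-out linear calibration of ROS against reference SpO2.

    Parameters
    ----------
    data : DataFrame
        One row per retained window, with columns ``subject_id``, ``ros``
        and ``spo2_ref``.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"subject_id", "ros", "spo2_ref"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        data = data.dropna(subset=["ros", "spo2_ref"])
        if data.empty:
            raise ValueError("no usable (ros, spo2_ref) pairs")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OximeterCalibration":
        return cls(df)

    @classmethod
    def from_windows(
        cls, windows: Iterable[WindowEstimate]
    ) -> "OximeterCalibration":
        """Build from processed windows: retained ones with a stable
        window-mean reference attached."""
        rows = [
            (w.subject_id, w.ros, w.ref_spo2_mean)
            for w in windows
            if not w.rejected
            and np.isfinite(w.ros)
            and w.ref_spo2_mean is not None
        ]
        return cls(
            pd.DataFrame(rows, columns=["subject_id", "ros", "spo2_ref"])
        )

    def fit(self) -> "OximeterCalibrationResults":
        """Fit one OLS line per held-out subject on all other subjects."""
        pairs_by_subject = {
            str(s): list(zip(g["ros"], g["spo2_ref"]))
            for s, g in self.data.groupby("subject_id", sort=True)
        }
        cohort = loo_calibrate(pairs_by_subject)
        return OximeterCalibrationResults(self, cohort)


class OximeterCalibrationResults:
    """Fitted leave-one-out calibration for a cohort."""

    def __init__(self, model: OximeterCalibration, cohort: CohortCalibration):
        self.model = model
        self.cohort = cohort

    @property
    def per_subject(self) -> pd.DataFrame:
        """One row per subject: its leave-one-out coefficients."""
        rows = {
            s: {
                "a": m.a,
                "b": m.b,
                "n_points": m.n_points,
                "residual_sd": m.residual_sd,
            }
            for s, m in self.cohort.per_subject_models.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis(
            "subject_id"
        )

    @property
    def params(self) -> pd.Series:
        """Mean slope and intercept across the leave-one-out models."""
        s = self.cohort.coefficient_summary
        return pd.Series({"a": s["a_mean"], "b": s["b_mean"]})

    @property
    def params_sd(self) -> pd.Series:
        """Sample sd (n-1) of the coefficients across subjects."""
        s = self.cohort.coefficient_summary
        return pd.Series({"a": s["a_sd"], "b": s["b_sd"]})

    def predict(self, ros, subject: Optional[str] = None):
        """Map ROS to SpO2 with a subject's model (or the mean line)."""
        if subject is not None:
            model = self.cohort.per_subject_models[subject]
            return apply_calibration(ros, model)
        p = self.params
        return p["a"] * np.asarray(ros, dtype=float) + p["b"]

    def apply_to_windows(
        self, windows: Iterable[WindowEstimate]
    ) -> list[WindowEstimate]:
        """Fill ``spo2_est`` on retained windows using each subject's own
        leave-one-out line; the reported value is clamped to [0, 100]."""
        windows = list(windows)
        for w in windows:
            if w.rejected or not np.isfinite(w.ros):
                continue
            m = self.cohort.per_subject_models.get(w.subject_id)
            if m is None:
                continue
            raw = float(apply_calibration(w.ros, m))
            w.spo2_est_unclamped = raw
            w.spo2_est = float(np.clip(raw, 0.0, 100.0))
        return windows

    def summary(self) -> str:
        """Text summary of the fitted calibration."""
        s = self.cohort.coefficient_summary
        lines = [
            "Leave-one-out ROS -> SpO2 calibration",
            "=" * 45,
            f"subjects:        {s['n_subjects']}",
            f"pairs:           {len(self.model.data)}",
            f"slope a [%/ROS]: {s['a_mean']: .3f} +/- {s['a_sd']:.3f}",
            f"intercept b [%]: {s['b_mean']: .3f} +/- {s['b_sd']:.3f}",
            "",
            "Per-subject models (each fitted excluding that subject):",
            self.per_subject.to_string(float_format=lambda v: f"{v: .3f}"),
        ]
        return "\n".join(lines)
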