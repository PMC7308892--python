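"""Linear ROS -> SpO2 calibration with leave-one-out cross-fitting.

A single line ``SpO2 = a * ROS + b`` maps the ratio of signals onto
saturation. To avoid self-calibration bias, each subject's coefficients are
fitted on the pooled window/reference pairs of *all other* subjects and
applied only to that subject (leave-one-out, LOO). The spread of the
coefficients across the LOO models summarises how stable the calibration is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "CohortCalibration",
    "DegenerateDesignError",
    "fit_calibration",
    "apply_calibration",
    "loo_calibrate",
]


class DegenerateDesignError(ValueError):
    """Raised when the ROS values do not span a fittable design."""


@dataclass
class CalibrationModel:
    """One fitted calibration line with provenance."""

    a: float  # slope, % per unit ROS
    b: float  # intercept, %
    n_points: int
    subjects_used: list[str] = field(default_factory=list)
    residual_sd: float = float("nan")  # % SpO2, n-2 denominator


@dataclass
class CohortCalibration:
    """Per-subject leave-one-out models and their coefficient summary."""

    per_subject_models: dict[str, CalibrationModel]

    @property
    def a_values(self) -> np.ndarray:
        return np.array([m.a for m in self.per_subject_models.values()])

    @property
    def b_values(self) -> np.ndarray:
        return np.array([m.b for m in self.per_subject_models.values()])

    @property
    def coefficient_summary(self) -> dict[str, float]:
        """Mean and sample sd (n-1) of a and b across the LOO models."""
        a, b = self.a_values, self.b_values
        ddof = 1 if a.size > 1 else 0
        return {
            "a_mean": float(a.mean()),
            "a_sd": float(a.std(ddof=ddof)),
            "b_mean": float(b.mean()),
            "b_sd": float(b.std(ddof=ddof)),
            "n_subjects": int(a.size),
        }


def fit_calibration(
    pairs: Sequence[tuple[float, float]],
    subjects_used: Sequence[str] = (),
) -> CalibrationModel:
    """Ordinary least squares of reference SpO2 on ROS.

    Parameters
    ----------
    pairs : sequence of (ros, reference_spo2)
        Retained window-level measurements.

    Raises
    ------
    DegenerateDesignError
        Fewer than two pairs, or all ROS values identical.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise DegenerateDesignError("need at least two (ros, spo2) pairs")
    ros, spo2 = arr[:, 0], arr[:, 1]
    if np.ptp(ros) == 0.0:
        raise DegenerateDesignError("all ROS values identical; slope undefined")
    res = stats.linregress(ros, spo2)
    n = ros.size
    resid = spo2 - (res.slope * ros + res.intercept)
    residual_sd = (
        float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else float("nan")
    )
    return CalibrationModel(
        a=float(res.slope),
        b=float(res.intercept),
        n_points=int(n),
        subjects_used=list(subjects_used),
        residual_sd=residual_sd,
    )


def apply_calibration(ros, model: CalibrationModel):
    """Evaluate the calibration line, ``a * ros + b`` (unclamped).

    Clamping to the reportable [0, 100] % range is a display concern and is
    applied where estimates are written out, so the raw value stays
    available for analysis.
    """
    return model.a * np.asarray(ros, dtype=float) + model.b


def loo_calibrate(
    pairs_by_subject: Mapping[str, Sequence[tuple[float, float]]],
) -> CohortCalibration:
    """Fit one leave-one-out model per subject.

    For subject ``i`` the fit pools the pairs of every subject except ``i``;
    the resulting model is the one applied to subject ``i``.
    """
    subjects = list(pairs_by_subject)
    if len(subjects) < 2:
        raise ValueError("leave-one-out calibration needs at least 2 subjects")
    models: dict[str, CalibrationModel] = {}
    for held_out in subjects:
        pooled: list[tuple[float, float]] = []
        used = []
        for s in subjects:
            if s == held_out:
                continue
            pooled.extend(pairs_by_subject[s])
            used.append(s)
        try:
            models[held_out] = fit_calibration(pooled, subjects_used=used)
        except DegenerateDesignError as exc:
            raise DegenerateDesignError(
                f"excluding subject {held_out!r} leaves a degenerate "
                f"calibration design: {exc}"
            ) from exc
    return CohortCalibration(per_subject_models=models)
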