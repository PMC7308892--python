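"""Evaluation statistics, stable-reference filtering, pairing, strata."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsox import (
    compute_accuracy_stats,
    filter_stable_reference,
    pair_with_reference,
    rejection_accounting,
    stratify,
)
from pulsox.dsp import WindowEstimate
from pulsox.evaluation import format_table
from pulsox.simulate import ReferenceSeries


def _window(sid="s1", t0=0.0, ros=1.0, sqi=90.0, activity="sitting",
            rejected=False, reason="none", spo2_est=None):
    return WindowEstimate(
        subject_id=sid,
        t_start_s=t0,
        t_end_s=t0 + 40.0,
        ac_red=1.0,
        dc_red=100.0,
        ac_ir=1.0,
        dc_ir=100.0,
        ros=ros,
        sqi=sqi,
        n_beats=40,
        activity=activity,
        rejected=rejected,
        rejection_reason=reason,
        spo2_est=spo2_est,
    )


def _reference(spo2_values, dt=1.0):
    t = np.arange(len(spo2_values), dtype=float) * dt
    return ReferenceSeries(
        time_s=t,
        spo2_ref=np.asarray(spo2_values, dtype=float),
        heart_rate_ref=np.full(t.size, 70.0),
        abga_times_s=np.array([]),
        sao2_abga=np.array([]),
    )


def _pairs(est, ref, activity=None):
    n = len(est)
    return pd.DataFrame(
        {
            "subject_id": ["s1"] * n,
            "t_window": np.arange(n, dtype=float),
            "spo2_est": np.asarray(est, dtype=float),
            "spo2_ref": np.asarray(ref, dtype=float),
            "activity": activity or ["sitting"] * n,
            "reference_kind": ["continuous"] * n,
        }
    )


class TestFilterStableReference:
    def test_constant_reference_passes(self):
        wins = [_window(t0=0.0), _window(t0=40.0)]
        ref = _reference([92.0] * 100)
        out = filter_stable_reference(wins, ref, 2.0)
        assert all(not w.rejected for w in out)
        assert out[0].ref_spo2_mean == pytest.approx(92.0)

    def test_ramp_window_discarded(self):
        # 85 -> 92 ramp inside the window: range 7 > 2
        vals = list(np.linspace(85, 92, 50)) + [92.0] * 50
        wins = [_window(t0=0.0)]
        out = filter_stable_reference(wins, _reference(vals), 2.0)
        assert out[0].rejected
        assert out[0].rejection_reason == "unstable_reference"

    def test_infinite_threshold_disables_filter(self):
        vals = list(np.linspace(80, 100, 100))
        wins = [_window(t0=0.0)]
        out = filter_stable_reference(wins, _reference(vals), math.inf)
        assert not out[0].rejected

    def test_missing_coverage_discarded(self):
        wins = [_window(t0=0.0)]
        out = filter_stable_reference(wins, _reference([92.0] * 20), 2.0)
        assert out[0].rejection_reason == "unstable_reference"

    def test_prior_rejection_reason_kept(self):
        wins = [_window(rejected=True, reason="low_sqi")]
        vals = list(np.linspace(80, 100, 100))
        out = filter_stable_reference(wins, _reference(vals), 2.0)
        assert out[0].rejection_reason == "low_sqi"


class TestRejectionAccounting:
    def test_sqi_filter_partition(self):
        # 36 candidate windows, 12 below the SQI threshold -> 24 retained
        wins = [_window(t0=40.0 * i) for i in range(24)] + [
            _window(t0=40.0 * (24 + i), sqi=30.0, rejected=True,
                    reason="low_sqi")
            for i in range(12)
        ]
        summ = rejection_accounting(wins)
        assert summ.n_total == 36
        assert summ.n_retained == 24
        assert summ.by_reason == {"low_sqi": 12}
        assert summ.rejection_rate_pct == pytest.approx(100 * 12 / 36)

    def test_extremes(self):
        all_kept = [_window(t0=40.0 * i) for i in range(5)]
        assert rejection_accounting(all_kept).rejection_rate_pct == 0.0
        all_rej = [
            _window(t0=40.0 * i, rejected=True, reason="low_sqi")
            for i in range(5)
        ]
        assert rejection_accounting(all_rej).rejection_rate_pct == 100.0

    def test_empty_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            rejection_accounting([])


class TestPairWithReference:
    def test_continuous_pairing_is_bijective_on_retained(self):
        wins = [
            _window(t0=0.0, spo2_est=91.0),
            _window(t0=40.0, spo2_est=92.0),
            _window(t0=80.0, spo2_est=90.0, rejected=True, reason="low_sqi"),
        ]
        ref = _reference([92.0] * 200)
        pairs = pair_with_reference(wins, ref, "continuous")
        assert len(pairs) == 2
        assert list(pairs["spo2_ref"]) == [92.0, 92.0]

    def test_abga_pairs_within_gap(self):
        wins = [_window(t0=0.0, spo2_est=91.0)]  # centre 20 s
        ref = _reference([92.0] * 100)
        ref.abga_times_s = np.array([30.0, 300.0])
        ref.sao2_abga = np.array([93.0, 85.0])
        pairs = pair_with_reference(wins, ref, "abga", max_gap_s=30.0)
        assert len(pairs) == 1  # the distant sample is dropped
        assert pairs.loc[0, "spo2_ref"] == 93.0

    def test_abga_sample_near_only_rejected_windows_dropped(self):
        wins = [
            _window(t0=0.0, spo2_est=91.0, rejected=True, reason="low_sqi")
        ]
        ref = _reference([92.0] * 100)
        ref.abga_times_s = np.array([20.0])
        ref.sao2_abga = np.array([93.0])
        assert len(pair_with_reference(wins, ref, "abga")) == 0


class TestComputeAccuracyStats:
    def test_perfect_agreement(self):
        rep = compute_accuracy_stats(_pairs([90, 92, 94], [90, 92, 94]))
        assert rep.bias == 0.0
        assert rep.arms == 0.0
        assert rep.bland_altman == (0.0, 0.0, 0.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_symmetric_errors(self):
        rep = compute_accuracy_stats(_pairs([92, 88], [90, 90]))
        assert rep.bias == 0.0
        assert rep.arms == pytest.approx(2.0)

    def test_arms_identity(self):
        rng = np.random.default_rng(9)
        est = rng.uniform(80, 100, 50)
        ref = est + rng.normal(0.5, 2.0, 50)
        rep = compute_accuracy_stats(_pairs(est, ref))
        n = rep.n_pairs
        lhs = rep.arms**2
        rhs = rep.bias**2 + (n - 1) / n * rep.precision_sd**2
        assert lhs == pytest.approx(rhs, rel=1e-10)
        assert rep.arms >= abs(rep.bias)

    def test_zero_variance_signalled(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = compute_accuracy_stats(_pairs([90, 90], [88, 92]))
        assert math.isnan(rep.pearson_r)

    def test_brute_force_oracle_equivalence(self):
        # every statistic re-derived by definition with plain Python sums
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            est = rng.uniform(80, 100, n)
            ref = rng.uniform(80, 100, n)
            rep = compute_accuracy_stats(_pairs(est, ref))
            d = [float(e) - float(r) for e, r in zip(est, ref)]
            bias = sum(d) / n
            arms = math.sqrt(sum(x * x for x in d) / n)
            sd = math.sqrt(sum((x - bias) ** 2 for x in d) / (n - 1))
            me, mr = sum(est) / n, sum(ref) / n
            cov = sum((e - me) * (r - mr) for e, r in zip(est, ref))
            r_num = cov / math.sqrt(
                sum((e - me) ** 2 for e in est)
                * sum((r - mr) ** 2 for r in ref)
            )
            assert rep.bias == pytest.approx(bias, abs=1e-12)
            assert rep.arms == pytest.approx(arms, abs=1e-12)
            assert rep.precision_sd == pytest.approx(sd, abs=1e-12)
            assert rep.pearson_r == pytest.approx(r_num, abs=1e-12)
            assert rep.bland_altman[1] == pytest.approx(
                bias - 1.96 * sd, abs=1e-12
            )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(70, 100), st.floats(70, 100)),
            min_size=2,
            max_size=20,
        )
    )
    def test_arms_identity_property(self, values):
        est = [v[0] for v in values]
        ref = [v[1] for v in values]
        rep = compute_accuracy_stats(_pairs(est, ref))
        n = rep.n_pairs
        assert rep.arms**2 == pytest.approx(
            rep.bias**2 + (n - 1) / n * rep.precision_sd**2, abs=1e-8
        )

    def test_bland_altman_gaussian_coverage(self):
        rng = np.random.default_rng(14)
        n = 20000
        ref = rng.uniform(80, 100, n)
        est = ref + rng.normal(0.3, 1.5, n)
        rep = compute_accuracy_stats(_pairs(est, ref))
        d = est - ref
        inside = np.mean(
            (d >= rep.bland_altman[1]) & (d <= rep.bland_altman[2])
        )
        assert 0.94 <= inside <= 0.96


class TestStratify:
    def test_all_walking_leaves_stationary_absent(self):
        pairs = _pairs([90, 91], [90, 90], activity=["walking", "walking"])
        strata = stratify(pairs)
        assert "stationary" not in strata
        assert strata["walking"].n_pairs == 2

    def test_partition_counts(self):
        pairs = _pairs(
            [90, 91, 92, 93],
            [90, 90, 90, 90],
            activity=["walking", "sitting", "cycling", "lying"],
        )
        strata = stratify(pairs)
        assert (
            strata["overall"].n_pairs
            == strata["walking"].n_pairs + strata["stationary"].n_pairs
        )

    def test_per_stratum_rejection_rates(self):
        wins = [
            _window(t0=0.0, activity="walking", rejected=True,
                    reason="low_sqi"),
            _window(t0=40.0, activity="walking", spo2_est=91.0),
            _window(t0=80.0, activity="sitting", spo2_est=91.0),
            _window(t0=120.0, activity="sitting", spo2_est=91.0),
        ]
        pairs = _pairs(
            [91, 91, 91], [90, 90, 90],
            activity=["walking", "sitting", "sitting"],
        )
        strata = stratify(pairs, wins)
        assert strata["walking"].rejection_rate_pct == pytest.approx(50.0)
        assert strata["stationary"].rejection_rate_pct == pytest.approx(0.0)

    def test_cohort_walking_rejection_exceeds_stationary(self, patient_run):
        # artefacts concentrate in walking, so its rejection rate is higher
        strata = patient_run.report.strata
        assert (
            strata["walking"].rejection_rate_pct
            > strata["stationary"].rejection_rate_pct
        )


def test_format_table_layout(patient_run):
    table = format_table(
        {"overall": patient_run.report, **patient_run.report.strata}
    )
    for label in ("Error (%)", "A_RMS (%)", "Rejection Rate (%)", "Walking"):
        assert label in table


def test_report_json_round_trip(patient_run):
    import json

    payload = json.loads(patient_run.report.to_json())
    assert payload["n_pairs"] == patient_run.report.n_pairs
    assert "walking" in payload["strata"]
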