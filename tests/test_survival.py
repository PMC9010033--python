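import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from coalescekit.data_io import ExposureLedger, OutcomeTable
from coalescekit.survival import (
    CountingProcessTable,
    breslow_loglik,
    build_counting_process,
    fit_cox_tv,
    prevalence_filter,
    run_antibiotic_panel,
)
from coalescekit.synthetic import simulate_exposure_cohort


def make_ledger(entries):
    rows = [{"patient_id": p, "drug": d, "day": day} for p, d, day in entries]
    return ExposureLedger(pd.DataFrame(rows, columns=["patient_id", "drug", "day"]))


def make_outcomes(recovery, death=None):
    rows = [
        {
            "patient_id": p,
            "recovery_day": r,
            "death_day": (death or {}).get(p, np.nan),
            "infection_pre": False,
            "infection_post90": False,
        }
        for p, r in recovery.items()
    ]
    return OutcomeTable(pd.DataFrame(rows))


def make_calls(event_days, patients):
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p,
                "coalesced": p in event_days,
                "event_day": event_days.get(p, np.nan),
                "eligible": True,
            }
        )
    return pd.DataFrame(rows)


class TestPrevalenceFilter:
    def _cohort_ledger(self, n_receiving, n_patients=100):
        entries = [(f"p{i}", "drug", 1) for i in range(n_receiving)]
        entries.append((f"p{n_patients - 1}", "other", 1))
        return make_ledger(entries), n_patients

    def test_boundary_exactly_15_percent_excluded(self):
        ledger, n = self._cohort_ledger(15)
        assert "drug" not in prevalence_filter(ledger, n)

    def test_16_percent_included(self):
        ledger, n = self._cohort_ledger(16)
        assert "drug" in prevalence_filter(ledger, n)

    def test_universal_drugs_all_retained(self):
        entries = [(f"p{i}", d, 0) for i in range(10) for d in ("a", "b")]
        ledger = make_ledger(entries)
        assert prevalence_filter(ledger, 10) == ["a", "b"]


class TestCountingProcess:
    def test_hand_constructed_cumulative_path(self):
        """Therapy days {2,3,5}, event day 6: covariate path 0,0,1,2,2,3."""
        ledger = make_ledger([("p1", "cefepime", 2), ("p1", "cefepime", 3), ("p1", "cefepime", 5)])
        calls = make_calls({"p1": 6}, ["p1"])
        outcomes = make_outcomes({"p1": 20})
        cp = build_counting_process(ledger, calls, outcomes, encoding="cumulative")
        rows = cp.rows.sort_values("start")
        path = []
        for _, r in rows.iterrows():
            path.extend([r["cefepime"]] * int(r["stop"] - r["start"]))
        assert path == [0, 0, 1, 2, 2, 3]
        assert rows.iloc[-1]["event"] and rows.iloc[-1]["stop"] == 6

    def test_any_encoding_switches_on_and_stays(self):
        ledger = make_ledger([("p1", "drug", 4)])
        calls = make_calls({}, ["p1"])
        outcomes = make_outcomes({"p1": 10})
        cp = build_counting_process(ledger, calls, outcomes, encoding="any")
        rows = cp.rows.sort_values("start")
        assert rows["drug"].tolist() == [0, 1]
        # the day-4 dose switches the indicator on for the interval (4, 5]
        assert rows.iloc[1]["start"] == 4

    def test_never_exposed_single_row(self):
        ledger = make_ledger([("p2", "drug", 1)])
        calls = make_calls({}, ["p1"])
        outcomes = make_outcomes({"p1": 15})
        cp = build_counting_process(ledger, calls, outcomes, drugs=["drug"])
        p1 = cp.rows[cp.rows["patient_id"] == "p1"]
        assert len(p1) == 1
        assert p1.iloc[0]["drug"] == 0
        assert (p1.iloc[0]["start"], p1.iloc[0]["stop"]) == (0, 15)

    def test_event_day_zero_rejected(self):
        ledger = make_ledger([("p1", "drug", 1)])
        calls = make_calls({"p1": 0}, ["p1"])
        outcomes = make_outcomes({"p1": 15})
        with pytest.raises(ValueError, match="at-risk"):
            build_counting_process(ledger, calls, outcomes)

    def test_event_after_censoring_rejected(self):
        ledger = make_ledger([("p1", "drug", 1)])
        calls = make_calls({"p1": 20}, ["p1"])
        outcomes = make_outcomes({"p1": 15})
        with pytest.raises(ValueError, match="censor"):
            build_counting_process(ledger, calls, outcomes)

    def test_death_censors_before_recovery(self):
        ledger = make_ledger([("p1", "drug", 1)])
        calls = make_calls({}, ["p1"])
        outcomes = make_outcomes({"p1": 30}, death={"p1": 12})
        cp = build_counting_process(ledger, calls, outcomes)
        assert cp.rows["stop"].max() == 12

    def test_immortal_time_shift_property(self):
        """Delaying first exposure never increases the cumulative covariate."""
        outcomes = make_outcomes({"p1": 20})
        calls = make_calls({"p1": 15}, ["p1"])
        for shift in range(0, 5):
            days = [(d + shift) for d in (2, 3, 5)]
            ledger = make_ledger([("p1", "drug", d) for d in days])
            cp = build_counting_process(ledger, calls, outcomes)
            row = cp.rows.sort_values("start").iloc[-1]
            if shift == 0:
                baseline = row["drug"]
            assert row["drug"] <= baseline


class TestBreslowFit:
    def _hand_table(self):
        """Six patients, two events, hand-built counting-process rows."""
        rows = [
            ("p1", 0, 4, False, 0), ("p1", 4, 8, True, 2),
            ("p2", 0, 6, False, 1), ("p2", 6, 10, False, 3),
            ("p3", 0, 5, True, 0),
            ("p4", 0, 9, False, 4),
            ("p5", 0, 3, False, 1), ("p5", 3, 12, False, 2),
            ("p6", 0, 11, False, 0),
        ]
        df = pd.DataFrame(rows, columns=["patient_id", "start", "stop", "event", "drug"])
        return CountingProcessTable(df, drugs=["drug"])

    def test_newton_matches_brute_force_maximization(self):
        cp = self._hand_table()
        fit = fit_cox_tv(cp, "drug")
        brute = optimize.minimize_scalar(
            lambda b: -breslow_loglik(cp, "drug", b)[0],
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.converged
        assert fit.log_hr == pytest.approx(brute.x, abs=1e-6)

    def test_no_information_flagged(self):
        df = pd.DataFrame(
            [("p1", 0, 5, True, 0), ("p2", 0, 7, False, 0)],
            columns=["patient_id", "start", "stop", "event", "drug"],
        )
        fit = fit_cox_tv(CountingProcessTable(df, drugs=["drug"]), "drug")
        assert fit.log_hr == 0.0
        assert math.isinf(fit.se)
        assert not fit.converged

    def test_zero_events_rejected(self):
        df = pd.DataFrame(
            [("p1", 0, 5, False, 1)],
            columns=["patient_id", "start", "stop", "event", "drug"],
        )
        with pytest.raises(ValueError, match="no events"):
            fit_cox_tv(CountingProcessTable(df, drugs=["drug"]), "drug")

    def test_splitting_intervals_leaves_likelihood_unchanged(self):
        cp = self._hand_table()
        split_rows = []
        for _, r in cp.rows.iterrows():
            mid = (r["start"] + r["stop"]) / 2
            split_rows.append({**r, "stop": mid, "event": False})
            split_rows.append({**r, "start": mid})
        cp2 = CountingProcessTable(pd.DataFrame(split_rows), drugs=["drug"])
        for beta in (-0.5, 0.0, 0.8):
            l1, u1, i1 = breslow_loglik(cp, "drug", beta)
            l2, u2, i2 = breslow_loglik(cp2, "drug", beta)
            assert l1 == pytest.approx(l2, abs=1e-10)
            assert u1 == pytest.approx(u2, abs=1e-10)

    def test_time_fixed_covariate_matches_lifelines_cox(self):
        """Expanded counting-process fit equals a standard Cox fit."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(10)
        n = 80
        x = rng.integers(0, 2, size=n)
        t = rng.exponential(scale=np.exp(-0.7 * x)) + 0.01
        censor_time = np.quantile(t, 0.7)
        event = t <= censor_time
        t = np.minimum(t, censor_time)
        rows = [
            {"patient_id": f"p{i}", "start": 0.0, "stop": float(t[i]),
             "event": bool(event[i]), "drug": int(x[i])}
            for i in range(n)
        ]
        cp = CountingProcessTable(pd.DataFrame(rows), drugs=["drug"])
        fit = fit_cox_tv(cp, "drug")
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"t": t, "e": event, "drug": x}),
            duration_col="t", event_col="e",
        )
        assert fit.log_hr == pytest.approx(float(cph.params_["drug"]), abs=1e-4)
        assert fit.se == pytest.approx(float(cph.standard_errors_["drug"]), abs=1e-4)

    def test_time_varying_matches_lifelines_ctv(self):
        lifelines = pytest.importorskip("lifelines")
        ledger, calls, outcomes = simulate_exposure_cohort(
            150, math.log(1.2), baseline_hazard=0.02, seed=11
        )
        cp = build_counting_process(ledger, calls, outcomes, encoding="cumulative")
        fit = fit_cox_tv(cp, "drug_a")
        ctv = lifelines.CoxTimeVaryingFitter()
        df = cp.rows.rename(columns={"patient_id": "id"})
        ctv.fit(df[["id", "start", "stop", "event", "drug_a"]],
                id_col="id", start_col="start", stop_col="stop", event_col="event")
        assert fit.log_hr == pytest.approx(float(ctv.params_["drug_a"]), abs=1e-4)

    def test_contiguity_validation(self):
        df = pd.DataFrame(
            [("p1", 0, 3, False, 0), ("p1", 4, 6, True, 1)],
            columns=["patient_id", "start", "stop", "event", "drug"],
        )
        with pytest.raises(ValueError, match="contiguous"):
            CountingProcessTable(df, drugs=["drug"])


class TestPanel:
    def test_filtered_drug_absent_and_row_counts(self):
        rng = np.random.default_rng(12)
        entries = []
        patients = [f"p{i}" for i in range(20)]
        for p in patients:
            for d in range(3, 8):
                entries.append((p, "common", d))
        entries.append(("p0", "rare", 4))
        ledger = make_ledger(entries)
        outcomes = make_outcomes({p: 15 for p in patients})
        events = {p: int(rng.integers(5, 15)) for p in patients[:6]}
        calls = make_calls(events, patients)
        panel = run_antibiotic_panel(ledger, calls, outcomes)
        assert set(panel["drug"]) == {"common"}
        assert len(panel) == 2  # one row per encoding
        assert set(panel["encoding"]) == {"cumulative", "any"}

    def test_recovers_sign_of_effect(self):
        ledger, calls, outcomes = simulate_exposure_cohort(
            400, math.log(1.3), baseline_hazard=0.015, seed=13
        )
        cp = build_counting_process(ledger, calls, outcomes, encoding="cumulative")
        fit = fit_cox_tv(cp, "drug_a")
        assert fit.log_hr > 0
        ledger, calls, outcomes = simulate_exposure_cohort(
            400, math.log(0.7), baseline_hazard=0.03, seed=14
        )
        cp = build_counting_process(ledger, calls, outcomes, encoding="cumulative")
        fit = fit_cox_tv(cp, "drug_a")
        assert fit.log_hr < 0
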