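"""Cohort selection, rate estimation, moment summaries and regressions."""

import math

import numpy as np
import pandas as pd
import pytest

import pedipace as pp
from pedipace.params import EventType
from pedipace.cost_inputs import (
    DegenerateDesignError,
    UndefinedRateError,
    REFERENCE_INDIRECT_PAIRS,
)

from conftest import make_patient


class TestCohortSelection:
    def test_thirty_day_window_is_inclusive(self, events_from_rows):
        ev = events_from_rows(make_patient("A", chs_delay_days=30),
                              make_patient("B", chs_delay_days=31))
        kept = pp.select_study_cohort(ev)
        assert set(kept["patient_id"]) == {"A"}

    def test_icd_patients_removed_entirely(self, events_from_rows):
        ev = events_from_rows(make_patient("A"), make_patient("B", icd=True))
        kept = pp.select_study_cohort(ev)
        assert set(kept["patient_id"]) == {"A"}

    def test_age_cutoff_is_strict(self, events_from_rows):
        ev = events_from_rows(make_patient("A", implant_age=3.99),
                              make_patient("B", implant_age=4.0))
        kept = pp.select_study_cohort(ev)
        assert set(kept["patient_id"]) == {"A"}

    def test_minimum_followup(self, events_from_rows):
        ev = events_from_rows(make_patient("A", last_day=183),
                              make_patient("B", last_day=100))
        kept = pp.select_study_cohort(ev, min_followup=0.5)
        assert set(kept["patient_id"]) == {"A"}

    def test_implant_without_chs_excluded_not_fatal(self, events_from_rows, caplog):
        rows = make_patient("A")
        orphan = [r for r in make_patient("B") if r["event"] != "chs"]
        ev = events_from_rows(rows, orphan)
        with caplog.at_level("INFO"):
            kept = pp.select_study_cohort(ev)
        assert set(kept["patient_id"]) == {"A"}
        assert any("without CHS" in r.message for r in caplog.records)

    def test_selection_is_idempotent(self, small_events):
        once = pp.select_study_cohort(small_events)
        twice = pp.select_study_cohort(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRates:
    def test_rate_is_events_over_person_years(self, events_from_rows):
        # 140 patients followed 20 whole years each = 2 800 person-years;
        # 56 malfunction events -> 0.020 exactly
        patients = [make_patient(f"P{i}", last_day=7300) for i in range(140)]
        ev = events_from_rows(*patients)
        rows = []
        for i in range(56):
            r = dict(patient_id=f"P{i}", event="malfunction_replacement",
                     age_at_event=2.0, days_since_implant=400, los=3.0,
                     direct_charge=50_000.0, indirect_cost=1800.0)
            rows.append(r)
        ev = pd.concat([ev, pd.DataFrame(rows)], ignore_index=True)
        est = pp.estimate_annual_rate(ev, EventType.MALFUNCTION_REPLACEMENT)
        assert est.person_years == 2800
        assert est.rate == pytest.approx(56 / 2800)
        assert est.ci_low < 0.02 < est.ci_high

    def test_zero_events_zero_rate(self, events_from_rows):
        ev = events_from_rows(make_patient("A", last_day=3650))
        est = pp.estimate_annual_rate(ev, EventType.INFECTION)
        assert est.rate == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0.0

    def test_zero_person_years_is_an_error(self):
        ev = pd.DataFrame([dict(patient_id="A", event="ppm_implant",
                                age_at_event=1.0, days_since_implant=0,
                                los=13.0, direct_charge=1e5, indirect_cost=7e3)])
        with pytest.raises(UndefinedRateError):
            pp.estimate_annual_rate(ev, EventType.INFECTION)

    def test_invariant_to_relabeling_and_row_order(self, small_events):
        base = pp.estimate_annual_rate(small_events, EventType.GENERATOR_CHANGE)
        shuffled = small_events.sample(frac=1, random_state=0).reset_index(drop=True)
        relabeled = shuffled.assign(
            patient_id=shuffled["patient_id"].map(lambda s: "X" + s[::-1]))
        alt = pp.estimate_annual_rate(relabeled, EventType.GENERATOR_CHANGE)
        assert alt.rate == pytest.approx(base.rate, rel=1e-12)
        assert alt.person_years == base.person_years

    def test_recovers_generating_rate(self):
        # >=10^4 person-years at the 11.2%/yr generator-change probability
        cfg = pp.GeneratorConfig(n_patients=1000, horizon=15, seed=21)
        ev = pp.generate_patient_histories(cfg)
        est = pp.estimate_annual_rate(ev, EventType.GENERATOR_CHANGE)
        se = math.sqrt(0.112 * 0.888 / est.person_years)
        assert abs(est.rate - 0.112) < 3 * se


class TestSummaries:
    def test_single_event_sd_zero(self, events_from_rows, caplog):
        ev = events_from_rows(make_patient("A"))
        ev = ev[ev["event"] == "ppm_implant"]
        ev.loc[:, "los"] = 5.0
        with caplog.at_level("INFO"):
            s = pp.summarize_event(ev, EventType.PPM_IMPLANT)
        assert (s.los_mean, s.los_sd) == (5.0, 0.0)
        assert s.n == 1

    def test_two_event_hand_computation(self):
        ev = pd.DataFrame([
            dict(patient_id="A", event="infection", age_at_event=1.0,
                 days_since_implant=100, los=2.0, direct_charge=10.0,
                 indirect_cost=1.0),
            dict(patient_id="A", event="infection", age_at_event=2.0,
                 days_since_implant=500, los=4.0, direct_charge=30.0,
                 indirect_cost=3.0),
        ])
        s = pp.summarize_event(ev, EventType.INFECTION)
        assert s.los_mean == pytest.approx(3.0)
        assert s.los_sd == pytest.approx(math.sqrt(2.0))
        assert s.direct_mean == pytest.approx(20.0)
        assert s.direct_sd == pytest.approx(math.sqrt(200.0))

    def test_recovers_generating_los_moments(self):
        # implant LOS generated at mean 13.005, SD 13.166
        cfg = pp.GeneratorConfig(n_patients=5000, horizon=1, seed=30,
                                 event_rates={e: 0.0 for e in
                                              pp.FOLLOWUP_EVENTS})
        ev = pp.generate_patient_histories(cfg)
        s = pp.summarize_event(ev, EventType.PPM_IMPLANT)
        se = 13.166 / math.sqrt(s.n)
        assert abs(s.los_mean - 13.005) < 3 * se

    def test_missing_event_type_is_an_error(self, events_from_rows):
        ev = events_from_rows(make_patient("A"))
        with pytest.raises(ValueError):
            pp.summarize_event(ev, EventType.HOLTER)


class TestRegressions:
    def test_exact_line(self):
        los = np.array([1.0, 2.0, 5.0, 9.0])
        ev = pd.DataFrame(dict(patient_id=list("ABCD"), event="infection",
                               age_at_event=1.0, days_since_implant=10,
                               los=los, direct_charge=1000 + 500 * los,
                               indirect_cost=0.0))
        fit = pp.fit_los_cost_regression(ev, EventType.INFECTION)
        assert fit.slope == pytest.approx(500.0)
        assert fit.intercept == pytest.approx(1000.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_identical_los_is_degenerate(self):
        ev = pd.DataFrame(dict(patient_id=list("ABC"), event="ecg",
                               age_at_event=1.0, days_since_implant=10,
                               los=0.125, direct_charge=[289.0, 300.0, 280.0],
                               indirect_cost=136.0))
        with pytest.raises(DegenerateDesignError):
            pp.fit_los_cost_regression(ev, EventType.ECG)

    def test_infection_billing_hits_published_r2(self):
        # synthetic infection billing is calibrated to R^2 = 0.864
        cfg = pp.GeneratorConfig(
            n_patients=2000, horizon=10, seed=8,
            event_rates={e: 0.0 for e in pp.FOLLOWUP_EVENTS}
            | {EventType.INFECTION: 0.25})
        ev = pp.generate_dataset(cfg)
        fit = pp.fit_los_cost_regression(ev, EventType.INFECTION)
        assert abs(fit.r_squared - 0.864) < 0.05


class TestIndirectModel:
    def test_exact_two_point_interpolation(self):
        m = pp.fit_indirect_model([(0.0, 100.0), (1.0, 700.0)])
        assert m.per_visit == pytest.approx(100.0)
        assert m.per_day == pytest.approx(600.0)

    def test_reference_pairs_match_normal_equations_oracle(self):
        # independent oracle: textbook normal equations on the same pairs
        pts = np.asarray(REFERENCE_INDIRECT_PAIRS)
        x, y = pts[:, 0], pts[:, 1]
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        m = pp.fit_indirect_model(REFERENCE_INDIRECT_PAIRS)
        assert m.per_day == pytest.approx(slope, rel=1e-12)
        assert m.per_visit == pytest.approx(intercept, rel=1e-12)

    def test_flat_line_gives_zero_per_day(self):
        m = pp.fit_indirect_model([(0.125, 136.0), (1.0, 136.0), (3.0, 136.0)])
        assert m.per_day == pytest.approx(0.0, abs=1e-12)
        assert m.per_visit == pytest.approx(136.0)

    def test_negative_per_visit_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m = pp.fit_indirect_model([(1.0, 10.0), (2.0, 510.0), (3.0, 1010.0)])
        assert m.per_visit == 0.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError):
            pp.fit_indirect_model([(1.0, 100.0)])
        with pytest.raises(ValueError):
            pp.fit_indirect_model([(1.0, 100.0), (1.0, 200.0)])


class TestEstimatorFrontEnd:
    def test_full_bundle_recovery_moderate_sample(self):
        """Estimation on synthetic data returns the generating bundle
        (rates and LOS/cost means within 3 SE)."""
        cfg = pp.GeneratorConfig(n_patients=2000, horizon=10, seed=77)
        ev = pp.generate_dataset(cfg)
        res = pp.CohortEstimator.from_events(ev).fit()
        gen = cfg.params
        py = res.person_years
        for e in pp.FOLLOWUP_EVENTS:
            true = gen.events[e].annual_rate
            if true == 0:
                continue
            se = (math.sqrt(true * (1 - true) / py) if e in pp.MAJOR_EVENTS
                  else math.sqrt(true / py))
            assert abs(res.params.events[e].annual_rate - true) < 3 * se, e
            s = res.summaries[e]
            true_los = cfg.los_moments(e)[0]
            if s.los_sd > 0:
                assert abs(s.los_mean - true_los) < 3 * s.los_sd / math.sqrt(s.n), e
            else:
                assert s.los_mean == pytest.approx(true_los)
            if s.direct_sd > 0:
                true_cost = gen.events[e].direct_mean
                assert abs(s.direct_mean - true_cost) < 3 * s.direct_sd / math.sqrt(s.n), e

    def test_summary_renders(self, small_events):
        res = pp.CohortEstimator.from_events(small_events).fit()
        text = res.summary()
        assert "person-years" in text and "generator_change" in text

    def test_bundle_round_trips_through_json(self, small_events, tmp_path):
        res = pp.CohortEstimator.from_events(small_events).fit()
        p = tmp_path / "params.json"
        res.params.to_json(p)
        back = pp.CostParameters.from_json(p)
        assert back.events[EventType.ECG].direct_mean == pytest.approx(
            res.params.events[EventType.ECG].direct_mean)
        assert back.discount_rate == res.params.discount_rate
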