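"""Estimate the cost-model input bundle from hospital event histories.

This is the estimation half of the package: given an event table (real
schema or synthetic), it selects the study cohort (postoperative pacemaker
implant within 30 days of surgery, implant age under 4 years, minimum
follow-up, no defibrillator), estimates annual event probabilities and
frequencies from person-years of follow-up, summarizes LOS and unit costs,
fits charge-on-LOS regressions, and fits the per-visit/per-day indirect
cost model — the full analogue of a cost-model input table.

The statsmodels-style entry point is :class:`CohortEstimator`:

    results = CohortEstimator.from_events(events).fit()
    results.params      # CostParameters bundle
    results.summary()   # text table
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm

from .params import (
    EventType,
    MAJOR_EVENTS,
    MINOR_EVENTS,
    FOLLOWUP_EVENTS,
    CostParameters,
    EventParams,
    IndirectCostModel,
    RegressionFit,
)
from .synthetic import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

#: Published (LOS, indirect cost) pairs, one per distinct event row, used to
#: back out the per-visit/per-day indirect model.
REFERENCE_INDIRECT_PAIRS: tuple[tuple[float, float], ...] = (
    (13.005, 7338.0),
    (3.156, 1792.0),
    (0.322, 355.0),
    (12.679, 7154.0),
    (0.125, 136.0),
    (1.0, 578.0),
)


class UndefinedRateError(ValueError):
    """Rate requested over zero person-years of follow-up."""


class DegenerateDesignError(ValueError):
    """Regression requested on a design with no LOS variation."""


def select_study_cohort(
    events: pd.DataFrame,
    window: float = 30.0,
    max_age: float = 4.0,
    min_followup: float = 0.5,
) -> pd.DataFrame:
    """Apply the study inclusion criteria patient-by-patient.

    Retained patients have a pacemaker implant at most ``window`` days
    (inclusive) after an index CHS, implant age strictly below ``max_age``
    years, a last recorded event at least ``min_followup`` years after
    implant, and no defibrillator record.  Patients whose implant lacks a
    matching CHS are excluded and logged, not an error.  Idempotent.
    """
    keep: list[str] = []
    for pid, g in events.groupby("patient_id", sort=True):
        ev = g["event"]
        if (ev == EventType.ICD_IMPLANT.value).any():
            continue
        implants = g[ev == EventType.PPM_IMPLANT.value]
        if len(implants) != 1:
            logger.info("patient %s: no unique implant record, excluded", pid)
            continue
        chs_days = -g.loc[ev == EventType.CHS.value, "days_since_implant"]
        if chs_days.empty:
            logger.info("patient %s: implant without CHS record, excluded", pid)
            continue
        if not ((chs_days >= 0) & (chs_days <= window)).any():
            continue
        if not implants["age_at_event"].iloc[0] < max_age:
            continue
        if g["days_since_implant"].max() / DAYS_PER_YEAR < min_followup:
            continue
        keep.append(pid)
    return events[events["patient_id"].isin(keep)].reset_index(drop=True)


def person_years(events: pd.DataFrame) -> float:
    """Total follow-up, in completed annual cycles, over all patients.

    Each patient contributes ceil(last event day / 365.25) whole years:
    events occur on an annual grid, so a last event inside cycle t means
    the patient was observed through t complete annual trials.
    """
    last = events.groupby("patient_id")["days_since_implant"].max()
    return float(np.ceil(np.maximum(last, 0) / DAYS_PER_YEAR).sum())


@dataclass
class RateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    person_years: float


def estimate_annual_rate(events: pd.DataFrame, event: EventType) -> RateEstimate:
    """Events per person-year with a 95% CI.

    Major events use a Wilson interval on person-year Bernoulli trials
    (the annual-probability reading); minor events use the exact Poisson
    (Garwood) interval on the event count.
    """
    total_py = person_years(events)
    if total_py <= 0:
        raise UndefinedRateError("cohort has zero person-years of follow-up")
    k = int((events["event"] == event.value).sum())
    rate = k / total_py
    if event in MAJOR_EVENTS:
        lo, hi = proportion_confint(k, int(round(total_py)), method="wilson")
    else:
        lo = stats.chi2.ppf(0.025, 2 * k) / 2 / total_py if k > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * k + 2) / 2 / total_py
    return RateEstimate(rate, float(lo), float(hi), k, total_py)


@dataclass
class EventSummary:
    los_mean: float
    los_sd: float
    direct_mean: float
    direct_sd: float
    indirect_mean: float
    indirect_sd: float
    n: int


def summarize_event(events: pd.DataFrame, event: EventType) -> EventSummary:
    """Sample mean and SD (n-1 denominator) of LOS and both cost streams."""
    g = events[events["event"] == event.value]
    if g.empty:
        raise ValueError(f"no events of type {event}")
    if len(g) == 1:
        logger.info("%s: single event, SDs reported as 0", event)

    def ms(col: str) -> tuple[float, float]:
        x = g[col].to_numpy(dtype=float)
        return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0

    lm, ls = ms("los")
    dm, ds = ms("direct_charge")
    im, isd = ms("indirect_cost")
    return EventSummary(lm, ls, dm, ds, im, isd, len(g))


def fit_los_cost_regression(events: pd.DataFrame, event: EventType) -> RegressionFit:
    """OLS of direct charge on LOS for one event type, with slope t-test."""
    g = events[events["event"] == event.value]
    los = g["los"].to_numpy(dtype=float)
    if len(g) < 3 or np.unique(los).size < 2:
        raise DegenerateDesignError(
            f"{event}: need >=3 events with LOS variation for regression"
        )
    y = g["direct_charge"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(los)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(g),
    )


def fit_indirect_model(pairs) -> IndirectCostModel:
    """Least-squares per-visit + per-day model from (LOS, indirect) points.

    A negative fitted per-visit intercept is clipped to 0 with a warning;
    fewer than two distinct LOS values is an error.
    """
    pts = np.asarray(list(pairs), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or np.unique(pts[:, 0]).size < 2:
        raise ValueError("need at least two points with distinct LOS")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([np.ones_like(x), x])
    (per_visit, per_day), *_ = np.linalg.lstsq(A, y, rcond=None)
    if per_visit < 0:
        logger.warning("fitted per-visit cost %.2f < 0, clipped to 0", per_visit)
        per_visit = 0.0
    return IndirectCostModel(per_visit=float(per_visit), per_day=float(per_day))


# ---------------------------------------------------------------------------
# Model/Results front end


class CohortEstimator:
    """Fits the full cost-parameter bundle to an event-history table.

    Parameters
    ----------
    events
        Canonical event table (one row per hospital event).  Pass it through
        :func:`select_study_cohort` first, or use ``from_events(...,
        select=True)``.
    discount_rate, horizon
        Carried into the resulting bundle (they are policy inputs, not
        estimated from data).
    """

    def __init__(self, events: pd.DataFrame, discount_rate: float = 0.03,
                 horizon: int = 20):
        self.events = events
        self.discount_rate = discount_rate
        self.horizon = horizon

    @classmethod
    def from_events(cls, events: pd.DataFrame, select: bool = False,
                    discount_rate: float = 0.03, horizon: int = 20,
                    **cohort_kwargs) -> "CohortEstimator":
        if select:
            events = select_study_cohort(events, **cohort_kwargs)
        return cls(events, discount_rate=discount_rate, horizon=horizon)

    def fit(self) -> "CostParameterResults":
        ev = self.events
        implant = summarize_event(ev, EventType.PPM_IMPLANT)
        rates: dict[EventType, RateEstimate] = {}
        bundle: dict[EventType, EventParams] = {}
        summaries: dict[EventType, EventSummary] = {}
        for e in FOLLOWUP_EVENTS:
            r = estimate_annual_rate(ev, e)
            rates[e] = r
            if r.n_events > 0:
                s = summarize_event(ev, e)
                summaries[e] = s
                bundle[e] = EventParams(r.rate, s.los_mean, s.los_sd,
                                        s.direct_mean, s.direct_sd,
                                        s.indirect_mean, s.indirect_sd)
            else:
                bundle[e] = EventParams(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        regressions: dict[EventType, RegressionFit] = {}
        for e in (EventType.PPM_IMPLANT, *FOLLOWUP_EVENTS):
            try:
                regressions[e] = fit_los_cost_regression(ev, e)
            except DegenerateDesignError:
                pass
        params = CostParameters(
            implant=EventParams(None, implant.los_mean, implant.los_sd,
                                implant.direct_mean, implant.direct_sd,
                                implant.indirect_mean, implant.indirect_sd),
            events=bundle,
            discount_rate=self.discount_rate,
            horizon=self.horizon,
        )
        pairs = [(implant.los_mean, implant.indirect_mean)] + [
            (s.los_mean, s.indirect_mean) for s in summaries.values()
        ]
        try:
            indirect = fit_indirect_model(pairs)
        except ValueError:
            indirect = None
        return CostParameterResults(
            params=params, rates=rates, summaries=summaries,
            regressions=regressions, indirect_model=indirect,
            n_patients=ev["patient_id"].nunique(),
            person_years=person_years(ev),
        )


@dataclass
class CostParameterResults:
    """Fitted input bundle plus per-parameter diagnostics."""

    params: CostParameters
    rates: dict[EventType, RateEstimate]
    summaries: dict[EventType, EventSummary]
    regressions: dict[EventType, RegressionFit]
    indirect_model: IndirectCostModel | None
    n_patients: int
    person_years: float

    def summary(self) -> str:
        rows = []
        imp = self.params.implant
        rows.append(["ppm_implant", "", f"{imp.los_mean:.3f} ({imp.los_sd:.3f})",
                     f"{imp.direct_mean:,.0f} ({imp.direct_sd:,.0f})",
                     f"{imp.indirect_mean:,.0f} ({imp.indirect_sd:,.0f})"])
        for e, p in self.params.events.items():
            r = self.rates[e]
            rows.append([
                e.value,
                f"{p.annual_rate:.4f} [{r.ci_low:.4f}, {r.ci_high:.4f}]",
                f"{p.los_mean:.3f} ({(p.los_sd or 0):.3f})",
                f"{p.direct_mean:,.0f} ({(p.direct_sd or 0):,.0f})",
                f"{p.indirect_mean:,.0f} ({(p.indirect_sd or 0):,.0f})",
            ])
        table = pd.DataFrame(
            rows,
            columns=["event", "annual rate [95% CI]", "LOS d (SD)",
                     "direct USD (SD)", "indirect USD (SD)"],
        )
        head = (
            f"Cost-parameter estimates: {self.n_patients} patients, "
            f"{self.person_years:,.0f} person-years\n"
            f"discount rate {self.params.discount_rate:.1%}/yr, "
            f"horizon {self.params.horizon} y\n"
        )
        return head + table.to_string(index=False)
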