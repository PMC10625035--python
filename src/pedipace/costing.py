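"""Follow-up-data costing: cumulative cost curves and 20-year extrapolation.

Patients are split by clinical course — "complication" if they ever had a
pacemaker malfunction requiring lead-and-generator replacement and/or a
device infection (a routine generator change does not count) — and each
group gets a year-indexed mean cumulative direct/indirect cost curve.  A
patient contributes to year y only while still under follow-up, so the
per-year sample size shrinks with y.  Because observed follow-up rarely
reaches 20 years, the tail of the curve is extrapolated by a linear fit
over years 10-19.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import (
    EventType,
    COMPLICATION_EVENTS,
    IndirectCostModel,
    RegressionFit,
)
from .synthetic import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

COMPLICATION = "complication"
NO_COMPLICATION = "no_complication"

#: rows that never carry pacing-related cost
_NON_COST_EVENTS = (EventType.CHS.value, EventType.ICD_IMPLANT.value)


class InsufficientDataError(ValueError):
    """Too few observed years inside the extrapolation window."""


def classify_course(patient_events: pd.DataFrame) -> str:
    """Label one patient's clinical course.

    ``complication`` iff the history contains at least one
    malfunction-replacement or infection event; generator changes alone
    leave the course uncomplicated.
    """
    ev = patient_events["event"]
    if not (ev == EventType.PPM_IMPLANT.value).any():
        raise ValueError("patient has no implant record")
    comp = ev.isin([e.value for e in COMPLICATION_EVENTS]).any()
    return COMPLICATION if comp else NO_COMPLICATION


def classify_patients(events: pd.DataFrame) -> pd.Series:
    """Course label per patient id (index: patient_id)."""
    comp_codes = [e.value for e in COMPLICATION_EVENTS]
    has_comp = (
        events.assign(_c=events["event"].isin(comp_codes))
        .groupby("patient_id")["_c"].any()
    )
    return has_comp.map({True: COMPLICATION, False: NO_COMPLICATION})


@dataclass
class CumulativeCostCurve:
    """Year-indexed mean cumulative costs for one patient group.

    ``table`` columns: year, n, direct_mean, direct_sd, indirect_mean,
    indirect_sd.  Only patients still under follow-up at year y contribute
    to that year's mean (varying-n convention, not last observation
    carried forward).
    """

    label: str
    table: pd.DataFrame

    def year_value(self, year: int, stream: str = "direct") -> float:
        row = self.table[self.table["year"] == year]
        if row.empty:
            raise KeyError(f"year {year} not observed")
        return float(row[f"{stream}_mean"].iloc[0])

    def plot(self, ax=None, stream: str = "direct"):
        """Mean cumulative cost vs year with an SD band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        m, s = t[f"{stream}_mean"], t[f"{stream}_sd"]
        ax.plot(t["year"], m, marker="o", label=self.label)
        ax.fill_between(t["year"], m - s, m + s, alpha=0.2)
        ax.set_xlabel("years since implantation")
        ax.set_ylabel(f"cumulative {stream} cost (2018 USD)")
        ax.legend()
        return ax


def build_curves(
    events: pd.DataFrame,
    indirect_model: IndirectCostModel | None = None,
    horizon: int = 20,
) -> dict[str, CumulativeCostCurve]:
    """Cumulative cost curves per clinical-course group.

    Direct cost accumulates billed charges of all events up to year y
    (year binning: floor(days since implant / 365.25)); indirect cost is
    the per-visit/per-day model applied to each event's LOS, or the
    table's own indirect column when no model is given.
    """
    labels = classify_patients(events)
    curves: dict[str, CumulativeCostCurve] = {}
    for label in (NO_COMPLICATION, COMPLICATION):
        pids = labels.index[labels == label]
        group = events[events["patient_id"].isin(pids)]
        if group.empty:
            logger.warning("group %r is empty; emitting empty curve", label)
            curves[label] = CumulativeCostCurve(
                label,
                pd.DataFrame(columns=["year", "n", "direct_mean", "direct_sd",
                                      "indirect_mean", "indirect_sd"]),
            )
            continue
        curves[label] = _group_curve(group, label, indirect_model, horizon)
    return curves


def _group_curve(group: pd.DataFrame, label: str,
                 indirect_model: IndirectCostModel | None,
                 horizon: int) -> CumulativeCostCurve:
    pids = np.sort(group["patient_id"].unique())
    pidx = pd.Series(np.arange(len(pids)), index=pids)
    followup = (
        group.groupby("patient_id")["days_since_implant"].max() / DAYS_PER_YEAR
    ).reindex(pids).to_numpy()

    cost_rows = group[~group["event"].isin(_NON_COST_EVENTS)]
    year = np.floor(
        cost_rows["days_since_implant"].to_numpy() / DAYS_PER_YEAR
    ).astype(int)
    inside = (year >= 0) & (year <= horizon)
    rows = cost_rows[inside]
    year = year[inside]
    pi = pidx[rows["patient_id"]].to_numpy()

    direct_amt = rows["direct_charge"].to_numpy(dtype=float)
    if indirect_model is not None:
        indirect_amt = indirect_model.predict(rows["los"].to_numpy(dtype=float))
    else:
        indirect_amt = rows["indirect_cost"].to_numpy(dtype=float)

    ny = horizon + 1
    md = np.zeros((len(pids), ny))
    mi = np.zeros((len(pids), ny))
    np.add.at(md, (pi, year), direct_amt)
    np.add.at(mi, (pi, year), indirect_amt)
    md = md.cumsum(axis=1)
    mi = mi.cumsum(axis=1)

    recs = []
    for y in range(ny):
        mask = followup >= y
        n = int(mask.sum())
        if n == 0:
            break
        dv, iv = md[mask, y], mi[mask, y]
        recs.append({
            "year": y,
            "n": n,
            "direct_mean": dv.mean(),
            "direct_sd": dv.std(ddof=1) if n > 1 else 0.0,
            "indirect_mean": iv.mean(),
            "indirect_sd": iv.std(ddof=1) if n > 1 else 0.0,
        })
    return CumulativeCostCurve(label, pd.DataFrame(recs))


def extrapolate_20y(
    curve: CumulativeCostCurve,
    window: tuple[int, int] = (10, 19),
    stream: str = "direct",
    at_year: int = 20,
) -> tuple[float, RegressionFit]:
    """Linear extrapolation of the mean cumulative curve to year 20.

    Fits OLS of mean cumulative cost on year over the observed years inside
    ``window`` and evaluates the line at ``at_year``; needs at least three
    observed window years.
    """
    t = curve.table
    sel = t[(t["year"] >= window[0]) & (t["year"] <= window[1])]
    if len(sel) < 3:
        raise InsufficientDataError(
            f"only {len(sel)} observed years in window {window}"
        )
    x = sel["year"].to_numpy(dtype=float)
    y = sel[f"{stream}_mean"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        # flat curve: perfect zero-slope fit; R^2 conventionally 1 (no residual)
        fit = RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=1.0,
                            p_value=1.0, n=len(sel))
        return float(y[0]), fit
    model = sm.OLS(y, sm.add_constant(x)).fit()
    fit = RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=len(sel),
    )
    return fit.predict(at_year), fit
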