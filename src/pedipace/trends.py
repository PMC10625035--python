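"""Surgical-volume trend analytics: CAGR, Poisson trends, normalization.

Sixty years of yearly congenital-heart-surgery counts are summarized three
ways: the compound annual growth rate between endpoint years, a Poisson
log-linear (or ordinary linear) trend fit with a Wald slope test, and the
postoperative pacemaker implantation rate per surgery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass
class TrendFit:
    """Fitted yearly trend: slope per calendar year with its Wald p-value.

    For the Poisson GLM the slope is on the log scale (a log-rate per
    year), so exp(beta) - 1 is the implied annual growth fraction; the
    intercept is the (log) level at the first observed year.
    """

    beta: float
    intercept: float
    p_value: float
    model: str


def compute_cagr(first: float, last: float, n_years: int) -> float:
    """Compound annual growth rate between two endpoint counts.

    ``n_years`` is the elapsed span last_year - first_year (58 for
    1960-2018).
    """
    if first <= 0 or last <= 0:
        raise InvalidConfigError("CAGR endpoints must be positive")
    if n_years < 1:
        raise InvalidConfigError("n_years must be >= 1")
    return (last / first) ** (1.0 / n_years) - 1.0


def series_cagr(series: pd.DataFrame, count_col: str = "count",
                smooth_endpoints: bool = False) -> float:
    """CAGR of a (year, count) table from its first to last year.

    With ``smooth_endpoints`` the endpoint counts are 3-year averages,
    which stabilizes the estimate on noisy series; the default uses the
    raw single-year endpoints.
    """
    s = series.sort_values("year")
    years = s["year"].to_numpy()
    counts = s[count_col].to_numpy(dtype=float)
    if smooth_endpoints and len(counts) >= 3:
        first, last = counts[:3].mean(), counts[-3:].mean()
    else:
        first, last = counts[0], counts[-1]
    return compute_cagr(first, last, int(years[-1] - years[0]))


def fit_count_trend(years, counts, model: str = "poisson_glm") -> TrendFit:
    """Yearly trend fit for a count series.

    ``poisson_glm`` fits counts ~ Poisson(exp(a + beta*year)) by maximum
    likelihood (years are internally re-origined to the first year for
    conditioning; beta is unchanged); ``linear`` is ordinary least
    squares on the raw counts.
    """
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if years.size < 3:
        raise InvalidConfigError("need at least 3 observations")
    if np.all(counts == 0):
        raise InvalidConfigError("all-zero counts: trend undefined")
    x = sm.add_constant(years - years[0])
    if model == "poisson_glm":
        fit = sm.GLM(counts, x, family=sm.families.Poisson()).fit()
    elif model == "linear":
        fit = sm.OLS(counts, x).fit()
    else:
        raise InvalidConfigError(f"unknown trend model {model!r}")
    return TrendFit(
        beta=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]),
        model=model,
    )


def normalize_ppm_rate(volumes: pd.DataFrame) -> pd.Series:
    """Postoperative pacemaker implantations per surgery, by year.

    rate_y = n_ppm_postop / (n_chs_under4 + n_chs_4plus); a year with no
    surgeries is emitted as missing and logged.
    """
    chs = volumes["n_chs_under4"] + volumes["n_chs_4plus"]
    rate = volumes["n_ppm_postop"] / chs.where(chs > 0)
    n_bad = int((~(chs > 0)).sum())
    if n_bad:
        logger.warning("%d year(s) with zero surgeries emitted as missing", n_bad)
    rate.index = pd.Index(volumes["year"], name="year")
    return rate.rename("ppm_per_chs")


def volume_trend_report(volumes: pd.DataFrame) -> dict:
    """CAGRs and Poisson trend fits for a full surgical-volume table."""
    v = volumes.sort_values("year").reset_index(drop=True)
    total = v["n_chs_under4"] + v["n_chs_4plus"]
    span = int(v["year"].iloc[-1] - v["year"].iloc[0])
    out: dict = {
        "chs_total_cagr": compute_cagr(total.iloc[0], total.iloc[-1], span),
        "glm_under4": fit_count_trend(v["year"], v["n_chs_under4"]).__dict__,
        "glm_4plus": fit_count_trend(v["year"], v["n_chs_4plus"]).__dict__,
        "glm_surgeons": fit_count_trend(v["year"], v["n_surgeons"]).__dict__,
    }
    ppm = v[v["n_ppm_postop"] > 0]
    if len(ppm) >= 2:
        span_ppm = int(ppm["year"].iloc[-1] - ppm["year"].iloc[0])
        out["ppm_cagr"] = compute_cagr(
            ppm["n_ppm_postop"].iloc[0], ppm["n_ppm_postop"].iloc[-1], span_ppm)
        rate = normalize_ppm_rate(ppm)
        out["ppm_per_chs_cagr"] = compute_cagr(
            rate.iloc[0], rate.iloc[-1], span_ppm)
        out["glm_ppm_per_chs"] = fit_count_trend(
            ppm["year"], rate.to_numpy(), model="linear").__dict__
    return out
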