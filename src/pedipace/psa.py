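"""Probabilistic sensitivity analysis over the cost-model inputs.

Each uncertain input gets a standard health-economics distribution — beta
for probabilities (moment-matched through an effective sample size when no
SD is published), gamma for positive costs, a point mass where no spread
is available — and the model is re-evaluated per draw.  The default inner
evaluator is the closed-form expectation, so the induced spread reflects
parameter uncertainty only, not Monte-Carlo noise; an inner simulation is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import (
    EventType,
    MAJOR_EVENTS,
    FOLLOWUP_EVENTS,
    CostParameters,
    InvalidConfigError,
)
from .markov import (
    SimulationConfig,
    discount_factor,
    expected_costs_closed_form,
    simulate_cohort,
)


def moment_match(family: str, mean: float, sd: float | None,
                 effective_n: float | None = None) -> dict:
    """Hyperparameters reproducing (mean, sd) for the given family.

    gamma: shape = (mean/sd)^2, scale = sd^2/mean.
    beta:  alpha = mean*m, beta = (1-mean)*m with m = effective_n
           (the implied sd is sqrt(mean*(1-mean)/(m+1))).
    A zero/absent sd collapses to a point mass.
    """
    if family == "point" or not sd:
        if family == "beta" and effective_n:
            m = float(effective_n)
            if not 0 < mean < 1:
                raise InvalidConfigError("beta requires mean in (0, 1)")
            return {"family": "beta", "alpha": mean * m, "beta": (1 - mean) * m}
        return {"family": "point", "value": float(mean)}
    if family == "gamma":
        if mean <= 0:
            raise InvalidConfigError("gamma requires mean > 0")
        return {"family": "gamma", "shape": (mean / sd) ** 2,
                "scale": sd**2 / mean}
    if family == "beta":
        if not 0 < mean < 1:
            raise InvalidConfigError("beta requires mean in (0, 1)")
        m = mean * (1 - mean) / sd**2 - 1
        if m <= 0:
            raise InvalidConfigError("beta sd too large for the mean")
        return {"family": "beta", "alpha": mean * m, "beta": (1 - mean) * m}
    raise InvalidConfigError(f"unknown family {family!r}")


@dataclass
class ParamDist:
    """One uncertain input: family plus matched hyperparameters."""

    family: str
    mean: float
    sd: float | None = None
    effective_n: float | None = None

    def hyper(self) -> dict:
        return moment_match(self.family, self.mean, self.sd, self.effective_n)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        h = self.hyper()
        if h["family"] == "point":
            return np.full(size, h["value"])
        if h["family"] == "gamma":
            return rng.gamma(h["shape"], h["scale"], size=size)
        return rng.beta(h["alpha"], h["beta"], size=size)


@dataclass
class PsaSpec:
    """Distributions over the input bundle, keyed "<event>.<field>".

    Fields drawn per event type are ``rate``, ``direct`` and ``indirect``
    (plus ``implant.direct``/``implant.indirect``); lengths of stay do not
    enter the cost model directly, so they are not varied here.
    """

    dists: dict[str, ParamDist]
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise InvalidConfigError("n_draws must be >= 2")

    @classmethod
    def from_params(cls, params: CostParameters, n_draws: int = 10_000,
                    effective_n: float | None = 255.0, seed: int = 0,
                    sd_scale: float = 1.0) -> "PsaSpec":
        """Default convention: beta on major-event probabilities (implied
        concentration from ``effective_n``; ``None`` leaves them fixed),
        gamma on costs with a published SD, point mass otherwise.
        ``sd_scale`` multiplies every cost SD (useful for
        sensitivity-of-the-sensitivity checks)."""
        def cost_dist(mean, sd):
            sd = (sd or 0.0) * sd_scale
            if sd > 0 and mean > 0:
                return ParamDist("gamma", mean, sd)
            return ParamDist("point", mean)

        dists: dict[str, ParamDist] = {
            "implant.direct": cost_dist(params.implant.direct_mean,
                                        params.implant.direct_sd),
            "implant.indirect": cost_dist(params.implant.indirect_mean,
                                          params.implant.indirect_sd),
        }
        for ev, p in params.events.items():
            key = ev.value
            if ev in MAJOR_EVENTS and effective_n and 0 < p.annual_rate < 1:
                dists[f"{key}.rate"] = ParamDist(
                    "beta", p.annual_rate, effective_n=effective_n)
            else:
                dists[f"{key}.rate"] = ParamDist("point", p.annual_rate)
            dists[f"{key}.direct"] = cost_dist(p.direct_mean, p.direct_sd)
            dists[f"{key}.indirect"] = cost_dist(p.indirect_mean, p.indirect_sd)
        return cls(dists=dists, n_draws=n_draws, seed=seed)


def _sample_sd(x: np.ndarray) -> float:
    # a constant sample has SD exactly 0 (pairwise-summation means would
    # otherwise leak ~1e-11 of rounding noise into it)
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0
    return float(x.std(ddof=1))


@dataclass
class PsaResults:
    """Per-draw outcomes and their summary."""

    direct: np.ndarray
    indirect: np.ndarray
    base_direct: float
    base_indirect: float
    spec: PsaSpec
    draws: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        return self.direct.size

    @property
    def direct_mean(self) -> float:
        return float(self.direct.mean())

    @property
    def direct_sd(self) -> float:
        return _sample_sd(self.direct)

    @property
    def indirect_mean(self) -> float:
        return float(self.indirect.mean())

    @property
    def indirect_sd(self) -> float:
        return _sample_sd(self.indirect)

    def to_dict(self) -> dict:
        return {
            "direct_mean": self.direct_mean,
            "direct_sd": self.direct_sd,
            "indirect_mean": self.indirect_mean,
            "indirect_sd": self.indirect_sd,
            "base_direct": self.base_direct,
            "base_indirect": self.base_indirect,
            "n_draws": self.n_draws,
            "seed": self.spec.seed,
            "conventions": "beta on probabilities, gamma on costs; "
                           "families are package conventions, not estimated",
        }

    def summary(self) -> str:
        return (
            f"PSA over {self.n_draws:,} parameter draws\n"
            f"  direct   mean {self.direct_mean:>12,.0f}  SD {self.direct_sd:>12,.0f}"
            f"   (base case {self.base_direct:,.0f})\n"
            f"  indirect mean {self.indirect_mean:>12,.0f}  SD {self.indirect_sd:>12,.0f}"
            f"   (base case {self.base_indirect:,.0f})"
        )


def run_psa(
    params: CostParameters,
    spec: PsaSpec,
    config: SimulationConfig | None = None,
    method: str = "closed_form",
    inner_n: int = 200,
    keep_draws: bool = False,
) -> PsaResults:
    """Sample parameter bundles and re-evaluate the cost model per draw.

    With ``method="closed_form"`` (default) each draw is scored exactly;
    ``method="simulate"`` runs a small inner cohort per draw, adding
    first-order Monte-Carlo noise on top of parameter uncertainty.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(spec.seed)
    nd = spec.n_draws
    samples = {k: spec.dists[k].draw(rng, nd) for k in sorted(spec.dists)}

    base_d, base_i = expected_costs_closed_form(params, config)

    if method == "closed_form":
        t = np.arange(1, config.horizon + 1)
        w = float(((1 - config.attrition) ** t
                   * discount_factor(config.discount_rate, t)).sum())
        # accumulate the per-cycle expected cost in the same event order as
        # the closed form, so point-mass specs reduce to it bit-for-bit
        per_d = np.zeros(nd)
        per_i = np.zeros(nd)
        for ev in params.events:
            k = ev.value
            per_d = per_d + samples[f"{k}.rate"] * samples[f"{k}.direct"]
            per_i = per_i + samples[f"{k}.rate"] * samples[f"{k}.indirect"]
        direct = samples["implant.direct"] + w * per_d
        indirect = samples["implant.indirect"] + w * per_i
    elif method == "simulate":
        direct = np.empty(nd)
        indirect = np.empty(nd)
        child_seeds = np.random.SeedSequence(spec.seed).spawn(nd)
        for j in range(nd):
            pj = _bundle_from_samples(params, samples, j)
            cfg = replace(config, n_patients=inner_n,
                          seed=int(child_seeds[j].generate_state(1)[0] % 2**31))
            res = simulate_cohort(pj, cfg)
            direct[j] = res.direct_mean
            indirect[j] = res.indirect_mean
    else:
        raise InvalidConfigError(f"unknown PSA method {method!r}")

    draws = None
    if keep_draws:
        draws = pd.DataFrame({**samples, "direct": direct, "indirect": indirect})
    return PsaResults(direct=direct, indirect=indirect,
                      base_direct=base_d, base_indirect=base_i,
                      spec=spec, draws=draws)


def _bundle_from_samples(params: CostParameters, samples: dict, j: int) -> CostParameters:
    new_events = {}
    for ev, p in params.events.items():
        k = ev.value
        new_events[ev] = replace(
            p,
            annual_rate=float(samples[f"{k}.rate"][j]),
            direct_mean=float(samples[f"{k}.direct"][j]),
            indirect_mean=float(samples[f"{k}.indirect"][j]),
        )
    return CostParameters(
        implant=replace(params.implant,
                        direct_mean=float(samples["implant.direct"][j]),
                        indirect_mean=float(samples["implant.indirect"][j])),
        events=new_events,
        discount_rate=params.discount_rate,
        horizon=params.horizon,
    )
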