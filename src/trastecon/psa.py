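"""Probabilistic sensitivity analysis: priors, joint sampling, evaluation.

Proportions, rates and utilities get beta priors; costs get gamma priors.
Where a source supplies alpha/beta directly (the Markov transition
probabilities, trial-count-based branch probabilities) those are used as
given; for every other parameter the method of moments converts a base-case
mean with lower/upper limits -- read as a central 95% interval -- into the
family's parameters:

    sd    = (upper - lower) / (2 * z),  z = 1.959964 by default
    beta  : alpha = mean*(mean*(1-mean)/sd^2 - 1),  beta = alpha*(1-mean)/mean
    gamma : shape = mean^2/sd^2,  scale = sd^2/mean

Bounded non-proportion quantities (the in-tree event time, the cardiac
utility-decrement duration) use a beta prior rescaled onto a declared
support interval.  Parameters are sampled independently; each parameter
owns a dedicated child stream spawned from the master seed, so adding a
parameter does not perturb the draws of the others.  Every draw is one full
tree+Markov evaluation per strategy (vectorised).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cea import (
    MarkovParams,
    ModelConfig,
    StrategyParams,
    StrategyResult,
    TreeTimingAssumptions,
    run_strategy,
)

__all__ = [
    "Z95",
    "PriorSpec",
    "PsaRun",
    "moments_to_beta",
    "moments_to_gamma",
    "build_priors",
    "run_psa",
    "summarize",
]

Z95 = 1.959963984540054


def moments_to_beta(
    mean: float, lower: float, upper: float, z: float = Z95
) -> tuple[float, float]:
    """Beta(alpha, beta) matching a mean and a central 95% range."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta prior needs mean in (0,1), got {mean}")
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    sd = (upper - lower) / (2.0 * z)
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"implied variance {var:.4g} >= mean(1-mean) = {mean*(1-mean):.4g}; "
            "bounds too wide for a beta prior -- review them"
        )
    alpha = mean * (mean * (1.0 - mean) / var - 1.0)
    return alpha, alpha * (1.0 - mean) / mean


def moments_to_gamma(
    mean: float, lower: float, upper: float, z: float = Z95
) -> tuple[float, float]:
    """Gamma(shape, scale) matching a mean and a central 95% range."""
    if mean <= 0:
        raise ValueError(f"gamma prior needs positive mean, got {mean}")
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    sd = (upper - lower) / (2.0 * z)
    return (mean / sd) ** 2, sd * sd / mean


@dataclass(frozen=True)
class PriorSpec:
    """Resolved sampling recipe for one scalar parameter."""

    parameter_id: str
    family: str  # beta | gamma | fixed
    mean: float
    lower: float | None = None
    upper: float | None = None
    alpha: float | None = None
    beta_or_scale: float | None = None
    support: tuple[float, float] | None = None  # rescaling for beta

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "beta":
            x = rng.beta(self.alpha, self.beta_or_scale, size=n)
            if self.support is not None:
                lo, hi = self.support
                x = lo + (hi - lo) * x
            return x
        if self.family == "gamma":
            return rng.gamma(self.alpha, self.beta_or_scale, size=n)
        raise ValueError(f"unknown family {self.family!r}")


def _resolve_leaf(parameter_id: str, leaf) -> PriorSpec:
    if not isinstance(leaf, Mapping):
        return PriorSpec(parameter_id, "fixed", float(leaf))
    value = float(leaf["value"])
    family = leaf.get("family", "fixed")
    if family == "fixed":
        return PriorSpec(parameter_id, "fixed", value)
    support = tuple(leaf["support"]) if "support" in leaf else None
    if "alpha" in leaf and "beta" in leaf and family == "beta":
        return PriorSpec(
            parameter_id, "beta", value,
            alpha=float(leaf["alpha"]), beta_or_scale=float(leaf["beta"]),
            support=support,
        )
    lower, upper = float(leaf["lower"]), float(leaf["upper"])
    if family == "beta":
        if support is not None:
            lo, hi = support
            a, b = moments_to_beta(
                (value - lo) / (hi - lo),
                (lower - lo) / (hi - lo),
                (upper - lo) / (hi - lo),
            )
        else:
            a, b = moments_to_beta(value, lower, upper)
        return PriorSpec(
            parameter_id, "beta", value, lower, upper, a, b, support=support
        )
    if family == "gamma":
        a, s = moments_to_gamma(value, lower, upper)
        return PriorSpec(parameter_id, "gamma", value, lower, upper, a, s)
    raise ValueError(f"{parameter_id}: unknown prior family {family!r}")


#: Config paths sampled in the PSA, in the deterministic stream order.
_SAMPLED_PATHS = [
    "costs.cardiac_event",
    "costs.clinic_per_year",
    "costs.met_per_cycle",
    "markov.p_ddf_to_met_per_cycle",
    "markov.p_met_to_dead_per_cycle",
    "timing.cardiac_duration_years",
    "timing.cardiac_utility_multiplier",
    "timing.event_time_years",
    "utilities.ddf",
    "utilities.met",
]
_STRATEGY_PATHS = [
    "p_cardiac_event",
    "split.dead",
    "split.met",
    "trastuzumab_schedule_cost",
    "cardiac_monitoring_cost",
]


def _dig(raw: Mapping, path: str):
    node = raw
    for part in path.split("."):
        node = node[part]
    return node


def build_priors(raw: Mapping) -> list[PriorSpec]:
    """Resolve the full, ordered prior list from a raw config mapping."""
    priors = [_resolve_leaf(p, _dig(raw, p)) for p in _SAMPLED_PATHS]
    for strat in sorted(raw["strategies"]):
        for sub in _STRATEGY_PATHS:
            pid = f"strategies.{strat}.{sub}"
            priors.append(_resolve_leaf(pid, _dig(raw, pid)))
    return priors


@dataclass
class PsaRun:
    n_sims: int
    seed: int
    parameter_draws: dict[str, np.ndarray]
    results: dict[str, StrategyResult]

    def strategies(self) -> list[str]:
        return list(self.results)

    def cost_matrix(self) -> np.ndarray:
        """(n_strategies, n_sims) discounted cost per patient."""
        return np.stack([r.cost for r in self.results.values()])

    def qaly_matrix(self) -> np.ndarray:
        return np.stack([r.qalys for r in self.results.values()])

    def draws_frame(self, wtp: float) -> pd.DataFrame:
        rows = []
        for name, res in self.results.items():
            rows.append(
                pd.DataFrame(
                    {
                        "sim_id": np.arange(self.n_sims),
                        "strategy": name,
                        "cost": res.cost,
                        "qalys": res.qalys,
                        "nmb": res.qalys * wtp - res.cost,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_psa(cfg: ModelConfig, n_sims: int = 5000, seed: int = 0) -> PsaRun:
    """Joint PSA: sample all priors, evaluate every strategy per draw."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    priors = build_priors(cfg.raw)
    streams = np.random.SeedSequence(seed).spawn(len(priors))
    draws: dict[str, np.ndarray] = {}
    for prior, ss in zip(priors, streams):
        draws[prior.parameter_id] = prior.sample(n_sims, np.random.default_rng(ss))

    timing = TreeTimingAssumptions(
        event_time_years=draws["timing.event_time_years"],
        cardiac_utility_multiplier=draws["timing.cardiac_utility_multiplier"],
        cardiac_duration_years=draws["timing.cardiac_duration_years"],
        clinic_followup_years=cfg.timing.clinic_followup_years,
    )
    base_mk = cfg.markov
    markov = MarkovParams(
        p_ddf_to_met_per_cycle=draws["markov.p_ddf_to_met_per_cycle"],
        p_met_to_dead_per_cycle=draws["markov.p_met_to_dead_per_cycle"],
        life_table=base_mk.life_table,
        utility_ddf=draws["utilities.ddf"],
        utility_met=draws["utilities.met"],
        age_utility_factors=base_mk.age_utility_factors,
        met_cost_per_cycle=draws["costs.met_per_cycle"],
        ddf_cost_per_cycle=base_mk.ddf_cost_per_cycle,
        clinic_cost_per_year=draws["costs.clinic_per_year"],
        met_risk_end_year=base_mk.met_risk_end_year,
        met_risk_taper=base_mk.met_risk_taper,
        tunnel_band_years=base_mk.tunnel_band_years,
        tunnel_end_year=base_mk.tunnel_end_year,
        start_age=base_mk.start_age,
        horizon_years=base_mk.horizon_years,
    )
    results = {}
    for name in cfg.strategies:
        pre = f"strategies.{name}."
        p_dead = draws[pre + "split.dead"]
        p_met = draws[pre + "split.met"]
        p_ddf = 1.0 - p_dead - p_met
        bad = p_ddf < 0.0  # numerically possible for tiny cohorts; renormalise
        if np.any(bad):
            total = p_dead[bad] + p_met[bad]
            p_dead = p_dead.copy()
            p_met = p_met.copy()
            p_dead[bad] /= total
            p_met[bad] /= total
            p_ddf = 1.0 - p_dead - p_met
        strat = StrategyParams(
            name=name,
            p_cardiac_event=draws[pre + "p_cardiac_event"],
            p_ddf_5y=p_ddf,
            p_met_5y=p_met,
            p_dead_5y=p_dead,
            trastuzumab_schedule_cost=draws[pre + "trastuzumab_schedule_cost"],
            cardiac_monitoring_cost=draws[pre + "cardiac_monitoring_cost"],
            cardiac_event_cost=draws["costs.cardiac_event"],
        )
        results[name] = run_strategy(
            strat, timing, markov, cfg.discount, cohort_size=cfg.cohort_size
        )
    return PsaRun(n_sims=n_sims, seed=seed, parameter_draws=draws, results=results)


def summarize(run: PsaRun, wtp: float) -> pd.DataFrame:
    """Per-strategy mean and percentile-based 95% intervals.

    Net monetary benefit is computed per draw (NMB = QALYs*WTP - cost) and
    then summarised, so its mean obeys the identity
    mean(NMB) = WTP*mean(QALYs) - mean(cost) exactly.
    """
    rows = []
    for name, res in run.results.items():
        nmb = res.qalys * wtp - res.cost
        for quantity, x in (("cost", res.cost), ("qalys", res.qalys), ("nmb", nmb)):
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                {
                    "strategy": name,
                    "quantity": quantity,
                    "mean": float(np.mean(x)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)
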