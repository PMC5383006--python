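"""Decision-tree + Markov cohort model for adjuvant trastuzumab durations.

Structure
---------
Years 0-5 are a decision tree: at time zero each strategy's cohort receives
its trastuzumab schedule (acquisition + delivery cost) and splits into a
cardiac-event / no-event branch; five-year trial survival then splits the
cohort into distant-disease-free (DDF), metastatic and dead.  Metastasis or
death within the tree is placed at a fixed event time (base 2.5 years, the
tree midpoint); decedents spend half the pre-event period DDF and half
metastatic.  DDF patients attend a breast-cancer clinic for three years or
until metastasis.

From year 5 the cohort enters a three-state Markov model (DDF, metastatic,
dead) with quarterly cycles to a lifetime horizon (entry age 52, horizon 48
years, to age 100).  DDF patients progress to metastasis at a per-cycle
probability that tapers to zero by year 20, and die of other causes per an
all-cause life table; metastatic patients additionally face a
disease-specific per-cycle death probability.  There is no recovery from
metastasis.  Utilities are banded in 5-year tunnels up to year 25 (frozen
thereafter); all-cause mortality always follows actual age.  Costs and
utilities are applied to state occupancy at the beginning of each cycle (no
half-cycle correction), and both streams are discounted at an annual rate
converted to the cycle length.

All rate-, cost- and probability-valued inputs accept scalars or aligned
1-D arrays, so a probabilistic sensitivity analysis is a single vectorised
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DiscountSpec",
    "StrategyParams",
    "TreeTimingAssumptions",
    "MarkovParams",
    "CohortTrace",
    "TreeResult",
    "StrategyResult",
    "per_cycle_rate",
    "run_decision_tree",
    "run_markov",
    "run_strategy",
    "load_life_table",
    "ModelConfig",
    "load_config",
    "leaf_value",
    "unfilled_placeholders",
]

ArrayLike = Any  # scalar or 1-D numpy array


def _arr(x: ArrayLike) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


# --------------------------------------------------------------------------
# Discounting


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate and model cycle length.

    ``per_cycle_rate`` compounds the annual rate down to one cycle:
    (1 + annual)^cycle_length - 1, so an annual rate of zero discounts
    nothing at any cycle length.
    """

    annual_rate: float = 0.035
    cycle_length_years: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.annual_rate <= 0.2):
            raise ValueError(f"annual discount rate {self.annual_rate} outside [0, 0.2]")
        if self.cycle_length_years <= 0:
            raise ValueError("cycle length must be positive")

    @property
    def per_cycle_rate(self) -> float:
        return (1.0 + self.annual_rate) ** self.cycle_length_years - 1.0

    def factor(self, t_years: np.ndarray | float) -> np.ndarray | float:
        """Discount factor applied to a reward occurring at ``t_years``."""
        return (1.0 + self.annual_rate) ** (-np.asarray(t_years, dtype=float))


def per_cycle_rate(spec: DiscountSpec) -> float:
    return spec.per_cycle_rate


# --------------------------------------------------------------------------
# Parameter containers


@dataclass
class StrategyParams:
    """Decision-tree inputs specific to one treatment strategy."""

    name: str
    p_cardiac_event: ArrayLike
    p_ddf_5y: ArrayLike
    p_met_5y: ArrayLike
    p_dead_5y: ArrayLike
    trastuzumab_schedule_cost: ArrayLike
    cardiac_monitoring_cost: ArrayLike
    cardiac_event_cost: ArrayLike

    def validate(self) -> None:
        s = _arr(self.p_ddf_5y) + _arr(self.p_met_5y) + _arr(self.p_dead_5y)
        if np.any(np.abs(s - 1.0) > 1e-9):
            raise ValueError(
                f"strategy {self.name}: five-year state split does not sum to 1 "
                f"(max deviation {np.max(np.abs(s - 1.0)):.2e})"
            )
        for name in ("p_cardiac_event", "p_ddf_5y", "p_met_5y", "p_dead_5y"):
            v = _arr(getattr(self, name))
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"strategy {self.name}: {name} outside [0, 1]")


@dataclass
class TreeTimingAssumptions:
    """When tree events happen and how a cardiac event weighs on utility.

    ``event_time_years`` places metastasis onset (metastatic branch) and
    death (dead branch) within the 5-year tree; decedents are DDF for
    ``pre_death_ddf_years`` then metastatic for ``pre_death_met_years``.
    In the base case the pre-death periods are linked to half the event
    time each.  A symptomatic cardiac event multiplies the DDF utility by
    ``cardiac_utility_multiplier`` for ``cardiac_duration_years``.
    """

    event_time_years: ArrayLike = 2.5
    pre_death_ddf_years: ArrayLike | None = None  # None -> event_time/2
    pre_death_met_years: ArrayLike | None = None
    cardiac_utility_multiplier: ArrayLike = 0.60
    cardiac_duration_years: ArrayLike = 0.25
    clinic_followup_years: float = 3.0

    def resolved(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ev = _arr(self.event_time_years)
        pre_d = _arr(self.pre_death_ddf_years) if self.pre_death_ddf_years is not None else ev / 2.0
        pre_m = _arr(self.pre_death_met_years) if self.pre_death_met_years is not None else ev / 2.0
        return ev, pre_d, pre_m


@dataclass
class MarkovParams:
    """Lifetime-extrapolation inputs shared by all strategies."""

    p_ddf_to_met_per_cycle: ArrayLike
    p_met_to_dead_per_cycle: ArrayLike
    life_table: np.ndarray  # annual all-cause mortality prob, indexed by age
    utility_ddf: ArrayLike
    utility_met: ArrayLike
    age_utility_factors: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    met_cost_per_cycle: ArrayLike = 0.0
    ddf_cost_per_cycle: ArrayLike = 0.0
    clinic_cost_per_year: ArrayLike = 0.0
    met_risk_end_year: float = 20.0
    met_risk_taper: str = "linear"  # linear | step
    #: cycle length on which the per-cycle probabilities and costs are
    #: defined; running the model at another cycle length rescales costs
    #: linearly and probabilities via compounding.
    reference_cycle_years: float = 0.25
    tunnel_band_years: float = 5.0
    tunnel_end_year: float = 25.0
    start_age: float = 52.0
    horizon_years: float = 48.0
    tree_years: float = 5.0

    def utility_band(self, t_years: float) -> int:
        t_banded = min(t_years, self.tunnel_end_year - 1e-12)
        return min(int(t_banded // self.tunnel_band_years), len(self.age_utility_factors) - 1)

    def state_utilities(self, t_years: float) -> tuple[np.ndarray, np.ndarray]:
        f = self.age_utility_factors[self.utility_band(t_years)]
        return _arr(self.utility_ddf) * f, _arr(self.utility_met) * f

    def annual_mortality(self, age: float) -> float:
        idx = int(np.floor(age))
        if idx >= len(self.life_table) or idx < 0:
            raise ValueError(f"life table does not cover age {idx}")
        return float(self.life_table[idx])

    def p_met_onset(self, t_years: float) -> np.ndarray:
        """Per-cycle DDF->metastatic probability at cycle start ``t_years``.

        Exactly zero for t >= met_risk_end_year; the linear taper declines
        from the year-5 value to zero at that endpoint.
        """
        p0 = _arr(self.p_ddf_to_met_per_cycle)
        if t_years >= self.met_risk_end_year:
            return np.zeros_like(p0)
        if self.met_risk_taper == "step":
            return p0
        if self.met_risk_taper == "linear":
            frac = (self.met_risk_end_year - t_years) / (
                self.met_risk_end_year - self.tree_years
            )
            return p0 * min(max(frac, 0.0), 1.0)
        raise ValueError(f"unknown taper {self.met_risk_taper!r}")


# --------------------------------------------------------------------------
# Results


@dataclass
class TreeResult:
    cost: np.ndarray
    qalys: np.ndarray
    end_split: tuple[np.ndarray, np.ndarray, np.ndarray]  # (ddf, met, dead)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and reward streams (per cohort member)."""

    times: np.ndarray  # cycle start times in years
    occupancy: np.ndarray  # (n_cycles, 3[, n]) in state order ddf, met, dead
    cycle_cost: np.ndarray
    cycle_cost_discounted: np.ndarray
    cycle_qalys: np.ndarray
    cycle_qalys_discounted: np.ndarray

    @property
    def total_cost(self) -> np.ndarray:
        return self.cycle_cost_discounted.sum(axis=0)

    @property
    def total_qalys(self) -> np.ndarray:
        return self.cycle_qalys_discounted.sum(axis=0)

    def as_frame(self) -> pd.DataFrame:
        occ = self.occupancy
        if occ.ndim == 3:
            occ = occ[..., 0]
        sel = (lambda a: a[..., 0]) if self.cycle_cost.ndim == 2 else (lambda a: a)
        return pd.DataFrame(
            {
                "time_years": self.times,
                "ddf": occ[:, 0],
                "metastatic": occ[:, 1],
                "dead": occ[:, 2],
                "cost": sel(self.cycle_cost),
                "cost_discounted": sel(self.cycle_cost_discounted),
                "qalys": sel(self.cycle_qalys),
                "qalys_discounted": sel(self.cycle_qalys_discounted),
            }
        )


@dataclass
class StrategyResult:
    name: str
    cost: np.ndarray  # discounted, per patient
    qalys: np.ndarray  # discounted, per patient

    def scalar(self) -> tuple[float, float]:
        return float(np.asarray(self.cost).ravel()[0]), float(
            np.asarray(self.qalys).ravel()[0]
        )


# --------------------------------------------------------------------------
# Decision tree


def run_decision_tree(
    strategy: StrategyParams,
    timing: TreeTimingAssumptions,
    markov: MarkovParams,
    discount: DiscountSpec,
) -> TreeResult:
    """Expected per-patient discounted cost and QALYs over years 0-5.

    Rewards accrue at cycle starts on the model's cycle grid; branch
    probabilities weight the three survival pathways, and the cardiac-event
    split adjusts utility multiplicatively for its duration.  Returns the
    year-5 state split handed to the Markov model.
    """
    strategy.validate()
    ev, pre_d, pre_m = timing.resolved()
    p_ddf, p_met, p_dead = (
        _arr(strategy.p_ddf_5y),
        _arr(strategy.p_met_5y),
        _arr(strategy.p_dead_5y),
    )
    u_ddf0, u_met0 = markov.state_utilities(0.0)
    dt = discount.cycle_length_years
    scale = dt / markov.reference_cycle_years
    clinic_q = _arr(markov.clinic_cost_per_year) * dt
    met_cost_q = _arr(markov.met_cost_per_cycle) * scale
    clinic_end = timing.clinic_followup_years

    times = np.arange(0.0, markov.tree_years - 1e-9, dt)
    qalys = np.zeros_like(u_ddf0 * p_ddf)
    cost = np.zeros_like(qalys)
    for t in times:
        f = discount.factor(t)
        band_u_ddf, band_u_met = markov.state_utilities(t)
        # state indicator per branch at this cycle start
        met_in_met_branch = (t >= ev).astype(float)  # else DDF
        dead_ddf = (t < pre_d).astype(float)
        dead_met = ((t >= pre_d) & (t < pre_d + pre_m)).astype(float)
        q = (
            p_ddf * band_u_ddf
            + p_met * ((1 - met_in_met_branch) * band_u_ddf + met_in_met_branch * band_u_met)
            + p_dead * (dead_ddf * band_u_ddf + dead_met * band_u_met)
        ) * dt
        c = (
            p_ddf * clinic_q * (t < clinic_end)
            + p_met * (
                (1 - met_in_met_branch) * clinic_q * (t < clinic_end)
                + met_in_met_branch * met_cost_q
            )
            + p_dead * (dead_ddf * clinic_q * (t < clinic_end) + dead_met * met_cost_q)
        )
        qalys = qalys + q * f
        cost = cost + c * f

    # cardiac-event branch: utility multiplier over its duration, plus the
    # event cost; monitoring and the trastuzumab schedule are paid at t=0.
    p_card = _arr(strategy.p_cardiac_event)
    mult = _arr(timing.cardiac_utility_multiplier)
    dur = _arr(timing.cardiac_duration_years)
    qalys = qalys - p_card * (1.0 - mult) * u_ddf0 * dur
    cost = (
        cost
        + _arr(strategy.trastuzumab_schedule_cost)
        + _arr(strategy.cardiac_monitoring_cost)
        + p_card * _arr(strategy.cardiac_event_cost)
    )
    return TreeResult(cost=cost, qalys=qalys, end_split=(p_ddf, p_met, p_dead))


# --------------------------------------------------------------------------
# Markov model


def run_markov(
    start_split: tuple[ArrayLike, ArrayLike, ArrayLike],
    params: MarkovParams,
    discount: DiscountSpec,
    cohort_size: float = 1.0,
) -> CohortTrace:
    """Iterate the three-state cohort from year 5 to the horizon.

    ``start_split`` is the year-5 (ddf, met, dead) occupancy on the
    simplex.  Rewards are applied to occupancy at each cycle start and
    discounted from model time zero.
    """
    ddf, met, dead = (_arr(s) * cohort_size for s in start_split)
    ddf, met, dead = np.broadcast_arrays(ddf, met, dead)
    ddf, met, dead = ddf.copy(), met.copy(), dead.copy()
    tot = ddf + met + dead
    if np.any(np.abs(tot - cohort_size) > 1e-9 * max(cohort_size, 1.0)):
        raise ValueError("start split does not sum to the cohort size")

    dt = discount.cycle_length_years
    times = np.arange(params.tree_years, params.horizon_years - 1e-9, dt)
    n_cycles = len(times)
    shape = ddf.shape
    occupancy = np.empty((n_cycles, 3) + shape)
    qaly_u = np.empty((n_cycles,) + shape)
    qaly_d = np.empty_like(qaly_u)
    cost_u = np.empty_like(qaly_u)
    cost_d = np.empty_like(qaly_u)

    scale = dt / params.reference_cycle_years
    met_cost = _arr(params.met_cost_per_cycle) * scale
    ddf_cost = _arr(params.ddf_cost_per_cycle) * scale
    p_md = 1.0 - (1.0 - _arr(params.p_met_to_dead_per_cycle)) ** scale

    for i, t in enumerate(times):
        occupancy[i, 0], occupancy[i, 1], occupancy[i, 2] = ddf, met, dead
        u_ddf, u_met = params.state_utilities(t)
        f = discount.factor(t)
        q = (ddf * u_ddf + met * u_met) * dt
        c = ddf * ddf_cost + met * met_cost
        qaly_u[i], cost_u[i] = q, c
        qaly_d[i], cost_d[i] = q * f, c * f

        q_annual = params.annual_mortality(params.start_age + t)
        q_cycle = 1.0 - (1.0 - q_annual) ** dt
        p_dm = 1.0 - (1.0 - params.p_met_onset(t)) ** scale
        # competing risks: all-cause applies first, disease-specific to survivors
        ddf_dead = ddf * q_cycle
        ddf_met = ddf * (1.0 - q_cycle) * p_dm
        met_dead = met * (1.0 - (1.0 - q_cycle) * (1.0 - p_md))
        ddf = ddf - ddf_dead - ddf_met
        met = met + ddf_met - met_dead
        dead = dead + ddf_dead + met_dead

    return CohortTrace(
        times=times,
        occupancy=occupancy,
        cycle_cost=cost_u,
        cycle_cost_discounted=cost_d,
        cycle_qalys=qaly_u,
        cycle_qalys_discounted=qaly_d,
    )


def run_strategy(
    strategy: StrategyParams,
    timing: TreeTimingAssumptions,
    markov: MarkovParams,
    discount: DiscountSpec,
    cohort_size: float = 100.0,
) -> StrategyResult:
    """Tree + Markov totals per patient (discounted).

    The cohort multiplier cancels in per-patient results; it is retained so
    traces report occupancy on the familiar per-100 scale.
    """
    tree = run_decision_tree(strategy, timing, markov, discount)
    trace = run_markov(tree.end_split, markov, discount, cohort_size=cohort_size)
    return StrategyResult(
        name=strategy.name,
        cost=tree.cost + trace.total_cost / cohort_size,
        qalys=tree.qalys + trace.total_qalys / cohort_size,
    )


# --------------------------------------------------------------------------
# Configuration


def load_life_table(path: str | Path) -> np.ndarray:
    """Read an age-indexed annual mortality CSV into a dense array.

    Expects columns ``age`` and ``annual_mortality_probability``; returns an
    array of length max(age)+1 with NaN outside the covered range.
    """
    df = pd.read_csv(path)
    required = {"age", "annual_mortality_probability"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: life table needs columns {sorted(required)}")
    ages = df["age"].astype(int).to_numpy()
    q = df["annual_mortality_probability"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError(f"{path}: mortality probabilities outside [0, 1]")
    table = np.full(int(ages.max()) + 1, np.nan)
    table[ages] = q
    return table


def leaf_value(leaf: Any) -> Any:
    """Extract the base-case value from a config leaf.

    Leaves are either plain scalars or mappings carrying ``value`` together
    with bounds, prior family and a data-source tag.
    """
    if isinstance(leaf, Mapping):
        return leaf.get("value")
    return leaf


def unfilled_placeholders(cfg: Mapping, prefix: str = "") -> list[str]:
    """Paths of leaves still flagged as placeholders or missing a value."""
    missing = []
    for key, node in cfg.items():
        path = f"{prefix}{key}"
        if isinstance(node, Mapping):
            if "value" in node or "source" in node:
                if node.get("source") == "placeholder" or (
                    "value" in node and node.get("value") is None
                ):
                    missing.append(path)
                continue
            missing.extend(unfilled_placeholders(node, prefix=f"{path}."))
    return missing


# Costs common to all strategies (e.g. chemotherapy backbone) are excluded
# from the model by design; naming them in the config is an error rather
# than a silently double-counted input.
FORBIDDEN_COST_KEYS = {"chemotherapy", "common_drug_costs", "common_procedure_costs"}


@dataclass
class ModelConfig:
    raw: dict
    discount: DiscountSpec
    timing: TreeTimingAssumptions
    markov: MarkovParams
    strategies: dict[str, StrategyParams]
    cohort_size: float
    wtp_grid: np.ndarray
    reference_wtp: float
    budget: dict = field(default_factory=dict)

    def strategy_names(self) -> list[str]:
        return list(self.strategies)


def load_config(
    source: str | Path | Mapping, life_table: np.ndarray | None = None
) -> ModelConfig:
    """Build model objects from a YAML/JSON mapping (or its file path)."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
        base_dir = Path(source).parent
    else:
        raw = dict(source)
        base_dir = Path(".")

    forbidden = FORBIDDEN_COST_KEYS & set(raw.get("costs", {}))
    if forbidden:
        raise ValueError(
            f"config names arm-common cost(s) {sorted(forbidden)}; costs shared by "
            "all strategies are excluded from the model by design"
        )

    v = leaf_value
    disc = raw.get("discount", {})
    discount = DiscountSpec(
        annual_rate=float(v(disc.get("annual_rate", 0.035))),
        cycle_length_years=float(v(disc.get("cycle_length_years", 0.25))),
    )
    t = raw.get("timing", {})
    timing = TreeTimingAssumptions(
        event_time_years=float(v(t.get("event_time_years", 2.5))),
        cardiac_utility_multiplier=float(v(t.get("cardiac_utility_multiplier", 0.60))),
        cardiac_duration_years=float(v(t.get("cardiac_duration_years", 0.25))),
        clinic_followup_years=float(v(t.get("clinic_followup_years", 3.0))),
    )
    if life_table is None:
        lt_path = raw.get("life_table_path")
        if lt_path is None:
            raise ValueError("config lacks life_table_path and no life table supplied")
        life_table = load_life_table(base_dir / lt_path)

    m = raw.get("markov", {})
    u = raw.get("utilities", {})
    c = raw.get("costs", {})
    markov = MarkovParams(
        p_ddf_to_met_per_cycle=float(v(m.get("p_ddf_to_met_per_cycle"))),
        p_met_to_dead_per_cycle=float(v(m.get("p_met_to_dead_per_cycle"))),
        life_table=life_table,
        utility_ddf=float(v(u.get("ddf"))),
        utility_met=float(v(u.get("met"))),
        age_utility_factors=tuple(u.get("age_factors", (1.0,) * 5)),
        met_cost_per_cycle=float(v(c.get("met_per_cycle", 0.0))),
        ddf_cost_per_cycle=float(v(c.get("ddf_per_cycle", 0.0))),
        clinic_cost_per_year=float(v(c.get("clinic_per_year", 0.0))),
        met_risk_end_year=float(v(m.get("met_risk_end_year", 20.0))),
        met_risk_taper=str(m.get("met_risk_taper", "linear")),
        tunnel_band_years=float(v(m.get("tunnel_band_years", 5.0))),
        tunnel_end_year=float(v(m.get("tunnel_end_year", 25.0))),
        start_age=float(v(raw.get("start_age", 52.0))),
        horizon_years=float(v(raw.get("horizon_years", 48.0))),
    )
    strategies = {}
    for name, s in raw.get("strategies", {}).items():
        split = s.get("split")
        strategies[name] = StrategyParams(
            name=name,
            p_cardiac_event=float(v(s.get("p_cardiac_event"))),
            p_ddf_5y=float(v(split.get("ddf"))),
            p_met_5y=float(v(split.get("met"))),
            p_dead_5y=float(v(split.get("dead"))),
            trastuzumab_schedule_cost=float(v(s.get("trastuzumab_schedule_cost"))),
            cardiac_monitoring_cost=float(v(s.get("cardiac_monitoring_cost", 0.0))),
            cardiac_event_cost=float(v(c.get("cardiac_event", 0.0))),
        )
        strategies[name].validate()
    econ = raw.get("economics", {})
    grid = econ.get("wtp_grid", {"start": 0, "stop": 150_000, "step": 2_500})
    if isinstance(grid, Mapping):
        wtp_grid = np.arange(
            float(grid["start"]), float(grid["stop"]) + 1e-9, float(grid["step"])
        )
    else:
        wtp_grid = np.asarray(grid, dtype=float)
    return ModelConfig(
        raw=raw,
        discount=discount,
        timing=timing,
        markov=markov,
        strategies=strategies,
        cohort_size=float(v(raw.get("cohort_size", 100.0))),
        wtp_grid=wtp_grid,
        reference_wtp=float(v(econ.get("reference_wtp", 30_000.0))),
        budget=raw.get("budget", {}),
    )


def run_all_strategies(cfg: ModelConfig) -> dict[str, StrategyResult]:
    return {
        name: run_strategy(
            s, cfg.timing, cfg.markov, cfg.discount, cohort_size=cfg.cohort_size
        )
        for name, s in cfg.strategies.items()
    }
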