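"""Downstream economics: NMB, pairwise ICERs, CEAC/CEAF, budget impact.

Net monetary benefit linearises the cost-effectiveness trade-off at a
willingness-to-pay threshold (NMB = QALYs x WTP - cost).  Pairwise
comparisons report an incremental cost-effectiveness ratio only when the
increments' signs call for one; strict dominance (cheaper and more
effective) and dominated positions are flagged instead of quoting a
meaningless ratio.  The acceptability curve (CEAC) is the fraction of PSA
draws in which a strategy has the highest NMB at each WTP; the frontier
(CEAF) is the strategy with the highest *expected* NMB at each WTP, which
need not be the CEAC argmax.  The budget-impact model applies an
incidence -> adjuvant-responsive -> HER2-positive -> eligible cascade and
scales per-patient cost and QALY increments to the annual eligible cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import StrategyResult
from .psa import PsaRun

__all__ = [
    "EconConfig",
    "PairwiseComparison",
    "BudgetImpactInputs",
    "nmb",
    "icer",
    "ceac",
    "ceaf",
    "budget_impact",
]


@dataclass(frozen=True)
class EconConfig:
    wtp_grid: np.ndarray
    reference_wtp: float = 30_000.0

    def __post_init__(self) -> None:
        g = np.asarray(self.wtp_grid, dtype=float)
        if g.ndim != 1 or len(g) < 1:
            raise ValueError("wtp_grid must be a 1-D sequence")
        if np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValueError("wtp_grid must be non-negative and strictly increasing")
        object.__setattr__(self, "wtp_grid", g)


def nmb(qalys, cost, wtp: float):
    """Net monetary benefit at a willingness-to-pay per QALY."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return np.asarray(qalys) * wtp - np.asarray(cost)


@dataclass(frozen=True)
class PairwiseComparison:
    new: str
    old: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    classification: str  # icer | dominant | dominated | equivalent | undefined

    def describe(self) -> str:
        if self.classification == "icer":
            return f"{self.new} vs {self.old}: ICER {self.icer:,.0f} per QALY"
        return f"{self.new} vs {self.old}: {self.classification}"


def icer(new: StrategyResult, old: StrategyResult) -> PairwiseComparison:
    """Pairwise incremental comparison with dominance classification.

    A negative ICER is never reported: cheaper-and-better is ``dominant``,
    dearer-and-worse is ``dominated``.  Zero QALY increment with a cost
    difference is flagged ``undefined`` rather than divided.
    """
    c_new, q_new = new.scalar()
    c_old, q_old = old.scalar()
    if not all(map(math.isfinite, (c_new, q_new, c_old, q_old))):
        raise ValueError("strategy results must be finite")
    d_cost = c_new - c_old
    d_q = q_new - q_old
    if d_q == 0.0 and d_cost == 0.0:
        cls, ratio = "equivalent", None
    elif d_q == 0.0:
        cls, ratio = "undefined", None
    elif d_cost <= 0.0 and d_q > 0.0:
        cls, ratio = "dominant", None
    elif d_cost >= 0.0 and d_q < 0.0:
        cls, ratio = "dominated", None
    else:
        cls, ratio = "icer", d_cost / d_q
    return PairwiseComparison(
        new=new.name, old=old.name, delta_cost=d_cost, delta_qalys=d_q,
        icer=ratio, classification=cls,
    )


def ceac(run: PsaRun, econ: EconConfig) -> pd.DataFrame:
    """Probability each strategy is most cost-effective at each WTP.

    Ties for the highest per-draw NMB are split equally, so probabilities
    sum to one at every WTP exactly.
    """
    costs = run.cost_matrix()
    qalys = run.qaly_matrix()
    names = run.strategies()
    rows = []
    for wtp in econ.wtp_grid:
        benefit = qalys * wtp - costs  # (S, n)
        best = benefit.max(axis=0, keepdims=True)
        is_best = benefit == best
        weights = is_best / is_best.sum(axis=0, keepdims=True)
        probs = weights.mean(axis=1)
        rows.extend(
            {"wtp": float(wtp), "strategy": n, "probability": float(p)}
            for n, p in zip(names, probs)
        )
    return pd.DataFrame(rows)


def ceaf(run: PsaRun, econ: EconConfig) -> pd.DataFrame:
    """Frontier strategy (highest mean NMB) per WTP, with switch points.

    Returned frame has one row per (wtp, strategy) with the strategy's mean
    NMB and a ``on_frontier`` flag; the frontier NMB is the pointwise
    maximum of the per-strategy mean NMB lines.
    """
    mean_cost = run.cost_matrix().mean(axis=1)
    mean_qaly = run.qaly_matrix().mean(axis=1)
    names = run.strategies()
    rows = []
    for wtp in econ.wtp_grid:
        mean_nmb = mean_qaly * wtp - mean_cost
        winner = int(np.argmax(mean_nmb))
        rows.extend(
            {
                "wtp": float(wtp),
                "strategy": n,
                "mean_nmb": float(v),
                "on_frontier": i == winner,
            }
            for i, (n, v) in enumerate(zip(names, mean_nmb))
        )
    return pd.DataFrame(rows)


def frontier_switch_points(frontier: pd.DataFrame) -> list[tuple[float, str]]:
    """(wtp, strategy) pairs where the frontier strategy changes."""
    on = frontier[frontier["on_frontier"]].sort_values("wtp")
    switches = []
    prev = None
    for _, row in on.iterrows():
        if row["strategy"] != prev:
            switches.append((row["wtp"], row["strategy"]))
            prev = row["strategy"]
    return switches


# --------------------------------------------------------------------------
# Budget impact


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BudgetImpactInputs:
    annual_incidence: float
    p_adjuvant_responsive: float
    p_her2_positive: float
    p_ineligible: float
    per_patient_cost_delta: float
    per_patient_qaly_delta: float

    def __post_init__(self) -> None:
        for name in ("p_adjuvant_responsive", "p_her2_positive", "p_ineligible"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.annual_incidence < 0:
            raise ValueError("annual incidence must be non-negative")


def budget_impact(inputs: BudgetImpactInputs) -> dict:
    """Annual eligibility cascade and totals for a policy switch.

    Patient counts are rounded half-up at each cascade stage, matching how
    such chained headline figures are typically published; unrounded values
    are reported alongside.
    """
    candidates_raw = (
        inputs.annual_incidence
        * inputs.p_adjuvant_responsive
        * inputs.p_her2_positive
    )
    candidates = _round_half_up(candidates_raw)
    eligible_raw = candidates * (1.0 - inputs.p_ineligible)
    eligible = _round_half_up(eligible_raw)
    return {
        "candidate_count": candidates,
        "candidate_count_unrounded": candidates_raw,
        "eligible_count": eligible,
        "eligible_count_unrounded": eligible_raw,
        "total_cost_delta": eligible * inputs.per_patient_cost_delta,
        "total_qaly_delta": eligible * inputs.per_patient_qaly_delta,
    }
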