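"""Rate-based network meta-analysis with SUCRA ranking.

Arm-level inputs are aggregate event counts d and person-years e.  Each
trial contributes, for each non-baseline arm, a contrast on the log rate
ratio scale,

    y = log((d_a/e_a) / (d_b/e_b)),   var(y) = 1/d_a + 1/d_b,

the usual normal approximation for Poisson rates.  Counts below 1 receive a
continuity correction (default +0.5) before the variance is formed, since
1/d is undefined or explosive for half-events.  Multi-arm trials induce a
shared-baseline covariance of 1/d_b between their contrasts.

The consistency model expresses every contrast as a difference of "basic
parameters" (log rate ratios of each node versus the reference node) and is
fitted by generalized least squares; a common-tau^2 random-effects variant
via the method of moments is available.  Treatment rankings (probability of
being best = fewest events, and the surface under the cumulative ranking
curve, SUCRA) are obtained by parametric resampling from the fitted
multivariate normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_network import EvidenceNetwork, TrialArm, ValidationError

__all__ = [
    "Contrast",
    "NmaFit",
    "SucraTable",
    "EstimationError",
    "build_contrasts",
    "fit_consistency",
    "sucra",
    "check_transitivity_effect",
]

OUTCOMES = ("proxy_survival", "os", "cardiac")


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Contrast:
    """One within-trial log rate ratio (node_a versus node_b)."""

    trial_id: str
    node_a: str
    node_b: str
    log_rate_ratio: float
    variance: float
    #: variance contribution of the shared baseline arm; equals the
    #: within-trial covariance with the trial's sibling contrasts.
    baseline_variance: float
    continuity_applied: bool = False

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValidationError(f"{self.trial_id}: non-positive contrast variance")


@dataclass(frozen=True)
class NmaFit:
    outcome: str
    reference: str
    nodes: tuple[str, ...]  # non-reference nodes, order of basic_parameters
    basic_parameters: np.ndarray
    covariance_matrix: np.ndarray
    model: str  # fixed | random
    tau2: float
    n_contrasts: int

    def summary(self) -> dict:
        return {
            "outcome": self.outcome,
            "reference": self.reference,
            "model": self.model,
            "tau2": self.tau2,
            "n_contrasts": self.n_contrasts,
            "log_rate_ratio_vs_reference": {
                n: float(b) for n, b in zip(self.nodes, self.basic_parameters)
            },
            "se": {
                n: float(np.sqrt(v))
                for n, v in zip(self.nodes, np.diag(self.covariance_matrix))
            },
        }


@dataclass(frozen=True)
class SucraTable:
    nodes: tuple[str, ...]
    rank_probabilities: np.ndarray  # (node, rank), rank 0 = best
    prob_best: np.ndarray
    sucra: np.ndarray  # in [0, 1]
    mean_rank: np.ndarray  # 1-based
    n_draws: int
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        """CSV-ready table: node, prob_best, sucra_pct, mean_rank."""
        return pd.DataFrame(
            {
                "node": self.nodes,
                "prob_best": np.round(self.prob_best, 6),
                "sucra_pct": np.round(100.0 * self.sucra, 4),
                "mean_rank": np.round(self.mean_rank, 4),
            }
        )

    def ordering(self) -> list[str]:
        """Nodes from best to worst by SUCRA (mean rank breaks ties)."""
        idx = np.lexsort((self.mean_rank, -self.sucra))
        return [self.nodes[i] for i in idx]


def _reference_node(network: EvidenceNetwork) -> str:
    zero = [n for n in network.nodes if n.startswith("zero")]
    return zero[0] if zero else network.nodes[0]


def build_contrasts(
    network: EvidenceNetwork,
    outcome: str,
    continuity: float = 0.5,
    reference: str | None = None,
) -> list[Contrast]:
    """Construct one contrast per non-baseline arm per trial.

    The trial baseline is the network reference node when the trial includes
    it, otherwise the trial's first node in sorted order.
    """
    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}")
    reference = reference or _reference_node(network)

    def corrected(d: float) -> tuple[float, bool]:
        return (d + continuity, True) if d < 1 else (d, False)

    contrasts: list[Contrast] = []
    for trial in sorted({a.trial_id for a in network.arms}):
        t_arms = [a for a in network.arms if a.trial_id == trial]
        base = next(
            (a for a in t_arms if a.node_label == reference),
            t_arms[0],
        )
        for arm in t_arms:
            if arm is base:
                continue
            for side in (arm, base):
                if side.person_years <= 0:
                    raise ValidationError(
                        f"{trial}/{side.node_label}: zero person-years"
                    )
            d_a, corr_a = corrected(arm.events(outcome))
            d_b, corr_b = corrected(base.events(outcome))
            contrasts.append(
                Contrast(
                    trial_id=trial,
                    node_a=arm.node_label,
                    node_b=base.node_label,
                    log_rate_ratio=float(
                        np.log((d_a / arm.person_years) / (d_b / base.person_years))
                    ),
                    variance=1.0 / d_a + 1.0 / d_b,
                    baseline_variance=1.0 / d_b,
                    continuity_applied=corr_a or corr_b,
                )
            )
    return contrasts


def _design(
    contrasts: Sequence[Contrast], reference: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    nodes = sorted(
        {c.node_a for c in contrasts} | {c.node_b for c in contrasts} - {reference}
    )
    nodes = [n for n in nodes if n != reference]
    col = {n: j for j, n in enumerate(nodes)}
    k = len(contrasts)
    X = np.zeros((k, len(nodes)))
    y = np.empty(k)
    for i, c in enumerate(contrasts):
        y[i] = c.log_rate_ratio
        if c.node_a != reference:
            X[i, col[c.node_a]] = 1.0
        if c.node_b != reference:
            X[i, col[c.node_b]] = -1.0
    S = np.zeros((k, k))
    for i, ci in enumerate(contrasts):
        S[i, i] = ci.variance
        for j in range(i + 1, k):
            cj = contrasts[j]
            if ci.trial_id == cj.trial_id and ci.node_b == cj.node_b:
                S[i, j] = S[j, i] = ci.baseline_variance
    return X, y, S, tuple(nodes)


def _connected_components_of(contrasts: Sequence[Contrast]) -> list[set[str]]:
    import networkx as nx

    g = nx.Graph()
    for c in contrasts:
        g.add_edge(c.node_a, c.node_b)
    return [set(c) for c in nx.connected_components(g)]


def fit_consistency(
    contrasts: Sequence[Contrast],
    outcome: str = "proxy_survival",
    model: str = "fixed",
    reference: str | None = None,
) -> NmaFit:
    """GLS fit of the consistency model on a list of contrasts.

    ``model="random"`` adds a single between-trial variance tau^2 estimated
    by the method of moments (DerSimonian-Laird generalisation of Cochran's
    Q) to every contrast variance.  With at most one or two trials per
    comparison tau^2 is usually degenerate at zero; fixed effects is the
    default.
    """
    if not contrasts:
        raise EstimationError("no contrasts to fit")
    comps = _connected_components_of(contrasts)
    if len(comps) > 1:
        raise EstimationError(
            f"network is disconnected; components: {[sorted(c) for c in comps]}"
        )
    if reference is None:
        nodes_all = {c.node_a for c in contrasts} | {c.node_b for c in contrasts}
        zero = sorted(n for n in nodes_all if n.startswith("zero"))
        reference = zero[0] if zero else sorted(nodes_all)[0]
    X, y, S, nodes = _design(contrasts, reference)

    def gls(S_: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Si = np.linalg.inv(S_)
        cov = np.linalg.inv(X.T @ Si @ X)
        beta = cov @ X.T @ Si @ y
        return beta, cov

    tau2 = 0.0
    beta, cov = gls(S)
    if model == "random":
        Si = np.linalg.inv(S)
        resid = y - X @ beta
        q = float(resid @ Si @ resid)
        df = len(y) - len(nodes)
        if df > 0:
            P = Si - Si @ X @ np.linalg.inv(X.T @ Si @ X) @ X.T @ Si
            denom = float(np.trace(P))
            tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
        if tau2 > 0:
            beta, cov = gls(S + tau2 * np.eye(len(y)))
    elif model != "fixed":
        raise ValueError(f"unknown model {model!r}")
    cov = 0.5 * (cov + cov.T)
    return NmaFit(
        outcome=outcome,
        reference=reference,
        nodes=nodes,
        basic_parameters=beta,
        covariance_matrix=cov,
        model=model,
        tau2=tau2,
        n_contrasts=len(contrasts),
    )


def sucra(
    fit: NmaFit,
    n_draws: int = 100_000,
    seed: int | None = None,
    direction: str = "lower_is_better",
) -> SucraTable:
    """Rank probabilities, prob-best and SUCRA via parametric resampling.

    Basic parameters are drawn from the fitted multivariate normal; per draw
    nodes are ranked by their relative log event rate (fewest events best).
    SUCRA equals (a - mean_rank)/(a - 1) for a nodes, i.e. the area under
    the cumulative ranking curve, and is 1 exactly when a node is certainly
    ranked first.
    """
    if direction != "lower_is_better":
        raise ValueError("only lower_is_better ranking is defined for event rates")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for stable rank probabilities")
    eigmin = float(np.linalg.eigvalsh(fit.covariance_matrix).min())
    if eigmin < -1e-10:
        raise np.linalg.LinAlgError(
            "covariance matrix not positive semi-definite: min eigenvalue "
            f"{eigmin:.3e}, condition number "
            f"{np.linalg.cond(fit.covariance_matrix):.3e}"
        )
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        fit.basic_parameters, fit.covariance_matrix, size=n_draws, method="svd"
    )
    full = np.concatenate([np.zeros((n_draws, 1)), draws], axis=1)
    labels = (fit.reference,) + fit.nodes
    a = full.shape[1]
    # rank 0 = best (lowest relative rate); random tie-break via argsort order
    order = np.argsort(full, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n_draws)[:, None]
    ranks[rows, order] = np.arange(a)[None, :]
    rank_prob = np.stack([(ranks == r).mean(axis=0) for r in range(a)], axis=1)
    mean_rank = ranks.mean(axis=0) + 1.0
    sucra_vals = (a - mean_rank) / (a - 1.0)
    return SucraTable(
        nodes=labels,
        rank_probabilities=rank_prob,
        prob_best=rank_prob[:, 0].copy(),
        sucra=sucra_vals,
        mean_rank=mean_rank,
        n_draws=n_draws,
        seed=seed,
    )


def rank_arms(
    network: EvidenceNetwork,
    outcome: str,
    n_draws: int = 100_000,
    seed: int | None = None,
    model: str = "fixed",
    continuity: float = 0.5,
) -> SucraTable:
    """Convenience pipeline: contrasts -> consistency fit -> SUCRA."""
    contrasts = build_contrasts(network, outcome, continuity=continuity)
    fit = fit_consistency(contrasts, outcome=outcome, model=model)
    return sucra(fit, n_draws=n_draws, seed=seed)


def check_transitivity_effect(
    network_with: EvidenceNetwork,
    network_without: EvidenceNetwork,
    outcome: str = "cardiac",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> dict:
    """Face-validity probe: how does adding a trial change the ranking?

    Fits and ranks both networks for the outcome and reports the orderings
    plus prob-best per node.  A sharply implausible reordering (e.g. a
    late-randomising trial's arm jumping to safest for cardiac events)
    signals that the added trial recruited a different population and the
    transitivity assumption fails.
    """
    with_tab = rank_arms(network_with, outcome, n_draws=n_draws, seed=seed)
    without_tab = rank_arms(network_without, outcome, n_draws=n_draws, seed=seed)
    shared = [n for n in with_tab.nodes if n in without_tab.nodes]
    added = [n for n in with_tab.nodes if n not in without_tab.nodes]
    pb_with = dict(zip(with_tab.nodes, with_tab.prob_best))
    pb_without = dict(zip(without_tab.nodes, without_tab.prob_best))
    return {
        "outcome": outcome,
        "ordering_with": with_tab.ordering(),
        "ordering_without": without_tab.ordering(),
        "prob_best_with": {k: round(v, 4) for k, v in pb_with.items()},
        "prob_best_without": {k: round(v, 4) for k, v in pb_without.items()},
        "shared_nodes": shared,
        "added_nodes": added,
        "added_node_ranked_first": bool(added)
        and with_tab.ordering()[0] in added,
        # how much the added trial disturbs the shared nodes' rank evidence
        "max_prob_best_shift_on_shared": max(
            (abs(pb_with[n] - pb_without[n]) for n in shared), default=0.0
        ),
        "ordering_changed_on_shared": (
            [n for n in with_tab.ordering() if n in shared]
            != [n for n in without_tab.ordering() if n in shared]
        ),
    }
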