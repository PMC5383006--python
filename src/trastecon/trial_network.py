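"""Arm-level trial data and jointly randomisable evidence networks.

Adjuvant-trastuzumab trials compared different durations (zero, 9-10 weeks,
6 months, 12-14 months) under different randomisation timings and with
different disease-free endpoints (DDFS counts only metastasis and death; DFS
additionally counts locoregional/contralateral recurrence and new primaries).
Arms are therefore categorised into treatment nodes, and only trials whose
nodes connect -- and whose populations could plausibly have been randomised
to any node of the component -- form a usable evidence network.  Node labels
are data carried by the input table, not inferred here; this module validates
consistency and computes connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "TrialArm",
    "EvidenceNetwork",
    "SchemaError",
    "ValidationError",
    "REQUIRED_COLUMNS",
    "load_arm_table",
    "build_networks",
    "select_cea_network",
    "relabel_and_merge",
    "network_summary",
]

REQUIRED_COLUMNS = [
    "trial_id",
    "node_label",
    "duration_class",
    "endpoint_type",
    "randomisation_timing",
    "proxy_events",
    "os_events",
    "cardiac_events",
    "sample_size",
    "followup_years",
    "person_years",
]

DURATION_CLASSES = {"zero", "short", "medium", "long"}
ENDPOINT_TYPES = {"DDFS", "DFS"}
RANDOMISATION_TIMINGS = {"at_start", "after_chemo", "after_chemo_and_6m_trastuzumab"}

# Tolerance for person_years <= sample_size * followup_years: published
# person-year totals occasionally exceed n*followup by rounding of follow-up.
PY_TOLERANCE = 1.05


class SchemaError(ValueError):
    """Input table does not have the expected columns."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class TrialArm:
    """Aggregate results for one randomised arm of one trial.

    Event counts may be fractional: when a published trial did not attribute
    events to a subgroup, an even split leaves half-events (e.g. 0.5 cardiac
    events in a control arm).  They are carried as reals and never rounded.
    """

    trial_id: str
    node_label: str
    duration_class: str
    endpoint_type: str
    randomisation_timing: str
    proxy_events: float
    os_events: float
    cardiac_events: float
    sample_size: int
    followup_years: float
    person_years: float

    def __post_init__(self) -> None:
        if self.duration_class not in DURATION_CLASSES:
            raise ValidationError(
                f"{self.trial_id}/{self.node_label}: unknown duration_class "
                f"{self.duration_class!r}"
            )
        if self.endpoint_type not in ENDPOINT_TYPES:
            raise ValidationError(
                f"{self.trial_id}/{self.node_label}: unknown endpoint_type "
                f"{self.endpoint_type!r}"
            )
        if self.randomisation_timing not in RANDOMISATION_TIMINGS:
            raise ValidationError(
                f"{self.trial_id}/{self.node_label}: unknown randomisation_timing "
                f"{self.randomisation_timing!r}"
            )
        for name in ("proxy_events", "os_events", "cardiac_events"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{self.trial_id}/{self.node_label}: negative {name}"
                )
        if self.sample_size <= 0:
            raise ValidationError(f"{self.trial_id}/{self.node_label}: sample_size <= 0")
        if self.person_years <= 0:
            raise ValidationError(f"{self.trial_id}/{self.node_label}: person_years <= 0")
        if self.followup_years <= 0:
            raise ValidationError(f"{self.trial_id}/{self.node_label}: followup_years <= 0")
        if self.proxy_events > self.sample_size or self.os_events > self.sample_size:
            raise ValidationError(
                f"{self.trial_id}/{self.node_label}: events exceed sample size"
            )
        if self.person_years > self.sample_size * self.followup_years * PY_TOLERANCE:
            raise ValidationError(
                f"{self.trial_id}/{self.node_label}: person_years "
                f"{self.person_years} exceed sample_size*followup_years beyond "
                f"rounding tolerance"
            )

    def events(self, outcome: str) -> float:
        """Event count for an outcome in {proxy_survival, os, cardiac}."""
        try:
            return {
                "proxy_survival": self.proxy_events,
                "os": self.os_events,
                "cardiac": self.cardiac_events,
            }[outcome]
        except KeyError:
            raise ValidationError(f"unknown outcome {outcome!r}") from None


@dataclass(frozen=True)
class EvidenceNetwork:
    """A connected component of treatment nodes linked by randomised contrasts.

    ``contrasts`` holds one (trial_id, node_a, node_b) edge per within-trial
    pairwise comparison (a k-arm trial contributes k-1 edges against its
    first-listed node).
    """

    nodes: tuple[str, ...]
    contrasts: tuple[tuple[str, str, str], ...]
    arms: tuple[TrialArm, ...] = field(repr=False)

    def arms_for_node(self, node: str) -> list[TrialArm]:
        if node not in self.nodes:
            raise KeyError(f"node {node!r} not in network")
        return [a for a in self.arms if a.node_label == node]

    def node_totals(self, node: str) -> dict[str, float]:
        arms = self.arms_for_node(node)
        return {
            "proxy_events": sum(a.proxy_events for a in arms),
            "os_events": sum(a.os_events for a in arms),
            "cardiac_events": sum(a.cardiac_events for a in arms),
            "sample_size": sum(a.sample_size for a in arms),
            "person_years": sum(a.person_years for a in arms),
        }

    @property
    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((a, b) for _, a, b in self.contrasts)
        return nx.is_connected(g) if len(self.nodes) else True


def load_arm_table(path: str | Path) -> list[TrialArm]:
    """Read a one-row-per-arm CSV and return validated :class:`TrialArm` records.

    Fractional event counts are preserved exactly as printed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    arms = []
    for idx, row in df.iterrows():
        try:
            arms.append(
                TrialArm(
                    trial_id=str(row["trial_id"]),
                    node_label=str(row["node_label"]),
                    duration_class=str(row["duration_class"]),
                    endpoint_type=str(row["endpoint_type"]),
                    randomisation_timing=str(row["randomisation_timing"]),
                    proxy_events=float(row["proxy_events"]),
                    os_events=float(row["os_events"]),
                    cardiac_events=float(row["cardiac_events"]),
                    sample_size=int(row["sample_size"]),
                    followup_years=float(row["followup_years"]),
                    person_years=float(row["person_years"]),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from None
    return arms


def _sorted_arms(arms: Iterable[TrialArm]) -> tuple[TrialArm, ...]:
    return tuple(sorted(arms, key=lambda a: (a.trial_id, a.node_label)))


def _component(arms: Sequence[TrialArm]) -> EvidenceNetwork:
    arms = _sorted_arms(arms)
    nodes = tuple(sorted({a.node_label for a in arms}))
    contrasts = []
    for trial in sorted({a.trial_id for a in arms}):
        t_nodes = [a.node_label for a in arms if a.trial_id == trial]
        base = t_nodes[0]
        for other in t_nodes[1:]:
            if other != base:
                contrasts.append((trial, other, base))
    net = EvidenceNetwork(nodes=nodes, contrasts=tuple(contrasts), arms=arms)
    endpoints = {a.endpoint_type for a in arms}
    if len(endpoints) > 1:
        raise ValidationError(
            f"network {nodes} mixes endpoint types {sorted(endpoints)}: node "
            "labels must separate DDFS- and DFS-reporting trials"
        )
    return net


def build_networks(arms: Sequence[TrialArm]) -> list[EvidenceNetwork]:
    """Partition arms into connected evidence networks by shared node labels.

    Two trials belong to the same network iff a chain of shared nodes links
    them.  Output order is deterministic (by first node label of each
    component); so is arm order within a component (trial_id, node_label).
    """
    if not arms:
        return []
    g = nx.Graph()
    for arm in arms:
        g.add_node(arm.node_label)
    for trial in {a.trial_id for a in arms}:
        t_nodes = [a.node_label for a in arms if a.trial_id == trial]
        for other in t_nodes[1:]:
            g.add_edge(t_nodes[0], other)
    components = []
    for comp in nx.connected_components(g):
        comp_arms = [a for a in arms if a.node_label in comp]
        components.append(_component(comp_arms))
    components.sort(key=lambda n: n.nodes[0])
    return components


def relabel_and_merge(
    arms: Sequence[TrialArm], node_map: Mapping[str, str]
) -> list[TrialArm]:
    """Relabel nodes and merge same-trial arms that land on the same node.

    Used both to pool a trial's interchangeable arms (e.g. two 12-month arms
    of a three-arm trial, events and person-years summed) and to postulate
    shared nodes across trials when probing the transitivity assumption.
    Arms whose label is absent from ``node_map`` keep their label.  Merging
    conserves events, person-years and sample sizes exactly.
    """
    relabelled = [
        replace(a, node_label=node_map.get(a.node_label, a.node_label)) for a in arms
    ]
    merged: dict[tuple[str, str], TrialArm] = {}
    order: list[tuple[str, str]] = []
    for arm in relabelled:
        key = (arm.trial_id, arm.node_label)
        if key not in merged:
            merged[key] = arm
            order.append(key)
        else:
            prev = merged[key]
            merged[key] = replace(
                prev,
                proxy_events=prev.proxy_events + arm.proxy_events,
                os_events=prev.os_events + arm.os_events,
                cardiac_events=prev.cardiac_events + arm.cardiac_events,
                sample_size=prev.sample_size + arm.sample_size,
                followup_years=max(prev.followup_years, arm.followup_years),
                person_years=prev.person_years + arm.person_years,
            )
    return [merged[k] for k in order]


#: The component holding the zero / 9-week / 12-month DDFS-reporting trials
#: (BCIRG006 and the FinHer docetaxel subgroup); the one network with more
#: than one non-zero duration under a common randomisation scheme.
CEA_COMPONENT_NODES = frozenset({"9w-ddfs", "zero-ddfs"})

#: Node map collapsing the component's two 12-month arms to a single node.
MERGE_LONG_MAP = {
    "12m-con-atR-ddfs": "12m-ddfs",
    "12m-con-later-ddfs": "12m-ddfs",
}


def select_cea_network(
    networks: Sequence[EvidenceNetwork], merge_long_arms: bool = True
) -> EvidenceNetwork:
    """Return the BCIRG006/FinHer component used by the economic model.

    With ``merge_long_arms`` the two 12-month arms (concomitant-at-
    randomisation and concomitant-later) are pooled into one 12-month node --
    their survival did not differ significantly in the source trial -- giving
    the 3-node {zero, 9 weeks, 12 months} network; otherwise the 4-node
    component is returned unchanged.
    """
    for net in networks:
        if CEA_COMPONENT_NODES <= set(net.nodes):
            if not merge_long_arms:
                return net
            return _component(relabel_and_merge(net.arms, MERGE_LONG_MAP))
    raise LookupError(
        "no network contains both the 9-week and zero DDFS nodes; cannot "
        "select the economic-model component"
    )


def network_summary(net: EvidenceNetwork) -> dict:
    """JSON-ready summary: nodes, edges and per-node totals."""
    return {
        "nodes": list(net.nodes),
        "edges": [list(c) for c in net.contrasts],
        "connected": net.is_connected,
        "node_totals": {n: net.node_totals(n) for n in net.nodes},
    }


def write_network_summary(net: EvidenceNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_summary(net), indent=2))
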