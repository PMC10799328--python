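"""Evidence-network construction and validation for one outcome/analysis set.

Treatments are nodes; each two-arm trial contributes one edge between its
treatment and comparator.  A network meta-analysis is fitted only on a
connected network, so connectivity is asserted before any model sees the
data.  All networks in the HIF-PHI evidence base are stars centred on the
common comparator (ESA or placebo), which is what makes closed-form
cross-checks of the Bayesian engine possible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .trial_data import TrialContrast, ValidationError

logger = logging.getLogger("hifnma")


class DisconnectedNetworkError(ValueError):
    """The evidence graph has more than one connected component."""

    def __init__(self, components: list[set[str]]):
        self.components = components
        listing = "; ".join("{" + ", ".join(sorted(c)) + "}" for c in components)
        super().__init__(f"evidence network is disconnected: components {listing}")


class EmptyNetworkError(ValueError):
    """No contrasts survived the exclusion rules."""


@dataclass(frozen=True)
class ExclusionRule:
    """Declarative trial-exclusion rule.

    A contrast is excluded when its comparator is in ``comparator_in`` (if
    set) and its outcome in ``outcome_in`` (if set).  ``reason`` records the
    methodological rationale, e.g. why placebo-controlled trials are dropped
    from efficacy and cardiovascular analyses.
    """

    rule_id: str
    reason: str = ""
    comparator_in: frozenset[str] = frozenset()
    outcome_in: frozenset[str] = frozenset()

    def applies(self, c: TrialContrast) -> bool:
        if self.comparator_in and c.comparator not in self.comparator_in:
            return False
        if self.outcome_in and c.outcome_id not in self.outcome_in:
            return False
        return bool(self.comparator_in or self.outcome_in)


#: Placebo-controlled trials are excluded from efficacy and cardiovascular
#: analyses: with a placebo arm, between-trial differences in Hgb target
#: range and dosing act as effect modifiers, whereas active-controlled
#: comparisons are affected symmetrically within each trial.
PLACEBO_EXCLUSION = ExclusionRule(
    rule_id="exclude_placebo_controlled",
    reason=(
        "placebo-controlled trials excluded for efficacy and CV outcomes: "
        "treatment-target and dosing differences modify effects vs placebo"
    ),
    comparator_in=frozenset({"placebo"}),
    outcome_in=frozenset({"hgb_cfb", "mace"}),
)


@dataclass(frozen=True)
class EvidenceNetwork:
    """Treatment nodes and per-edge trial lists for one outcome.

    ``edges`` maps an unordered node pair (stored sorted) to the tuple of
    trial ids providing direct evidence on that comparison.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], tuple[str, ...]]
    reference: str
    outcome_id: str
    contrasts: tuple[TrialContrast, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        if self.reference not in nodeset:
            raise ValidationError(f"reference {self.reference!r} not a network node")
        for (a, b) in self.edges:
            if a == b:
                raise ValidationError(f"self-edge on node {a!r}")
            if a not in nodeset or b not in nodeset:
                raise ValidationError(f"edge ({a!r}, {b!r}) has endpoint outside nodes")

    @property
    def n_trials(self) -> int:
        return sum(len(trials) for trials in self.edges.values())

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), trials in self.edges.items():
            g.add_edge(a, b, trials=list(trials))
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph())

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "outcome_id": self.outcome_id,
            "reference": self.reference,
            "nodes": list(self.nodes),
            "edges": [
                {"nodes": [a, b], "trials": list(trials)}
                for (a, b), trials in sorted(self.edges.items())
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_edgelist_csv(self, path: str | Path) -> None:
        rows = [
            {"node_a": a, "node_b": b, "n_trials": len(trials), "trials": ";".join(trials)}
            for (a, b), trials in sorted(self.edges.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_network(
    contrasts: Iterable[TrialContrast],
    reference: str | None = None,
    exclusion_rules: Sequence[ExclusionRule] = (),
) -> EvidenceNetwork:
    """Build the evidence network for one outcome after applying exclusions.

    Every applied exclusion is logged with the rule that fired.  The
    reference defaults to the most-connected node (highest degree, ties
    broken lexicographically) — in this evidence base, the ESA or placebo
    star centre.  Multi-arm trials (a trial id contributing more than one
    contrast) are rejected: their likelihood contributions are correlated
    and out of scope here.
    """
    kept: list[TrialContrast] = []
    fired: list[str] = []
    outcome_ids = set()
    for c in contrasts:
        outcome_ids.add(c.outcome_id)
        rule = next((r for r in exclusion_rules if r.applies(c)), None)
        if rule is not None:
            fired.append(rule.rule_id)
            logger.info(
                "excluded trial %s (%s vs %s) by rule %s: %s",
                c.trial_id, c.treatment, c.comparator, rule.rule_id, rule.reason,
            )
            continue
        kept.append(c)
    if len(outcome_ids) > 1:
        raise ValidationError(
            f"contrasts span multiple outcomes: {sorted(outcome_ids)}"
        )
    if not kept:
        applied = ", ".join(sorted(set(fired))) or "none"
        raise EmptyNetworkError(
            f"no contrasts left after exclusions (rules applied: {applied})"
        )

    seen_trials: dict[str, TrialContrast] = {}
    for c in kept:
        if c.trial_id in seen_trials:
            raise ValidationError(
                f"trial {c.trial_id!r} contributes more than one contrast: "
                "multi-arm trials are not supported (correlated arms)"
            )
        seen_trials[c.trial_id] = c

    nodes = sorted({n for c in kept for n in (c.treatment, c.comparator)})
    edges: dict[tuple[str, str], tuple[str, ...]] = {}
    for c in sorted(kept, key=lambda c: c.trial_id):
        key = _edge_key(c.treatment, c.comparator)
        edges[key] = edges.get(key, ()) + (c.trial_id,)

    if reference is None:
        degree: dict[str, int] = {n: 0 for n in nodes}
        for (a, b) in edges:
            degree[a] += 1
            degree[b] += 1
        reference = min(nodes, key=lambda n: (-degree[n], n))

    return EvidenceNetwork(
        nodes=tuple(nodes),
        edges=edges,
        reference=reference,
        outcome_id=next(iter(outcome_ids)),
        contrasts=tuple(kept),
    )


def assert_connected(net: EvidenceNetwork) -> None:
    """Raise :class:`DisconnectedNetworkError` listing components if the
    network does not permit indirect comparisons."""
    g = net.graph()
    if not nx.is_connected(g):
        raise DisconnectedNetworkError([set(c) for c in nx.connected_components(g)])


def is_star(net: EvidenceNetwork) -> tuple[bool, str | None]:
    """Whether all edges share one common node; returns (flag, centre).

    A two-node network is a degenerate star; its centre is the reference if
    the reference is an endpoint, else the lexicographically first node.
    """
    assert_connected(net)
    edge_keys = list(net.edges)
    common = set(edge_keys[0])
    for key in edge_keys[1:]:
        common &= set(key)
    if not common:
        return False, None
    if net.reference in common:
        return True, net.reference
    return True, sorted(common)[0]
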