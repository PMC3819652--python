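"""Blocked reactions, gap metabolites and their classification.

A reaction is *blocked* under a medium when it carries zero flux in every
steady-state distribution; detection computes the flux minimum and
maximum of each reaction (two LPs per reaction) and tests both against a
zero threshold.  A metabolite is a *gap* exactly when every reaction it
participates in is blocked — this single criterion covers both root
dead-ends and everything they silence downstream/upstream.

Gaps are then classified:

* ``RNP`` (root-non-produced): no reaction direction admissible under the
  bounds produces the metabolite.
* ``RNC`` (root-non-consumed): no admissible direction consumes it.
* ``DNP`` / ``UNC``: non-root gaps created by propagation from an RNP /
  towards an RNC, decided by directed reachability inside the metabolite's
  unconnected module.
* ``UNCLASSIFIED``: rules tie or no root explains the gap (the typical
  signature of a pseudo-gap cause, see :mod:`umcheck.pseudogap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .lp import fba
from .model import MediumSpec, Model, apply_medium

__all__ = [
    "GapClass",
    "BlockedSet",
    "GapSet",
    "sigma",
    "find_blocked",
    "find_gaps",
    "classify_gaps",
    "check_model",
    "write_blocked_tsv",
    "write_gaps_tsv",
]


class GapClass:
    RNP = "RNP"
    RNC = "RNC"
    DNP = "DNP"
    UNC = "UNC"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class BlockedSet:
    """Reactions with provably zero flux in every steady state."""

    blocked: frozenset[str]
    medium: str
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.blocked

    def __len__(self) -> int:
        return len(self.blocked)

    def __iter__(self):
        return iter(self.blocked)


@dataclass(frozen=True)
class GapSet:
    """Gap metabolites with (optionally) their classes."""

    gaps: frozenset[str]
    classes: Mapping[str, str] = field(default_factory=dict)
    orphans: frozenset[str] = frozenset()

    def __contains__(self, met_id: str) -> bool:
        return met_id in self.gaps

    def __len__(self) -> int:
        return len(self.gaps)

    def __iter__(self):
        return iter(self.gaps)


def sigma(model: Model, metabolite_id: str) -> frozenset[str]:
    """Reactions with a nonzero stoichiometric coefficient for the
    metabolite (exchanges included)."""
    model.metabolite(metabolite_id)  # raises for unknown ids
    return frozenset(
        rxn.id for rxn in model.reactions if metabolite_id in rxn.stoichiometry
    )


def find_blocked(
    model: Model,
    medium: MediumSpec | Mapping[str, tuple[float, float]] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> BlockedSet:
    """Detect blocked reactions by per-reaction flux minimisation and
    maximisation.

    When *medium* is omitted, every exchange is opened to ``[-M, M]``:
    the most permissive medium, so any reaction blocked here is blocked
    under every medium.  When a medium is given, listed exchanges get its
    bounds and unlisted ones stay open.
    """
    if medium is None:
        scoped = apply_medium(model, {}, "open", config)
        medium_desc = "all-exchanges-open"
    else:
        scoped = apply_medium(model, medium, "open", config)
        medium_desc = "custom:" + ",".join(sorted(dict(medium)))
    eps = config.zero_tol

    blocked: set[str] = set()
    ranges: dict[str, tuple[float, float]] = {}
    for rid in scoped.reaction_ids:
        hi = fba(scoped, rid, "max", config)
        if hi.status == "infeasible":
            raise ValueError("flux space empty: model admits no steady state")
        if hi.objective_value is not None and abs(hi.objective_value) >= eps:
            continue  # provably nonzero flux; the min LP cannot change that
        lo = fba(scoped, rid, "min", config)
        if lo.status == "infeasible":
            raise ValueError("flux space empty: model admits no steady state")
        if abs(lo.objective_value) < eps and abs(hi.objective_value) < eps:
            blocked.add(rid)
            ranges[rid] = (lo.objective_value, hi.objective_value)
    return BlockedSet(blocked=frozenset(blocked), medium=medium_desc, ranges=ranges)


def find_gaps(model: Model, blocked: BlockedSet) -> GapSet:
    """Gap metabolites: those whose whole reaction set is blocked.

    Metabolites occurring in no reaction at all are gaps too and flagged
    as orphans.
    """
    gaps: set[str] = set()
    orphans: set[str] = set()
    for met_id in model.metabolite_ids:
        sig = sigma(model, met_id)
        if not sig:
            gaps.add(met_id)
            orphans.add(met_id)
        elif sig <= blocked.blocked:
            gaps.add(met_id)
    return GapSet(gaps=frozenset(gaps), classes={}, orphans=frozenset(orphans))


def _has_admissible_producer(model: Model, met_id: str, rxn_id: str) -> bool:
    rxn = model.reaction(rxn_id)
    coeff = rxn.stoichiometry.get(met_id, 0)
    return (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0)


def _has_admissible_consumer(model: Model, met_id: str, rxn_id: str) -> bool:
    rxn = model.reaction(rxn_id)
    coeff = rxn.stoichiometry.get(met_id, 0)
    return (coeff < 0 and rxn.upper_bound > 0) or (coeff > 0 and rxn.lower_bound < 0)


def _weak_components(nodes: set[str], edges: list[tuple[str, str]]) -> list[set[str]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


def classify_gaps(
    model: Model,
    gaps: GapSet,
    blocked: BlockedSet,
    um_partition: Iterable[set[str]] | None = None,
) -> GapSet:
    """Assign RNP/RNC/DNP/UNC classes to the detected gaps.

    Root classes come from scanning the admissible reaction directions in
    the stoichiometric matrix; DNP/UNC come from directed reachability
    between roots and non-root gaps inside each unconnected module.  Gaps
    matching both rules (or neither) stay UNCLASSIFIED.
    """
    roots: dict[str, str] = {}
    for met_id in gaps:
        sig = sigma(model, met_id)
        producible = any(_has_admissible_producer(model, met_id, j) for j in sig)
        consumable = any(_has_admissible_consumer(model, met_id, j) for j in sig)
        if not producible and not consumable:
            roots[met_id] = GapClass.UNCLASSIFIED  # orphan or fully closed
        elif not producible:
            roots[met_id] = GapClass.RNP
        elif not consumable:
            roots[met_id] = GapClass.RNC

    # Directed arcs within the gap/blocked subgraph, by admissible direction.
    nodes = set(gaps.gaps) | set(blocked.blocked)
    arcs: list[tuple[str, str]] = []
    for rxn_id in blocked:
        rxn = model.reaction(rxn_id)
        for met_id in rxn.stoichiometry:
            if met_id not in gaps.gaps:
                continue
            if _has_admissible_consumer(model, met_id, rxn_id):
                arcs.append((met_id, rxn_id))
            if _has_admissible_producer(model, met_id, rxn_id):
                arcs.append((rxn_id, met_id))

    if um_partition is None:
        undirected = [(a, b) for a, b in arcs]
        # include membership edges even when no direction is admissible
        for rxn_id in blocked:
            for met_id in model.reaction(rxn_id).stoichiometry:
                if met_id in gaps.gaps:
                    undirected.append((rxn_id, met_id))
        modules = _weak_components(nodes, undirected)
    else:
        modules = [set(mod) for mod in um_partition]

    succ: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in arcs:
        succ.setdefault(a, set()).add(b)

    def reachable_from(sources: set[str]) -> set[str]:
        seen = set(sources)
        stack = list(sources)
        while stack:
            node = stack.pop()
            for nxt in succ.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    classes: dict[str, str] = {}
    for module in modules:
        module_gaps = module & gaps.gaps
        rnp_roots = {m for m in module_gaps if roots.get(m) == GapClass.RNP}
        rnc_roots = {m for m in module_gaps if roots.get(m) == GapClass.RNC}
        downstream_of_rnp = reachable_from(rnp_roots) if rnp_roots else set()
        # reverse reachability to RNC: walk predecessors == forward walk on
        # reversed arcs
        pred: dict[str, set[str]] = {n: set() for n in nodes}
        for a, b in arcs:
            if a in module or b in module:
                pred.setdefault(b, set()).add(a)
        upstream_of_rnc: set[str] = set()
        if rnc_roots:
            seen = set(rnc_roots)
            stack = list(rnc_roots)
            while stack:
                node = stack.pop()
                for nxt in pred.get(node, ()):
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            upstream_of_rnc = seen
        for met_id in module_gaps:
            if met_id in roots:
                classes[met_id] = roots[met_id]
                continue
            is_dnp = met_id in downstream_of_rnp
            is_unc = met_id in upstream_of_rnc
            if is_dnp and not is_unc:
                classes[met_id] = GapClass.DNP
            elif is_unc and not is_dnp:
                classes[met_id] = GapClass.UNC
            else:
                classes[met_id] = GapClass.UNCLASSIFIED
    return replace(gaps, classes=classes)


def check_model(
    model: Model,
    medium: MediumSpec | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[BlockedSet, GapSet]:
    """One-call consistency check: blocked set, classified gap set."""
    blocked = find_blocked(model, medium, config)
    gaps = find_gaps(model, blocked)
    gaps = classify_gaps(model, gaps, blocked)
    return blocked, gaps


def write_blocked_tsv(blocked: BlockedSet, path: str | Path) -> None:
    rows = [
        {"reaction": rid,
         "min": blocked.ranges.get(rid, (0.0, 0.0))[0],
         "max": blocked.ranges.get(rid, (0.0, 0.0))[1]}
        for rid in sorted(blocked.blocked)
    ]
    pd.DataFrame(rows, columns=["reaction", "min", "max"]).to_csv(
        Path(path), sep="\t", index=False
    )


def write_gaps_tsv(gaps: GapSet, model: Model, path: str | Path) -> None:
    rows = []
    for met_id in sorted(gaps.gaps):
        rows.append(
            {
                "metabolite": met_id,
                "class": gaps.classes.get(met_id, ""),
                "n_reactions": len(sigma(model, met_id)),
                "orphan": int(met_id in gaps.orphans),
            }
        )
    pd.DataFrame(rows, columns=["metabolite", "class", "n_reactions", "orphan"]
                 ).to_csv(Path(path), sep="\t", index=False)
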