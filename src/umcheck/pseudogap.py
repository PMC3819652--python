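"""Coenzyme pseudo-gaps: detection and repair.

A *pseudo-gap* is a metabolite that is not a gap — it sits in actively
cycling reactions — yet is the reason an entire pathway is blocked.  The
canonical case is a cofactor pair (D, D*) interconverted by a closed
loop: the pair forms a conserved moiety, so no net production of D is
possible, which forces the flux of every reaction *synthesising* D to
zero and silences the upstream pathway.  Such metabolites are found by a
sink test: temporarily grant the metabolite a drain and see whether the
blocked set shrinks.  Supporting evidence comes from conserved moieties
(semi-positive left-null vectors of the column-scoped stoichiometric
matrix) computed in exact arithmetic.

Repairs mirror standard curation moves: add a sink or exchange, include
the cofactor in the biomass equation, relax an irreversibility, or add a
bespoke reaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

from .config import DEFAULT_CONFIG, RunConfig
from .gapfind import BlockedSet, GapSet, find_blocked, find_gaps
from .model import Model, ModelValidationError, Reaction
from .rational import RayLimitExceeded, extreme_rays, rational_nullspace

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationRelation",
    "PseudoGapFinding",
    "RepairAction",
    "RepairDelta",
    "conservation_relations",
    "scan_pseudo_gaps",
    "apply_repair",
    "resolve_um",
    "add_sink_reaction",
]


@dataclass(frozen=True)
class ConservationRelation:
    """Semi-positive left-null vector of a column-scoped stoichiometric
    matrix: a weighted metabolite pool that every in-scope flux
    distribution conserves."""

    weights: Mapping[str, Fraction]
    scope: str  # "all" | "unblocked_only"
    exact: bool = True  # False when produced by the nullspace fallback

    @property
    def support(self) -> frozenset[str]:
        return frozenset(m for m, w in self.weights.items() if w != 0)


@dataclass(frozen=True)
class PseudoGapFinding:
    metabolite_id: str
    unblocked_neighbors: frozenset[str]
    blocked_neighbors: frozenset[str]
    unblocks: frozenset[str]  # blocked reactions freed by a temporary sink
    relation: ConservationRelation | None = None


@dataclass(frozen=True)
class RepairAction:
    """One elementary model edit used to restore connectivity."""

    kind: str  # add_sink | add_exchange | add_biomass_component |
    #            relax_irreversibility | add_reaction
    target: str
    parameters: Mapping[str, object] = field(default_factory=dict)

    KINDS = ("add_sink", "add_exchange", "add_biomass_component",
             "relax_irreversibility", "add_reaction")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown repair kind {self.kind!r}")


@dataclass(frozen=True)
class RepairDelta:
    blocked_before: frozenset[str]
    blocked_after: frozenset[str]
    n_ums_before: int
    n_ums_after: int


def conservation_relations(
    model: Model,
    scope: str = "unblocked_only",
    blocked: BlockedSet | None = None,
    max_rays: int | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[ConservationRelation]:
    """Conserved moieties of the (optionally column-scoped) network.

    ``scope="unblocked_only"`` drops blocked columns first, which is
    where cofactor moieties show up: the Fig.-2-style loop conserves
    D + D* only once the moiety-breaking blocked synthesis column is
    removed.  Enumeration is exact double description on the transposed
    scoped matrix; systems wider than ``config.dd_max_cols`` fall back to
    a rational left-nullspace basis filtered for semi-positive vectors
    (flagged ``exact=False``).
    """
    if scope not in ("all", "unblocked_only"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "unblocked_only":
        if blocked is None:
            raise ValueError("scope='unblocked_only' requires a BlockedSet")
        columns = [rid for rid in model.reaction_ids if rid not in blocked.blocked]
    else:
        columns = model.reaction_ids
    if not columns:
        return []
    row_ids, _, matrix = model.rational_columns(columns)
    if not row_ids:
        return []
    # left-null vectors of N' == right-null vectors of N'^T
    transposed = [[matrix[i][j] for i in range(len(row_ids))]
                  for j in range(len(columns))]
    cap = max_rays if max_rays is not None else config.max_rays
    if len(row_ids) <= config.dd_max_cols:
        try:
            rays = extreme_rays(transposed, max_rays=cap)
        except RayLimitExceeded:
            logger.warning("ray cap hit; returning nullspace fallback")
            rays = None
    else:
        logger.warning(
            "scoped matrix has %d metabolite columns (> %d); using rational "
            "nullspace fallback", len(row_ids), config.dd_max_cols,
        )
        rays = None
    if rays is not None:
        return [
            ConservationRelation(
                weights={m: w for m, w in zip(row_ids, ray) if w != 0},
                scope=scope,
            )
            for ray in rays
        ]
    basis = rational_nullspace(transposed)
    out = []
    for vec in basis:
        if all(v >= 0 for v in vec) or all(v <= 0 for v in vec):
            sign = 1 if any(v > 0 for v in vec) else -1
            out.append(
                ConservationRelation(
                    weights={m: sign * w for m, w in zip(row_ids, vec) if w != 0},
                    scope=scope,
                    exact=False,
                )
            )
    return out


def add_sink_reaction(model: Model, metabolite_id: str,
                      config: RunConfig = DEFAULT_CONFIG,
                      sink_id: str | None = None) -> tuple[Model, str]:
    """Copy of *model* with an irreversible drain for the metabolite."""
    model.metabolite(metabolite_id)
    sid = sink_id or f"SK_{metabolite_id}"
    if model.has_reaction(sid):
        raise ModelValidationError(f"reaction id {sid!r} already exists")
    out = model.copy()
    out.add_reaction(
        Reaction(id=sid, stoichiometry={metabolite_id: Fraction(-1)},
                 lower_bound=0.0, upper_bound=config.big_bound),
        exchange=True,
    )
    return out, sid


def scan_pseudo_gaps(
    model: Model,
    blocked: BlockedSet,
    gaps: GapSet,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[PseudoGapFinding]:
    """Sink-test every plausible pseudo-gap candidate.

    Primary candidates are non-gap metabolites adjacent to at least one
    blocked and one unblocked reaction.  Metabolites tied to a primary
    candidate through an unblocked-scope conserved moiety (the other half
    of a cofactor pair) are tested as well.  For each candidate, an
    irreversible sink is added to a copy of the model, the blocked set is
    recomputed, and a finding is emitted whenever it shrinks.  The input
    model is never mutated.
    """
    if not blocked.blocked:
        return []
    relations = conservation_relations(model, "unblocked_only", blocked,
                                       config=config)

    adjacency: dict[str, tuple[set[str], set[str]]] = {}
    for met_id in model.metabolite_ids:
        if met_id in gaps.gaps:
            continue
        touched_blocked, touched_open = set(), set()
        for rxn in model.reactions:
            if met_id in rxn.stoichiometry:
                (touched_blocked if rxn.id in blocked.blocked
                 else touched_open).add(rxn.id)
        adjacency[met_id] = (touched_blocked, touched_open)

    primary = {m for m, (b, u) in adjacency.items() if b and u}
    secondary: set[str] = set()
    for relation in relations:
        if relation.support & primary:
            secondary |= {
                m for m in relation.support
                if m not in gaps.gaps and adjacency.get(m, (set(), set()))[1]
            }
    candidates = sorted(primary | secondary)

    findings: list[PseudoGapFinding] = []
    for met_id in candidates:
        probe, _ = add_sink_reaction(model, met_id, config,
                                     sink_id=f"__probe_sink__{met_id}")
        after = find_blocked(probe, None, config)
        freed = blocked.blocked - after.blocked
        if not freed:
            continue
        supporting = next(
            (rel for rel in relations if met_id in rel.support), None
        )
        touched_blocked, touched_open = adjacency[met_id]
        findings.append(
            PseudoGapFinding(
                metabolite_id=met_id,
                unblocked_neighbors=frozenset(touched_open),
                blocked_neighbors=frozenset(touched_blocked),
                unblocks=frozenset(freed),
                relation=supporting,
            )
        )
    return findings


def _count_ums(model: Model, blocked: BlockedSet,
               config: RunConfig = DEFAULT_CONFIG) -> int:
    from .graph import build_graph, find_ums, um_subgraph

    gaps = find_gaps(model, blocked)
    graph = build_graph(model, blocked, gaps)
    return len(find_ums(um_subgraph(graph, gaps, blocked), model, gaps))


def apply_repair(
    model: Model,
    action: RepairAction,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[Model, RepairDelta]:
    """Apply one repair action to a copy of the model and report the
    change in blocked reactions and module count."""
    before = find_blocked(model, None, config)
    n_before = _count_ums(model, before, config)
    big = config.big_bound

    if action.kind == "add_sink":
        out, _ = add_sink_reaction(model, action.target, config)
    elif action.kind == "add_exchange":
        model.metabolite(action.target)
        rid = str(action.parameters.get("id", f"EX_{action.target}"))
        out = model.copy()
        out.add_reaction(
            Reaction(id=rid, stoichiometry={action.target: Fraction(-1)},
                     lower_bound=-big, upper_bound=big),
            exchange=True,
        )
    elif action.kind == "add_biomass_component":
        if model.biomass_id is None:
            raise ModelValidationError(
                "add_biomass_component requires a biomass reaction"
            )
        model.metabolite(action.target)
        coeff = Fraction(str(action.parameters.get("coefficient", "1e-4")))
        out = model.copy()
        biomass = out.reaction(out.biomass_id)
        stoich = dict(biomass.stoichiometry)
        stoich[action.target] = stoich.get(action.target, Fraction(0)) - coeff
        out.set_reaction(
            Reaction(id=biomass.id, stoichiometry=stoich,
                     lower_bound=biomass.lower_bound,
                     upper_bound=biomass.upper_bound, name=biomass.name,
                     gpr=biomass.gpr, subsystem=biomass.subsystem)
        )
    elif action.kind == "relax_irreversibility":
        rxn = model.reaction(action.target)
        out = model.copy()
        out.set_reaction(rxn.with_bounds(-big, rxn.upper_bound))
    elif action.kind == "add_reaction":
        params = dict(action.parameters)
        stoich = {m: Fraction(str(c)) for m, c in params["stoichiometry"].items()}
        out = model.copy()
        out.add_reaction(
            Reaction(id=action.target, stoichiometry=stoich,
                     lower_bound=float(params.get("lb", 0.0)),
                     upper_bound=float(params.get("ub", big))),
            exchange=bool(params.get("exchange", len(stoich) == 1)),
        )
    else:  # pragma: no cover - guarded by RepairAction
        raise ValueError(action.kind)

    after = find_blocked(out, None, config)
    n_after = _count_ums(out, after, config)
    delta = RepairDelta(
        blocked_before=before.blocked,
        blocked_after=after.blocked,
        n_ums_before=n_before,
        n_ums_after=n_after,
    )
    return out, delta


def resolve_um(
    model: Model,
    um,
    candidate_actions: Iterable[RepairAction],
    config: RunConfig = DEFAULT_CONFIG,
) -> list[tuple[RepairAction, int, int]]:
    """Score candidate repairs for one unconnected module.

    Returns ``(action, unblocked_in_module, unblocked_globally)`` sorted
    by effectiveness (module first, then global), descending.  The input
    model is not mutated.
    """
    before = find_blocked(model, None, config)
    scored = []
    for action in candidate_actions:
        _, delta = apply_repair(model, action, config)
        freed = before.blocked - delta.blocked_after
        freed_in_module = freed & set(um.reaction_ids)
        scored.append((action, len(freed_in_module), len(freed)))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0].kind, t[0].target))
    return scored
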