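"""Downstream curation analyses.

These are the validation tools run before/after repairing a model:

* gene-knockout essentiality via FBA with GPR-disabled reactions;
* minimal-medium prediction as a MILP that minimises the number of
  exchange fluxes allowed to run negative (uptake) while keeping biomass
  production above a cutoff;
* reaction subsets (fully coupled reaction groups with fixed flux
  ratios), from proportional rows of a nullspace basis of the reduced
  stoichiometric matrix;
* Jaccard comparison of two subset decompositions and structural model
  diffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .config import DEFAULT_CONFIG, RunConfig
from .gapfind import BlockedSet, GapSet
from .lp import fba, solve_milp
from .model import Model, apply_medium
from .rational import rational_nullspace

__all__ = [
    "KnockoutResult",
    "MinimalMedium",
    "ReactionSubset",
    "ModelDiff",
    "knockout_scan",
    "minimal_medium",
    "reaction_subsets",
    "compare_subsets",
    "SubsetComparison",
    "jaccard",
    "diff_models",
]


# ---------------------------------------------------------------------------
# knockouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnockoutResult:
    gene: str
    disabled_reactions: tuple[str, ...]
    growth: float
    essential: bool


def knockout_scan(
    model: Model,
    lethal_threshold_fraction: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[KnockoutResult]:
    """Single-gene deletion scan.

    For each gene, every reaction whose GPR rule evaluates false without
    the gene is constrained to zero flux; FBA then gives the mutant's
    maximal biomass.  A knockout is lethal when that optimum drops below
    ``lethal_threshold_fraction`` of the wild-type optimum.  Orphan
    reactions (no GPR) are never disabled.
    """
    if model.biomass_id is None:
        raise ValueError("knockout scan requires a biomass reaction")
    threshold_fraction = (
        lethal_threshold_fraction
        if lethal_threshold_fraction is not None
        else config.lethal_threshold_fraction
    )
    open_model = apply_medium(model, {}, "open", config)
    wild_type = fba(open_model, config=config)
    if not wild_type.optimal or wild_type.objective_value <= config.zero_tol:
        raise ValueError("no baseline growth: wild-type FBA optimum is zero "
                         "or infeasible")
    cutoff = threshold_fraction * wild_type.objective_value

    results: list[KnockoutResult] = []
    for gene in sorted(model.genes()):
        disabled = tuple(
            rxn.id for rxn in open_model.reactions
            if rxn.gpr is not None and not rxn.gpr.evaluate({gene})
        )
        if not disabled:
            results.append(KnockoutResult(gene, (), wild_type.objective_value,
                                          False))
            continue
        mutant = open_model.copy()
        for rid in disabled:
            mutant.set_reaction(mutant.reaction(rid).with_bounds(0.0, 0.0))
        sol = fba(mutant, config=config)
        growth = sol.objective_value if sol.optimal else 0.0
        results.append(
            KnockoutResult(gene, disabled, growth, growth < cutoff)
        )
    return results


# ---------------------------------------------------------------------------
# minimal medium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinimalMedium:
    exchanges: frozenset[str]  # exchanges allowed to run negative (uptake)
    indicators: Mapping[str, int]
    fluxes: Mapping[str, float]
    biomass_lb: float
    status: str

    @property
    def cardinality(self) -> int:
        return len(self.exchanges)


def minimal_medium(
    model: Model,
    biomass_lb: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> MinimalMedium:
    """Smallest set of uptakes sustaining biomass production.

    One binary ``y_j`` per exchange flux; ``y_j = 0`` forces the exchange
    nonnegative (secretion only), so minimising the sum of the binaries
    minimises the number of consumed medium components, subject to the
    steady-state constraints and a biomass lower bound.  The MILP
    optimum certifies minimal cardinality.
    """
    if model.biomass_id is None:
        raise ValueError("minimal medium prediction requires a biomass reaction")
    scoped = apply_medium(model, {}, "open", config)
    if biomass_lb is None:
        wild_type = fba(scoped, config=config)
        if not wild_type.optimal or wild_type.objective_value <= config.zero_tol:
            raise ValueError("model cannot grow with all exchanges open")
        biomass_lb = config.biomass_lb_fraction * wild_type.objective_value
    if biomass_lb <= 0:
        raise ValueError("biomass_lb must be positive")

    rxn_ids = scoped.reaction_ids
    exchange_ids = [rid for rid in rxn_ids if rid in scoped.exchange_ids]
    n = len(rxn_ids)
    k = len(exchange_ids)
    rxn_index = {rid: j for j, rid in enumerate(rxn_ids)}

    n_mat = scoped.stoichiometric_matrix().toarray()
    lbs, ubs = scoped.bounds_arrays()

    # variables: v (n) then y (k)
    n_var = n + k
    c = np.concatenate([np.zeros(n), np.ones(k)])
    rows: list[np.ndarray] = []
    con_lb: list[float] = []
    con_ub: list[float] = []
    for i in range(n_mat.shape[0]):
        row = np.concatenate([n_mat[i], np.zeros(k)])
        rows.append(row)
        con_lb.append(0.0)
        con_ub.append(0.0)
    for idx, rid in enumerate(exchange_ids):
        row = np.zeros(n_var)
        row[rxn_index[rid]] = 1.0
        row[n + idx] = -lbs[rxn_index[rid]]
        rows.append(row)  # v_j - lb_j * y_j >= 0
        con_lb.append(0.0)
        con_ub.append(np.inf)

    var_lb = np.concatenate([lbs, np.zeros(k)])
    var_ub = np.concatenate([ubs, np.ones(k)])
    var_lb[rxn_index[scoped.biomass_id]] = max(
        biomass_lb, var_lb[rxn_index[scoped.biomass_id]]
    )
    integrality = np.concatenate([np.zeros(n), np.ones(k)])

    res = solve_milp(c, np.vstack(rows), con_lb, con_ub, var_lb, var_ub,
                     integrality, config)
    if res.status != "optimal":
        return MinimalMedium(frozenset(), {}, {}, biomass_lb, res.status)
    indicators = {
        rid: int(round(res.x[n + idx])) for idx, rid in enumerate(exchange_ids)
    }
    fluxes = {rid: float(res.x[rxn_index[rid]]) for rid in rxn_ids}
    active = frozenset(rid for rid, y in indicators.items() if y == 1)
    return MinimalMedium(active, indicators, fluxes, biomass_lb, "optimal")


# ---------------------------------------------------------------------------
# reaction subsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionSubset:
    """Group of reactions locked in fixed flux proportions."""

    members: tuple[str, ...]
    ratios: Mapping[str, Fraction]  # flux ratio relative to the first member
    inconsistent: bool = False  # negative ratio between two irreversibles

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


def _reduced_matrix(model: Model, blocked: BlockedSet, gaps: GapSet):
    """Rows minus gaps, columns minus blocked and biomass, plus one
    irreversible drain per biomass reactant."""
    keep_rows = [m for m in model.metabolite_ids if m not in gaps.gaps]
    keep_cols = [
        r for r in model.reaction_ids
        if r not in blocked.blocked and r != model.biomass_id
    ]
    drains: list[str] = []
    drain_targets: list[str] = []
    if model.biomass_id is not None:
        biomass = model.reaction(model.biomass_id)
        for met_id, coeff in biomass.stoichiometry.items():
            if coeff < 0 and met_id in keep_rows:
                drains.append(f"__drain__{met_id}")
                drain_targets.append(met_id)
    row_index = {m: i for i, m in enumerate(keep_rows)}
    n_cols = len(keep_cols) + len(drains)
    matrix = [[Fraction(0)] * n_cols for _ in keep_rows]
    for j, rid in enumerate(keep_cols):
        for met_id, coeff in model.reaction(rid).stoichiometry.items():
            if met_id in row_index:
                matrix[row_index[met_id]][j] = coeff
    for d, met_id in enumerate(drain_targets):
        matrix[row_index[met_id]][len(keep_cols) + d] = Fraction(-1)
    return keep_rows, keep_cols + drains, matrix


def reaction_subsets(
    model: Model,
    blocked: BlockedSet,
    gaps: GapSet,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[ReactionSubset]:
    """Fully coupled reaction groups of the unblocked network.

    The reduced stoichiometric matrix (gap rows and blocked columns
    removed, biomass column replaced by independent drains for its
    reactants) is kernelled; reactions whose kernel rows are proportional
    carry fixed flux ratios in every steady state and form one subset.
    Only groups with at least two model reactions are reported.  Exact
    rational arithmetic is used up to 500 columns, an SVD nullspace with
    relative tolerance 1e-6 beyond.
    """
    _, col_ids, matrix = _reduced_matrix(model, blocked, gaps)
    if not col_ids or not matrix:
        return []
    exact = len(col_ids) < 500
    groups: dict[tuple, list[tuple[str, Fraction]]] = {}
    if exact:
        basis = rational_nullspace(matrix)
        if not basis:
            return []
        for j, rid in enumerate(col_ids):
            coords = tuple(vec[j] for vec in basis)
            if all(v == 0 for v in coords):
                continue  # carries no flux in the reduced network
            pivot = next(v for v in coords if v != 0)
            key = tuple(v / pivot for v in coords)
            groups.setdefault(key, []).append((rid, pivot))
    else:
        dense = np.array([[float(x) for x in row] for row in matrix])
        kernel = linalg.null_space(dense)
        if kernel.size == 0:
            return []
        for j, rid in enumerate(col_ids):
            coords = kernel[j]
            scale = coords[np.argmax(np.abs(coords))]
            if abs(scale) < 1e-9:
                continue
            key = tuple(np.round(coords / scale, 6))
            groups.setdefault(key, []).append(
                (rid, Fraction(str(round(float(scale), 9))))
            )

    out: list[ReactionSubset] = []
    order = {rid: i for i, rid in enumerate(col_ids)}
    for members in groups.values():
        real = [(rid, pivot) for rid, pivot in members
                if not rid.startswith("__drain__")]
        if len(real) < 2:
            continue
        real.sort(key=lambda t: order[t[0]])
        first_pivot = real[0][1]
        ratios = {rid: pivot / first_pivot for rid, pivot in real}
        inconsistent = False
        for rid, ratio in ratios.items():
            if ratio < 0:
                rxn_a = model.reaction(real[0][0])
                rxn_b = model.reaction(rid)
                if rxn_a.lower_bound >= 0 and rxn_b.lower_bound >= 0:
                    inconsistent = True
        out.append(
            ReactionSubset(members=tuple(r for r, _ in real), ratios=ratios,
                           inconsistent=inconsistent)
        )
    out.sort(key=lambda s: (-len(s.members), s.members))
    return out


# ---------------------------------------------------------------------------
# subset comparison
# ---------------------------------------------------------------------------

def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|intersection| / |union|; 1.0 for two empty sets."""
    set_a, set_b = set(a), set(b)
    union = set_a | set_b
    if not union:
        return 1.0
    return len(set_a & set_b) / len(union)


@dataclass(frozen=True)
class SubsetComparison:
    pairs: tuple[tuple[int, int, float], ...]  # (index in a, index in b, J)
    counts: Mapping[float, int] = field(default_factory=dict)


def compare_subsets(
    rs_a: Sequence[ReactionSubset],
    rs_b: Sequence[ReactionSubset],
    thresholds: Sequence[float] = (1.0, 0.75),
) -> SubsetComparison:
    """Greedy one-to-one matching of two subset decompositions by
    descending Jaccard index, with matched-pair counts per threshold."""
    scored = []
    for i, sub_a in enumerate(rs_a):
        for j, sub_b in enumerate(rs_b):
            index = jaccard(sub_a.member_set, sub_b.member_set)
            if index > 0:
                scored.append((index, i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for index, i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, index))
    counts = {
        th: sum(1 for _, _, index in pairs if index >= th) for th in thresholds
    }
    return SubsetComparison(pairs=tuple(pairs), counts=counts)


# ---------------------------------------------------------------------------
# model diff
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelDiff:
    genes_added: frozenset[str]
    genes_removed: frozenset[str]
    reactions_added: frozenset[str]
    reactions_removed: frozenset[str]
    exchanges_added: frozenset[str]
    exchanges_removed: frozenset[str]
    biomass_added: frozenset[str]
    biomass_removed: frozenset[str]

    @property
    def empty(self) -> bool:
        return not any(
            (self.genes_added, self.genes_removed, self.reactions_added,
             self.reactions_removed, self.exchanges_added,
             self.exchanges_removed, self.biomass_added, self.biomass_removed)
        )

    def to_dict(self) -> dict:
        return {
            key: sorted(getattr(self, key))
            for key in (
                "genes_added", "genes_removed", "reactions_added",
                "reactions_removed", "exchanges_added", "exchanges_removed",
                "biomass_added", "biomass_removed",
            )
        }


def _biomass_components(model: Model) -> frozenset[str]:
    if model.biomass_id is None:
        return frozenset()
    biomass = model.reaction(model.biomass_id)
    return frozenset(m for m, c in biomass.stoichiometry.items() if c < 0)


def diff_models(model_a: Model, model_b: Model) -> ModelDiff:
    """Structural differences from *model_a* to *model_b* (added =
    present only in b, removed = present only in a)."""
    genes_a, genes_b = model_a.genes(), model_b.genes()
    rxns_a, rxns_b = set(model_a.reaction_ids), set(model_b.reaction_ids)
    ex_a, ex_b = set(model_a.exchange_ids), set(model_b.exchange_ids)
    bio_a, bio_b = _biomass_components(model_a), _biomass_components(model_b)
    return ModelDiff(
        genes_added=frozenset(genes_b - genes_a),
        genes_removed=frozenset(genes_a - genes_b),
        reactions_added=frozenset(rxns_b - rxns_a),
        reactions_removed=frozenset(rxns_a - rxns_b),
        exchanges_added=frozenset(ex_b - ex_a),
        exchanges_removed=frozenset(ex_a - ex_b),
        biomass_added=frozenset(bio_b - bio_a),
        biomass_removed=frozenset(bio_a - bio_b),
    )


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_knockouts_tsv(results: list[KnockoutResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": r.gene, "growth": r.growth, "essential": int(r.essential),
             "disabled_reactions": ";".join(r.disabled_reactions)}
            for r in results
        ],
        columns=["gene", "growth", "essential", "disabled_reactions"],
    ).to_csv(Path(path), sep="\t", index=False)


def write_medium_tsv(medium: MinimalMedium, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"exchange": rid, "y": y, "flux": medium.fluxes.get(rid, 0.0)}
            for rid, y in sorted(medium.indicators.items())
        ],
        columns=["exchange", "y", "flux"],
    ).to_csv(Path(path), sep="\t", index=False)


def write_subsets_tsv(subsets: list[ReactionSubset], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"subset": i + 1, "n_members": len(sub),
             "members": ";".join(sub.members),
             "ratios": ";".join(str(sub.ratios[m]) for m in sub.members),
             "inconsistent": int(sub.inconsistent)}
            for i, sub in enumerate(subsets)
        ],
        columns=["subset", "n_members", "members", "ratios", "inconsistent"],
    ).to_csv(Path(path), sep="\t", index=False)
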