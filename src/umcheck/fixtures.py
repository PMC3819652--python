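"""Reference networks, seeded random models with planted defects, and
independent brute-force oracles.

Three hand-sized networks capture the canonical failure modes of a draft
metabolic reconstruction:

* ``fig1a_network`` — a missing producer turns A into a root-non-produced
  dead end and silences the whole downstream chain;
* ``fig1b_network`` — the symmetric case: a missing consumer of H blocks
  the chain upstream;
* ``fig2_network`` — a cofactor pair (D, D*) cycling in an active loop
  conserves its total pool, so the synthesis pathway of D is blocked even
  though D itself is not a gap: the pseudo-gap situation.

``random_model`` plants any number of such structures on an active
backbone and returns the ground truth alongside, so detector outputs can
be checked exactly.  The oracles re-derive blocked sets (by exact
flux-mode enumeration) and minimal media (by exhaustive subset search)
without touching the LP/MILP code paths they validate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .gapfind import GapClass
from .lp import fba
from .model import Metabolite, Model, Reaction
from .rational import extreme_rays

__all__ = [
    "PlantedTruth",
    "fig1a_network",
    "fig1b_network",
    "fig2_network",
    "random_model",
    "oracle_blocked",
    "oracle_minimal_medium",
    "write_fixture",
]

_M = DEFAULT_CONFIG.big_bound


@dataclass(frozen=True)
class PlantedTruth:
    """Generator-side ground truth for a fixture model."""

    blocked: frozenset[str]
    gap_classes: dict[str, str]
    modules: tuple[frozenset[str], ...]  # member ids (metabolites + reactions)
    pseudo_gaps: frozenset[str] = frozenset()
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def gaps(self) -> frozenset[str]:
        return frozenset(self.gap_classes)

    @property
    def module_count(self) -> int:
        return len(self.modules)

    def to_dict(self) -> dict:
        return {
            "blocked": sorted(self.blocked),
            "gap_classes": dict(sorted(self.gap_classes.items())),
            "modules": [sorted(m) for m in self.modules],
            "pseudo_gaps": sorted(self.pseudo_gaps),
            "seed": self.seed,
            "params": self.params,
        }


def _rxn(rid: str, stoich: dict[str, int | str | Fraction],
         lb: float = 0.0, ub: float = _M, **kw) -> Reaction:
    return Reaction(id=rid,
                    stoichiometry={m: Fraction(c) for m, c in stoich.items()},
                    lower_bound=lb, upper_bound=ub, **kw)


def fig1a_network() -> tuple[Model, PlantedTruth]:
    """Linear chain with a missing producer: A is RNP, B and C are DNP."""
    mets = [Metabolite(m) for m in ("A", "B", "C", "E", "P")]
    rxns = [
        _rxn("R1", {"A": -1, "B": 1}),
        _rxn("R2", {"B": -1, "C": 1}),
        _rxn("R3", {"C": -1, "E": 1}),
        _rxn("R4", {"P": -1, "E": 1}),
        _rxn("EX_P", {"P": -1}, lb=-_M),
        _rxn("EX_E", {"E": -1}, lb=-_M),
    ]
    model = Model(id="fig1a", metabolites=mets, reactions=rxns,
                  exchange_ids={"EX_P", "EX_E"})
    truth = PlantedTruth(
        blocked=frozenset({"R1", "R2", "R3"}),
        gap_classes={"A": GapClass.RNP, "B": GapClass.DNP, "C": GapClass.DNP},
        modules=(frozenset({"A", "B", "C", "R1", "R2", "R3"}),),
    )
    return model, truth


def fig1b_network() -> tuple[Model, PlantedTruth]:
    """Chain with a missing consumer: H is RNC, F and G are UNC."""
    mets = [Metabolite(m) for m in ("F", "G", "H")]
    rxns = [
        _rxn("EX_F", {"F": -1}, lb=-_M),
        _rxn("R1", {"F": -1, "G": 1}),
        _rxn("R2", {"G": -1, "H": 1}),
    ]
    model = Model(id="fig1b", metabolites=mets, reactions=rxns,
                  exchange_ids={"EX_F"})
    truth = PlantedTruth(
        blocked=frozenset({"EX_F", "R1", "R2"}),
        gap_classes={"F": GapClass.UNC, "G": GapClass.UNC, "H": GapClass.RNC},
        modules=(frozenset({"F", "G", "H", "EX_F", "R1", "R2"}),),
    )
    return model, truth


def fig2_network() -> tuple[Model, PlantedTruth]:
    """Cofactor loop pseudo-gap: the conserved pair D/D* blocks the
    synthesis chain of D without either being a gap."""
    mets = [Metabolite(m) for m in
            ("A", "B", "C", "Cp", "D", "Dstar", "S", "P", "U", "W")]
    rxns = [
        _rxn("EX_A", {"A": -1}, lb=-_M),
        _rxn("v1", {"A": -1, "B": 1}),
        _rxn("v2", {"B": -1, "C": 1}),
        _rxn("v3", {"C": -1, "Cp": 1}),
        _rxn("v4", {"Cp": -1, "D": 1}),
        _rxn("v5", {"D": -1, "S": -1, "Dstar": 1, "P": 1}),
        _rxn("v6", {"Dstar": -1, "U": -1, "D": 1, "W": 1}),
        _rxn("EX_S", {"S": -1}, lb=-_M),
        _rxn("EX_P", {"P": -1}, lb=-_M),
        _rxn("EX_U", {"U": -1}, lb=-_M),
        _rxn("EX_W", {"W": -1}, lb=-_M),
    ]
    model = Model(id="fig2", metabolites=mets, reactions=rxns,
                  exchange_ids={"EX_A", "EX_S", "EX_P", "EX_U", "EX_W"})
    truth = PlantedTruth(
        blocked=frozenset({"EX_A", "v1", "v2", "v3", "v4"}),
        gap_classes={m: GapClass.UNCLASSIFIED for m in ("A", "B", "C", "Cp")},
        modules=(frozenset({"A", "B", "C", "Cp", "EX_A", "v1", "v2", "v3",
                            "v4"}),),
        pseudo_gaps=frozenset({"D", "Dstar"}),
    )
    return model, truth


# ---------------------------------------------------------------------------
# random generator
# ---------------------------------------------------------------------------

MODULE_KINDS = ("rnp_chain", "rnc_chain", "pseudogap_loop")


def random_model(
    n_backbone: int = 2,
    n_modules: int = 1,
    module_kinds: tuple[str, ...] = MODULE_KINDS,
    sizes: tuple[int, int] = (1, 3),
    seed: int = 0,
    with_biomass: bool = True,
) -> tuple[Model, PlantedTruth]:
    """Active backbone plus *n_modules* planted, mutually disjoint defects.

    The backbone uptakes two precursors through open exchanges, runs them
    down internal chains (*n_backbone* chain reactions in total, split
    randomly between the branches) and consumes both chain ends in a
    biomass reaction, so every backbone reaction can carry flux.  Each
    planted module touches the backbone only through the shared
    attachment metabolite (itself never a gap), so the planted modules
    are provably the connected components of the gap/blocked subgraph.

    ``sizes`` is an inclusive range for per-module size; kinds are drawn
    uniformly from *module_kinds*.
    """
    if sizes[0] < 1 or sizes[0] > sizes[1]:
        raise ValueError("sizes must be an inclusive range with min >= 1")
    unknown = set(module_kinds) - set(MODULE_KINDS)
    if unknown:
        raise ValueError(f"unknown module kinds: {sorted(unknown)}")
    if with_biomass and n_backbone < 0:
        raise ValueError("backbone length must be nonnegative")
    rng = np.random.default_rng(seed)

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    exchange_ids: set[str] = set()

    split = int(rng.integers(0, n_backbone + 1))
    len_a, len_b = split, n_backbone - split
    chain_a = [f"A{i}" for i in range(len_a + 1)]
    chain_b = [f"B{i}" for i in range(len_b + 1)]
    for mid in chain_a + chain_b:
        mets.append(Metabolite(mid))
    rxns.append(_rxn("EX_A0", {"A0": -1}, lb=-_M))
    rxns.append(_rxn("EX_B0", {"B0": -1}, lb=-_M))
    exchange_ids |= {"EX_A0", "EX_B0"}
    for i in range(1, len_a + 1):
        rxns.append(_rxn(f"RA{i}", {chain_a[i - 1]: -1, chain_a[i]: 1}))
    for i in range(1, len_b + 1):
        rxns.append(_rxn(f"RB{i}", {chain_b[i - 1]: -1, chain_b[i]: 1}))
    biomass_id = None
    if with_biomass:
        biomass_id = "BM"
        rxns.append(_rxn("BM", {chain_a[-1]: -1, chain_b[-1]: -1}))
    attach = "A0"

    blocked: set[str] = set()
    gap_classes: dict[str, str] = {}
    modules: list[frozenset[str]] = []
    pseudo_gaps: set[str] = set()
    for mod in range(n_modules):
        kind = module_kinds[int(rng.integers(0, len(module_kinds)))]
        size = int(rng.integers(sizes[0], sizes[1] + 1))
        tag = f"m{mod}"
        members: set[str] = set()
        if kind == "rnp_chain":
            gs = [f"{tag}_G{i}" for i in range(1, size + 1)]
            for gid in gs:
                mets.append(Metabolite(gid))
            for i in range(1, size):
                rid = f"{tag}_P{i}"
                rxns.append(_rxn(rid, {gs[i - 1]: -1, gs[i]: 1}))
                blocked.add(rid)
                members.add(rid)
            rid = f"{tag}_P{size}"
            rxns.append(_rxn(rid, {gs[-1]: -1, attach: 1}))
            blocked.add(rid)
            members.add(rid)
            gap_classes[gs[0]] = GapClass.RNP
            for gid in gs[1:]:
                gap_classes[gid] = GapClass.DNP
            members |= set(gs)
        elif kind == "rnc_chain":
            hs = [f"{tag}_H{i}" for i in range(1, size + 1)]
            for hid in hs:
                mets.append(Metabolite(hid))
            rid = f"{tag}_C1"
            rxns.append(_rxn(rid, {attach: -1, hs[0]: 1}))
            blocked.add(rid)
            members.add(rid)
            for i in range(1, size):
                rid = f"{tag}_C{i + 1}"
                rxns.append(_rxn(rid, {hs[i - 1]: -1, hs[i]: 1}))
                blocked.add(rid)
                members.add(rid)
            gap_classes[hs[-1]] = GapClass.RNC
            for hid in hs[:-1]:
                gap_classes[hid] = GapClass.UNC
            members |= set(hs)
        else:  # pseudogap_loop
            qs = [f"{tag}_Q{i}" for i in range(1, size + 1)]
            cof, cof2 = f"{tag}_D", f"{tag}_Ds"
            sub, prod = f"{tag}_S", f"{tag}_P"
            for mid in qs + [cof, cof2, sub, prod]:
                mets.append(Metabolite(mid))
            prev = attach
            for i, qid in enumerate(qs, start=1):
                rid = f"{tag}_T{i}"
                rxns.append(_rxn(rid, {prev: -1, qid: 1}))
                blocked.add(rid)
                members.add(rid)
                prev = qid
            rid = f"{tag}_T{size + 1}"
            rxns.append(_rxn(rid, {prev: -1, cof: 1}))
            blocked.add(rid)
            members.add(rid)
            rxns.append(_rxn(f"{tag}_L1", {cof: -1, sub: -1, cof2: 1, prod: 1}))
            rxns.append(_rxn(f"{tag}_L2", {cof2: -1, cof: 1}))
            rxns.append(_rxn(f"EX_{sub}", {sub: -1}, lb=-_M))
            rxns.append(_rxn(f"EX_{prod}", {prod: -1}, lb=-_M))
            exchange_ids |= {f"EX_{sub}", f"EX_{prod}"}
            for qid in qs:
                gap_classes[qid] = GapClass.UNCLASSIFIED
            pseudo_gaps |= {cof, cof2}
            members |= set(qs)
        modules.append(frozenset(members))

    # deterministic shuffle so detector results cannot depend on insertion
    # order
    met_order = rng.permutation(len(mets))
    rxn_order = rng.permutation(len(rxns))
    mets = [mets[i] for i in met_order]
    rxns = [rxns[i] for i in rxn_order]

    model = Model(id=f"random_{seed}", metabolites=mets, reactions=rxns,
                  exchange_ids=exchange_ids, biomass_id=biomass_id)
    truth = PlantedTruth(
        blocked=frozenset(blocked),
        gap_classes=gap_classes,
        modules=tuple(modules),
        pseudo_gaps=frozenset(pseudo_gaps),
        seed=seed,
        params={"n_backbone": n_backbone, "n_modules": n_modules,
                "module_kinds": list(module_kinds), "sizes": list(sizes),
                "with_biomass": with_biomass},
    )
    return model, truth


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def small_random_battery(n_models: int = 100, base_seed: int = 0):
    """Deterministic stream of small random models (<= 12 reactions each)
    with planted truth, sized for the exact brute-force oracles.

    Every fourth model carries a pseudo-gap loop; the rest mix RNP/RNC
    chains (0-2 planted modules) over varying backbone lengths.
    """
    for i in range(n_models):
        seed = base_seed + i
        if i % 4 == 0:
            yield random_model(n_backbone=i % 2, n_modules=1,
                               module_kinds=("pseudogap_loop",),
                               sizes=(1, 2), seed=seed)
        else:
            yield random_model(n_backbone=i % 3, n_modules=i % 3,
                               module_kinds=("rnp_chain", "rnc_chain"),
                               sizes=(1, 2), seed=seed)


def oracle_blocked(model: Model, max_columns: int = 24) -> frozenset[str]:
    """Blocked set by exact flux-mode enumeration (independent of LP).

    Reversible reactions are split into forward/backward parts; the
    extreme rays of the resulting irreversible flux cone are the
    elementary modes.  A reaction is unblocked exactly when some mode —
    other than the spurious forward/backward two-cycle of a reversible
    reaction — uses it.  Requires ``lb <= 0 <= ub`` for every reaction.
    """
    met_ids = model.metabolite_ids
    row_index = {m: i for i, m in enumerate(met_ids)}
    columns: list[tuple[str, int]] = []  # (reaction id, direction +1/-1)
    forced: set[str] = set()
    for rxn in model.reactions:
        if rxn.lower_bound > 0 or rxn.upper_bound < 0:
            raise ValueError(
                f"oracle requires lb <= 0 <= ub (reaction {rxn.id!r})"
            )
        if rxn.upper_bound > 0:
            columns.append((rxn.id, +1))
        if rxn.lower_bound < 0:
            columns.append((rxn.id, -1))
        if rxn.upper_bound == 0 and rxn.lower_bound == 0:
            forced.add(rxn.id)
    if len(columns) > max_columns:
        raise ValueError(
            f"{len(columns)} split columns exceed the oracle cap "
            f"{max_columns}; use the LP detector"
        )
    matrix = [[Fraction(0)] * len(columns) for _ in met_ids]
    for j, (rid, direction) in enumerate(columns):
        for met_id, coeff in model.reaction(rid).stoichiometry.items():
            matrix[row_index[met_id]][j] = direction * coeff
    if not matrix:  # no metabolites cannot happen for a valid model
        return frozenset(forced)
    rays = extreme_rays(matrix)
    unblocked: set[str] = set()
    col_of = {}
    for j, (rid, direction) in enumerate(columns):
        col_of.setdefault(rid, {})[direction] = j
    for ray in rays:
        support = {j for j, v in enumerate(ray) if v != 0}
        # spurious mode: exactly a reaction's own forward+backward pair
        if len(support) == 2:
            rids = {columns[j][0] for j in support}
            if len(rids) == 1:
                continue
        for j in support:
            unblocked.add(columns[j][0])
    return frozenset(set(model.reaction_ids) - unblocked)


def oracle_minimal_medium(
    model: Model,
    biomass_lb: float,
    config: RunConfig = DEFAULT_CONFIG,
    max_exchanges: int = 8,
) -> tuple[int, frozenset[str]]:
    """Exhaustive minimal-medium search over exchange subsets.

    Exchanges outside the trial subset are restricted to secretion only
    (``[0, M]``); the smallest subset under which FBA reaches
    *biomass_lb* is returned as (cardinality, witness set).
    """
    if model.biomass_id is None:
        raise ValueError("oracle requires a biomass reaction")
    exchanges = sorted(model.exchange_ids)
    if len(exchanges) > max_exchanges:
        raise ValueError(
            f"{len(exchanges)} exchanges exceed the oracle cap {max_exchanges}"
        )
    big = config.big_bound
    for cardinality in range(len(exchanges) + 1):
        for subset in itertools.combinations(exchanges, cardinality):
            trial = model.copy()
            for rid in exchanges:
                if rid in subset:
                    trial.set_reaction(trial.reaction(rid).with_bounds(-big, big))
                else:
                    trial.set_reaction(trial.reaction(rid).with_bounds(0.0, big))
            sol = fba(trial, config=config)
            if sol.optimal and sol.objective_value >= biomass_lb - 1e-6:
                return cardinality, frozenset(subset)
    return len(exchanges) + 1, frozenset()  # unreachable for feasible inputs


def write_fixture(name: str, out_dir: str | Path, seed: int = 0,
                  **random_kwargs) -> tuple[Model, PlantedTruth]:
    """Materialise a named fixture as a TSV bundle plus truth JSON."""
    from .io import write_model_tsv

    builders = {"fig1a": fig1a_network, "fig1b": fig1b_network,
                "fig2": fig2_network}
    if name in builders:
        model, truth = builders[name]()
    elif name == "random":
        model, truth = random_model(seed=seed, **random_kwargs)
    else:
        raise ValueError(
            f"unknown fixture {name!r}; expected fig1a|fig1b|fig2|random"
        )
    out_dir = Path(out_dir)
    write_model_tsv(model, out_dir)
    (out_dir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2)
                                        + "\n")
    return model, truth
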