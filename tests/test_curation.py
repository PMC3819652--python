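from fractions import Fraction

import numpy as np
import pytest

from umcheck.curation import (
    compare_subsets,
    diff_models,
    jaccard,
    knockout_scan,
    minimal_medium,
    reaction_subsets,
)
from umcheck.fixtures import oracle_minimal_medium, random_model
from umcheck.gapfind import check_model
from umcheck.gpr import parse_gpr
from umcheck.lp import fba_objective
from umcheck.model import Metabolite, Model, Reaction


def _chain_model(two_sources: bool):
    """Biomass needs M1 and M2; M2 is producible from M1 unless
    two_sources is requested."""
    mets = [Metabolite(x) for x in ("M1", "M2")]
    rxns = [
        Reaction("EX_M1", {"M1": Fraction(-1)}, -1000, 1000),
        Reaction("EX_M2", {"M2": Fraction(-1)}, -1000, 1000),
        Reaction("BM", {"M1": Fraction(-1), "M2": Fraction(-1)}, 0, 1000),
    ]
    if not two_sources:
        rxns.append(Reaction("CONV", {"M1": Fraction(-1), "M2": Fraction(1)},
                             0, 1000))
    return Model("mm", mets, rxns, exchange_ids={"EX_M1", "EX_M2"},
                 biomass_id="BM")


# -- knockouts --------------------------------------------------------------

def test_single_gated_path_is_essential():
    mets = [Metabolite(x) for x in ("A", "B")]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000),
        Reaction("R1", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000,
                 gpr=parse_gpr("g1")),
        Reaction("BM", {"A": Fraction(-1), "B": Fraction(-1)}, 0, 1000),
    ]
    model = Model("m", mets, rxns, exchange_ids={"EX_A"}, biomass_id="BM")
    results = {r.gene: r for r in knockout_scan(model)}
    assert results["g1"].essential
    assert results["g1"].growth == pytest.approx(0.0, abs=1e-8)


def test_parallel_paths_make_neither_gene_essential(toy_gpr_model):
    results = {r.gene: r for r in knockout_scan(toy_gpr_model)}
    assert not results["g1"].essential
    assert not results["g2"].essential


def test_gene_on_blocked_reaction_is_not_essential(toy_gpr_model):
    # g3 gates RDEAD, which is blocked (DEAD has no producer)
    results = {r.gene: r for r in knockout_scan(toy_gpr_model)}
    wild_type = max(r.growth for r in results.values())
    assert not results["g3"].essential
    assert results["g3"].growth == pytest.approx(wild_type, rel=1e-6)


def test_and_gpr_disables_reaction_on_either_gene():
    mets = [Metabolite(x) for x in ("A", "B")]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000),
        Reaction("R1", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000,
                 gpr=parse_gpr("g1 and g2")),
        Reaction("BM", {"A": Fraction(-1), "B": Fraction(-1)}, 0, 1000),
    ]
    model = Model("m", mets, rxns, exchange_ids={"EX_A"}, biomass_id="BM")
    results = {r.gene: r for r in knockout_scan(model)}
    assert results["g1"].essential and results["g2"].essential


def test_no_baseline_growth_raises(fig1a):
    model, _ = fig1a
    grounded = model.copy()
    grounded.biomass_id = "R1"  # blocked reaction as biomass
    with pytest.raises(ValueError, match="no baseline growth"):
        knockout_scan(grounded)


# -- minimal medium ---------------------------------------------------------

def test_minimal_medium_uses_internal_conversion():
    model = _chain_model(two_sources=False)
    medium = minimal_medium(model, biomass_lb=1.0)
    assert medium.status == "optimal"
    assert medium.exchanges == {"EX_M1"}
    card, witness = oracle_minimal_medium(model, 1.0)
    assert card == 1 and witness == {"EX_M1"}


def test_minimal_medium_requires_both_precursors():
    model = _chain_model(two_sources=True)
    medium = minimal_medium(model, biomass_lb=1.0)
    assert medium.exchanges == {"EX_M1", "EX_M2"}
    card, _ = oracle_minimal_medium(model, 1.0)
    assert card == 2


def test_minimal_medium_infeasible_above_max_growth():
    model = _chain_model(two_sources=False)
    medium = minimal_medium(model, biomass_lb=1e9)
    assert medium.status == "infeasible"
    assert medium.exchanges == frozenset()


def test_minimal_medium_matches_oracle_on_random_models():
    for seed in range(8):
        model, _ = random_model(n_backbone=seed % 3, n_modules=seed % 2,
                                module_kinds=("rnp_chain", "rnc_chain"),
                                sizes=(1, 2), seed=seed)
        medium = minimal_medium(model)
        card, _ = oracle_minimal_medium(model, medium.biomass_lb)
        assert medium.cardinality == card


# -- reaction subsets -------------------------------------------------------

def _linear_chain():
    mets = [Metabolite(x) for x in ("A", "B", "C")]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000),
        Reaction("R1", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000),
        Reaction("R2", {"B": Fraction(-1), "C": Fraction(1)}, 0, 1000),
        Reaction("EX_C", {"C": Fraction(-1)}, -1000, 1000),
    ]
    return Model("chain", mets, rxns, exchange_ids={"EX_A", "EX_C"})


def test_linear_chain_is_one_subset():
    model = _linear_chain()
    blocked, gaps = check_model(model)
    subsets = reaction_subsets(model, blocked, gaps)
    assert len(subsets) == 1
    subset = subsets[0]
    assert set(subset.members) == {"EX_A", "R1", "R2", "EX_C"}
    first = subset.members[0]
    assert subset.ratios[first] == 1
    # chain stoichiometry is 1:1 throughout; exchange sign flips uptake
    assert {abs(r) for r in subset.ratios.values()} == {Fraction(1)}


def test_branch_point_splits_subsets():
    mets = [Metabolite(x) for x in ("A", "B", "C")]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000),
        Reaction("RB", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000),
        Reaction("RC", {"A": Fraction(-1), "C": Fraction(1)}, 0, 1000),
        Reaction("EX_B", {"B": Fraction(-1)}, -1000, 1000),
        Reaction("EX_C", {"C": Fraction(-1)}, -1000, 1000),
    ]
    model = Model("branch", mets, rxns, exchange_ids={"EX_A", "EX_B", "EX_C"})
    blocked, gaps = check_model(model)
    subsets = reaction_subsets(model, blocked, gaps)
    for subset in subsets:
        assert not {"RB", "RC"} <= set(subset.members)
    assert any(set(s.members) == {"RB", "EX_B"} for s in subsets)
    assert any(set(s.members) == {"RC", "EX_C"} for s in subsets)


def test_subset_members_are_flux_proportional():
    model, _ = random_model(n_backbone=4, n_modules=0, seed=11)
    blocked, gaps = check_model(model)
    subsets = reaction_subsets(model, blocked, gaps)
    assert subsets, "backbone chain should form at least one subset"
    rng = np.random.default_rng(11)
    for _ in range(25):
        weights = {rid: float(w) for rid, w in
                   zip(model.reaction_ids,
                       rng.normal(size=model.n_reactions))}
        sol = fba_objective(model, weights, "max")
        assert sol.optimal
        for subset in subsets:
            first = subset.members[0]
            reference = sol.fluxes[first]
            for member in subset.members[1:]:
                expected = float(subset.ratios[member]) * reference
                assert sol.fluxes[member] == pytest.approx(
                    expected, rel=1e-6, abs=1e-6)


def test_blocked_and_biomass_columns_are_excluded(fig1a):
    model, truth = fig1a
    blocked, gaps = check_model(model)
    subsets = reaction_subsets(model, blocked, gaps)
    for subset in subsets:
        assert not (set(subset.members) & truth.blocked)


# -- Jaccard and comparison -------------------------------------------------

def test_jaccard_basics():
    assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
    assert jaccard({"a"}, {"a"}) == 1.0
    assert jaccard({"a"}, {"b"}) == 0.0
    assert jaccard({"a", "b"}, {"b", "a"}) == 1.0


def test_jaccard_symmetric_and_bounded():
    rng = np.random.default_rng(0)
    universe = [f"r{i}" for i in range(10)]
    for _ in range(50):
        a = {r for r in universe if rng.random() < 0.5}
        b = {r for r in universe if rng.random() < 0.5}
        ab = jaccard(a, b)
        assert ab == jaccard(b, a)
        assert 0.0 <= ab <= 1.0
        assert (ab == 1.0) == (a == b)


def test_compare_identical_and_disjoint_lists():
    from umcheck.curation import ReactionSubset

    def subset(*members):
        return ReactionSubset(members=members,
                              ratios={m: Fraction(1) for m in members})

    rs = [subset("a", "b"), subset("c", "d", "e")]
    same = compare_subsets(rs, rs)
    assert same.counts[1.0] == 2 and same.counts[0.75] == 2
    other = [subset("x", "y"), subset("z", "w")]
    nothing = compare_subsets(rs, other)
    assert nothing.counts[1.0] == 0 and nothing.counts[0.75] == 0
    partial = compare_subsets([subset("a", "b")], [subset("b", "c")])
    assert partial.pairs[0][2] == pytest.approx(1 / 3)


# -- diffs ------------------------------------------------------------------

def test_diff_of_identical_models_is_empty(fig2):
    model, _ = fig2
    assert diff_models(model, model).empty


def test_diff_reports_added_sink_and_biomass_component(fig2):
    from umcheck.pseudogap import RepairAction, apply_repair

    model, _ = fig2
    with_sink, _ = apply_repair(model, RepairAction("add_sink", "D"))
    delta = diff_models(model, with_sink)
    assert delta.reactions_added == {"SK_D"}
    assert delta.reactions_removed == frozenset()

    extended = model.copy()
    extended.add_reaction(
        Reaction("BM", {"P": Fraction(-1)}, 0, 1000), exchange=False)
    extended.biomass_id = "BM"
    richer, _ = apply_repair(
        extended, RepairAction("add_biomass_component", "D"))
    delta2 = diff_models(extended, richer)
    assert delta2.biomass_added == {"D"}
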