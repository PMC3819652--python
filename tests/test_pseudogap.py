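from fractions import Fraction

import pytest

from umcheck.gapfind import check_model, find_blocked
from umcheck.model import Metabolite, Model, ModelValidationError, Reaction
from umcheck.pseudogap import (
    RepairAction,
    apply_repair,
    conservation_relations,
    resolve_um,
    scan_pseudo_gaps,
)


def test_cofactor_moiety_found_only_in_unblocked_scope(fig2):
    model, _ = fig2
    blocked = find_blocked(model)
    scoped = conservation_relations(model, "unblocked_only", blocked)
    assert [dict(r.weights) for r in scoped] == [
        {"D": Fraction(1), "Dstar": Fraction(1)}
    ]
    # the blocked synthesis column v4 breaks the moiety over the full scope
    full = conservation_relations(model, "all")
    assert not any(r.support == {"D", "Dstar"} for r in full)


def test_closed_two_cycle_is_a_moiety():
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("F", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000),
        Reaction("R", {"B": Fraction(-1), "A": Fraction(1)}, 0, 1000),
    ]
    model = Model("cycle", mets, rxns, exchange_ids=set())
    relations = conservation_relations(model, "all")
    assert [dict(r.weights) for r in relations] == [
        {"A": Fraction(1), "B": Fraction(1)}
    ]


def test_relations_annihilate_scoped_matrix(fig2):
    model, _ = fig2
    blocked = find_blocked(model)
    for scope, blk in (("all", None), ("unblocked_only", blocked)):
        for relation in conservation_relations(model, scope, blk):
            columns = (
                model.reaction_ids if scope == "all"
                else [r for r in model.reaction_ids if r not in blocked.blocked]
            )
            for rid in columns:
                rxn = model.reaction(rid)
                total = sum(
                    relation.weights.get(m, Fraction(0)) * c
                    for m, c in rxn.stoichiometry.items()
                )
                assert total == 0


def test_scan_reports_both_halves_of_the_cofactor_pair(fig2):
    model, _ = fig2
    blocked, gaps = check_model(model)
    findings = scan_pseudo_gaps(model, blocked, gaps)
    by_met = {f.metabolite_id: f for f in findings}
    assert set(by_met) == {"D", "Dstar"}
    for finding in findings:
        assert finding.unblocks == blocked.blocked  # frees the whole chain
        assert finding.relation is not None
        assert finding.relation.support == {"D", "Dstar"}


def test_scan_finds_nothing_for_true_root_gaps(fig1a):
    model, _ = fig1a
    blocked, gaps = check_model(model)
    assert scan_pseudo_gaps(model, blocked, gaps) == []


def test_scan_finds_nothing_when_nothing_blocked():
    mets = [Metabolite("A")]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000),
        Reaction("SK_A", {"A": Fraction(-1)}, -1000, 1000),
    ]
    model = Model("ok", mets, rxns, exchange_ids={"EX_A", "SK_A"})
    blocked, gaps = check_model(model)
    assert scan_pseudo_gaps(model, blocked, gaps) == []


def test_scan_does_not_mutate_model(fig2):
    model, _ = fig2
    before = model.state_fingerprint()
    blocked, gaps = check_model(model)
    scan_pseudo_gaps(model, blocked, gaps)
    assert model.state_fingerprint() == before


def test_add_sink_unblocks_cofactor_chain(fig2):
    model, _ = fig2
    repaired, delta = apply_repair(model, RepairAction("add_sink", "D"))
    assert len(delta.blocked_before) == 5
    assert delta.blocked_after == frozenset()
    assert delta.n_ums_before == 1 and delta.n_ums_after == 0
    assert repaired.has_reaction("SK_D")
    assert not model.has_reaction("SK_D")  # input untouched


def test_biomass_inclusion_is_equivalent_to_a_sink(fig2):
    model, _ = fig2
    # give the network a biomass drain fed by the active loop product
    extended = model.copy()
    extended.add_reaction(
        Reaction("BM", {"P": Fraction(-1), "W": Fraction(-1)}, 0, 1000),
        exchange=False,
    )
    extended.biomass_id = "BM"
    repaired, delta = apply_repair(
        extended, RepairAction("add_biomass_component", "D",
                               {"coefficient": "1e-4"})
    )
    assert delta.blocked_after == frozenset()
    coeff = repaired.reaction("BM").stoichiometry["D"]
    assert coeff == Fraction("-1e-4")


def test_biomass_repair_requires_biomass(fig2):
    model, _ = fig2
    with pytest.raises(ModelValidationError, match="biomass"):
        apply_repair(model, RepairAction("add_biomass_component", "D"))


def test_relax_irreversibility_changes_root_class_only(fig1b):
    # H's sole reaction is R2, so mass balance pins v_R2 = 0 whether or
    # not R2 is reversible: the blocked set cannot shrink.  What changes
    # is H's root status — the reverse direction is an admissible
    # consumer, so H stops being RNC.
    model, _ = fig1b
    repaired, delta = apply_repair(
        model, RepairAction("relax_irreversibility", "R2"))
    assert repaired.reaction("R2").lower_bound < 0
    assert delta.blocked_after == delta.blocked_before
    _, gaps = check_model(repaired)
    assert gaps.classes["H"] != "RNC"


def test_relax_irreversibility_can_unblock():
    # R2 is written H -> G but H has no producer; its secretion-only
    # exchange cannot help.  Making R2 reversible opens G -> H -> out.
    mets = [Metabolite(x) for x in ("F", "G", "H")]
    rxns = [
        Reaction("EX_F", {"F": Fraction(-1)}, -1000, 1000),
        Reaction("R1", {"F": Fraction(-1), "G": Fraction(1)}, 0, 1000),
        Reaction("R2", {"H": Fraction(-1), "G": Fraction(1)}, 0, 1000),
        Reaction("EX_G", {"G": Fraction(-1)}, -1000, 1000),
        # secretion-only drain kept internal so media cannot reverse it
        Reaction("SK_H", {"H": Fraction(-1)}, 0, 1000),
    ]
    model = Model("wrongway", mets, rxns, exchange_ids={"EX_F", "EX_G"})
    before = find_blocked(model).blocked
    assert before == {"R2", "SK_H"}
    _, delta = apply_repair(model, RepairAction("relax_irreversibility", "R2"))
    assert delta.blocked_after == frozenset()


def test_sink_monotonicity_over_all_metabolites(fig2):
    model, _ = fig2
    base = find_blocked(model).blocked
    for met_id in model.metabolite_ids:
        _, delta = apply_repair(model, RepairAction("add_sink", met_id))
        assert delta.blocked_after <= base


def test_resolve_um_ranks_roots_first(fig1a):
    from umcheck.graph import build_graph, find_ums, um_subgraph

    model, _ = fig1a
    blocked, gaps = check_model(model)
    ums = find_ums(um_subgraph(build_graph(model, blocked, gaps), gaps,
                               blocked), model, gaps)
    candidates = [RepairAction("add_exchange", "A"),
                  RepairAction("add_exchange", "B")]
    ranking = resolve_um(model, ums[0], candidates)
    assert ranking[0][0].target == "A" and ranking[0][1] == 3
    assert ranking[1][0].target == "B" and ranking[1][1] == 2
    assert resolve_um(model, ums[0], []) == []


def test_unknown_repair_kind_rejected():
    with pytest.raises(ValueError, match="unknown repair kind"):
        RepairAction("teleport", "A")
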