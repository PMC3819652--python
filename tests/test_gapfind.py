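from fractions import Fraction

import pytest

from umcheck.fixtures import oracle_blocked, random_model
from umcheck.gapfind import (
    GapClass,
    check_model,
    classify_gaps,
    find_blocked,
    find_gaps,
    sigma,
)
from umcheck.model import Metabolite, Model, Reaction


def test_sigma_returns_touching_reactions(fig1a):
    model, _ = fig1a
    assert sigma(model, "B") == {"R1", "R2"}
    assert sigma(model, "E") == {"R3", "R4", "EX_E"}
    with pytest.raises(KeyError):
        sigma(model, "nope")


def test_sigma_empty_for_orphan_metabolite():
    model = Model(
        "m",
        [Metabolite("A"), Metabolite("LONELY")],
        [Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000)],
        exchange_ids={"EX_A"},
    )
    assert sigma(model, "LONELY") == frozenset()
    blocked = find_blocked(model)
    gaps = find_gaps(model, blocked)
    assert "LONELY" in gaps.gaps
    assert "LONELY" in gaps.orphans


def test_blocked_and_gaps_missing_producer_chain(fig1a):
    model, truth = fig1a
    blocked = find_blocked(model)
    assert blocked.blocked == truth.blocked == {"R1", "R2", "R3"}
    gaps = find_gaps(model, blocked)
    assert gaps.gaps == {"A", "B", "C"}


def test_blocked_and_gaps_cofactor_loop(fig2):
    model, truth = fig2
    blocked = find_blocked(model)
    assert blocked.blocked == truth.blocked
    gaps = find_gaps(model, blocked)
    assert gaps.gaps == {"A", "B", "C", "Cp"}
    # D and D* escape the gap definition through the active loop
    assert "D" not in gaps.gaps and "Dstar" not in gaps.gaps


def test_gap_membership_identity(fig1a, fig1b, fig2):
    """Gap membership must equal sigma-subset-of-blocked for every
    metabolite, independent of how detection iterated."""
    for model, _ in (fig1a, fig1b, fig2):
        blocked = find_blocked(model)
        gaps = find_gaps(model, blocked)
        for met_id in model.metabolite_ids:
            expected = sigma(model, met_id) <= blocked.blocked
            assert (met_id in gaps.gaps) == expected


@pytest.mark.parametrize(
    "fixture, expected",
    [
        ("fig1a", {"A": GapClass.RNP, "B": GapClass.DNP, "C": GapClass.DNP}),
        ("fig1b", {"F": GapClass.UNC, "G": GapClass.UNC, "H": GapClass.RNC}),
        ("fig2", {m: GapClass.UNCLASSIFIED for m in ("A", "B", "C", "Cp")}),
    ],
)
def test_gap_classification(fixture, expected, request):
    model, _ = request.getfixturevalue(fixture)
    _, gaps = check_model(model)
    assert dict(gaps.classes) == expected


def test_root_rule_matches_row_scan(fig1a, fig1b, fig2):
    """RNP/RNC from the classifier agree with a direct scan of admissible
    directions in the stoichiometric matrix rows."""
    for model, _ in (fig1a, fig1b, fig2):
        blocked, gaps = check_model(model)
        for met_id in gaps.gaps:
            producers = consumers = 0
            for rxn in model.reactions:
                coeff = rxn.stoichiometry.get(met_id)
                if coeff is None:
                    continue
                if (coeff > 0 and rxn.upper_bound > 0) or (
                        coeff < 0 and rxn.lower_bound < 0):
                    producers += 1
                if (coeff < 0 and rxn.upper_bound > 0) or (
                        coeff > 0 and rxn.lower_bound < 0):
                    consumers += 1
            assert (gaps.classes[met_id] == GapClass.RNP) == (
                producers == 0 and consumers > 0)
            assert (gaps.classes[met_id] == GapClass.RNC) == (
                consumers == 0 and producers > 0)


def test_reversible_consumer_counts_as_producer():
    """A reversible reaction consuming a metabolite forward can also
    produce it, so the metabolite is not RNP."""
    mets = [Metabolite(x) for x in ("A", "B")]
    rxns = [
        Reaction("R_rev", {"A": Fraction(-1), "B": Fraction(1)}, -1000, 1000),
        Reaction("R_out", {"A": Fraction(-1)}, 0, 1000),
        Reaction("EX_B", {"B": Fraction(-1)}, -1000, 1000),
    ]
    model = Model("rev", mets, rxns, exchange_ids={"R_out", "EX_B"})
    blocked, gaps = check_model(model)
    assert "A" not in gaps.gaps or gaps.classes.get("A") != GapClass.RNP


def test_blocked_matches_flux_mode_oracle_small_battery():
    for seed in range(10):
        model, truth = random_model(n_backbone=seed % 3, n_modules=seed % 3,
                                    module_kinds=("rnp_chain", "rnc_chain"),
                                    sizes=(1, 2), seed=seed)
        lp_detected = find_blocked(model).blocked
        assert lp_detected == oracle_blocked(model) == truth.blocked


def test_adding_sink_never_enlarges_blocked_set(fig2):
    from umcheck.pseudogap import add_sink_reaction

    model, _ = fig2
    base = find_blocked(model).blocked
    for met_id in model.metabolite_ids:
        extended, _ = add_sink_reaction(model, met_id)
        assert find_blocked(extended).blocked <= base


def test_closing_exchange_never_shrinks_blocked_set(fig2):
    model, _ = fig2
    base = find_blocked(model).blocked
    for rid in sorted(model.exchange_ids):
        restricted = model.copy()
        restricted.set_reaction(restricted.reaction(rid).with_bounds(0.0, 0.0))
        assert find_blocked(restricted).blocked >= base


def test_infeasible_model_raises():
    mets = [Metabolite("A"), Metabolite("B")]
    # internal reaction forced to run with no way to balance A or B
    rxns = [Reaction("R", {"A": Fraction(-1), "B": Fraction(1)}, 5, 10)]
    model = Model("bad", mets, rxns, exchange_ids=set())
    with pytest.raises(ValueError, match="flux space empty"):
        find_blocked(model)


def test_classification_with_explicit_partition(fig1a):
    model, truth = fig1a
    blocked = find_blocked(model)
    gaps = find_gaps(model, blocked)
    classified = classify_gaps(model, gaps, blocked,
                               um_partition=list(truth.modules))
    assert dict(classified.classes) == truth.gap_classes
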