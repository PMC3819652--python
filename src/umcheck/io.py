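"""Readers and writers: TSV bundle, SBML (Level 2 / Level 3 + FBC), media.

The TSV bundle mirrors the three-sheet layout common for published model
supplements: ``metabolites.tsv`` (id, name, compartment, extracellular),
``reactions.tsv`` (id, equation, lb, ub, gpr, subsystem, is_biomass) and
``exchanges.tsv`` (id, metabolite, lb, ub).  Reaction equations use the
text form ``"2 A + B -> C"``; ``->`` marks an irreversible reaction and
``<=>`` a reversible one (the bound columns, when present, win).
"""

from __future__ import annotations

import json
import logging
from fractions import Fraction
from pathlib import Path

import libsbml
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .gpr import GPRExpression, parse_gpr
from .model import (
    MediumSpec,
    Metabolite,
    Model,
    ModelValidationError,
    Reaction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_model_tsv",
    "write_model_tsv",
    "read_model_sbml",
    "write_model_sbml",
    "read_model",
    "write_model",
    "read_medium",
    "parse_equation",
    "format_equation",
]


class ModelParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reaction equation strings
# ---------------------------------------------------------------------------

def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"2 A + B -> C"`` into (stoichiometry, reversible).

    Coefficients may be integers, decimals or fractions (``3/2``); a bare
    metabolite name means coefficient 1.  Either side may be empty (sink /
    uptake pseudo-reactions).
    """
    if "<=>" in text:
        arrow, reversible = "<=>", True
    elif "<->" in text:
        arrow, reversible = "<->", True
    elif "->" in text:
        arrow, reversible = "->", False
    else:
        raise ModelParseError(f"equation {text!r} has no '->' or '<=>' arrow")
    left, _, right = text.partition(arrow)
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelParseError(f"empty term in equation {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, met = Fraction(1), parts[0]
            elif len(parts) == 2:
                try:
                    coeff = Fraction(parts[0])
                except ValueError:
                    raise ModelParseError(
                        f"bad coefficient {parts[0]!r} in equation {text!r}"
                    ) from None
                met = parts[1]
            else:
                raise ModelParseError(f"cannot parse term {term!r} in {text!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    add_side(left, -1)
    add_side(right, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ModelParseError(f"equation {text!r} has empty net stoichiometry")
    return stoich, reversible


def format_equation(stoich: dict[str, Fraction], reversible: bool) -> str:
    def side(items: list[tuple[str, Fraction]]) -> str:
        terms = []
        for met, coeff in items:
            terms.append(met if coeff == 1 else f"{coeff} {met}")
        return " + ".join(terms)

    left = [(m, -c) for m, c in stoich.items() if c < 0]
    right = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "->"
    return f"{side(left)} {arrow} {side(right)}".strip()


# ---------------------------------------------------------------------------
# TSV bundle
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_model_tsv(directory: str | Path, model_id: str | None = None,
                   config: RunConfig = DEFAULT_CONFIG) -> Model:
    """Read a model from a directory holding the three-table bundle."""
    directory = Path(directory)
    met_path = directory / "metabolites.tsv"
    rxn_path = directory / "reactions.tsv"
    ex_path = directory / "exchanges.tsv"
    for path in (met_path, rxn_path):
        if not path.exists():
            raise FileNotFoundError(path)

    mets = _read_table(met_path)
    if "id" not in mets.columns:
        raise ModelParseError(f"{met_path}: missing 'id' column")
    metabolites = []
    for _, row in mets.iterrows():
        metabolites.append(
            Metabolite(
                id=row["id"],
                name=row.get("name", ""),
                compartment=row.get("compartment", "c") or "c",
                is_extracellular=str(row.get("extracellular", "")).lower()
                in ("1", "true", "yes")
                or (row.get("compartment", "") == "e"),
            )
        )
    declared = {m.id for m in metabolites}

    rxns = _read_table(rxn_path)
    if rxns.empty:
        raise ModelParseError(f"{rxn_path}: model has no reactions")
    reactions: list[Reaction] = []
    biomass_id = None
    big = config.big_bound
    for idx, row in rxns.iterrows():
        rid = row["id"]
        stoich, reversible = parse_equation(row["equation"])
        missing = set(stoich) - declared
        if missing:
            raise ModelParseError(
                f"{rxn_path} row {idx + 2} (reaction {rid!r}): undeclared "
                f"metabolite id(s) {sorted(missing)}"
            )
        lb_text = row.get("lb", "")
        ub_text = row.get("ub", "")
        lb = float(lb_text) if lb_text != "" else (-big if reversible else 0.0)
        ub = float(ub_text) if ub_text != "" else big
        lb, ub = _clamp_bounds(rid, lb, ub, big)
        gpr = parse_gpr(row.get("gpr", ""))
        reactions.append(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                     name=row.get("name", ""), gpr=gpr,
                     subsystem=row.get("subsystem", ""))
        )
        if str(row.get("is_biomass", "")).lower() in ("1", "true", "yes"):
            biomass_id = rid

    exchange_ids: set[str] | None = None
    if ex_path.exists():
        exch = _read_table(ex_path)
        exchange_ids = set()
        for idx, row in exch.iterrows():
            rid = row["id"]
            met = row.get("metabolite", "")
            if met and met not in declared:
                raise ModelParseError(
                    f"{ex_path} row {idx + 2}: undeclared metabolite id {met!r}"
                )
            lb = float(row["lb"]) if row.get("lb", "") != "" else -big
            ub = float(row["ub"]) if row.get("ub", "") != "" else big
            lb, ub = _clamp_bounds(rid, lb, ub, big)
            if rid not in {r.id for r in reactions}:
                if not met:
                    raise ModelParseError(
                        f"{ex_path} row {idx + 2}: exchange {rid!r} lists no "
                        "metabolite and no matching reaction row exists"
                    )
                reactions.append(
                    Reaction(id=rid, stoichiometry={met: Fraction(-1)},
                             lower_bound=lb, upper_bound=ub)
                )
            exchange_ids.add(rid)
        auto = {r.id for r in reactions if len(r.stoichiometry) == 1}
        if auto - exchange_ids:
            logger.warning(
                "single-metabolite reactions not listed in exchanges.tsv kept "
                "internal: %s", sorted(auto - exchange_ids)
            )

    model = Model(
        id=model_id or directory.name,
        metabolites=metabolites,
        reactions=reactions,
        exchange_ids=exchange_ids,
        biomass_id=biomass_id,
    )
    for warning in model.validate():
        logger.warning("%s: %s", model.id, warning)
    return model


def write_model_tsv(model: Model, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "extracellular": int(m.is_extracellular),
            }
            for m in model.metabolites
        ]
    ).to_csv(directory / "metabolites.tsv", sep="\t", index=False)

    has_gpr = any(r.gpr is not None for r in model.reactions)
    rows = []
    for rxn in model.reactions:
        if rxn.id in model.exchange_ids:
            continue
        row = {
            "id": rxn.id,
            "name": rxn.name,
            "equation": format_equation(rxn.stoichiometry, rxn.reversible),
            "lb": rxn.lower_bound,
            "ub": rxn.upper_bound,
            "subsystem": rxn.subsystem,
            "is_biomass": int(rxn.id == model.biomass_id),
        }
        if has_gpr:
            row["gpr"] = rxn.gpr.to_string() if rxn.gpr else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "reactions.tsv", sep="\t", index=False)

    ex_rows = []
    for rid in model.reaction_ids:
        if rid not in model.exchange_ids:
            continue
        rxn = model.reaction(rid)
        met = next(iter(rxn.stoichiometry))
        ex_rows.append(
            {"id": rid, "metabolite": met, "lb": rxn.lower_bound,
             "ub": rxn.upper_bound}
        )
    pd.DataFrame(ex_rows, columns=["id", "metabolite", "lb", "ub"]).to_csv(
        directory / "exchanges.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _clamp_bounds(rid: str, lb: float, ub: float, big: float) -> tuple[float, float]:
    clamped_lb = max(lb, -big)
    clamped_ub = min(ub, big)
    if (clamped_lb, clamped_ub) != (lb, ub):
        logger.info("reaction %s: bounds clamped to [%s, %s]", rid, clamped_lb,
                    clamped_ub)
    if clamped_lb > clamped_ub:
        raise ModelValidationError(f"reaction {rid!r}: lb {lb} > ub {ub}")
    return clamped_lb, clamped_ub


def _gpr_from_association(assoc) -> GPRExpression | None:
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = assoc.getGeneProduct()
        return GPRExpression(op="gene", gene=gp)
    children = tuple(
        _gpr_from_association(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    op = "and" if assoc.isFbcAnd() else "or"
    return GPRExpression(op=op, children=children)


def read_model_sbml(path: str | Path, config: RunConfig = DEFAULT_CONFIG) -> Model:
    """Read an SBML file (Level 2, or Level 3 with the FBC package).

    Species flagged ``boundaryCondition=true`` are treated as outside the
    system and dropped from the row set.  Reactions left touching exactly
    one species are classified as exchange fluxes.  Missing bounds default
    to ``[-M, M]`` for reversible and ``[0, M]`` for irreversible
    reactions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromString(path.read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML parse error: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: document contains no model")
    fbc = sbml_model.getPlugin("fbc")
    big = config.big_bound

    gene_labels: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    boundary: set[str] = set()
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        comp = sp.getCompartment() or "c"
        metabolites.append(
            Metabolite(id=sp.getId(), name=sp.getName() or "", compartment=comp,
                       is_extracellular=comp.lower().startswith("e"))
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, Fraction] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            if ref.getSpecies() in boundary:
                continue
            coeff = ref.getStoichiometry()
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) - \
                Fraction(str(coeff if coeff == coeff else 1.0))
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            if ref.getSpecies() in boundary:
                continue
            coeff = ref.getStoichiometry()
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + \
                Fraction(str(coeff if coeff == coeff else 1.0))
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            logger.warning("reaction %s touches only boundary species; skipped",
                           rxn.getId())
            continue

        lb = ub = None
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and rfbc.getLowerFluxBound():
            lb = params.get(rfbc.getLowerFluxBound())
        if rfbc is not None and rfbc.getUpperFluxBound():
            ub = params.get(rfbc.getUpperFluxBound())
        kl = rxn.getKineticLaw()
        if lb is None and kl is not None and kl.getParameter("LOWER_BOUND"):
            lb = kl.getParameter("LOWER_BOUND").getValue()
        if ub is None and kl is not None and kl.getParameter("UPPER_BOUND"):
            ub = kl.getParameter("UPPER_BOUND").getValue()
        if lb is None:
            lb = -big if rxn.getReversible() else 0.0
            logger.info("reaction %s: missing lower bound, defaulted to %s",
                        rxn.getId(), lb)
        if ub is None:
            ub = big
            logger.info("reaction %s: missing upper bound, defaulted to %s",
                        rxn.getId(), ub)
        lb, ub = _clamp_bounds(rxn.getId(), float(lb), float(ub), big)

        gpr = None
        if rfbc is not None:
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _gpr_from_association(gpa.getAssociation())
                if gpr is not None and gene_labels:
                    gpr = _relabel(gpr, gene_labels)
        reactions.append(
            Reaction(id=rxn.getId(), stoichiometry=stoich, lower_bound=lb,
                     upper_bound=ub, name=rxn.getName() or "", gpr=gpr)
        )

    biomass_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = obj.getFluxObjective(0).getReaction()

    model = Model(id=sbml_model.getId() or path.stem, metabolites=metabolites,
                  reactions=reactions, exchange_ids=None, biomass_id=biomass_id)
    for warning in model.validate():
        logger.warning("%s: %s", model.id, warning)
    return model


def _relabel(gpr: GPRExpression, labels: dict[str, str]) -> GPRExpression:
    if gpr.op == "gene":
        return GPRExpression(op="gene", gene=labels.get(gpr.gene, gpr.gene))
    return GPRExpression(op=gpr.op,
                         children=tuple(_relabel(c, labels) for c in gpr.children))


def _sanitize(sid: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out


def _gpr_to_association(gpr: GPRExpression, gpa, id_map: dict[str, str]):
    if gpr.op == "gene":
        ref = gpa.createGeneProductRef() if hasattr(gpa, "createGeneProductRef") \
            else gpa.createGeneProductRef()
        ref.setGeneProduct(id_map[gpr.gene])
        return
    node = gpa.createAnd() if gpr.op == "and" else gpa.createOr()
    for child in gpr.children:
        _gpr_child(node, child, id_map)


def _gpr_child(node, gpr: GPRExpression, id_map: dict[str, str]) -> None:
    if gpr.op == "gene":
        ref = node.createGeneProductRef()
        ref.setGeneProduct(id_map[gpr.gene])
        return
    sub = node.createAnd() if gpr.op == "and" else node.createOr()
    for child in gpr.children:
        _gpr_child(sub, child, id_map)


def write_model_sbml(model: Model, path: str | Path) -> None:
    """Write SBML Level 3 Version 1 with the FBC v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sanitize(model.id))
    mfbc = sbml_model.getPlugin("fbc")
    mfbc.setStrict(False)

    compartments = {m.compartment for m in model.metabolites} or {"c"}
    for comp in sorted(compartments):
        c = sbml_model.createCompartment()
        c.setId(_sanitize(comp))
        c.setConstant(True)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sanitize(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    genes = sorted(model.genes())
    gene_map = {g: "G_" + _sanitize(g) for g in genes}
    for gene in genes:
        gp = mfbc.createGeneProduct()
        gp.setId(gene_map[gene])
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        srx = sbml_model.createReaction()
        srx.setId(_sanitize(rxn.id))
        srx.setName(rxn.name or rxn.id)
        srx.setReversible(rxn.lower_bound < 0)
        srx.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = srx.createReactant()
                ref.setStoichiometry(float(-coeff))
            else:
                ref = srx.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(_sanitize(met_id))
            ref.setConstant(True)
        rfbc = srx.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rfbc.createGeneProductAssociation()
            _gpr_to_association(rxn.gpr, gpa, gene_map)

    if model.biomass_id is not None:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        flux_obj = obj.createFluxObjective()
        flux_obj.setReaction(_sanitize(model.biomass_id))
        flux_obj.setCoefficient(1.0)
        mfbc.setActiveObjectiveId("obj")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# dispatch + media
# ---------------------------------------------------------------------------

def read_model(path: str | Path, config: RunConfig = DEFAULT_CONFIG) -> Model:
    """Read a model from an SBML file or a TSV-bundle directory."""
    path = Path(path)
    if path.is_dir():
        return read_model_tsv(path, config=config)
    return read_model_sbml(path, config=config)


def write_model(model: Model, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        write_model_tsv(model, path)
    elif format == "sbml":
        write_model_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r} (expected tsv|sbml)")


def read_medium(path: str | Path) -> MediumSpec:
    """Read a medium from JSON (``{"EX_x": [lb, ub], ...}``) or TSV with
    columns id, lb, ub."""
    path = Path(path)
    text = path.read_text()
    spec = MediumSpec()
    if text.lstrip().startswith("{"):
        for key, value in json.loads(text).items():
            spec[key] = tuple(value)
        return spec
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for _, row in df.iterrows():
        spec[row["id"]] = (float(row["lb"]), float(row["ub"]))
    return spec
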