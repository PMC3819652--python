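"""In-memory representation of a constraint-based metabolic model.

A model is a stoichiometric matrix ``N`` (metabolites x reactions) with
per-reaction flux bounds, a partition of the reaction set into internal
reactions and exchange fluxes, an optional biomass reaction and optional
GPR rules.  Steady-state flux distributions satisfy ``N @ v == 0`` with
``lb_j <= v_j <= ub_j``; this polyhedron is the flux space the analyses in
the rest of the package interrogate.

Sign conventions
----------------
Stoichiometric coefficients are negative for reactants and positive for
products.  Exchange fluxes are written as single-metabolite reactions
``A -> (outside)`` with coefficient -1, so positive exchange flux means
the system secretes the metabolite and negative flux means uptake.

Coefficients are stored as exact :class:`fractions.Fraction` values so
structural analyses (nullspaces, conserved moieties, brute-force oracles)
can run in exact arithmetic; LP solving converts to floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy import sparse

from .config import DEFAULT_CONFIG, RunConfig
from .gpr import GPRExpression


class ModelValidationError(ValueError):
    """Raised when a model (or an edit to one) violates an invariant."""


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        if not math.isfinite(value):
            raise ModelValidationError("stoichiometric coefficients must be finite")
        # str() round-trips the decimal literal, keeping 0.1 as 1/10.
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class Metabolite:
    """One row of the stoichiometric matrix."""

    id: str
    name: str = ""
    compartment: str = "c"
    is_extracellular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """One column of the stoichiometric matrix with its flux bounds.

    ``stoichiometry`` maps metabolite id to a signed rational coefficient
    (negative = consumed, positive = produced).
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    lower_bound: float
    upper_bound: float
    name: str = ""
    gpr: GPRExpression | None = None
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        stoich = {m: _as_fraction(c) for m, c in dict(self.stoichiometry).items()}
        if not stoich:
            raise ModelValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if any(c == 0 for c in stoich.values()):
            raise ModelValidationError(
                f"reaction {self.id!r} has a zero stoichiometric coefficient"
            )
        object.__setattr__(self, "stoichiometry", stoich)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def reactants(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


class MediumSpec(dict):
    """Map exchange-reaction id -> (lower_bound, upper_bound).

    A metabolite available for uptake needs a negative lower bound on its
    exchange flux; a closed exchange gets ``(0, 0)``.
    """

    def __setitem__(self, key: str, value) -> None:
        lb, ub = value
        if lb > ub:
            raise ModelValidationError(f"medium entry {key!r}: lb {lb} > ub {ub}")
        super().__setitem__(key, (float(lb), float(ub)))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[float, float]]) -> "MediumSpec":
        spec = cls()
        for key, value in mapping.items():
            spec[key] = value
        return spec


class Model:
    """Ordered collection of metabolites and reactions.

    The metabolite order defines the row index set I (size m), the
    reaction order the column index set J (size n).  J is partitioned into
    internal reactions and exchange fluxes; exchange fluxes touch exactly
    one metabolite.
    """

    def __init__(
        self,
        id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        exchange_ids: Iterable[str] | None = None,
        biomass_id: str | None = None,
    ) -> None:
        self.id = id
        self._metabolites: dict[str, Metabolite] = {}
        self._reactions: dict[str, Reaction] = {}
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        if exchange_ids is None:
            self.exchange_ids = self._autodetect_exchanges()
        else:
            self.exchange_ids = set(exchange_ids)
        self.biomass_id = biomass_id
        self.validate()

    # -- construction ---------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self._metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, exchange: bool | None = None) -> None:
        if rxn.id in self._reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                )
        self._reactions[rxn.id] = rxn
        if hasattr(self, "exchange_ids"):
            if exchange is None:
                exchange = len(rxn.stoichiometry) == 1
            if exchange:
                self.exchange_ids.add(rxn.id)

    def remove_reaction(self, rxn_id: str) -> None:
        if rxn_id not in self._reactions:
            raise KeyError(rxn_id)
        del self._reactions[rxn_id]
        self.exchange_ids.discard(rxn_id)
        if self.biomass_id == rxn_id:
            self.biomass_id = None

    def set_reaction(self, rxn: Reaction) -> None:
        """Replace an existing reaction in place (order preserved)."""
        if rxn.id not in self._reactions:
            raise KeyError(rxn.id)
        self._reactions[rxn.id] = rxn

    def _autodetect_exchanges(self) -> set[str]:
        return {r.id for r in self._reactions.values() if len(r.stoichiometry) == 1}

    # -- access ---------------------------------------------------------

    @property
    def metabolites(self) -> list[Metabolite]:
        return list(self._metabolites.values())

    @property
    def reactions(self) -> list[Reaction]:
        return list(self._reactions.values())

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self._metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self._reactions)

    @property
    def internal_ids(self) -> list[str]:
        return [rid for rid in self._reactions if rid not in self.exchange_ids]

    @property
    def n_metabolites(self) -> int:
        return len(self._metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self._reactions)

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._metabolites[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._reactions[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._metabolites

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._reactions

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self._reactions

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self._reactions.values())

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self._reactions.values():
            if rxn.gpr is not None:
                out |= rxn.gpr.genes()
        return frozenset(out)

    # -- matrices -------------------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csc_matrix:
        """Sparse float N (m x n), rows in metabolite order, columns in
        reaction order."""
        row_index = {mid: i for i, mid in enumerate(self._metabolites)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self._reactions.values()):
            for met_id, coeff in rxn.stoichiometry.items():
                rows.append(row_index[met_id])
                cols.append(j)
                data.append(float(coeff))
        return sparse.csc_matrix(
            (data, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
        )

    def rational_columns(
        self, reaction_ids: Iterable[str] | None = None
    ) -> tuple[list[str], list[str], list[list[Fraction]]]:
        """Exact column-restricted stoichiometric matrix.

        Returns (row ids, column ids, dense matrix of Fractions) with rows
        restricted to metabolites touched by the selected reactions.
        """
        col_ids = list(reaction_ids) if reaction_ids is not None else self.reaction_ids
        touched: list[str] = []
        seen: set[str] = set()
        for rid in col_ids:
            for met_id in self._reactions[rid].stoichiometry:
                if met_id not in seen:
                    seen.add(met_id)
                    touched.append(met_id)
        row_index = {mid: i for i, mid in enumerate(touched)}
        matrix = [[Fraction(0)] * len(col_ids) for _ in touched]
        for j, rid in enumerate(col_ids):
            for met_id, coeff in self._reactions[rid].stoichiometry.items():
                matrix[row_index[met_id]][j] = coeff
        return touched, col_ids, matrix

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lbs = np.array([r.lower_bound for r in self._reactions.values()])
        ubs = np.array([r.upper_bound for r in self._reactions.values()])
        return lbs, ubs

    # -- invariants -----------------------------------------------------

    def validate(self) -> list[str]:
        """Check model invariants; returns a list of warnings.

        Raises :class:`ModelValidationError` on hard violations.
        """
        warnings: list[str] = []
        unknown = self.exchange_ids - set(self._reactions)
        if unknown:
            raise ModelValidationError(
                f"exchange ids not in reaction set: {sorted(unknown)}"
            )
        for rid in self.exchange_ids:
            if len(self._reactions[rid].stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rid!r} must touch exactly one metabolite"
                )
        if self.biomass_id is not None:
            if self.biomass_id not in self._reactions:
                raise ModelValidationError(
                    f"biomass id {self.biomass_id!r} not in reaction set"
                )
            if self.biomass_id in self.exchange_ids:
                raise ModelValidationError("biomass reaction must be internal")
        used = {m for r in self._reactions.values() for m in r.stoichiometry}
        for met_id in self._metabolites:
            if met_id not in used:
                warnings.append(f"orphan metabolite {met_id!r} occurs in no reaction")
        return warnings

    # -- copies and edits -----------------------------------------------

    def copy(self) -> "Model":
        clone = Model.__new__(Model)
        clone.id = self.id
        clone._metabolites = dict(self._metabolites)
        clone._reactions = dict(self._reactions)
        clone.exchange_ids = set(self.exchange_ids)
        clone.biomass_id = self.biomass_id
        return clone

    def state_fingerprint(self) -> tuple:
        """Hashable snapshot used to assert non-mutation after scans."""
        return (
            self.id,
            tuple(self._metabolites.items()),
            tuple(
                (rid, tuple(sorted(r.stoichiometry.items())), r.lower_bound,
                 r.upper_bound, r.name, r.subsystem,
                 r.gpr.to_string() if r.gpr else "")
                for rid, r in self._reactions.items()
            ),
            frozenset(self.exchange_ids),
            self.biomass_id,
        )

    def equal_structure(self, other: "Model") -> bool:
        """Equality up to element order: same stoichiometry, bounds and
        reaction partition."""
        if set(self._metabolites) != set(other._metabolites):
            return False
        if set(self._reactions) != set(other._reactions):
            return False
        if self.exchange_ids != other.exchange_ids:
            return False
        if self.biomass_id != other.biomass_id:
            return False
        for rid, rxn in self._reactions.items():
            oth = other._reactions[rid]
            if dict(rxn.stoichiometry) != dict(oth.stoichiometry):
                return False
            if (rxn.lower_bound, rxn.upper_bound) != (oth.lower_bound, oth.upper_bound):
                return False
        return True


def apply_medium(
    model: Model,
    medium: MediumSpec | Mapping[str, tuple[float, float]] | None,
    default_policy: str = "open",
    config: RunConfig = DEFAULT_CONFIG,
) -> Model:
    """Return a copy of *model* with exchange bounds set by *medium*.

    Exchanges listed in *medium* get the given bounds.  Unlisted exchanges
    get ``[-M, M]`` under the ``"open"`` policy (every metabolite freely
    available and secretable) or ``[0, M]`` under ``"closed"`` (secretion
    only).  Internal reaction bounds are untouched.
    """
    if default_policy not in ("open", "closed"):
        raise ValueError(f"unknown default_policy {default_policy!r}")
    medium = MediumSpec.from_mapping(medium or {})
    bad = set(medium) - set(model.exchange_ids)
    if bad:
        raise ModelValidationError(
            f"medium names non-exchange reaction(s): {sorted(bad)}"
        )
    big = config.big_bound
    out = model.copy()
    for rid in out.exchange_ids:
        if rid in medium:
            lb, ub = medium[rid]
        elif default_policy == "open":
            lb, ub = -big, big
        else:
            lb, ub = 0.0, big
        out.set_reaction(out.reaction(rid).with_bounds(lb, ub))
    return out
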