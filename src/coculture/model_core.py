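"""Metabolic model data structures, SBML I/O, and diet constraints.

A :class:`MetabolicModel` is the unit of simulation: a stoichiometric matrix
with flux bounds, subsystem labels and a biomass objective. Diets are tables
of exchange-reaction bounds; applying a diet closes uptake for every
exchanged metabolite the diet does not mention, which is how an in-silico
medium is imposed on a genome-scale reconstruction.

Sign convention (COBRA/AGORA): an exchange reaction is written
``1 metabolite <-> (nothing)`` with a negative stoichiometric coefficient, so
negative flux is uptake and positive flux is secretion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: Default flux bound magnitude (mmol/gDCW/h).
DEFAULT_BOUND = 1000.0

#: Compartments considered outside the cell ("e" extracellular, "u" lumen).
EXTERNAL_COMPARTMENTS = frozenset({"e", "u"})


class ModelError(ValueError):
    """A structurally invalid metabolic model."""


class SBMLFormatError(ValueError):
    """An unparsable or malformed SBML document."""


@dataclass(frozen=True)
class Metabolite:
    """A metabolite species tagged with its compartment ('c', 'e', 'u', ...)."""

    id: str
    compartment: str

    @property
    def base_id(self) -> str:
        """Id with the trailing compartment suffix stripped (``glc_D_e`` -> ``glc_D``)."""
        suffix = "_" + self.compartment
        if self.compartment and self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        return self.id


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol/gDCW/h.

    Negative coefficients are consumed, positive produced. ``reversible`` and
    ``is_exchange`` are derived properties so they can never disagree with the
    bounds or the stoichiometry.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Single-metabolite boundary reaction (robust to id naming conventions)."""
        return len(self.stoichiometry) == 1

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} > "
                f"upper bound {self.upper_bound}"
            )
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ModelError(
                    f"reaction {self.id!r}: bad coefficient {coef} for {met!r}"
                )


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    ``objective`` maps reaction ids to objective coefficients. Single-organism
    models carry exactly one positive entry (the biomass reaction); merged
    community models carry one per member.
    """

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective: dict[str, float]

    def __post_init__(self) -> None:
        self._met_index: dict[str, Metabolite] = {m.id: m for m in self.metabolites}
        self._rxn_index: dict[str, Reaction] = {r.id: r for r in self.reactions}

    # -- lookups ----------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def objective_reaction(self) -> str:
        """The single biomass reaction id (errors on community objectives)."""
        positive = [r for r, c in self.objective.items() if c > 0]
        if len(positive) != 1:
            raise ModelError(
                f"model {self.id!r} has {len(positive)} positive objective "
                "coefficients; expected exactly one"
            )
        return positive[0]

    def is_exchange_reaction(self, rxn: Reaction) -> bool:
        """Boundary test: single-metabolite reaction on an external-compartment
        species. The compartment requirement keeps internal demand/sink
        reactions (e.g. a one-metabolite biomass drain) out of the boundary."""
        if not rxn.is_exchange:
            return False
        (met_id,) = rxn.stoichiometry
        return self.metabolite(met_id).compartment in EXTERNAL_COMPARTMENTS

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange_reaction(r)]

    def exchange_metabolite(self, rxn: Reaction) -> Metabolite:
        (met_id,) = rxn.stoichiometry
        return self.metabolite(met_id)

    # -- structure --------------------------------------------------------

    def validate(self, require_single_objective: bool = True) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ModelError(f"model {self.id!r}: duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelError(f"model {self.id!r}: duplicate reaction ids")
        for rxn in self.reactions:
            rxn.validate()
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelError(
                        f"model {self.id!r}: reaction {rxn.id!r} references "
                        f"undeclared metabolite {met_id!r}"
                    )
        if not self.objective:
            raise ModelError(f"model {self.id!r}: no objective reaction")
        for rxn_id in self.objective:
            if rxn_id not in self._rxn_index:
                raise ModelError(
                    f"model {self.id!r}: objective reaction {rxn_id!r} not found"
                )
        if require_single_objective:
            self.objective_reaction  # raises unless exactly one

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            objective=dict(self.objective),
        )


@dataclass
class DietSpec:
    """Exchange-bound overrides representing a diet/medium.

    Entries are keyed by the exchanged metabolite's compartment-stripped base
    id, so one diet applies unchanged to single models (``glc_D_e``) and to
    community lumen exchanges (``glc_D_u``). Uptake-permitting entries carry a
    negative lower bound.
    """

    entries: dict[str, tuple[float, float]]
    name: str = "diet"

    def validate(self) -> None:
        for met, (lb, ub) in self.entries.items():
            if lb > ub:
                raise ModelError(f"diet {self.name!r}: entry {met!r} has lb > ub")


def apply_diet(model: MetabolicModel, diet: DietSpec) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set by ``diet``.

    Exchange reactions whose metabolite appears in the diet get the diet's
    bounds; all other exchange reactions are closed for uptake (lb = 0) with
    secretion left open. Non-exchange reactions are untouched, so the
    operation is idempotent. Diet entries with no matching exchange reaction
    are skipped with a warning (AGORA diets cover metabolites absent from
    many models).
    """
    diet.validate()
    out = model.copy()
    matched: set[str] = set()
    for rxn in out.reactions:
        if not out.is_exchange_reaction(rxn):
            continue
        base = out.exchange_metabolite(rxn).base_id
        if base in diet.entries:
            rxn.lower_bound, rxn.upper_bound = diet.entries[base]
            matched.add(base)
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for missing in sorted(set(diet.entries) - matched):
        logger.warning(
            "diet %r entry %r has no matching exchange reaction in model %r; skipped",
            diet.name, missing, model.id,
        )
    return out


# ---------------------------------------------------------------------------
# Diet table I/O: tab-separated `metabolite_id  lower_bound  upper_bound`.
# ---------------------------------------------------------------------------

def read_diet_table(path, name: str | None = None) -> DietSpec:
    """Read a three-column TSV diet table (header row required)."""
    entries: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise SBMLFormatError(f"diet table {path}: empty file")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise SBMLFormatError(
                    f"diet table {path}:{line_no}: expected 3 columns, got {len(parts)}"
                )
            entries[parts[0]] = (float(parts[1]), float(parts[2]))
    import os

    diet = DietSpec(entries=entries, name=name or os.path.splitext(os.path.basename(path))[0])
    diet.validate()
    return diet


def write_diet_table(diet: DietSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite_id\tlower_bound\tupper_bound\n")
        for met in sorted(diet.entries):
            lb, ub = diet.entries[met]
            fh.write(f"{met}\t{lb:.10g}\t{ub:.10g}\n")


# ---------------------------------------------------------------------------
# SBML I/O via cobrapy (Level 3 + FBC). Subsystems travel in reaction notes,
# which cobra restores to Reaction.subsystem on read.
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (used for SBML I/O and as a solver cross-check)."""
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    crxns = []
    for rxn in model.reactions:
        crxn = cobra.Reaction(rxn.id)
        crxn.lower_bound = rxn.lower_bound
        crxn.upper_bound = rxn.upper_bound
        crxn.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.subsystem:
            crxn.subsystem = rxn.subsystem
            crxn.notes["SUBSYSTEM"] = rxn.subsystem
        crxns.append(crxn)
    cmodel.add_reactions(crxns)
    cmodel.objective = cmodel.problem.Objective(
        sum(coef * cmodel.reactions.get_by_id(rid).flux_expression
            for rid, coef in model.objective.items()),
        direction="max",
    )
    return cmodel


def from_cobra(cmodel, model_id: str | None = None) -> MetabolicModel:
    """Convert a cobra.Model into the package's own structures."""
    from cobra.util.solver import linear_reaction_coefficients

    metabolites = [
        Metabolite(m.id, m.compartment or "c") for m in cmodel.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            subsystem=r.subsystem or "",
        )
        for r in cmodel.reactions
    ]
    objective = {
        r.id: float(c) for r, c in linear_reaction_coefficients(cmodel).items() if c
    }
    return MetabolicModel(
        id=model_id or cmodel.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        objective=objective,
    )


def read_sbml(path) -> MetabolicModel:
    """Read an SBML Level 2/3 model (FBC bounds honoured) into a MetabolicModel.

    Raises :class:`SBMLFormatError` for unparsable files and
    :class:`ModelError` (naming the file) when no objective reaction is found.
    """
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises CobraSBMLError subclasses
        raise SBMLFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    model = from_cobra(cmodel)
    if not model.objective:
        raise ModelError(f"SBML file {path}: no objective (biomass) reaction found")
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    import cobra.io

    model.validate(require_single_objective=False)
    cobra.io.write_sbml_model(to_cobra(model), str(path))
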