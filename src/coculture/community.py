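"""Pairwise community models with a shared lumen compartment.

Two organism models are merged through a common extracellular "lumen"
compartment (no host compartment): every organism-level exchange reaction
``met[e] <-> (nothing)`` becomes a transport ``met[e] <-> met[u]`` with open
bounds, and the lumen communicates with the environment through one community
exchange per metabolite. Diets constrain only the community boundary, so both
members compete for the same nutrient allowance. Joint growth is simulated
with parsimonious FBA maximizing the unweighted sum of the two biomass
fluxes, with each member's biomass bounded in [0, 1000].
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fba_core import (
    DEFAULT_TIME_LIMIT,
    FluxSolution,
    STATUS_OPTIMAL,
    pfba,
)
from .model_core import (
    DEFAULT_BOUND,
    DietSpec,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    apply_diet,
)

LUMEN = "u"
TAG_A = "A"
TAG_B = "B"


@dataclass
class CommunityModel:
    """Two namespaced organism sub-models joined through a shared lumen."""

    base: MetabolicModel
    model_id_of: dict[str, str]                     # tag -> original model id
    organism_of: dict[str, str]                     # reaction id -> tag or "shared"
    lumen_exchange_of: dict[tuple[str, str], str]   # (tag, base metabolite) -> rxn id
    community_exchange_of: dict[str, str]           # base metabolite -> rxn id
    biomass_A: str
    biomass_B: str

    def biomass_of(self, tag: str) -> str:
        return self.biomass_A if tag == TAG_A else self.biomass_B


@dataclass
class PairResult:
    """Outcome of one co-culture simulation.

    ``lumen_fluxes_*`` are organism->lumen transport fluxes (positive =
    secretion into the lumen); ``community_fluxes`` are lumen->environment
    exchanges (positive = net secretion). At steady state
    ``lumen_A + lumen_B - community = 0`` for every lumen metabolite.
    """

    pair: tuple[str, str]
    biomass_A: float
    biomass_B: float
    lumen_fluxes_A: dict[str, float]
    lumen_fluxes_B: dict[str, float]
    community_fluxes: dict[str, float]
    status: str
    objective_value: float = 0.0
    #: Full community flux solution (kept for network analysis).
    solution: FluxSolution | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OPTIMAL


def _namespace(model: MetabolicModel, tag: str, lumen_bases: dict[str, Metabolite]):
    """Prefix one organism's metabolites/reactions; rewrite its exchanges as
    lumen transports. Returns (metabolites, reactions, organism_of,
    lumen_exchange_of, biomass id)."""
    prefix = model.id + "__"
    mets = [Metabolite(prefix + m.id, m.compartment) for m in model.metabolites]
    reactions: list[Reaction] = []
    lumen_exchanges: dict[tuple[str, str], str] = {}
    for rxn in model.reactions:
        if model.is_exchange_reaction(rxn):
            met = model.exchange_metabolite(rxn)
            base = met.base_id
            lumen_met = lumen_bases.setdefault(base, Metabolite(f"{base}_{LUMEN}", LUMEN))
            (coef,) = rxn.stoichiometry.values()
            if coef >= 0:
                raise ModelError(
                    f"model {model.id!r}: exchange {rxn.id!r} must consume its "
                    "metabolite (negative coefficient)"
                )
            rid = prefix + rxn.id + "_lu"
            if (tag, base) in lumen_exchanges:
                raise ModelError(f"model {model.id!r}: duplicate exchange for {base!r}")
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry={prefix + met.id: coef, lumen_met.id: -coef},
                    lower_bound=-DEFAULT_BOUND,
                    upper_bound=DEFAULT_BOUND,
                    subsystem="Transport, extracellular",
                )
            )
            lumen_exchanges[(tag, base)] = rid
        else:
            reactions.append(
                Reaction(
                    id=prefix + rxn.id,
                    stoichiometry={prefix + m: c for m, c in rxn.stoichiometry.items()},
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    subsystem=rxn.subsystem,
                )
            )
    biomass = prefix + model.objective_reaction
    return mets, reactions, lumen_exchanges, biomass


def build_pair(model_a: MetabolicModel, model_b: MetabolicModel) -> CommunityModel:
    """Merge two validated models into a shared-lumen community.

    Biomass bounds are reset to [0, 1000] for both members and the combined
    objective assigns coefficient +1 to each biomass reaction. Community
    exchanges are created for the union of both members' exchanged
    metabolites with open bounds (the diet is applied later).
    """
    model_a.validate()
    model_b.validate()
    if model_a.id == model_b.id:
        raise ModelError(
            f"community members need distinct ids (both are {model_a.id!r})"
        )
    lumen_bases: dict[str, Metabolite] = {}
    mets_a, rxns_a, lumen_a, bm_a = _namespace(model_a, TAG_A, lumen_bases)
    mets_b, rxns_b, lumen_b, bm_b = _namespace(model_b, TAG_B, lumen_bases)

    community_exchanges: dict[str, str] = {}
    exchange_rxns = []
    for base in sorted(lumen_bases):
        rid = f"EX_{base}_{LUMEN}"
        exchange_rxns.append(
            Reaction(
                id=rid,
                stoichiometry={lumen_bases[base].id: -1.0},
                lower_bound=-DEFAULT_BOUND,
                upper_bound=DEFAULT_BOUND,
                subsystem="Exchange",
            )
        )
        community_exchanges[base] = rid

    metabolites = mets_a + mets_b + [lumen_bases[b] for b in sorted(lumen_bases)]
    reactions = rxns_a + rxns_b + exchange_rxns
    seen: set[str] = set()
    for rxn in reactions:
        if rxn.id in seen:
            raise ModelError(f"community id collision after namespacing: {rxn.id!r}")
        seen.add(rxn.id)

    base = MetabolicModel(
        id=f"{model_a.id}|{model_b.id}",
        metabolites=metabolites,
        reactions=reactions,
        objective={bm_a: 1.0, bm_b: 1.0},
    )
    for bm in (bm_a, bm_b):
        rxn = base.reaction(bm)
        rxn.lower_bound = 0.0
        rxn.upper_bound = DEFAULT_BOUND
    base.validate(require_single_objective=False)

    organism_of = {r.id: TAG_A for r in rxns_a}
    organism_of.update({r.id: TAG_B for r in rxns_b})
    organism_of.update({r.id: "shared" for r in exchange_rxns})
    return CommunityModel(
        base=base,
        model_id_of={TAG_A: model_a.id, TAG_B: model_b.id},
        organism_of=organism_of,
        lumen_exchange_of={**lumen_a, **lumen_b},
        community_exchange_of=community_exchanges,
        biomass_A=bm_a,
        biomass_B=bm_b,
    )


def simulate_pair(
    community: CommunityModel,
    diet: DietSpec,
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> PairResult:
    """Apply the diet at the community boundary and run joint pFBA.

    Never raises on infeasible or timed-out solves: the status is recorded
    and the flux maps left empty, so a large screen can simply carry on.
    """
    constrained = apply_diet(community.base, diet)
    solution = pfba(constrained, time_limit=time_limit)
    pair = (community.model_id_of[TAG_A], community.model_id_of[TAG_B])
    if solution.status != STATUS_OPTIMAL:
        return PairResult(
            pair=pair, biomass_A=0.0, biomass_B=0.0,
            lumen_fluxes_A={}, lumen_fluxes_B={}, community_fluxes={},
            status=solution.status,
        )
    lumen_a = {
        base: solution.fluxes[rid]
        for (tag, base), rid in community.lumen_exchange_of.items()
        if tag == TAG_A
    }
    lumen_b = {
        base: solution.fluxes[rid]
        for (tag, base), rid in community.lumen_exchange_of.items()
        if tag == TAG_B
    }
    comm = {
        base: solution.fluxes[rid]
        for base, rid in community.community_exchange_of.items()
    }
    return PairResult(
        pair=pair,
        biomass_A=max(solution.fluxes[community.biomass_A], 0.0),
        biomass_B=max(solution.fluxes[community.biomass_B], 0.0),
        lumen_fluxes_A=lumen_a,
        lumen_fluxes_B=lumen_b,
        community_fluxes=comm,
        status=STATUS_OPTIMAL,
        objective_value=solution.objective_value,
        solution=solution,
    )


def lumen_residuals(result: PairResult) -> dict[str, float]:
    """Lumen steady-state residual per metabolite (zero at optimality)."""
    residuals = {}
    for base in result.community_fluxes:
        residuals[base] = (
            result.lumen_fluxes_A.get(base, 0.0)
            + result.lumen_fluxes_B.get(base, 0.0)
            - result.community_fluxes[base]
        )
    return residuals


def organism_solution(
    community: CommunityModel, solution_fluxes: dict[str, float], tag: str
) -> dict[str, float]:
    """Project a community flux vector onto one member's original reaction ids.

    Lumen transports map back onto the member's exchange-reaction ids, so the
    projected vector is comparable with a monoculture solution.
    """
    prefix = community.model_id_of[tag] + "__"
    out: dict[str, float] = {}
    for rid, flux in solution_fluxes.items():
        if community.organism_of.get(rid) != tag:
            continue
        original = rid[len(prefix):]
        if original.endswith("_lu"):
            original = original[: -len("_lu")]
        out[original] = flux
    return out
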