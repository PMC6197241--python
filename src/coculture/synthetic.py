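"""Designed toy metabolic models realizing known ecological interactions.

Each scenario builds two small (<= 30 reactions) stoichiometric models plus a
diet such that monoculture and co-culture parsimonious FBA provably realize a
designed outcome: the six ecological interaction types, the transfer
categories, emergent metabolites and greater-than-additive production. The
models follow AGORA conventions (compartment-suffixed metabolite ids,
``EX_*`` single-metabolite exchanges, a biomass objective), so the same
parsers and solvers serve synthetic and real inputs.

Where a joint optimum would leave the A/B biomass split degenerate, the
scenario is engineered so the classification is split-invariant (see the
competitive scenario's maintenance drain) or so pFBA's total-flux
minimization pins the split uniquely (the mutualistic cross-feed). Yields
are chosen so every classification clears its decision band by at least 2x.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model_core import DEFAULT_BOUND, DietSpec, MetabolicModel, Metabolite, Reaction
from . import fba_core

SCENARIO_NAMES = (
    "mutualistic_crossfeed",
    "commensal_endproduct",
    "competitive_shared_substrate",
    "neutral_disjoint",
    "parasitic_theft",
    "emergent_chain",
    "overproducer_pair",
    "inert_partner",
)

_COMPARTMENTS = {"c", "e"}


def _build_model(mid: str, objective: str, reactions) -> MetabolicModel:
    """Assemble a model from ``(rid, stoichiometry, lb, ub[, subsystem])``
    tuples; metabolites are inferred from stoichiometry keys, with the
    compartment read from the id suffix."""
    met_ids: dict[str, None] = {}
    rxns = []
    for spec in reactions:
        rid, stoich, lb, ub = spec[:4]
        subsystem = spec[4] if len(spec) > 4 else ""
        for met in stoich:
            met_ids.setdefault(met)
        rxns.append(Reaction(id=rid, stoichiometry=dict(stoich),
                             lower_bound=lb, upper_bound=ub, subsystem=subsystem))
    mets = []
    for met in met_ids:
        comp = met.rsplit("_", 1)[-1]
        mets.append(Metabolite(met, comp if comp in _COMPARTMENTS else "c"))
    model = MetabolicModel(id=mid, metabolites=mets, reactions=rxns,
                           objective={objective: 1.0})
    model.validate()
    return model


def _exchange(base: str):
    """EX + reversible extracellular transport for one metabolite."""
    return [
        (f"EX_{base}_e", {f"{base}_e": -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND, "Exchange"),
        (f"{base.upper()}t", {f"{base}_e": -1.0, f"{base}_c": 1.0},
         -DEFAULT_BOUND, DEFAULT_BOUND, "Transport, extracellular"),
    ]


@dataclass
class ScenarioExpectation:
    """Machine-checkable designed outcomes of one scenario."""

    interaction: str | None
    mono_viable: tuple[bool, bool]
    mono_biomass: tuple[float, float]
    #: Exact co-culture biomass split when the optimum is unique, else None.
    co_biomass: tuple[float, float] | None
    #: Sum of co-culture biomasses (unique even when the split is not).
    co_biomass_sum: float
    #: metabolite base id -> (donor tag, transfer category)
    transfers: dict[str, tuple[str, str]] = field(default_factory=dict)
    emergent: frozenset[str] = frozenset()
    #: target metabolite -> expected overproduction flag
    overproduced: dict[str, bool] = field(default_factory=dict)


@dataclass
class Scenario:
    name: str
    model_a: MetabolicModel
    model_b: MetabolicModel
    diet: DietSpec
    expected: ScenarioExpectation

    def as_tuple(self):
        return self.model_a, self.model_b, self.diet, self.expected


def _mutualistic_crossfeed() -> Scenario:
    # Each member's growth is limited by an amino-acid-like metabolite only
    # the partner produces (growth-coupled byproduct); the diet supplies a
    # trickle of both so the monocultures are viable at biomass 1 while the
    # co-culture shares 10 glc and reaches 5 + 5.
    a = _build_model("mutA", "biomass_mutA",
        _exchange("glc_D") + _exchange("aa_a") + _exchange("aa_b") + [
            ("biomass_mutA", {"glc_D_c": -1.0, "aa_b_c": -1.0, "aa_a_c": 1.0}, 0.0, DEFAULT_BOUND),
        ])
    b = _build_model("mutB", "biomass_mutB",
        _exchange("glc_D") + _exchange("aa_a") + _exchange("aa_b") + [
            ("biomass_mutB", {"glc_D_c": -1.0, "aa_a_c": -1.0, "aa_b_c": 1.0}, 0.0, DEFAULT_BOUND),
        ])
    diet = DietSpec({"glc_D": (-10.0, DEFAULT_BOUND),
                     "aa_a": (-1.0, DEFAULT_BOUND),
                     "aa_b": (-1.0, DEFAULT_BOUND)}, name="mutualistic_crossfeed")
    expected = ScenarioExpectation(
        interaction="mutualistic",
        mono_viable=(True, True),
        mono_biomass=(1.0, 1.0),
        co_biomass=(5.0, 5.0),
        co_biomass_sum=10.0,
        transfers={"aa_a": ("A", "end_product_removal_and_cross_fed"),
                   "aa_b": ("B", "end_product_removal_and_cross_fed")},
    )
    return Scenario("mutualistic_crossfeed", a, b, diet, expected)


def _commensal_endproduct() -> Scenario:
    # A ferments glucose to acetate (growth-coupled); B grows slowly on
    # ribose in monoculture and harvests A's acetate in co-culture. The diet
    # has no acetate, so B's monoculture never takes it up: the transfer is a
    # pure end-product removal.
    a = _build_model("comA", "biomass_comA",
        _exchange("glc_D") + _exchange("ac") + [
            ("biomass_comA", {"glc_D_c": -1.0, "ac_c": 2.0}, 0.0, DEFAULT_BOUND),
        ])
    b = _build_model("comB", "biomass_comB",
        _exchange("rib_D") + _exchange("ac") + [
            ("PRE_AC", {"ac_c": -1.0, "pre_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("PRE_RIB", {"rib_D_c": -1.0, "pre_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("biomass_comB", {"pre_c": -1.0}, 0.0, DEFAULT_BOUND),
        ])
    diet = DietSpec({"glc_D": (-10.0, DEFAULT_BOUND),
                     "rib_D": (-1.0, DEFAULT_BOUND)}, name="commensal_endproduct")
    expected = ScenarioExpectation(
        interaction="commensal",
        mono_viable=(True, True),
        mono_biomass=(10.0, 1.0),
        co_biomass=(10.0, 21.0),
        co_biomass_sum=31.0,
        transfers={"ac": ("A", "end_product_removal")},
    )
    return Scenario("commensal_endproduct", a, b, diet, expected)


def _competitive_shared_substrate() -> Scenario:
    # Two near-identical glucose consumers, each paying a flux-forced
    # maintenance drain of 2 glc. Alone: 10 - 2 = 8. Together the drain is
    # paid twice, so the joint total is 6 and EVERY optimal split leaves both
    # members at most 6 <= 0.75 * 8 — the competitive call is split-invariant
    # and clears the -10% band by more than 2x.
    def member(mid: str) -> MetabolicModel:
        return _build_model(mid, f"biomass_{mid}",
            _exchange("glc_D") + _exchange("co2") + [
                ("MAINT", {"glc_D_c": -1.0, "co2_c": 1.0}, 2.0, 2.0),
                (f"biomass_{mid}", {"glc_D_c": -1.0}, 0.0, DEFAULT_BOUND),
            ])
    diet = DietSpec({"glc_D": (-10.0, DEFAULT_BOUND)},
                    name="competitive_shared_substrate")
    expected = ScenarioExpectation(
        interaction="competitive",
        mono_viable=(True, True),
        mono_biomass=(8.0, 8.0),
        co_biomass=None,
        co_biomass_sum=6.0,
        overproduced={"co2": False},
    )
    return Scenario("competitive_shared_substrate", member("cmpA"), member("cmpB"),
                    diet, expected)


def _neutral_disjoint() -> Scenario:
    a = _build_model("neuA", "biomass_neuA",
        _exchange("glc_D") + [("biomass_neuA", {"glc_D_c": -1.0}, 0.0, DEFAULT_BOUND)])
    b = _build_model("neuB", "biomass_neuB",
        _exchange("xyl_D") + [("biomass_neuB", {"xyl_D_c": -1.0}, 0.0, DEFAULT_BOUND)])
    diet = DietSpec({"glc_D": (-5.0, DEFAULT_BOUND),
                     "xyl_D": (-5.0, DEFAULT_BOUND)}, name="neutral_disjoint")
    expected = ScenarioExpectation(
        interaction="neutral",
        mono_viable=(True, True),
        mono_biomass=(5.0, 5.0),
        co_biomass=(5.0, 5.0),
        co_biomass_sum=10.0,
    )
    return Scenario("neutral_disjoint", a, b, diet, expected)


def _parasitic_theft() -> Scenario:
    # A makes pyruvate from glucose and grows on it (plus a small private
    # malate pathway); B converts pyruvate to biomass twice as efficiently.
    # The joint optimum diverts ALL of A's pyruvate to B: A crashes to its
    # private pathway (still viable), B booms.
    a = _build_model("parA", "biomass_parA",
        _exchange("glc_D") + _exchange("mal_L") + _exchange("pyr") + [
            ("PYRSYN", {"glc_D_c": -1.0, "pyr_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("PRE_PYR", {"pyr_c": -1.0, "pre_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("PRE_MAL", {"mal_L_c": -1.0, "pre_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("biomass_parA", {"pre_c": -1.0}, 0.0, DEFAULT_BOUND),
        ])
    b = _build_model("parB", "biomass_parB",
        _exchange("pyr") + [
            ("biomass_parB", {"pyr_c": -0.5}, 0.0, DEFAULT_BOUND),
        ])
    diet = DietSpec({"glc_D": (-10.0, DEFAULT_BOUND),
                     "mal_L": (-2.0, DEFAULT_BOUND),
                     "pyr": (-1.0, DEFAULT_BOUND)}, name="parasitic_theft")
    expected = ScenarioExpectation(
        interaction="parasitic",
        mono_viable=(True, True),
        mono_biomass=(13.0, 2.0),
        co_biomass=(2.0, 22.0),
        co_biomass_sum=24.0,
        transfers={"pyr": ("A", "cross_fed")},
    )
    return Scenario("parasitic_theft", a, b, diet, expected)


def _emergent_chain() -> Scenario:
    # A secretes lactate (growth-coupled); B turns lactate into biomass plus
    # butanol. Neither monoculture makes butanol (A lacks the pathway, B
    # lacks lactate), so the co-culture's butanol is emergent.
    a = _build_model("emgA", "biomass_emgA",
        _exchange("glc_D") + _exchange("lac_L") + [
            ("biomass_emgA", {"glc_D_c": -1.0, "lac_L_c": 1.0}, 0.0, DEFAULT_BOUND),
        ])
    b = _build_model("emgB", "biomass_emgB",
        _exchange("rib_D") + _exchange("lac_L") + _exchange("btoh") + [
            ("PRE_RIB", {"rib_D_c": -1.0, "pre_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("PRE_LAC", {"lac_L_c": -1.0, "pre_c": 1.0, "btoh_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("biomass_emgB", {"pre_c": -1.0}, 0.0, DEFAULT_BOUND),
        ])
    diet = DietSpec({"glc_D": (-10.0, DEFAULT_BOUND),
                     "rib_D": (-1.0, DEFAULT_BOUND)}, name="emergent_chain")
    expected = ScenarioExpectation(
        interaction="commensal",
        mono_viable=(True, True),
        mono_biomass=(10.0, 1.0),
        co_biomass=(10.0, 11.0),
        co_biomass_sum=21.0,
        transfers={"lac_L": ("A", "end_product_removal")},
        emergent=frozenset({"btoh"}),
        overproduced={"btoh": True},
    )
    return Scenario("emergent_chain", a, b, diet, expected)


def _overproducer_pair() -> Scenario:
    # Both members make H2 alone (20 + 2 = 22 additive); acetate
    # cross-feeding lifts the co-culture to 32 > 1.1 * 22 — greater than
    # additive, but not emergent.
    a = _build_model("ovrA", "biomass_ovrA",
        _exchange("glc_D") + _exchange("ac") + _exchange("h2") + [
            ("biomass_ovrA", {"glc_D_c": -1.0, "h2_c": 2.0, "ac_c": 1.0}, 0.0, DEFAULT_BOUND),
        ])
    b = _build_model("ovrB", "biomass_ovrB",
        _exchange("ac") + _exchange("h2") + [
            ("biomass_ovrB", {"ac_c": -1.0, "h2_c": 1.0}, 0.0, DEFAULT_BOUND),
        ])
    diet = DietSpec({"glc_D": (-10.0, DEFAULT_BOUND),
                     "ac": (-2.0, DEFAULT_BOUND)}, name="overproducer_pair")
    expected = ScenarioExpectation(
        interaction="commensal",
        mono_viable=(True, True),
        mono_biomass=(10.0, 2.0),
        co_biomass=(10.0, 12.0),
        co_biomass_sum=22.0,
        transfers={"ac": ("A", "end_product_removal_and_cross_fed")},
        overproduced={"h2": True, "ac": False},
    )
    return Scenario("overproducer_pair", a, b, diet, expected)


def _inert_partner() -> Scenario:
    # B's biomass requires a substrate absent from the diet, so B is never
    # viable and the community must reproduce A's monoculture exactly. The
    # pair is excluded from interaction typing (expected type None).
    a = _build_model("inrA", "biomass_inrA",
        _exchange("glc_D") + [("biomass_inrA", {"glc_D_c": -1.0}, 0.0, DEFAULT_BOUND)])
    b = _build_model("inrB", "biomass_inrB",
        _exchange("cbl1") + [("biomass_inrB", {"cbl1_c": -1.0}, 0.0, DEFAULT_BOUND)])
    diet = DietSpec({"glc_D": (-5.0, DEFAULT_BOUND)}, name="inert_partner")
    expected = ScenarioExpectation(
        interaction=None,
        mono_viable=(True, False),
        mono_biomass=(5.0, 0.0),
        co_biomass=(5.0, 0.0),
        co_biomass_sum=5.0,
    )
    return Scenario("inert_partner", a, b, diet, expected)


_BUILDERS = {
    "mutualistic_crossfeed": _mutualistic_crossfeed,
    "commensal_endproduct": _commensal_endproduct,
    "competitive_shared_substrate": _competitive_shared_substrate,
    "neutral_disjoint": _neutral_disjoint,
    "parasitic_theft": _parasitic_theft,
    "emergent_chain": _emergent_chain,
    "overproducer_pair": _overproducer_pair,
    "inert_partner": _inert_partner,
}


def make_scenario(name: str) -> Scenario:
    """Build a named scenario (see :data:`SCENARIO_NAMES`)."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}") from None


def all_scenarios() -> list[Scenario]:
    return [make_scenario(name) for name in SCENARIO_NAMES]


# ---------------------------------------------------------------------------
# Focal-organism screen for the network / ordination case study
# ---------------------------------------------------------------------------

def make_focal_screen(n_partners: int = 6):
    """A focal fermenter plus donor partners for the network case study.

    The focal organism runs a glycolysis-like internal chain through the
    classic precursor branch points (g6p -> pep -> pyr -> accoa, plus
    pep -> oaa) and can shortcut it with cross-fed acetate (-> accoa) and
    lactate (-> pyr). Its biomass consumes g6p/accoa/oaa and is coupled to
    butyrate and ethanol export, so metabolic outputs are a deterministic
    function of what each partner donates. Partners grow on private diet
    substrates and secrete partner-specific amounts of acetate and lactate,
    giving the screen designed between-pair variation: output-flux distances
    are driven by transfer inputs first and by hub-precursor centrality only
    indirectly.

    Returns ``(focal_model, partner_models, diet)``.
    """
    if n_partners < 3:
        raise ValueError("the case study needs at least 3 partners")
    # Internal conversions are reversible so the active backbone forms a
    # strongly connected component after flux pruning; cross-fed nodes (ac,
    # lac) join it only in pairs where the shortcut actually carries flux.
    focal = _build_model("focal", "biomass_focal",
        _exchange("glc_D") + _exchange("ac") + _exchange("lac_L")
        + _exchange("but") + _exchange("etoh") + [
            ("GLK", {"glc_D_c": -1.0, "g6p_c": 1.0}, 0.0, DEFAULT_BOUND),
            ("GLYC", {"g6p_c": -1.0, "pep_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("PYK", {"pep_c": -1.0, "pyr_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("PPC", {"pep_c": -1.0, "oaa_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("PFOR", {"pyr_c": -1.0, "accoa_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("ACS", {"ac_c": -1.0, "accoa_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("LDH", {"lac_L_c": -1.0, "pyr_c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND),
            ("biomass_focal",
             {"g6p_c": -0.5, "accoa_c": -0.5, "oaa_c": -0.25,
              "but_c": 0.3, "etoh_c": 0.2}, 0.0, DEFAULT_BOUND),
        ])
    partners = []
    diet_entries = {"glc_D": (-10.0, DEFAULT_BOUND)}
    for k in range(n_partners):
        # Designed donation schedule: 0/0.4/0.8 units of acetate and lactate
        # per unit of partner growth — every pair's total donation is
        # distinct and stays below the focal organism's acetyl-CoA demand,
        # so outputs respond to inputs without saturating.
        alpha = 0.4 * (k % 3)
        beta = 0.4 * ((k // 3 + k) % 3)
        substrate = f"sub{k}"
        stoich = {f"{substrate}_c": -1.0}
        rxns = _exchange(substrate)
        if alpha:
            stoich["ac_c"] = alpha
            rxns += _exchange("ac")
        if beta:
            stoich["lac_L_c"] = beta
            rxns += _exchange("lac_L")
        rxns.append((f"biomass_p{k}", stoich, 0.0, DEFAULT_BOUND))
        partners.append(_build_model(f"partner{k}", f"biomass_p{k}", rxns))
        diet_entries[substrate] = (-(2.0 + k % 3), DEFAULT_BOUND)
    diet = DietSpec(diet_entries, name="focal_screen")
    return focal, partners, diet


# ---------------------------------------------------------------------------
# Random models and screens
# ---------------------------------------------------------------------------

def make_random_model(
    n_metabolites: int, n_reactions: int, seed: int
) -> MetabolicModel:
    """A random sparse model guaranteed to grow: a substrate-to-biomass chain
    with randomized uptake bound and yields, plus random internal
    conversions. Deterministic under ``seed``; rejection-sampled so FBA is
    optimal with positive objective."""
    if n_reactions < 3:
        raise ValueError("need at least 3 reactions (exchange, conversion, biomass)")
    for attempt in range(20):
        rng = np.random.default_rng((seed, attempt))
        uptake = float(rng.integers(1, 11))
        n_internal = max(1, min(n_metabolites - 1, n_reactions - 2))
        n_extra = n_reactions - 2 - n_internal
        mets = [f"m{i}_c" for i in range(n_internal)]
        reactions = [
            ("EX_s_e", {"s_e": -1.0}, -uptake, DEFAULT_BOUND, "Exchange"),
            ("T_s", {"s_e": -1.0, mets[0]: 1.0}, 0.0, DEFAULT_BOUND,
             "Transport, extracellular"),
        ]
        for i in range(n_internal - 1):
            yield_coef = float(rng.choice([0.5, 1.0]))
            reactions.append(
                (f"C{i}", {mets[i]: -1.0, mets[i + 1]: yield_coef}, 0.0, DEFAULT_BOUND)
            )
        for k in range(n_extra):
            i, j = rng.choice(n_internal, size=2, replace=False) if n_internal > 1 else (0, 0)
            if i == j:
                continue
            lb = -DEFAULT_BOUND if rng.random() < 0.3 else 0.0
            coef = float(rng.choice([0.5, 1.0]))
            reactions.append((f"R{k}", {mets[i]: -1.0, mets[j]: coef}, lb, DEFAULT_BOUND))
        reactions.append(("biomass", {mets[-1]: -1.0}, 0.0, DEFAULT_BOUND))
        model = _build_model(f"rand{seed}", "biomass", reactions)
        solution = fba_core.fba(model)
        if solution.status == fba_core.STATUS_OPTIMAL and solution.objective_value > 0:
            return model
    raise RuntimeError(f"could not sample a growing model for seed {seed}")


def enumerate_pairs(ids) -> list[tuple]:
    """All unordered distinct pairs (the screen's unit of work):
    n ids -> n(n-1)/2 pairs, no self-pairs, no duplicates."""
    items = list(ids)
    if len(set(items)) != len(items):
        raise ValueError("pair enumeration requires unique ids")
    return list(itertools.combinations(items, 2))


def make_screen(n_models: int, seed: int, n_reactions: int = 6,
                n_metabolites: int = 6):
    """Random models plus their all-vs-all pair list and the expected pair
    count n(n-1)/2."""
    if n_models < 2:
        raise ValueError("a screen needs at least 2 models")
    models = [
        make_random_model(n_metabolites, n_reactions, seed=seed * 1000 + i)
        for i in range(n_models)
    ]
    pairs = enumerate_pairs(range(n_models))
    model_pairs = [(models[i], models[j]) for i, j in pairs]
    expected = n_models * (n_models - 1) // 2
    return models, model_pairs, expected
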