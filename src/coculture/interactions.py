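"""Classify co-culture outcomes.

Biomass effects compare co-culture vs. monoculture growth with a +/-10%
band; the pair of effects maps onto six ecological interaction types
(neutral, commensal, mutualistic, competitive, amensal, parasitic).
Transferred metabolites — secreted into the lumen by one member and taken up
by the other — are categorized by whether the recipient also consumes them
in monoculture ("cross fed") and/or the donor already secretes them in
monoculture ("end product removal"). A metabolite is emergent when the
co-culture secretes it but neither monoculture does, and overproduced when
community secretion exceeds 1.1x the additive monoculture baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .community import PairResult, TAG_A, TAG_B
from .fba_core import FluxSolution
from .model_core import MetabolicModel

#: Flux threshold (mmol/gDCW/h) above which a metabolite counts as
#: produced / consumed; one order of magnitude below the network-pruning
#: threshold so small but real transfers are kept.
PRODUCTION_THRESHOLD = 1e-6
#: Relative band for biomass effects and the overproduction factor.
EFFECT_FACTOR = 1.1

NEUTRAL = "neutral"
COMMENSAL = "commensal"
MUTUALISTIC = "mutualistic"
COMPETITIVE = "competitive"
AMENSAL = "amensal"
PARASITIC = "parasitic"
INTERACTION_TYPES = (NEUTRAL, COMMENSAL, MUTUALISTIC, COMPETITIVE, AMENSAL, PARASITIC)

CROSS_FED = "cross_fed"
END_PRODUCT_REMOVAL = "end_product_removal"
END_PRODUCT_REMOVAL_AND_CROSS_FED = "end_product_removal_and_cross_fed"
OTHER = "other"
TRANSFER_CATEGORIES = (
    CROSS_FED, END_PRODUCT_REMOVAL, END_PRODUCT_REMOVAL_AND_CROSS_FED, OTHER,
)

_TYPE_OF_EFFECTS = {
    frozenset({0}): NEUTRAL,
    frozenset({0, 1}): COMMENSAL,
    frozenset({1}): MUTUALISTIC,
    frozenset({-1}): COMPETITIVE,
    frozenset({0, -1}): AMENSAL,
    frozenset({-1, 1}): PARASITIC,
}


@dataclass
class InteractionRecord:
    pair: tuple[str, str]
    effect_A: int
    effect_B: int
    type: str


@dataclass
class TransferRecord:
    pair: tuple[str, str]
    metabolite: str
    donor: str
    recipient: str
    flux: float
    category: str | None = None


def biomass_effect(mono_flux: float, co_flux: float) -> int:
    """+1 / -1 / 0 for co-culture growth at least 10% above / below / within
    the monoculture flux. Requires a viable monoculture."""
    if mono_flux <= 0:
        raise ValueError("biomass_effect requires a viable (positive) monoculture flux")
    if co_flux >= EFFECT_FACTOR * mono_flux:
        return 1
    if co_flux <= 0.9 * mono_flux:
        return -1
    return 0


def interaction_type(effect_a: int, effect_b: int) -> str:
    """Map an (unordered) pair of biomass effects onto the six ecological
    interaction types."""
    if effect_a not in (-1, 0, 1) or effect_b not in (-1, 0, 1):
        raise ValueError(f"effects must be in {{-1,0,1}}, got {(effect_a, effect_b)}")
    return _TYPE_OF_EFFECTS[frozenset({effect_a, effect_b})]


def classify_pair(
    pair: PairResult, mono_biomass_a: float, mono_biomass_b: float
) -> InteractionRecord:
    ea = biomass_effect(mono_biomass_a, pair.biomass_A)
    eb = biomass_effect(mono_biomass_b, pair.biomass_B)
    return InteractionRecord(pair=pair.pair, effect_A=ea, effect_B=eb,
                             type=interaction_type(ea, eb))


def exchange_fluxes(model: MetabolicModel, solution: FluxSolution) -> dict[str, float]:
    """Monoculture exchange flux per compartment-stripped metabolite base id
    (positive = secretion). Metabolites without an exchange flux are absent."""
    out: dict[str, float] = {}
    for rxn in model.exchange_reactions:
        base = model.exchange_metabolite(rxn).base_id
        out[base] = out.get(base, 0.0) + solution.fluxes.get(rxn.id, 0.0)
    return out


def detect_transfers(
    pair: PairResult, threshold: float = PRODUCTION_THRESHOLD
) -> list[TransferRecord]:
    """One record per lumen metabolite secreted by one member (> threshold)
    and consumed by the other (< -threshold); the transferred amount is
    min(|secretion|, |uptake|), the organism-to-organism overlap (the
    environment may supply or absorb the remainder)."""
    records: list[TransferRecord] = []
    for base in sorted(pair.community_fluxes):
        fa = pair.lumen_fluxes_A.get(base, 0.0)
        fb = pair.lumen_fluxes_B.get(base, 0.0)
        if fa > threshold and fb < -threshold:
            donor, recipient, magnitude = TAG_A, TAG_B, min(fa, -fb)
        elif fb > threshold and fa < -threshold:
            donor, recipient, magnitude = TAG_B, TAG_A, min(fb, -fa)
        else:
            continue
        records.append(
            TransferRecord(pair=pair.pair, metabolite=base, donor=donor,
                           recipient=recipient, flux=magnitude)
        )
    return records


def classify_transfer(
    transfer: TransferRecord,
    mono_exchanges_a: dict[str, float],
    mono_exchanges_b: dict[str, float],
    threshold: float = PRODUCTION_THRESHOLD,
) -> str:
    """Assign the transfer category from the two monoculture exchange-flux
    maps (as produced by :func:`exchange_fluxes`)."""
    donor_mono = mono_exchanges_a if transfer.donor == TAG_A else mono_exchanges_b
    recipient_mono = mono_exchanges_b if transfer.donor == TAG_A else mono_exchanges_a
    cross_fed = recipient_mono.get(transfer.metabolite, 0.0) < -threshold
    end_product = donor_mono.get(transfer.metabolite, 0.0) > threshold
    if cross_fed and end_product:
        return END_PRODUCT_REMOVAL_AND_CROSS_FED
    if cross_fed:
        return CROSS_FED
    if end_product:
        return END_PRODUCT_REMOVAL
    return OTHER


def detect_emergent(
    pair: PairResult,
    mono_exchanges_a: dict[str, float],
    mono_exchanges_b: dict[str, float],
    threshold: float = PRODUCTION_THRESHOLD,
) -> list[str]:
    """Metabolites the community secretes (> threshold) that neither
    monoculture secretes (<= threshold)."""
    emergent = []
    for base, flux in sorted(pair.community_fluxes.items()):
        if flux <= threshold:
            continue
        if mono_exchanges_a.get(base, 0.0) > threshold:
            continue
        if mono_exchanges_b.get(base, 0.0) > threshold:
            continue
        emergent.append(base)
    return emergent


def detect_overproduction(
    pair: PairResult,
    mono_exchanges_a: dict[str, float],
    mono_exchanges_b: dict[str, float],
    metabolite: str,
    threshold: float = PRODUCTION_THRESHOLD,
) -> bool:
    """True iff community secretion of ``metabolite`` is positive and exceeds
    1.1x the additive monoculture baseline.

    Monoculture secretion is clamped at >= 0 (consumption contributes zero to
    the baseline) and values at or below the production threshold count as
    zero, so every emergent metabolite is also overproducing.
    """
    co = pair.community_fluxes.get(metabolite, 0.0)
    if co <= threshold:
        return False
    additive = 0.0
    for mono in (mono_exchanges_a, mono_exchanges_b):
        flux = mono.get(metabolite, 0.0)
        if flux > threshold:
            additive += flux
    return co > EFFECT_FACTOR * additive
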