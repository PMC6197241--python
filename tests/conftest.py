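"""Shared fixtures: tiny hand-built models and cached scenario runs."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pytest

from coculture import community, fba_core, interactions, synthetic
from coculture.model_core import (
    DEFAULT_BOUND,
    DietSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_diet,
)

logging.getLogger("coculture").setLevel(logging.ERROR)


def build_model(mid, objective, reactions) -> MetabolicModel:
    """Thin wrapper over the synthetic module's model assembler."""
    return synthetic._build_model(mid, objective, reactions)


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_a (lb -10) -> transport -> biomass: objective 10."""
    return build_model("chain", "BIOMASS", [
        ("EX_a_e", {"a_e": -1.0}, -10.0, DEFAULT_BOUND, "Exchange"),
        ("At", {"a_e": -1.0, "a_c": 1.0}, 0.0, DEFAULT_BOUND, "Transport, extracellular"),
        ("BIOMASS", {"a_c": -1.0}, 0.0, DEFAULT_BOUND),
    ])


@pytest.fixture
def branched_model() -> MetabolicModel:
    """Two substrates (uptake limits 10 and 4); biomass needs 1 of each."""
    return build_model("branched", "BIOMASS", [
        ("EX_a_e", {"a_e": -1.0}, -10.0, DEFAULT_BOUND, "Exchange"),
        ("EX_b_e", {"b_e": -1.0}, -4.0, DEFAULT_BOUND, "Exchange"),
        ("At", {"a_e": -1.0, "a_c": 1.0}, 0.0, DEFAULT_BOUND),
        ("Bt", {"b_e": -1.0, "b_c": 1.0}, 0.0, DEFAULT_BOUND),
        ("BIOMASS", {"a_c": -1.0, "b_c": -1.0}, 0.0, DEFAULT_BOUND),
    ])


@dataclass
class ScenarioRun:
    """A scenario plus every simulation output the pipeline derives from it."""

    scenario: synthetic.Scenario
    mono_a: fba_core.FluxSolution
    mono_b: fba_core.FluxSolution
    exchanges_a: dict
    exchanges_b: dict
    community: community.CommunityModel
    pair: community.PairResult


def _run_scenario(name: str) -> ScenarioRun:
    sc = synthetic.make_scenario(name)
    constrained_a = apply_diet(sc.model_a, sc.diet)
    constrained_b = apply_diet(sc.model_b, sc.diet)
    mono_a = fba_core.pfba(constrained_a)
    mono_b = fba_core.pfba(constrained_b)
    com = community.build_pair(sc.model_a, sc.model_b)
    pair = community.simulate_pair(com, sc.diet)
    return ScenarioRun(
        scenario=sc,
        mono_a=mono_a,
        mono_b=mono_b,
        exchanges_a=interactions.exchange_fluxes(constrained_a, mono_a),
        exchanges_b=interactions.exchange_fluxes(constrained_b, mono_b),
        community=com,
        pair=pair,
    )


@pytest.fixture(scope="session")
def scenario_runs() -> dict[str, ScenarioRun]:
    """All eight designed scenarios run once through the real pipeline."""
    return {name: _run_scenario(name) for name in synthetic.SCENARIO_NAMES}
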