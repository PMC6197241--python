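"""Interaction typing, transfers, emergent and overproduced metabolites."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from coculture import interactions
from coculture.community import PairResult
from coculture.interactions import (
    AMENSAL,
    COMMENSAL,
    COMPETITIVE,
    MUTUALISTIC,
    NEUTRAL,
    PARASITIC,
    biomass_effect,
    classify_transfer,
    detect_emergent,
    detect_overproduction,
    detect_transfers,
    interaction_type,
)

TRUTH_TABLE = {
    (0, 0): NEUTRAL,
    (0, 1): COMMENSAL, (1, 0): COMMENSAL,
    (1, 1): MUTUALISTIC,
    (-1, -1): COMPETITIVE,
    (0, -1): AMENSAL, (-1, 0): AMENSAL,
    (-1, 1): PARASITIC, (1, -1): PARASITIC,
}


def _pair(lumen_a, lumen_b, community):
    return PairResult(pair=("a", "b"), biomass_A=1.0, biomass_B=1.0,
                      lumen_fluxes_A=lumen_a, lumen_fluxes_B=lumen_b,
                      community_fluxes=community, status="optimal")


class TestBiomassEffect:
    @pytest.mark.parametrize("mono, co, expected", [
        (1.0, 1.2, 1),     # at least 10% greater
        (1.0, 1.1, 1),     # boundary inclusive
        (1.0, 1.05, 0),    # inside the band
        (1.0, 0.95, 0),
        (1.0, 0.9, -1),    # boundary inclusive
        (1.0, 0.8, -1),    # at least 10% less
    ])
    def test_bands(self, mono, co, expected):
        assert biomass_effect(mono, co) == expected

    def test_nonviable_monoculture_rejected(self):
        with pytest.raises(ValueError):
            biomass_effect(0.0, 1.0)


class TestInteractionType:
    @pytest.mark.parametrize("effects, expected", sorted(TRUTH_TABLE.items()))
    def test_truth_table(self, effects, expected):
        assert interaction_type(*effects) == expected

    def test_symmetric_and_partitioning(self):
        combos = list(itertools.product((-1, 0, 1), repeat=2))
        for ea, eb in combos:
            assert interaction_type(ea, eb) == interaction_type(eb, ea)
        assert {interaction_type(*c) for c in combos} == set(
            interactions.INTERACTION_TYPES)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interaction_type(2, 0)


class TestTransfers:
    def test_min_rule(self):
        pair = _pair({"ac": 3.0}, {"ac": -2.0}, {"ac": 1.0})
        (record,) = detect_transfers(pair)
        assert (record.donor, record.recipient) == ("A", "B")
        assert record.flux == pytest.approx(2.0)

    def test_no_consumer_no_transfer(self):
        pair = _pair({"ac": 3.0}, {"ac": 1.0}, {"ac": 4.0})
        assert detect_transfers(pair) == []

    def test_below_threshold_ignored(self):
        pair = _pair({"ac": 5e-7}, {"ac": -5e-7}, {"ac": 0.0})
        assert detect_transfers(pair) == []

    @pytest.mark.parametrize("recipient_mono, donor_mono, expected", [
        (-0.5, 0.0, interactions.CROSS_FED),
        (0.0, 2.0, interactions.END_PRODUCT_REMOVAL),
        (-0.5, 2.0, interactions.END_PRODUCT_REMOVAL_AND_CROSS_FED),
        (0.0, 0.0, interactions.OTHER),
    ])
    def test_categories(self, recipient_mono, donor_mono, expected):
        pair = _pair({"ac": 3.0}, {"ac": -2.0}, {"ac": 1.0})
        (record,) = detect_transfers(pair)
        category = classify_transfer(
            record, {"ac": donor_mono}, {"ac": recipient_mono})
        assert category == expected


class TestEmergentAndOverproduction:
    def test_emergent_definition(self):
        pair = _pair({}, {}, {"p": 0.5})
        assert detect_emergent(pair, {"p": 0.0}, {"p": 0.0}) == ["p"]
        assert detect_emergent(pair, {"p": 0.2}, {"p": 0.0}) == []

    @pytest.mark.parametrize("mono_a, mono_b, co, expected", [
        (2.0, 3.0, 6.0, True),    # 6 > 1.1 * 5
        (2.0, 3.0, 5.4, False),   # below 1.1x additive
        (0.0, 0.0, 0.5, True),    # emergent implies overproducing
        (-1.0, 0.0, 0.5, True),   # consumption clamps to zero baseline
    ])
    def test_overproduction(self, mono_a, mono_b, co, expected):
        pair = _pair({}, {}, {"x": co})
        got = detect_overproduction(pair, {"x": mono_a}, {"x": mono_b}, "x")
        assert got is expected

    @given(
        co=st.floats(0, 10),
        mono_a=st.floats(0, 10),
        mono_b=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_emergent_is_always_overproducing(self, co, mono_a, mono_b):
        pair = _pair({}, {}, {"x": co})
        ex_a, ex_b = {"x": mono_a}, {"x": mono_b}
        if "x" in detect_emergent(pair, ex_a, ex_b):
            assert detect_overproduction(pair, ex_a, ex_b, "x")


class TestEnrichmentContract:
    def test_overproducers_enriched_for_positive_interactions(self):
        """A replicated scenario screen in which overproducing pairs arise
        from cross-feeding scenarios shows significant enrichment of
        mutualistic+commensal types among overproducers (one-sided)."""
        from coculture import fba_core, stats, synthetic
        from coculture.community import build_pair, simulate_pair
        from coculture.model_core import DietSpec, apply_diet

        targets = {"emergent_chain": "btoh", "overproducer_pair": "h2"}
        overall = {t: 0 for t in interactions.INTERACTION_TYPES}
        subset = {t: 0 for t in interactions.INTERACTION_TYPES}
        pos_over, pos_total, n_over, n_total = 0, 0, 0, 0
        for scale in (0.8, 1.0, 1.25):
            for name in synthetic.SCENARIO_NAMES:
                sc = synthetic.make_scenario(name)
                if sc.expected.interaction is None:
                    continue
                diet = DietSpec({k: (lb * scale, ub)
                                 for k, (lb, ub) in sc.diet.entries.items()})
                mono_a = fba_core.pfba(apply_diet(sc.model_a, diet))
                mono_b = fba_core.pfba(apply_diet(sc.model_b, diet))
                pair = simulate_pair(build_pair(sc.model_a, sc.model_b), diet)
                record = interactions.classify_pair(
                    pair, mono_a.objective_value, mono_b.objective_value)
                ex_a = interactions.exchange_fluxes(
                    apply_diet(sc.model_a, diet), mono_a)
                ex_b = interactions.exchange_fluxes(
                    apply_diet(sc.model_b, diet), mono_b)
                overproducing = name in targets and detect_overproduction(
                    pair, ex_a, ex_b, targets[name])
                overall[record.type] += 1
                n_total += 1
                pos_total += record.type in (MUTUALISTIC, COMMENSAL)
                if overproducing:
                    subset[record.type] += 1
                    n_over += 1
                    pos_over += record.type in (MUTUALISTIC, COMMENSAL)
        assert n_over >= 6  # the designed overproducers all survive rescaling
        # Combined mutualistic+commensal enrichment among overproducers.
        p_combined = stats.fisher_greater(
            pos_over, n_over - pos_over,
            pos_total - pos_over, (n_total - n_over) - (pos_total - pos_over))
        assert p_combined < 0.05
        pvals = stats.enrichment_test(overall, subset)
        assert pvals[COMMENSAL] < 0.05
        assert pvals[COMPETITIVE] > 0.5


class TestScenarioRecovery:
    """The designed scenarios drive the classification stage end to end."""

    def test_types_and_transfers(self, scenario_runs):
        for name, run in scenario_runs.items():
            expected = run.scenario.expected
            if expected.interaction is None:
                continue
            record = interactions.classify_pair(
                run.pair, run.mono_a.objective_value, run.mono_b.objective_value)
            assert record.type == expected.interaction, name
            transfers = detect_transfers(run.pair)
            got = {}
            for tr in transfers:
                tr.category = classify_transfer(tr, run.exchanges_a, run.exchanges_b)
                got[tr.metabolite] = (tr.donor, tr.category)
            assert got == expected.transfers, name

    def test_emergent_and_overproduction_flags(self, scenario_runs):
        for name, run in scenario_runs.items():
            expected = run.scenario.expected
            if expected.interaction is None:
                continue
            emergent = set(detect_emergent(run.pair, run.exchanges_a, run.exchanges_b))
            assert emergent == set(expected.emergent), name
            for met, flag in expected.overproduced.items():
                got = detect_overproduction(
                    run.pair, run.exchanges_a, run.exchanges_b, met)
                assert got is flag, f"{name}:{met}"
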