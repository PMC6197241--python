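"""End-to-end screen orchestration with provenance and TSV outputs.

Three stages mirror the screening workflow: ``run_monocultures`` (per-model
growth and exchange fluxes under the diet), ``run_screen`` (all pairwise
co-cultures: biomasses, interaction types, transfers, emergent and
greater-than-additive production for configured target metabolites) and
``run_network_stats`` (the focal-organism case study: flux-pruned metabolite
graphs per co-culture, hub-precursor centrality, Mantel tests and CCA).

Every output table has a header and a stable row order; a provenance sidecar
records the configuration and seed, so a rerun with the same inputs is
byte-identical. Pairs are independent units of work: results do not depend
on the order in which they are solved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fba_core, interactions, network, stats
from .community import TAG_A, TAG_B, build_pair, simulate_pair
from .fba_core import FluxSolution, is_viable
from .model_core import DietSpec, MetabolicModel, apply_diet
from .synthetic import enumerate_pairs

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Screen-level parameters (units: h^-1 for biomass, mmol/gDCW/h else)."""

    viability_cutoff: float = fba_core.VIABILITY_CUTOFF
    transfer_threshold: float = interactions.PRODUCTION_THRESHOLD
    prune_threshold: float = network.FLUX_PRUNE_THRESHOLD
    overproduction_factor: float = 1.1
    cca_flux_filter: float = stats.FLUX_FILTER
    time_limit: float = fba_core.DEFAULT_TIME_LIMIT
    hub_quantile: float = 0.95
    seed: int = 0
    target_metabolites: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for name in ("viability_cutoff", "transfer_threshold", "prune_threshold",
                     "overproduction_factor", "cca_flux_filter", "time_limit",
                     "hub_quantile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")


def _write(df: pd.DataFrame, outdir: str | None, name: str, index: bool = False) -> None:
    if outdir is None:
        return
    os.makedirs(outdir, exist_ok=True)
    df.to_csv(os.path.join(outdir, name), sep="\t", index=index,
              float_format=_FLOAT_FMT)


def write_provenance(config: RunConfig, outdir: str | None, stage: str) -> None:
    """Config + seed sidecar written next to each stage's tables."""
    if outdir is None:
        return
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, f"{stage}.provenance.json"), "w") as fh:
        json.dump({"stage": stage, "config": dataclasses.asdict(config)},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class MonocultureResult:
    model: MetabolicModel                 # diet-constrained copy
    solution: FluxSolution
    exchanges: dict[str, float]           # base metabolite -> flux

    @property
    def viable(self) -> bool:
        return is_viable(self.solution)


def run_monocultures(
    models: list[MetabolicModel],
    diet: DietSpec,
    config: RunConfig | None = None,
    outdir: str | None = None,
) -> tuple[pd.DataFrame, dict[str, MonocultureResult]]:
    """pFBA every model alone under the diet.

    Returns the summary table (model, biomass, viable, status) and a mapping
    of per-model results reused by the later stages. Unreadable/failed
    models are recorded, not raised.
    """
    config = config or RunConfig()
    config.validate()
    rows, results = [], {}
    exchange_rows = []
    for model in models:
        constrained = apply_diet(model, diet)
        solution = fba_core.pfba(constrained, time_limit=config.time_limit)
        exchanges = (interactions.exchange_fluxes(constrained, solution)
                     if solution.ok else {})
        results[model.id] = MonocultureResult(constrained, solution, exchanges)
        rows.append({
            "model": model.id,
            "biomass": solution.objective_value,
            "viable": solution.ok and solution.objective_value > config.viability_cutoff,
            "status": solution.status,
        })
        for met in sorted(exchanges):
            if abs(exchanges[met]) > config.transfer_threshold:
                exchange_rows.append({"model": model.id, "metabolite": met,
                                      "flux": exchanges[met]})
    table = pd.DataFrame(rows, columns=["model", "biomass", "viable", "status"])
    if table.empty:
        logger.warning("run_monocultures: no models given; empty table")
    _write(table, outdir, "monocultures.tsv")
    _write(pd.DataFrame(exchange_rows, columns=["model", "metabolite", "flux"]),
           outdir, "monoculture_exchanges.tsv")
    write_provenance(config, outdir, "monocultures")
    return table, results


@dataclass
class ScreenResult:
    pairs: pd.DataFrame
    interactions: pd.DataFrame
    transfers: pd.DataFrame
    production: pd.DataFrame
    emergent: pd.DataFrame


def run_screen(
    models: list[MetabolicModel],
    diet: DietSpec,
    config: RunConfig | None = None,
    outdir: str | None = None,
    monocultures: dict[str, MonocultureResult] | None = None,
) -> ScreenResult:
    """Simulate every unordered pair of viable-monoculture models.

    Pairs where either member's co-culture biomass stays at or below the
    viability cutoff are recorded in the pair table but excluded from the
    interaction/transfer/production analyses, as are solver failures.
    """
    config = config or RunConfig()
    config.validate()
    if monocultures is None:
        _, monocultures = run_monocultures(models, diet, config)
    by_id = {m.id: m for m in models}
    pair_rows, inter_rows, transfer_rows, prod_rows, emergent_rows = [], [], [], [], []
    for id_a, id_b in enumerate_pairs(sorted(by_id)):
        mono_a, mono_b = monocultures[id_a], monocultures[id_b]
        if not (mono_a.viable and mono_b.viable):
            continue
        pair_id = f"{id_a}|{id_b}"
        community = build_pair(by_id[id_a], by_id[id_b])
        result = simulate_pair(community, diet, time_limit=config.time_limit)
        pair_rows.append({
            "pair_id": pair_id, "model_a": id_a, "model_b": id_b,
            "biomass_a": result.biomass_A, "biomass_b": result.biomass_B,
            "status": result.status,
        })
        included = (result.ok
                    and result.biomass_A > config.viability_cutoff
                    and result.biomass_B > config.viability_cutoff)
        if not included:
            continue
        record = interactions.classify_pair(
            result, mono_a.solution.objective_value, mono_b.solution.objective_value)
        inter_rows.append({
            "pair_id": pair_id, "type": record.type,
            "effect_a": record.effect_A, "effect_b": record.effect_B,
        })
        transfers = interactions.detect_transfers(result, config.transfer_threshold)
        for tr in transfers:
            tr.category = interactions.classify_transfer(
                tr, mono_a.exchanges, mono_b.exchanges, config.transfer_threshold)
            transfer_rows.append({
                "pair_id": pair_id, "metabolite": tr.metabolite,
                "donor": id_a if tr.donor == TAG_A else id_b,
                "recipient": id_b if tr.donor == TAG_A else id_a,
                "flux": tr.flux, "category": tr.category,
            })
        emergent = interactions.detect_emergent(
            result, mono_a.exchanges, mono_b.exchanges, config.transfer_threshold)
        for met in emergent:
            emergent_rows.append({"pair_id": pair_id, "metabolite": met,
                                  "co_flux": result.community_fluxes.get(met, 0.0)})
        for met in config.target_metabolites:
            additive = sum(
                max(mono.exchanges.get(met, 0.0), 0.0)
                for mono in (mono_a, mono_b)
                if mono.exchanges.get(met, 0.0) > config.transfer_threshold
            )
            prod_rows.append({
                "pair_id": pair_id, "metabolite": met,
                "co_flux": result.community_fluxes.get(met, 0.0),
                "additive_flux": additive,
                "overproducing": interactions.detect_overproduction(
                    result, mono_a.exchanges, mono_b.exchanges, met,
                    config.transfer_threshold),
                "emergent": met in emergent,
            })
    screen = ScreenResult(
        pairs=pd.DataFrame(pair_rows, columns=[
            "pair_id", "model_a", "model_b", "biomass_a", "biomass_b", "status"]),
        interactions=pd.DataFrame(inter_rows, columns=[
            "pair_id", "type", "effect_a", "effect_b"]),
        transfers=pd.DataFrame(transfer_rows, columns=[
            "pair_id", "metabolite", "donor", "recipient", "flux", "category"]),
        production=pd.DataFrame(prod_rows, columns=[
            "pair_id", "metabolite", "co_flux", "additive_flux",
            "overproducing", "emergent"]),
        emergent=pd.DataFrame(emergent_rows, columns=[
            "pair_id", "metabolite", "co_flux"]),
    )
    if not screen.interactions.empty:
        histogram = screen.interactions["type"].value_counts().to_dict()
        logger.info("screen: %d pairs solved, interaction types %s",
                    len(pair_rows), histogram)
    _write(screen.pairs, outdir, "pairs.tsv")
    _write(screen.interactions, outdir, "interactions.tsv")
    _write(screen.transfers, outdir, "transfers.tsv")
    _write(screen.production, outdir, "production.tsv")
    _write(screen.emergent, outdir, "emergent.tsv")
    write_provenance(config, outdir, "screen")
    return screen


@dataclass
class NetworkStatsResult:
    hubs: list[str]
    centrality: pd.DataFrame       # long: pair_id, metabolite, degree, betweenness
    outputs: pd.DataFrame          # transformed output-flux matrix (pairs x mets)
    inputs: pd.DataFrame           # transformed transfer-input matrix
    hub_betweenness: pd.DataFrame
    hub_degree: pd.DataFrame
    mantel: pd.DataFrame           # comparison, r, p, ok
    cca: pd.DataFrame              # constraint, proportion_constrained, ...
    ordinations: dict[str, stats.OrdinationResult]


def run_network_stats(
    focal: MetabolicModel,
    partners: list[MetabolicModel],
    diet: DietSpec,
    config: RunConfig | None = None,
    outdir: str | None = None,
) -> NetworkStatsResult:
    """Focal-organism case study over its viable co-cultures.

    For each partner the pair is simulated, the focal member's flux vector
    extracted, its metabolite graph flux-pruned, and hub-precursor
    centrality computed. Output-flux distances are then correlated (Mantel)
    with transfer-input distances and hub centrality distances, and the
    output matrix is constrained by each explanatory matrix with CCA.
    """
    from .community import organism_solution

    config = config or RunConfig()
    config.validate()
    mono_focal = apply_diet(focal, diet)
    focal_solution = fba_core.pfba(mono_focal, time_limit=config.time_limit)
    if not is_viable(focal_solution):
        raise ValueError(f"focal model {focal.id!r} is not viable under the diet")
    graph = network.build_graph(focal)

    mono_pruned = network.prune_by_flux(graph, focal_solution, config.prune_threshold)
    mono_centrality = network.centrality(mono_pruned) if len(mono_pruned) else None
    out_rows: dict[str, dict[str, float]] = {}
    in_rows: dict[str, dict[str, float]] = {}
    bet_rows: dict[str, dict[str, float]] = {}
    deg_rows: dict[str, dict[str, float]] = {}
    centrality_tables: list[pd.DataFrame] = []
    centrality_long = []
    for partner in partners:
        community = build_pair(focal, partner)
        result = simulate_pair(community, diet, time_limit=config.time_limit)
        if not result.ok or result.biomass_A <= config.viability_cutoff:
            logger.warning("case study: skipping pair with %s (status %s)",
                           partner.id, result.status)
            continue
        pair_id = f"{focal.id}|{partner.id}"
        focal_fluxes = organism_solution(community, result.solution.fluxes, TAG_A)
        focal_view = FluxSolution(fluxes=focal_fluxes, objective_value=result.biomass_A,
                                  status=result.status, total_absolute_flux=0.0)
        pruned = network.prune_by_flux(graph, focal_view, config.prune_threshold)
        if len(pruned) == 0:
            logger.warning("case study: empty pruned graph for %s", pair_id)
            continue
        table = network.centrality(pruned)
        centrality_tables.append(table)
        for met, row in table.iterrows():
            centrality_long.append({
                "pair_id": pair_id, "metabolite": met,
                "degree_norm": row["degree_norm"],
                "betweenness_norm": row["betweenness_norm"],
            })
        out_rows[pair_id] = {m: f for m, f in result.lumen_fluxes_A.items() if f > 0}
        in_rows[pair_id] = {
            tr.metabolite: tr.flux
            for tr in interactions.detect_transfers(result, config.transfer_threshold)
            if tr.recipient == TAG_A
        }
        bet_rows[pair_id] = table["betweenness_norm"].to_dict()
        deg_rows[pair_id] = table["degree_norm"].to_dict()

    if len(out_rows) < 3:
        raise ValueError(
            f"focal model {focal.id!r} appears in only {len(out_rows)} viable "
            "co-culture(s); the case study needs at least 3"
        )

    hub_source = [mono_centrality] if mono_centrality is not None else centrality_tables
    hubs = sorted(network.find_hubs(hub_source, config.hub_quantile,
                                    precursors=network.precursor_metabolites()))

    pair_ids = sorted(out_rows)
    outputs = stats.transform_fluxes(
        pd.DataFrame.from_dict(out_rows, orient="index").reindex(pair_ids)
        .fillna(0.0).sort_index(axis=1))
    inputs = stats.transform_fluxes(
        pd.DataFrame.from_dict(in_rows, orient="index").reindex(pair_ids)
        .fillna(0.0).sort_index(axis=1))
    hub_bet = (pd.DataFrame.from_dict(bet_rows, orient="index")
               .reindex(pair_ids).fillna(0.0).reindex(columns=hubs, fill_value=0.0))
    hub_deg = (pd.DataFrame.from_dict(deg_rows, orient="index")
               .reindex(pair_ids).fillna(0.0).reindex(columns=hubs, fill_value=0.0))

    comparisons = {
        "outputs_vs_transfer_inputs": inputs,
        "outputs_vs_hub_betweenness": hub_bet,
        "outputs_vs_hub_degree": hub_deg,
    }
    mantel_rows = []
    for i, (name, matrix) in enumerate(comparisons.items()):
        res = stats.mantel_test(outputs.to_numpy(), matrix.to_numpy(),
                                seed=config.seed + i)
        mantel_rows.append({"comparison": name, "r": res.r, "p": res.p,
                            "permutations": res.permutations, "ok": res.ok,
                            "message": res.message})
    mantel = pd.DataFrame(mantel_rows, columns=[
        "comparison", "r", "p", "permutations", "ok", "message"])

    cca_rows, ordinations = [], {}
    response = outputs.loc[:, outputs.sum(axis=0) > 0]
    response = response.loc[response.sum(axis=1) > 0]
    for name, matrix in comparisons.items():
        constraint = matrix.reindex(response.index)
        label = name.replace("outputs_vs_", "")
        if response.shape[0] < 3 or constraint.to_numpy().std() == 0:
            logger.warning("case study: skipping CCA for %s (degenerate input)", label)
            continue
        try:
            ord_res = stats.cca(response, constraint)
        except ValueError as exc:
            logger.warning("case study: skipping CCA for %s (%s)", label, exc)
            continue
        ordinations[label] = ord_res
        cca_rows.append({
            "constraint": label,
            "proportion_constrained": ord_res.proportion_constrained,
            "constrained_inertia": ord_res.constrained_inertia,
            "total_inertia": ord_res.total_inertia,
            "n_axes": len(ord_res.eigenvalues),
        })
    cca_table = pd.DataFrame(cca_rows, columns=[
        "constraint", "proportion_constrained", "constrained_inertia",
        "total_inertia", "n_axes"])

    centrality_df = pd.DataFrame(centrality_long, columns=[
        "pair_id", "metabolite", "degree_norm", "betweenness_norm"])
    _write(centrality_df, outdir, "focal_centrality.tsv")
    _write(outputs, outdir, "focal_outputs.tsv", index=True)
    _write(inputs, outdir, "focal_inputs.tsv", index=True)
    _write(hub_bet, outdir, "focal_hub_betweenness.tsv", index=True)
    _write(hub_deg, outdir, "focal_hub_degree.tsv", index=True)
    _write(mantel, outdir, "mantel.tsv")
    _write(cca_table, outdir, "cca.tsv")
    if outdir is not None:
        for label, ord_res in ordinations.items():
            _write(ord_res.site_scores, outdir, f"cca_{label}_sites.tsv", index=True)
            _write(ord_res.response_scores, outdir, f"cca_{label}_responses.tsv",
                   index=True)
            _write(ord_res.biplot_scores, outdir, f"cca_{label}_biplot.tsv", index=True)
        with open(os.path.join(outdir, "hubs.txt"), "w") as fh:
            fh.write("\n".join(hubs) + "\n")
    write_provenance(config, outdir, "network_stats")
    return NetworkStatsResult(
        hubs=hubs, centrality=centrality_df, outputs=outputs, inputs=inputs,
        hub_betweenness=hub_bet, hub_degree=hub_deg, mantel=mantel,
        cca=cca_table, ordinations=ordinations,
    )
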