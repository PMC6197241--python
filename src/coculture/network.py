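"""Directed metabolite graphs and hub-metabolite centrality.

Each organism's internal metabolism is abstracted as a directed
metabolite-to-metabolite graph: for every retained reaction, an edge runs
from each reactant to each product (and back for reversible reactions).
Boundary/transport subsystems are excluded, highly connected currency
metabolites are deleted, and within-reaction cofactor pairs (ATP/ADP,
NAD/NADH, ...) are disconnected so that centrality reflects carbon/nitrogen
routing rather than cofactor bookkeeping. Graphs are then pruned to the
reactions a simulation actually uses (|flux| >= 1e-5 mmol/gDCW/h) and to the
largest strongly connected component, and summarized by normalized degree
and betweenness per metabolite.
"""

from __future__ import annotations

import logging
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from .fba_core import FluxSolution
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

#: Edges from reactions with |flux| below this are pruned (mmol/gDCW/h).
FLUX_PRUNE_THRESHOLD = 1e-5

#: Reactions with these subsystem labels never enter the graph (boundary,
#: transport and species-specific biosynthesis subsystems).
EXCLUDED_SUBSYSTEMS = frozenset({
    "Transport, extracellular",
    "Exchange/demand reaction",
    "Exchange",
    "Fatty acid synthesis",
    "Cell wall biosynthesis",
    "Nucleotide interconversion",
    "Terpenoid backbone biosynthesis",
    "Lipopolysaccharide biosynthesis",
    "Glycerophospholipid metabolism",
})

#: Compartments treated as external; reactions touching them are dropped.
EXTERNAL_COMPARTMENTS = frozenset({"e", "u"})

_KNOWN_COMPARTMENTS = ("c", "e", "p", "u", "m")


def _read_lines(name: str) -> list[str]:
    text = resources.files("coculture.data").joinpath(name).read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


def removed_metabolites() -> frozenset[str]:
    """Highly connected metabolite base ids deleted from every graph."""
    return frozenset(_read_lines("removed_metabolites.txt"))


def currency_pairs() -> list[frozenset[str]]:
    """Within-reaction cofactor pairs whose edges are deleted."""
    lines = _read_lines("currency_pairs.tsv")[1:]  # skip header
    return [frozenset(ln.split("\t")) for ln in lines]


def precursor_metabolites() -> list[str]:
    """The 13 central-carbon biomass-precursor base ids."""
    return _read_lines("precursor_metabolites.txt")


def strip_compartment(met_id: str) -> str:
    """Base id of a possibly organism-namespaced, compartment-suffixed
    metabolite id (``Abug__pyr_c`` -> ``pyr``)."""
    base = met_id.split("__", 1)[-1]
    for comp in _KNOWN_COMPARTMENTS:
        if base.endswith("_" + comp):
            return base[: -(len(comp) + 1)]
    return base


def build_graph(model: MetabolicModel) -> nx.MultiDiGraph:
    """Reactant->product multigraph of the model's internal metabolism.

    Edges carry their reaction id; weights are attached later by
    :func:`prune_by_flux`. Output is independent of reaction ordering.
    """
    removed = removed_metabolites()
    pairs = currency_pairs()
    graph = nx.MultiDiGraph(model_id=model.id)
    compartment = {m.id: m.compartment for m in model.metabolites}
    base = {m.id: m.base_id for m in model.metabolites}
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.subsystem in EXCLUDED_SUBSYSTEMS:
            continue
        if any(compartment[m] in EXTERNAL_COMPARTMENTS for m in rxn.stoichiometry):
            continue
        reactants = sorted(m for m, c in rxn.stoichiometry.items() if c < 0)
        products = sorted(m for m, c in rxn.stoichiometry.items() if c > 0)
        for r in reactants:
            if base[r] in removed:
                continue
            for p in products:
                if base[p] in removed or r == p:
                    continue
                if frozenset({base[r], base[p]}) in pairs:
                    continue
                graph.add_edge(r, p, key=(rxn.id, "fwd"), reaction=rxn.id, weight=0.0)
                if rxn.reversible:
                    graph.add_edge(p, r, key=(rxn.id, "rev"), reaction=rxn.id, weight=0.0)
    return graph


def prune_by_flux(
    graph: nx.MultiDiGraph,
    solution: FluxSolution,
    threshold: float = FLUX_PRUNE_THRESHOLD,
) -> nx.MultiDiGraph:
    """Keep edges whose reaction carries |flux| >= threshold, weight them by
    |flux|, and restrict to the largest strongly connected component.

    Reversible reactions contribute |flux| to both edge directions.
    Idempotent: pruning an already-pruned graph with the same solution is a
    no-op. An empty result is returned (with a warning) rather than raised.
    """
    pruned = nx.MultiDiGraph(**graph.graph)
    pruned.add_nodes_from(graph.nodes)
    for u, v, key, data in graph.edges(keys=True, data=True):
        flux = abs(solution.fluxes.get(data["reaction"], 0.0))
        if flux >= threshold:
            pruned.add_edge(u, v, key=key, reaction=data["reaction"], weight=flux)
    components = list(nx.strongly_connected_components(pruned))
    if not components:
        logger.warning("flux pruning produced an empty graph")
        return nx.MultiDiGraph(**graph.graph)
    # Deterministic tie-break on equal component sizes.
    largest = max(components, key=lambda comp: (len(comp), min(comp)))
    result = pruned.subgraph(largest).copy()
    if result.number_of_edges() == 0:
        logger.warning("flux pruning left no edges (largest SCC is a single node)")
    return result


def centrality(graph: nx.MultiDiGraph) -> pd.DataFrame:
    """Normalized degree and betweenness per metabolite.

    Both statistics are computed on the simple directed, unweighted topology
    (flux weights are for reporting only). Degree is the number of distinct
    neighbours divided by n-1; betweenness is raw betweenness divided by
    (n-1)(n-2), the directed-graph normalization. Both lie in [0, 1]; for
    n < 3 betweenness is 0 by convention.
    """
    simple = nx.DiGraph(graph)
    nodes = sorted(simple.nodes)
    n = len(nodes)
    degree = {}
    for node in nodes:
        neighbours = (set(simple.successors(node)) | set(simple.predecessors(node)))
        neighbours.discard(node)
        degree[node] = len(neighbours) / (n - 1) if n > 1 else 0.0
    if n >= 3:
        betweenness = nx.betweenness_centrality(simple, normalized=True)
    else:
        betweenness = {node: 0.0 for node in nodes}
    return pd.DataFrame(
        {
            "degree_norm": [degree[node] for node in nodes],
            "betweenness_norm": [betweenness[node] for node in nodes],
        },
        index=pd.Index(nodes, name="metabolite"),
    )


def mean_centrality(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-metabolite mean of each centrality metric across simulations
    (metabolites are averaged over the tables in which they appear)."""
    if not tables:
        raise ValueError("mean_centrality needs at least one table")
    stacked = pd.concat(tables)
    return stacked.groupby(level=0).mean()


def find_hubs(
    tables: list[pd.DataFrame],
    quantile: float = 0.95,
    precursors: list[str] | None = None,
) -> set[str]:
    """Hub metabolites: at or above the given quantile of the across-table
    mean of EITHER centrality metric.

    When ``precursors`` is given (base ids; pass
    :func:`precursor_metabolites` for hub-precursor mode) the hub set is
    intersected with it by compartment-stripped base id.
    """
    means = mean_centrality(tables)
    deg_cut = float(np.quantile(means["degree_norm"], quantile))
    bet_cut = float(np.quantile(means["betweenness_norm"], quantile))
    hubs = {
        met
        for met, row in means.iterrows()
        if row["degree_norm"] >= deg_cut or row["betweenness_norm"] >= bet_cut
    }
    if precursors is not None:
        wanted = set(precursors)
        hubs = {met for met in hubs if strip_compartment(met) in wanted}
    return hubs


def write_edge_list(graph: nx.MultiDiGraph, path) -> None:
    """Export as tab-separated ``from  to  reaction  weight``."""
    rows = sorted(
        (u, v, data["reaction"], data["weight"])
        for u, v, data in graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("from\tto\treaction\tweight\n")
        for u, v, rxn, w in rows:
            fh.write(f"{u}\t{v}\t{rxn}\t{w:.10g}\n")


def write_centrality(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")
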