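"""Flux balance analysis and parsimonious FBA as linear programs.

FBA maximizes the objective (biomass) flux subject to steady-state mass
balance ``S v = 0`` and flux bounds. Parsimonious FBA (the "mtf" variant)
then fixes the objective at its optimum and minimizes total absolute flux
sum(|v|), linearized by splitting each flux into non-negative forward and
backward components. Both are solved with scipy's HiGHS interface, which is
deterministic on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import MetabolicModel

#: Growth-rate viability cutoff (h^-1): slower simulations are discarded.
VIABILITY_CUTOFF = 1e-3
#: Tolerance used when fixing the biomass optimum inside pFBA.
OPTIMUM_TOLERANCE = 1e-6
#: Default wall-clock limit per LP solve, in seconds.
DEFAULT_TIME_LIMIT = 300.0

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_TIMEOUT = "timeout"


@dataclass
class FluxSolution:
    """A steady-state flux vector (mmol/gDCW/h; biomass flux in h^-1)."""

    fluxes: dict[str, float]
    objective_value: float
    status: str
    total_absolute_flux: float

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OPTIMAL


def is_viable(solution: FluxSolution) -> bool:
    """True iff the solve succeeded and biomass flux exceeds 0.001 h^-1."""
    return solution.status == STATUS_OPTIMAL and solution.objective_value > VIABILITY_CUTOFF


def _build_lp(model: MetabolicModel):
    """Stoichiometric matrix (all metabolites balanced; exchanges are the
    boundary), bounds and objective vector in a fixed reaction order."""
    rxn_ids = [r.id for r in model.reactions]
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_pos[met_id])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    c = np.zeros(len(model.reactions))
    for rid, coef in model.objective.items():
        c[rxn_ids.index(rid)] = coef
    return rxn_ids, S, lb, ub, c


def _status_of(res) -> str:
    if res.status == 0:
        return STATUS_OPTIMAL
    if res.status == 2:
        return STATUS_INFEASIBLE
    if res.status == 1:  # iteration/time limit reached
        return STATUS_TIMEOUT
    raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")


def _empty(status: str) -> FluxSolution:
    return FluxSolution(fluxes={}, objective_value=0.0, status=status,
                        total_absolute_flux=0.0)


def fba(model: MetabolicModel, time_limit: float = DEFAULT_TIME_LIMIT) -> FluxSolution:
    """Maximize the objective flux subject to S v = 0 and the flux bounds."""
    model.validate(require_single_objective=False)
    rxn_ids, S, lb, ub, c = _build_lp(model)
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"time_limit": time_limit},
    )
    status = _status_of(res)
    if status != STATUS_OPTIMAL:
        return _empty(status)
    v = res.x
    return FluxSolution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(c @ v),
        status=STATUS_OPTIMAL,
        total_absolute_flux=float(np.abs(v).sum()),
    )


def pfba(model: MetabolicModel, time_limit: float = DEFAULT_TIME_LIMIT) -> FluxSolution:
    """Parsimonious FBA: attain the FBA optimum, then minimize sum(|v|).

    Each flux is split as ``v = f - b`` with ``f, b >= 0``; minimizing
    ``sum(f + b)`` subject to the original constraints plus
    ``c.v >= opt - 1e-6`` yields the minimum-total-flux optimum.
    """
    first = fba(model, time_limit=time_limit)
    if first.status != STATUS_OPTIMAL:
        return first
    rxn_ids, S, lb, ub, c = _build_lp(model)
    n = len(rxn_ids)
    # Split bounds: f in [max(lb,0), max(ub,0)], b in [max(-ub,0), max(-lb,0)].
    f_bounds = np.column_stack([np.maximum(lb, 0.0), np.maximum(ub, 0.0)])
    b_bounds = np.column_stack([np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)])
    A_eq = sparse.hstack([S, -S], format="csr")
    # Objective attainment: c.(f-b) >= opt - tol  <=>  -c.f + c.b <= -(opt - tol)
    opt = first.objective_value
    A_ub = sparse.csr_matrix(np.concatenate([-c, c])[None, :])
    b_ub = np.array([-(opt - OPTIMUM_TOLERANCE)])
    res = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.vstack([f_bounds, b_bounds]),
        method="highs",
        options={"time_limit": time_limit},
    )
    status = _status_of(res)
    if status != STATUS_OPTIMAL:
        return _empty(status)
    v = res.x[:n] - res.x[n:]
    return FluxSolution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(c @ v),
        status=STATUS_OPTIMAL,
        total_absolute_flux=float(np.abs(v).sum()),
    )


def mass_balance_residuals(model: MetabolicModel, solution: FluxSolution) -> dict[str, float]:
    """Per-metabolite residual of S v; ~0 for any optimal solution."""
    residuals: dict[str, float] = {m.id: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        v = solution.fluxes.get(rxn.id, 0.0)
        for met_id, coef in rxn.stoichiometry.items():
            residuals[met_id] += coef * v
    return residuals


def write_flux_table(solution: FluxSolution, path) -> None:
    """Export as tab-separated ``reaction_id  flux``."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tflux\n")
        for rid in sorted(solution.fluxes):
            fh.write(f"{rid}\t{solution.fluxes[rid]:.10g}\n")
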