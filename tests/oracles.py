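"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (vertex
enumeration, exhaustive path enumeration, direct hypergeometric summation)
so they share no code path with the implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def polytope_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                      tol: float = 1e-9) -> list[np.ndarray]:
    """All vertices of {v : S v = 0, lb <= v <= ub} for small n.

    A vertex has n linearly independent active constraints; with rank(S)
    equalities always active, some subset of variables sits at a bound and
    the rest are determined uniquely by S. Enumerate every subset and bound
    assignment (3^n candidate systems) and keep the feasible unique
    solutions.
    """
    n = S.shape[1]
    vertices: list[np.ndarray] = []
    seen: set[tuple] = set()
    for fixed in itertools.chain.from_iterable(
        itertools.combinations(range(n), k) for k in range(n + 1)
    ):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
            if free:
                A = S[:, free]
                rhs = -S[:, list(fixed)] @ np.array(bounds_choice) if fixed else np.zeros(S.shape[0])
                if np.linalg.matrix_rank(A, tol=1e-10) < len(free):
                    continue  # not uniquely determined; caught by a larger fixed set
                x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free] = x
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            key = tuple(np.round(v, 6))
            if key not in seen:
                seen.add(key)
                vertices.append(v)
    return vertices


def model_matrices(model):
    """Dense (S, lb, ub, c) for a MetabolicModel, in reaction order."""
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            S[met_pos[met], j] = coef
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(len(model.reactions))
    rxn_ids = [r.id for r in model.reactions]
    for rid, coef in model.objective.items():
        c[rxn_ids.index(rid)] = coef
    return S, lb, ub, c


def brute_force_betweenness(nodes, edges) -> dict:
    """Normalized directed betweenness by exhaustive simple-path enumeration.

    For every ordered pair (s, t) all simple paths are enumerated, the
    shortest kept, and each interior node credited with its fraction of
    shortest paths; totals are divided by (n-1)(n-2).
    """
    nodes = list(nodes)
    adjacency = {u: set() for u in nodes}
    for u, v in edges:
        if u != v:
            adjacency[u].add(v)
    n = len(nodes)
    score = {u: 0.0 for u in nodes}
    if n < 3:
        return score

    def all_paths(s, t):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nxt in adjacency[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))

    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = list(all_paths(s, t))
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            best = [p for p in paths if len(p) == shortest]
            for path in best:
                for interior in path[1:-1]:
                    score[interior] += 1.0 / len(best)
    norm = (n - 1) * (n - 2)
    return {u: s / norm for u, s in score.items()}


def hypergeometric_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p for [[a, b], [c, d]] by direct summation
    of the hypergeometric tail."""
    row1, col1, total = a + b, a + c, a + b + c + d
    if total == 0:
        return 1.0
    denom = math.comb(total, col1)
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > total - row1:
            continue
        p += math.comb(row1, k) * math.comb(total - row1, col1 - k) / denom
    return min(p, 1.0)
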