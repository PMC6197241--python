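"""Statistical stage: enrichment, ANOVA, Mantel tests and CCA.

The screen's categorical outcomes (interaction types) are tested for
enrichment among overproducing pairs with per-type one-sided Fisher exact
tests; transfer counts are compared across interaction types with a one-way
ANOVA; and the focal-organism case study correlates distance matrices
(Mantel, Spearman, 999 permutations) and partitions output-flux inertia with
canonical correspondence analysis (CCA) under the screen's log10(x+1)
transform with a 1 mmol/gDCW/h floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Fluxes below this magnitude (mmol/gDCW/h) are zeroed before the log
#: transform, limiting ordination to major fluxes.
FLUX_FILTER = 1.0
DEFAULT_PERMUTATIONS = 999


def transform_fluxes(raw):
    """Zero entries below 1 mmol/gDCW/h, then map x -> log10(x + 1).

    Accepts an array or DataFrame of non-negative flux magnitudes and
    returns the same type. Applying the transform twice is NOT a no-op, so
    callers transform exactly once.
    """
    values = np.asarray(raw, dtype=float)
    if (values < 0).any():
        raise ValueError("transform_fluxes expects non-negative flux magnitudes")
    out = np.where(values < FLUX_FILTER, 0.0, values)
    out = np.log10(out + 1.0)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrichment_test(
    counts_overall: dict[str, int], counts_subset: dict[str, int]
) -> dict[str, float]:
    """Per-category one-sided overrepresentation test of the subset.

    For each category the 2x2 table is {subset, remainder} x {this category,
    other categories}; the remainder is overall minus subset. Zero-margin
    tables give p = 1.
    """
    total_overall = sum(counts_overall.values())
    total_subset = sum(counts_subset.values())
    if total_subset > total_overall:
        raise ValueError("subset counts exceed overall counts")
    pvalues: dict[str, float] = {}
    for category in counts_overall:
        a = counts_subset.get(category, 0)
        c = counts_overall[category] - a
        if c < 0:
            raise ValueError(f"subset exceeds overall for category {category!r}")
        b = total_subset - a
        d = (total_overall - total_subset) - c
        pvalues[category] = fisher_greater(a, b, c, d)
    return pvalues


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def transfer_count_anova(groups: dict[str, list[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over transfer counts grouped by
    interaction type; returns (F, p).

    Degenerate edge cases are pinned: zero between-group variance gives
    (0, 1); zero within-group variance with distinct means gives (inf, 0).
    """
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >=2 groups with >=2 observations each")
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_between = len(samples) - 1
    df_within = sum(len(s) for s in samples) - len(samples)
    if ss_between <= 1e-300:
        return 0.0, 1.0
    if ss_within <= 1e-300:
        return float("inf"), 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return float(F), p


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    ok: bool = True
    message: str = ""


def _spearman_from_ranks(rx: np.ndarray, vec: np.ndarray) -> float:
    ry = sps.rankdata(vec)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    return float((rxc * ryc).sum() / denom)


def mantel_test(
    matrix_x,
    matrix_y,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test between two row-aligned feature matrices.

    Euclidean distance matrices are computed for each input; the statistic is
    the Spearman rank correlation between their condensed lower triangles.
    Significance is assessed by permuting the row labels of ``matrix_y``:
    p = (1 + #{permuted r >= observed r}) / (permutations + 1). A constant
    distance matrix makes r undefined; the result is flagged not-ok instead
    of raising.
    """
    X = np.asarray(matrix_x, dtype=float)
    Y = np.asarray(matrix_y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("mantel_test requires the same rows in both matrices")
    if X.shape[0] < 4:
        raise ValueError("mantel_test needs at least 4 rows")
    dx = pdist(X)
    dy = pdist(Y)
    if np.ptp(dx) == 0 or np.ptp(dy) == 0:
        return MantelResult(r=float("nan"), p=float("nan"),
                            permutations=permutations, ok=False,
                            message="constant distance matrix; r undefined")
    rx = sps.rankdata(dx)
    r_obs = _spearman_from_ranks(rx, dy)
    Dy = squareform(dy)
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        order = rng.permutation(n)
        dy_perm = Dy[np.ix_(order, order)][iu]
        if _spearman_from_ranks(rx, dy_perm) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (permutations + 1)
    return MantelResult(r=r_obs, p=p, permutations=permutations)


# ---------------------------------------------------------------------------
# Canonical correspondence analysis
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """CCA output: the inertia partition plus scores for plotting.

    ``proportion_constrained`` is the fraction of the response's total
    chi-square inertia explained by the constraint matrix (the headline
    "X constrained NN% of outputs" number).
    """

    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame
    response_scores: pd.DataFrame
    biplot_scores: pd.DataFrame

    @property
    def unconstrained_inertia(self) -> float:
        return self.total_inertia - self.constrained_inertia

    @property
    def proportion_constrained(self) -> float:
        return self.constrained_inertia / self.total_inertia


def cca(response, constraints) -> OrdinationResult:
    """Canonical correspondence analysis of a non-negative response matrix.

    The response is chi-square transformed (correspondence-analysis
    residuals), regressed on the row-weighted, centered constraints, and the
    fitted part eigen-decomposed; constrained + unconstrained inertia equals
    the total chi-square inertia exactly (orthogonal projection). Collinear
    constraint columns are dropped with a warning.
    """
    Y = np.asarray(response, dtype=float)
    X = np.asarray(constraints, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("response and constraints must be row-aligned 2-D matrices")
    if (Y < 0).any():
        raise ValueError("CCA response must be non-negative")
    row_ids = (response.index if isinstance(response, pd.DataFrame)
               else pd.RangeIndex(Y.shape[0]))
    col_ids = (response.columns if isinstance(response, pd.DataFrame)
               else pd.RangeIndex(Y.shape[1]))
    con_ids = (constraints.columns if isinstance(constraints, pd.DataFrame)
               else pd.RangeIndex(X.shape[1]))

    total = Y.sum()
    if total <= 0 or (Y.sum(axis=1) <= 0).any() or (Y.sum(axis=0) <= 0).any():
        raise ValueError("CCA requires positive row and column sums")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    total_inertia = float((Qbar ** 2).sum())
    if total_inertia <= 1e-300:
        raise ValueError("CCA response has zero inertia (all row profiles identical)")

    # Row-weighted centering, then weight rows by sqrt(r).
    Xc = X - r @ X
    Z = Xc * np.sqrt(r)[:, None]
    # Orthonormal basis of the constraint space; collinear directions are
    # dropped by the singular-value tolerance (projection is unaffected).
    Uz, sz, _ = np.linalg.svd(Z, full_matrices=False)
    tol = max(Z.shape) * np.finfo(float).eps * (sz.max() if sz.size else 0.0)
    rank_z = int((sz > tol).sum())
    if rank_z < Z.shape[1]:
        logger.warning("CCA: constraints are rank deficient; using %d of %d column(s)",
                       rank_z, Z.shape[1])
    Qk = Uz[:, :rank_z]
    fitted = Qk @ (Qk.T @ Qbar)
    constrained_inertia = float((fitted ** 2).sum())

    U, svals, Vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int((svals > 1e-12).sum())
    U, svals, Vt = U[:, :rank], svals[:rank], Vt[:rank]
    axes = [f"CCA{i + 1}" for i in range(rank)]
    # Site (LC) scores and response scores in the classic CA scalings.
    site = (U * svals) / np.sqrt(r)[:, None]
    resp = Vt.T / np.sqrt(c)[:, None]
    # Biplot scores: correlations of constraint columns with the site axes.
    biplot = np.zeros((X.shape[1], rank))
    for j in range(X.shape[1]):
        zj = Z[:, j]
        nz = np.linalg.norm(zj)
        if nz > 0:
            biplot[j] = (zj @ U) / nz
    return OrdinationResult(
        eigenvalues=svals ** 2,
        total_inertia=total_inertia,
        constrained_inertia=constrained_inertia,
        site_scores=pd.DataFrame(site, index=row_ids, columns=axes),
        response_scores=pd.DataFrame(resp, index=col_ids, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=con_ids, columns=axes),
    )
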