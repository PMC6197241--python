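# Methods

## Model and scope

The package screens pairs of genome-scale metabolic models (GSMMs) for the
metabolic consequences of co-culture under an anaerobic diet. A GSMM is a
stoichiometric matrix **S** with flux bounds `lb ≤ v ≤ ub` and a biomass
objective; growth is predicted by flux balance analysis (FBA),

    max c·v   s.t.   S v = 0,   lb ≤ v ≤ ub,

followed by parsimonious FBA (pFBA, the "mtf" variant): the biomass flux is
fixed at its FBA optimum and Σ|v| is minimized, linearized by splitting each
flux into non-negative forward/backward parts. pFBA returns a single,
biologically parsimonious flux vector, which makes large screens comparable
across pairs. Simulations with biomass flux ≤ 0.001 h⁻¹ are treated as
non-growth and excluded downstream.

Two organisms are merged through a shared **lumen** compartment and no host
compartment: each organism-level exchange `met[e] ↔ ∅` becomes a transport
`met[e] ↔ met[u]` with open (±1000) bounds, and one community exchange
`met[u] ↔ ∅` per metabolite connects the lumen to the environment. The diet
constrains only the community boundary, so both members compete for one
nutrient allowance; organism-level biomass bounds are reset to [0, 1000] and
the joint objective is the unweighted sum of the two biomass fluxes. At
optimality the lumen is at steady state: for every metabolite,
`transport_A + transport_B − community_exchange = 0`.

Co-culture outcomes are classified relative to monoculture:

- **biomass effect**: +1 / −1 / 0 for co-culture growth at least 10 % above
  / below / within the monoculture flux; the unordered effect pair maps to
  the six ecological types (neutral, commensal, mutualistic, competitive,
  amensal, parasitic).
- **transfers**: a metabolite secreted into the lumen by one member and
  consumed by the other; the transferred amount is min(|secretion|,
  |uptake|), since the environment may absorb or supply the remainder.
  Categories: *cross fed* (recipient also consumes it in monoculture), *end
  product removal* (donor already secretes it in monoculture), both, or
  *other*.
- **emergent**: secreted by the community but by neither monoculture.
- **overproduced**: community secretion > 1.1 × the additive monoculture
  baseline, with monoculture secretion clamped at ≥ 0 and sub-threshold
  fluxes counted as zero (so emergent ⇒ overproduced holds exactly).

Internal metabolism is abstracted as a directed metabolite graph (edges from
every reactant to every product, reversed too for reversible reactions),
excluding boundary/transport and species-specific biosynthesis subsystems,
deleting highly connected currency metabolites, and cutting within-reaction
cofactor pairs (ATP/ADP, NAD/NADH, …; shipped as editable data files under
`coculture/data/`). After a simulation the graph is pruned to edges whose
reaction carries |flux| ≥ 1e-5 mmol/gDCW/h and to the largest strongly
connected component. Per-metabolite normalized degree and betweenness are
computed on the unweighted topology; hub metabolites sit at or above a
quantile of either metric, optionally intersected with the 13 central-carbon
precursor metabolites.

The statistical stage provides one-sided Fisher enrichment of interaction
types in a subset (per-type 2×2 tables {subset, remainder} × {type, other}),
one-way ANOVA of transfer counts by type, Mantel tests (Euclidean distances,
Spearman on the condensed triangles, 999 row-label permutations with the +1
correction), and canonical correspondence analysis of the output-flux matrix
(chi-square residuals regressed on row-weighted centered constraints; the
constrained/unconstrained split of inertia is an orthogonal projection, so
the parts sum to the total exactly). Flux matrices entering ordination are
filtered (values < 1 mmol/gDCW/h zeroed) and log₁₀(x+1)-transformed.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| viability cutoff | 0.001 | h⁻¹ | minimum biomass flux for a simulation to count |
| effect band | ±10 % | — | biomass-effect classification and overproduction factor |
| transfer threshold | 1e-6 | mmol/gDCW/h | flux below which nothing is "produced"/"consumed" |
| network pruning | 1e-5 | mmol/gDCW/h | minimum |flux| for a graph edge to survive |
| ordination filter | 1.0 | mmol/gDCW/h | fluxes below this are zeroed before log₁₀(x+1) |
| hub quantile | 0.95 | — | cutoff on mean degree/betweenness for hub status |
| solver time limit | 300 | s | per-LP wall clock; timeouts are recorded, not raised |

The transfer threshold sits one order of magnitude below the network-pruning
threshold: small but real cross-feeding is kept while solver noise (HiGHS
feasibility ~1e-9) is excluded. pFBA fixes the objective at `optimum − 1e-6`
rather than exactly, the standard numerical slack for LP solvers; reported
biomass fluxes can therefore sit 1e-6 below the FBA optimum, and tests
compare objectives at 2e-6.

## Synthetic data: what it emulates and what it does not

The generator builds small (≤ 30 reactions) AGORA-convention models —
compartment-suffixed metabolite ids, `EX_*` single-metabolite exchanges on
extracellular species, a biomass objective — so the same parsers, diet
tables and solvers serve synthetic and real inputs. Eight designed scenarios
realize the six interaction types plus emergent and greater-than-additive
production, each with machine-checkable expected outcomes; a deterministic
focal-organism screen couples metabolic outputs to partner donations through
an internal network built on real precursor metabolites (g6p, pep, pyr,
accoa, oaa); and a seeded random-model generator supplies feasible toy LPs
for oracle comparisons.

Degenerate optima are handled by construction rather than by solver luck:

- the *mutualistic* pair's biomass split is pinned because any asymmetric
  split forces extra community-exchange flux that pFBA's Σ|v| minimization
  removes;
- the *competitive* pair pays a flux-forced maintenance drain (2 units of
  glucose, `lb = ub`) per member, so the duplicated overhead caps **every**
  optimal split more than 2× below the −10 % band — the classification is
  split-invariant;
- the *parasitic* optimum is unique because the parasite's yield on the
  stolen intermediate strictly dominates the host's.

Yield coefficients clear each classification band by at least 2×, so green
tests certify the classification logic, not a lucky threshold. What a green
synthetic run does **not** establish: realistic gut taxonomy or AGORA's
reaction content, subsystem vocabulary beyond the exclusion labels, growth
on realistic diets, alternate-optima behaviour of thousand-reaction LPs, or
solver timeouts at screen scale. Published screen-scale numbers depend on
the 773-model collection and are out of desk-scale reach; acceptance is
property-based (exact combinatorics, brute-force LP/graph oracles, designed
scenario recovery, statistical calibration, conservation, determinism).

## Numerical and design choices

- **LP solver**: scipy's HiGHS interface; deterministic single-threaded
  solves make rerun tables byte-identical. Statuses map 0 → optimal,
  2 → infeasible, iteration/time limit → timeout; community screens record
  failures and continue. The solver sits behind a small formulation layer
  (`fba_core._build_lp`), so another LP backend can be substituted.
- **Exchange detection**: a reaction with exactly one metabolite *in an
  external compartment* (`e`/`u`). The compartment requirement keeps
  single-metabolite internal demand reactions (toy biomass drains) from
  being treated as boundary exchanges.
- **Diet semantics**: exchanges named by the diet get its bounds verbatim;
  all other exchanges are closed for uptake but left open for secretion —
  output-flux analyses need secretion unconstrained. Unmatched diet entries
  are skipped with a warning, since one diet serves models with different
  exchange repertoires. Entries are keyed by compartment-stripped base id so
  one diet file serves monocultures (`_e`) and communities (`_u`).
- **Normalized degree** is the distinct-neighbour count over n−1 (bounded in
  [0, 1] even with reciprocal edges); betweenness is normalized by
  (n−1)(n−2) and defined 0 for n < 3. Both are computed on the unweighted
  topology; |flux| is kept as edge weight for reporting. Reverse edges of a
  reversible reaction carry the same |flux| as the forward edges.
- **"Strongest connected component"** is read as the largest strongly
  connected component, with a deterministic tie-break (size, then smallest
  node label).
- **Hub cutoff**: "highest values of each metric" made testable as a
  quantile (default 0.95) on the across-simulation mean of either metric;
  downstream analyses intersect with the precursor list, which dominates the
  outcome. The fixture case study uses 0.5 because its graphs have ~10
  nodes.
- **CCA filter**: sub-threshold fluxes are zeroed rather than columns
  dropped, keeping row/column alignment across constraint matrices; the
  choice is exposed via the transform. Collinear constraint columns are
  dropped by SVD tolerance with a warning. A response with identical row
  profiles has zero inertia and is rejected (the pipeline skips it with a
  warning).
- **Mantel p** uses the +1 correction, `p = (1 + #{r_perm ≥ r}) / (perms+1)`,
  so p is never 0; constant distance matrices yield a flagged
  (not-raised) degenerate result. Every permutation test takes an explicit
  seed.
- **ANOVA** is computed from explicit sums of squares with pinned edge
  cases: zero between-group variance → (F = 0, p = 1); zero within-group
  variance with distinct means → (F = ∞, p = 0).

## Known limitations

- Only the objective value and Σ|v| are optimum-invariant in general; the
  A/B biomass split under the summed objective can be non-unique on models
  not designed for uniqueness. Assertions on individual fluxes are limited
  to fixtures constructed to have unique optima.
- Communities of 3+ organisms are not precluded by the data model but are
  unbuilt and untested.
- The pipeline runs pairs sequentially; pairs are independent units of
  work, so parallel execution would change nothing but wall-clock time.
- Aerobic conditions are just a diet entry; no oxygen-specific handling
  exists.
- Bounds present in input SBML are taken as authoritative; no curation or
  gap-filling is attempted.
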