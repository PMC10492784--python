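# Methods

This note documents the models implemented in `paleodiv`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real fossil data.

## Conventions

Time is measured in Ma before present (larger = older).  All intervals —
rate episodes, preservation bins, stage rows — are half-open
`[older, younger)`.  Rates are events per lineage per Myr.  The packaged
stage table covers the Kasimovian–Valanginian with GTS2020-style boundary
ages; substages are equal early/late halves of their stage.  Analyses of a
window should carry buffer stages on both sides: standing diversity at the
simulation edge otherwise masquerades as an origination burst at the old
edge of the rate grid (see `examples/04_rate_shifts.py`).

## Preservation process

Occurrences of a genus are a Poisson process on its lifespan `(Te, Ts)`:

* **HPP** — constant rate `q`;
* **TPP** — piecewise-constant `q_k` with shifts at stage boundaries (or
  series boundaries for coarser analyses), the model usually selected for
  real occurrence data;
* **NHPP** — within-lineage intensity shaped as a symmetric Beta(2,2) hat
  over the span, scaled so the integrated intensity equals `q·duration`.
  A hat profile encodes the expectation that sampling peaks mid-range;
  the exact within-lineage profile used elsewhere in the literature is not
  standardized, so this form is deliberately isolated behind the
  `PreservationModel` interface and easily swapped.

All likelihoods condition each sampled genus on having produced at least
one occurrence (`− ln(1 − e^{−Q_i})`).  Preservation rates carry a
gamma prior with shape 1.5; a prior rate of 0 means the rate hyperparameter
is itself estimated (a vague exponential hyperprior in the Gibbs sampler,
a flat power prior at MAP time).  Model selection fits each candidate at
fixed times by MAP and compares `−2·logP + 2·(#q parameters)`; per-lineage
rate heterogeneity (a Gamma mixture over lineages) is intentionally not
modelled.

## Two-step Bayesian rate estimation

Joint sampling of times, preservation and rates is avoided deliberately:
the two-step design (times first, rates second) converges quickly on large
datasets and matches how the downstream driver analysis consumes fixed
times.

**Step 1 (`sample_times`).**  The extension of `Ts` beyond the oldest
occurrence (and of `Te` beyond the youngest) has the exact generative
conditional `Exp(q + μ)` truncated at the window edge: an extension of
length δ requires both no occurrences (`e^{−qδ}`) and survival
(`e^{−μδ}`).  Preservation rates are refreshed by conjugate gamma draws
(per TPP bin), with the conditioning factor omitted from the conditionals —
the sampler targets the same approximate posterior that fast Gibbs
implementations of this model use.  Genera flagged extant keep `Te` at the
young window edge (right-censoring).

**Incomplete genus-level sampling.**  Genera with zero fossils are absent
from any occurrence table, and they are disproportionately short-lived, so
event counts per lineage-Myr computed from sampled genera alone
underestimate both rates (by 10–20% under the validation conditions).
Each sampled genus therefore carries Horvitz–Thompson weights computed in
step 1: an event weight `E[1/P(sampled)]` and a separate exposure weight
`E[d/P(sampled)]/E[d]` (two weights because `1/P` is convex in the duration
`d`; using one weight for both tallies over-corrects the exposure).  Both
are Rao-Blackwellized over the posterior of `(Ts, Te, q)`.  With weights in
place the recovered rates are unbiased to within ~3% — the residual is the
familiar heavy-tail property of Horvitz–Thompson estimators (the very
shortest-lived stratum has no sampled representative in any one dataset).

**Step 2 (`rjmcmc_rates`).**  λ(t) and μ(t) are independent
piecewise-constant processes with: a Poisson(1) prior on the number of
shifts (exposed in config), ordered-uniform shift positions, and Gamma(2,2)
priors on segment rates.  Moves per sweep: a conjugate Gibbs refresh of all
segment rates (exact given segment event counts and exposures — this
replaces generic multiplicative rate proposals and mixes faster), a 5-Myr
sliding-uniform shift move, and birth/death dimension moves using the
weighted geometric-mean height split with its standard Jacobian
`(h1+h2)²/h`.  The likelihood is exact: the integral of `N(t)(λ+μ)` comes
from the piecewise-linear cumulative lineage-time, never quadrature.  With
the likelihood switched off the chain reproduces Poisson(1) shift counts
(chi-square) and Gamma(2,2) heights (KS), which validates the
reversible-jump balance end to end.

Times uncertainty is propagated by running the rate sampler over several
posterior draws of the times and pooling the samples — the same pooling
used to combine age-randomized replicates (`combine_replicates`).  Chains
are desk-scaled (10⁴–10⁵ sweeps by default, burn-in 0.10, ~1000 saved
samples); convergence is accepted at ESS > 200 and flagged otherwise rather
than raised, so callers can extend chains.

## Diversity and discrete-bin cross-checks

Lineage-through-time diversity counts genera with `Ts ≥ t > Te`.  The
discrete-bin estimators (Foote's per-capita rates from boundary-crosser
tallies, three-timer completeness `3T/(3T+PT)` pooled over the dataset)
serve as independent cross-checks; a boundary `b` is crossed when
`Ts ≥ b > Te`.  Bins with no bottom crossers propagate as missing, never
as zero, and rate correlations drop two bins at each edge to suppress
edge effects.

## Multivariate birth–death drivers

Predictors are optionally LOWESS-smoothed (δ13C-like series), min–max
rescaled to [0, 1] and linearly interpolated on a 0.1 Myr grid; constant
series are flagged degenerate (their effect is absorbed by the baseline).
The links are `λ(t) = λ0·exp(Σ G_j v_j(t))` and
`λ(t) = λ0·max(0, 1 + Σ G_j v_j(t))`; the linear link clamps at zero and an
event at a zero rate yields −∞.  The integral uses trapezoidal rates on the
grid times the exact per-interval lineage-time, so the all-`G`-zero case
reduces to the constant-rate likelihood exactly.

Each `G_j` has a horseshoe prior `N(0, τ²κ_j²)` with half-Cauchy local
scales `κ_j` and one global `τ` per rate vector, sampled by
parameter-expanded inverse-gamma Gibbs steps (geometric ergodicity).  The
shrinkage weight is the standard "1 − shrinkage factor",
`w_j = E[1 − 1/(1 + τ²κ_j²)]`, reported in [0, 1] with `w > 0.5` read as
signal.  `G` moves by a two-component Metropolis mixture (a fixed local
step and a step scaled to the current prior scale, so collapsed components
can escape and the heavy prior tails are explored), plus a "ridge" move
that shifts one `G` and compensates the baseline to break the strong
`λ0`–`G` posterior correlation of the exponential link.

Link choice uses stepping-stone marginal likelihoods on a reduced
temperature ladder `β_k = (k/K)^{1/0.3}` with a common simplified prior for
both links (log-normal baselines, standard-normal `G`), so the Bayes factor
compares the links rather than shrinkage configurations; `|log BF| < 2` is
reported as no clear support.

## Spatial analyses

The geodesic grid is the Voronoi tessellation of a subdivided icosahedron's
vertices; all cells are hexagonal except the 12 pentagons at the original
vertices, which are necessarily smaller (hexagon areas are within ±10% of
their mean at the default resolution; the distortion of the naive
subdivision grows at higher resolutions).  Pair dissimilarity of cells uses
the corrected Forbes index `F′ = a(n+√n)/(a(n+√n)+1.5bc)`, `n = a+b+c`,
isolated in one function for substitution.  Regionalization runs two
independent methods — PAM (BUILD+SWAP, written here because no installed
library provides k-medoids) with k chosen by silhouette, and greedy
modularity communities on the cell graph weighted by shared-taxon counts —
and returns both labelings with their adjusted-Rand agreement.  The package
never auto-selects final regions; the two labelings are a reference for the
analyst, and all scoring is label-permutation invariant.

MST standardization removes, per time bin, the occupied cell with the
fewest occurrences (ties: the deletion that most shortens the tree, then
cell id) until the great-circle MST length of occupied cell centres meets
the threshold — by default the median of the raw per-bin MST lengths.  The
loop terminates because the cell count strictly decreases; each
standardized bin ends at or below max(raw length, threshold), and the
across-bin variance of MST lengths shrinks.

## What the synthetic data do and do not show

The generator reproduces the statistical structure that matters to these
methods: clustered collections within (region × substage × lithology)
cells, stage/substage age censoring with occasional series-level coarse
dating, heterogeneous preservation, qualifier/subgenus/terrestrial noise
with a truth sidecar, regionally clustered and drifting palaeocoordinates,
and GP-like predictor curves whose correlation length (about a tenth of the
window per unit roughness) leaves ten predictors mutually distinguishable —
over short windows very smooth curves become nearly collinear and no method
can attribute a rate signal among them.  It does not emulate taxonomic
synonymy, spatially structured preservation, lithology-dependent sampling,
or the empirical distribution of collection sizes (exposed as a tunable).
Passing tests therefore demonstrate statistical correctness of the
machinery under the stated generating processes, not robustness to every
bias of the empirical fossil record.

Validation studies condition each simulated replicate on survival and a
minimum sampled size (120 genera), the usual protocol for birth–death
recovery studies, and use problem sizes of a few hundred genera over
15–17 Myr windows so the full suite runs on one CPU in minutes.
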