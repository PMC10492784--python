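# paleodiv

Preservation-corrected Bayesian diversification analysis of fossil
occurrence data.

`paleodiv` is a Python library for palaeobiologists who want to estimate
origination and extinction dynamics of marine invertebrate clades (e.g.
brachiopods and bivalves across the Permian–Triassic mass extinction) from
genus-level occurrence tables, and to ask *what drove them*.  It covers the
whole workflow:

* **Synthetic data with ground truth** — a forward-time birth–death
  simulator with piecewise rates, an inhomogeneous Poisson preservation
  process, and a PBDB-dialect table emitter that injects the real-world
  noise (open-nomenclature qualifiers, bracketed subgenera, terrestrial
  contaminants, stage-censored ages, clustered collections, out-of-range
  records), so every downstream method is testable without any download.
* **Curation** — auditable cleaning rules (qualifier handling, terrestrial
  filter, the >10 Myr age-span rule with the international-stage exemption),
  subgenus resolution, stratigraphic-range density outlier flags, and
  collection-level age randomization into replicate datasets.
* **Preservation models** — HPP / NHPP / TPP likelihoods conditioned on
  sampling, with a gamma(1.5, ·) prior on preservation rates and AIC-style
  model selection.
* **Bayesian birth–death core** — a two-step sampler: (1) Gibbs sampling of
  each genus's true origination/extinction times (*Ts*, *Te*) beyond its
  fossil range, jointly with preservation rates; (2) reversible-jump MCMC
  over piecewise-constant λ(t) and μ(t) with a Poisson prior on the number
  of rate shifts, exact (non-quadrature) likelihood, ESS/HPD diagnostics and
  replicate pooling.  Sampled genera carry Horvitz–Thompson weights so the
  rates refer to the complete fauna, not just the sampled part.
* **Diversity & traditional rates** — lineage-through-time diversity,
  Foote's per-capita rates from boundary crossers, three-timer sampling
  completeness, and edge-trimmed rate correlations.
* **Multivariate birth–death (MBD)** — rates linked to time-continuous
  predictors through exponential or linear links, horseshoe-prior MCMC over
  the correlation parameters *G*, shrinkage weights *w* (signal iff
  *w* > 0.5), and stepping-stone Bayes factors for link choice.
* **Spatial analyses** — geodesic hexagonal binning, the modified Forbes
  dissimilarity, dual regionalization (PAM + network communities), moving
  spatial windows, and minimum-spanning-tree standardization of per-bin
  spatial footprints.

## The model in brief

Occurrences of genus *i* are a Poisson process with rate *q(t)* on its
latent lifespan (*Te_i*, *Ts_i*); lineages originate at rate λ(t)·N(t) and
die at μ(t)·N(t).  The birth–death log-likelihood for piecewise-constant
rates is

    log L = Σ_b log λ(Ts_b) + Σ_d log μ(Te_d) − ∫ N(t)·(λ(t)+μ(t)) dt,

evaluated exactly from the piecewise-linear cumulative lineage-time.  The
extension of *Ts* beyond the oldest fossil (and *Te* beyond the youngest) is
exponential with rate *q + μ*, truncated at the window edge.  In the MBD
model λ(t) = λ0·exp(Σ_j Gλ_j·v_j(t)) with predictors *v_j* rescaled to
[0, 1] on a 0.1 Myr grid, and each *G* carries a horseshoe prior whose
shrinkage weight scores the correlation.

## Worked example

`examples/04_rate_shifts.py` simulates a few hundred genera over
254–237 Ma with a 5× extinction spike at 246–244 Ma, samples
preservation-corrected times and runs the reversible-jump rate sampler on a
buffered analysis window:

```
sampled genera: 232; preservation q posterior mean 1.05 (true 1.0)

 age    lambda_mean   mu_mean   mu_95%HPD
 252.0      0.224      0.141   (0.101, 0.179)
 250.0      0.214      0.141   (0.104, 0.179)
 248.0      0.214      0.141   (0.101, 0.179)
 246.0      0.214      0.179   (0.104, 0.319)
 244.0      0.213      0.301   (0.119, 0.411)
 242.0      0.213      0.112   (0.076, 0.152)
 240.0      0.213      0.108   (0.075, 0.138)
 238.0      0.236      0.108   (0.075, 0.138)

posterior mean mu-shift age: 244.3 Ma (true spike 246-244 Ma)
```

μ(t) sits near its background value (0.1 per lineage-Myr) away from the
spike, roughly triples inside it (the 2-Myr pulse is smoothed by the
piecewise-constant posterior mean), and the posterior shift ages cluster at
the spike.  λ(t) stays flat at its true 0.2.  The other scripts in `examples/` walk
through simulation, curation, preservation model choice, diversity and
per-capita rates, MBD driver detection and spatial standardization, one
capability each.

A thin CLI wraps the pipeline:
`paleodiv all --config run.yaml --seed 1 --out rundir` executes
simulate → curate → times → rates → diversity → MBD → spatial and persists
every intermediate table plus a JSON run report.

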