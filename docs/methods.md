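# Methods

## Model and assumptions

The package implements a contrast-based fixed-effects network meta-analysis
for aggregate two-arm trial data. Writing d_k for the basic parameter of
treatment k relative to a chosen reference (d_ref ≡ 0), trial i comparing
t(i) with c(i) contributes

    y_i ~ Normal(d_t(i) − d_c(i), se_i²)

on the analysis scale: the identity scale for continuous outcomes (Hgb
change from baseline in g/dL, SF-36 Vitality change in points) and the
natural-log scale for hazard ratios (time to first MACE). All pairwise
contrasts are derived by consistency, d_jk = d_j − d_k. The fixed-effects
assumption — a single true effect per comparison — is deliberate: with one
to a handful of trials per edge, a random-effects heterogeneity variance
would be driven almost entirely by its prior, so it is not offered.

Assumptions inherited from the aggregate-data design: trials are two-arm
(multi-arm inputs are rejected rather than mis-modelled, since their arm
contrasts are correlated), within-trial sampling error is normal with known
SE, and there are no effect modifiers imbalanced across the network. The
evidence networks this package was built around are all stars centred on
the common comparator (ESA or placebo), which makes the indirect
comparisons between peripheral treatments identifiable but leaves no loops
on which inconsistency could be tested — hence no node-splitting machinery.

## Priors and sampling

"Non-informative" priors are made concrete as independent Normal(0, 100²)
on each basic parameter, the standard evidence-synthesis convention on both
the mean-difference and log-HR scales. `prior_sd` is configurable;
doubling it from 100 to 200 moves fixture league-table medians by less
than 1e-3 (a tested property), so the data dominate.

With Gaussian likelihood and priors the joint posterior is exactly
multivariate normal with precision A = XᵀWX + I/σ₀² (X the edge-incidence
design matrix over non-reference nodes, W = diag(1/se²)). Each chain
therefore draws independent exact samples μ + L⁻ᵀz with A = LLᵀ, rather
than running a Gibbs scan whose stationary distribution is the same normal.
The conventional run design is kept — 3 chains, 10 000 burn-in draws
(generated and discarded), 50 000 kept iterations per chain, thinning 1 —
so seeded runs are bit-reproducible (chain generators spawned from the
master seed via `numpy.random.SeedSequence`) and convergence is verified
like any MCMC output: plain split-R̂ per parameter, asserted ≤ 1.01 after
every fit, with a diagnostic-carrying error on failure.

Summaries are pooled across chains before taking the median and the
2.5%/97.5% centiles (linear interpolation of order statistics, numpy's
default type-7 rule), then mapped to the reporting scale (exp for HRs) by a
single boundary function shared with the closed-form oracle. League-table
diagonals are exactly 0 (identity) or 1 (exponentiated); full precision is
kept internally and two-decimal rounding is applied only in the
human-readable summary.

## Scale algebra

Printed 95% CIs are converted to SEs as (U − L)/(2z) after mapping bounds
to the analysis scale, with z fixed at 1.959964 (six decimals, not the
textbook 1.96) so CI→SE→CI round-trips are stable to 1e-9. When an input
row carries both a CI and an SE, the CI wins and the SE is cross-checked to
1e-6 — the published inputs are CIs, so the CI-derived route is the one
the analyses actually exercise. Whether the original analyses used
CI-derived SEs or SEs from trial reports is not stated in the publication;
the CI-derived route reproduces every recomputable published result within
two-decimal rounding.

## Closed-form oracle

Under flat priors the posterior mean and covariance equal the weighted
least squares solution (XᵀWX)⁻¹XᵀWy, solved via Cholesky with a
condition-number warning above 1e8 (small dense systems; stability over
speed). On a star this reduces edgewise to inverse-variance pooling, and
the two-edge indirect comparison reduces to the Bucher formula
d_AB = d_AC − d_BC with variances summed. The oracle shares the league
CSV schema (method column "gls") and serves as the independent cross-check
for the sampler: medians and centiles must agree within 3 Monte Carlo
standard errors (≈0.002 on the analysis scale at 150 000 pooled draws).

## Evidence-network handling

Networks are built per outcome and analysis set. Analysis sets are
declarative: a population-tag filter (all patients; ESA non-users at
baseline; prevalent dialysis) plus an explicit node-merge map collapsing
comparator ESAs (darbepoetin, epoetin, rHEpo) onto a single reference
node — explicit because published reports state results "relative to
darbepoetin/epoetin" without fixing the node structure, and both merged and
split configurations are expressible. Exclusion rules are likewise
declarative config entries; the bundled placebo-exclusion rule records its
rationale (treatment-target and dosing differences act as effect modifiers
against placebo but cancel within active-controlled trials) and applies to
the efficacy and cardiovascular outcomes only, never to SF-36 where placebo
is the connecting node. The reference defaults to the most-connected node,
ties broken lexicographically.

## Synthetic data generator

`synthetic_data` emulates exactly what the analysis consumes: per-trial
normal contrasts y ~ Normal(d_t − d_c, se²) on the analysis scale, with SEs
either fixed per edge or derived from event counts via var(log HR) ≈
1/e₁ + 1/e₀ (events ≥ 5 per arm). The bundled MACE-like design mirrors the
real non-dialysis network: three HIF-PHI nodes vs an ESA centre, per-edge
SEs of 0.105/0.203/0.107 matching the precision of the published intervals,
true log HRs at the published point estimates. What it does not emulate:
individual-patient data, survival-time generation, Hgb trajectories,
informative dosing or titration, and between-trial heterogeneity. Passing
recovery and coverage tests therefore show the estimator is correct for the
model it assumes — they cannot show the fixed-effects or
no-effect-modification assumptions hold in any real evidence base.

Recovery experiments refit each replicate with reduced settings (2 chains ×
5000 kept after 1000 burn-in) — ample for an exact Gaussian sampler — with
a switch to the full run design; replicate seeds derive deterministically
from the design seed, and convergence failures are counted and reported,
never hidden. The default acceptance-grade experiment uses 500 replicates
per outcome scale, at which nominal 95% coverage should fall in
[0.93, 0.97] (99% binomial band around 0.95).

## Numerical and degenerate-input choices

- Singular GLS normal matrix (disconnected network) raises, listing
  components; fits refuse disconnected networks up front.
- Zero-width or non-bracketing CIs, non-positive HR bounds, and
  tag-contradicting filters raise validation errors citing the row.
- Empty evidence after filtering raises an explicit empty-evidence error
  naming the exclusion rules applied.
- Node-merge maps must be terminal (no chained relabelling) so filtering is
  idempotent.
- Determinism: identical master seed ⇒ bit-identical draws, league tables,
  and reports.

## Bundled evidence files

The CSVs under `src/hifnma/data/` carry only the vs-reference summaries
printed in the source publication's text (never values read off figures):
the non-dialysis MACE summaries, the non-dialysis SF-36 Vitality summaries,
and the dialysis Hgb summaries. Several of these printed inputs are
themselves pooled NMA summaries of multiple trials; they are stored as
single contrasts, which is exactly the information the star-network
indirect comparisons need. The full per-trial input tables of the original
analyses were published only as supplementary material and are not
reproduced; the two haemoglobin network-structure fixtures used in graph
tests are therefore generated in the test suite with real trial names and
arms but synthetic effect values, and are never used for numerical checks.

## Known limitations

- Two-arm trials only; correlated multi-arm likelihoods are out of scope.
- Fixed effects only; no DerSimonian–Laird or Bayesian random effects.
- No rank probabilities/SUCRA, meta-regression, or inconsistency models
  (star networks have no loops to test).
- Hazard-ratio likelihoods treat the log HR as normal with known SE — the
  standard large-sample approximation for aggregate data.
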