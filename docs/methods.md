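# Methods

## The model

`ramets` analyses repeated-measures census data from a multiannual induced-
defense field experiment on bilberry (*Vaccinium myrtillus*): ten blocks,
four transects per block (two randomly assigned to a methyl-jasmonate
treatment of the transect's first ramet, two to a water control), five
marked ramets per transect at distance classes 0–4 from the treated/
reference ramet, censused three times per season over three years.  Five
responses are modelled — ramet dry mass, the ratio of insect-grazed
leaves, the number of ungulate-browsed shoots, and flower and berry
counts.

Every response is fitted with a means-parameterized GLMM: each treatment
group × study year combination (6 groups × 3 years = 18 cells) has its own
link-scale intercept α[g,y] and — for the within-season responses — its own
seasonal time slope β[g,y].  For observation *j* of ramet *i* in cell *c*,

    η_j = α[c] + β[c]·t_j + u_i (+ ε_j)

with ramet random intercepts u_i ~ N(0, σ_u²) for the repeated measures
and, in the binomial/Poisson families, observation-level random effects
ε_j ~ N(0, σ_ε²) absorbing overdispersion.  Families and links are fixed:
Gaussian/identity for dry mass (on the log2 scale of the allometric
equation), binomial/logit for grazed leaves (successes = grazed leaves,
trials = leaves — the only reading of a "ratio" consistent with a binomial
logit model), Poisson/log for the three count responses.  Browsing counts
are additionally zero-inflated: a latent observation-level Bernoulli(ψ)
"on" state gates the Poisson process, giving
P(y) = (1−ψ)·1{y=0} + ψ·Poisson(y; e^η).  Flower and berry models use one
record per ramet-year (the last census of each season), so seasonal slopes
and zero-inflation do not apply to them.

The intercept contrast α[g,y] − α[control,y] is the group's effect at the
first census of year y; the slope contrast is its effect on within-season
temporal development.  Block is deliberately **not** a model term by
default: with mortality making later-year panels increasingly unbalanced,
block-level random effects are weakly identified and destabilize the fit.
An `include_block` flag exists as an optional extension.

### Control group and distance classes

The control group comprises only the distance-0 ramets of control
transects: every reported comparison is a MeJA group versus the control at
distance 0.  Untreated neighbors on control transects stay in the data
model but are excluded from fitting by default
(`include_control_neighbors` re-adds them as extra groups).

### Seasonal time coding

The three census occasions are coded as season time t ∈ {0, 0.5, 1}
("slot" coding).  An alternative "days" coding, proportional to the year-1
census days {0, 30, 72} (t ∈ {0, 0.417, 1}), is available via
`ModelSpec.season_time_coding`; neither coding is asserted to be the
original analysis's choice.  Slot coding is the default for its symmetry
and because slope *contrasts* (the quantity of interest) only rescale
between the two codings.

## Priors

* Cell intercepts and slopes: Normal(0, precision 0.001), i.e. sd ≈ 31.6
  on the link scale.  The protocol description of this prior as "standard
  deviation 0.001" is read as the BUGS/JAGS precision parameterization: a
  literal sd of 0.001 would pin every coefficient to zero, contradicting
  the stated intent of uninformative priors.  `PriorSpec(coef_sd_is_literal=True)`
  switches to the literal reading for sensitivity analysis.
* σ_u ~ Uniform(0, 100); residual and observation-level scales likewise
  arise from σ ~ Uniform(0, 100) with precision σ⁻² ("the inverse of a
  uniform distribution"); `precision_is_inverse_uniform=True` selects the
  alternative literal reading (precision = 1/U(0,100)).
* ψ ~ Uniform(0, 1).

## Posterior sampling

The sampler is an adaptive Metropolis-within-Gibbs scheme (vectorized
numpy).  Componentwise Gaussian random-walk proposals are used for α, β,
u, ε and the log-scales, with per-component proposal scales tuned toward
44% acceptance during the adaptation phase only; the retained chain runs
with a fixed kernel.  The zero-inflation latent states and ψ are Gibbs
updates (exact conditionals), as are the ε of observations whose count
process is currently "off".  Two extra Metropolis moves handle the weakly
identified directions that make hierarchical models mix slowly: a group
shift (α[g,·] + δ, u of group g's ramets − δ; likelihood-invariant) and,
in overdispersed models, a cell shift (α[c] + δ, ε of cell c's rows − δ).

Chain protocol: 4 chains × 200,000 iterations, first 100,000 discarded as
adaptation, every 20th retained → 20,000 final posterior draws
(`FULL_PROFILE`).  The test suite and worked examples use a desk-scale
profile (`TEST_PROFILE`: 4 × 7,000, discard 2,000, thin 5 → 4,000 draws),
which converges for these models at the default dataset size; problem
sizes throughout the suite (replicate counts, block counts, chain lengths)
are chosen so the whole study runs on a single desktop core in minutes.
Everything is deterministic given the seed (one `SeedSequence` spawned per
chain).

Start values are data-informed (empirical cell means on the link scale,
per-chain jitter) rather than prior draws: with sd-31.6 coefficient priors
a prior draw would start log-link models at rates around e^{±70}, which is
numerically useless, and BUGS-style samplers likewise initialize at typical
values, not prior draws.  A non-finite start is retried up to ten times
(`InitializationError` after that); a chain whose proposals are all
rejected over a 2,000-iteration window raises `SamplingError`.

`sample_posterior(..., prior_only=True)` replaces MCMC by exact ancestral
draws from the joint prior (the prior factorizes), which is what the
prior-recovery tests check.  `fixed={...}` holds chosen hyperparameters at
known values, enabling conjugate closed-form oracle tests.

## Diagnostics

Convergence: classic Gelman–Rubin potential scale reduction factor,
R̂ = sqrt(V/W) with V = (n−1)/n·W + B/n; all monitored parameters must be
below 1.1.  Monitored parameters default to the cell coefficients and
scalar hyperparameters (u and ε can be added via `monitor`).

Posterior shape: the protocol's visual "unimodal, no shoulders" check is
automated as a KDE multimodality screen — Gaussian KDE (Scott bandwidth,
scale-equivariant), local maxima with prominence above 8% of the global
density maximum are counted; more than one mode raises an advisory (not
fatal) flag.  The 8% threshold was chosen so that unimodal posteriors at
realistic draw counts (4,000+) are never flagged while well-separated
mixture components always are; it is a heuristic stand-in for visual
inspection, not a test with guaranteed error rates.

## Contrasts and significance

For each MeJA group, year and component, the control draws are subtracted
from the group draws *draw-by-draw within the same joint posterior sample*
(never across independent runs), and the fractions of difference draws
below and above zero are computed.  The reported two-sided tail
probability is 2·min(frac_below, frac_above) and stars follow
*** < 0.001, ** < 0.01, * < 0.05, (*) < 0.1.  Whether the original
star assignment was one- or two-sided is not determinable from the
protocol text; the two-sided convention matches conventional star
semantics and both raw fractions are always reported so a one-sided
reading can be recovered.  Exact-zero differences (degenerate inputs only)
are split evenly between the sides.  No multiplicity correction is applied
across the 30-per-model contrasts; with ~150 contrasts over five models, a
handful of marginal stars is expected by chance alone.

Under the null scenario this procedure behaves like a two-sided test:
across 50 replicate refits the rate of contrasts with 2·min-tail < 0.05 is
≈5% (checked in the acceptance suite with a cluster-widened binomial
band — the 30 contrasts within one fit share a posterior and are not
independent).

## The synthetic-data generator

`simulate_dataset` draws data forward from exactly the generative
structure the models assume, plus field-design realism the models do not
use: negative-binomial leaf counts (mean 40, dispersion 5) so binomial
trials vary; ramet mortality as a per-year hazard (default 0.1), absorbing
and applied between years, producing the unbalanced later-year panels;
heights uniform on 10–25 cm (the marked-ramet range) with stem diameter
back-solved through the allometric equation from the simulated log2 dry
mass (resampling the height up to 20 times if the implied diameter leaves
0.3–15 mm, then clamping with a warning).

The field-effects scenario injects the reported distance-0 effect values
verbatim as true contrasts (grazing reduced most in year 2, browsing in
year 3, flowers/berries increased in year 3) and scales them by
0.8/0.6/0.4/0.2 for distance classes 1–4, making neighbor effects
monotone in distance.  Control baselines (logit −2.0 + 0.8t for grazing;
log 0.0 + 0.3t browsing; log2 0.0 + 0.3t dry mass; log 1.1 flowers, 0.7
berries; σ_u 0.5–0.8, σ_ε 0.4–0.5, ψ 0.6, σ_resid 0.6) are plausible field
magnitudes chosen once and documented here.  The null scenario zeroes all
contrasts.

What passing tests show — and what they do not: the generator matches the
model family exactly, so recovery and calibration results demonstrate the
correctness of the fitting and contrast machinery, not robustness to
model misspecification (spatial correlation, non-Poisson browsing bursts,
treatment-dependent mortality, observer effects are all absent).

## Known limitations

* The effect tables of the original field study are not reproduction
  targets: its raw data are archived without a printed accession, so all
  quantitative checks run on synthetic data.
* Random-walk MCMC mixes more slowly than gradient-based samplers; the
  zero-inflated model at several times the default data size can need more
  than the desk-scale profile to pass the R̂ < 1.1 screen.  The full-protocol
  profile is always available.
* The dry-mass unit is whatever the allometric calibration used
  ("dry-mass units"); only link-scale differences are interpreted.
* One shared ψ per model (not per group); the protocol text does not
  resolve this, and the latent-state reading adopted here is the standard
  one.
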