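# ramets

Bayesian hierarchical analysis of multiannual induced-defense field
experiments on clonal plants — means-parameterized GLMMs with
overdispersion and zero-inflation, an MCMC protocol with Gelman–Rubin
convergence screening, posterior-contrast significance tables, a
nondestructive allometric dry-mass measure, and a synthetic-data generator
that emulates the field design.

## The problem

Bilberry (*Vaccinium myrtillus*) activates chemical defenses when treated
with methyl jasmonate (MeJA), and neighboring ramets may respond to the
emitted volatiles.  The field design behind this package follows marked
ramets in ten blocks — four transects each, five ramets per transect at
distance classes 0–4 from a treated (or control) focal ramet — through
three censuses per season over three years, recording growth, herbivory
and reproduction.  The statistical questions: does induction reduce insect
grazing and ungulate browsing, does it cost growth or reproduction, how
long do effects last, and how far do they reach along the transect?

## The model

For each response a GLMM in means parameterization: every treatment
group × year cell gets its own link-scale intercept α[g,y] and (for
within-season responses) seasonal slope β[g,y]:

    η_j = α[g,y] + β[g,y]·t_j + u_i + ε_j

with ramet random intercepts u_i ~ N(0, σ_u²), observation-level effects
ε_j ~ N(0, σ_ε²) for overdispersed binomial/Poisson responses, and a
latent Bernoulli(ψ) zero-inflation state for browsing counts.  Families:
Gaussian/identity (log2 dry mass via the allometric equation
log2 DM = 1.41700·log2 DS + 0.97104·log2 H + 0.44153·log2(AS+1) − 7.52070),
binomial/logit (grazed leaves of total leaves), Poisson/log (browsed
shoots, flowers, berries).  Inference is MCMC (4 chains × 200,000,
discard 100,000, thin 20 → 20,000 draws at the full protocol; a desk-scale
profile is the default), convergence is screened at R̂ < 1.1, and effects
are read off by subtracting control posteriors from MeJA-group posteriors
draw-by-draw, with stars from the two-sided tail mass
(\*\*\*<0.001, \*\*<0.01, \*<0.05, (\*)<0.1).

See `docs/methods.md` for assumptions, priors, sampler design and
limitations.

## Worked example

```python
from ramets import CensusGLMM, TEST_PROFILE, scenario_field_effects, simulate_dataset

df, truth = simulate_dataset(scenario_field_effects(seed=1))   # 1800 census rows
res = CensusGLMM(df, "grazed_ratio").fit(TEST_PROFILE.with_seed(1))

print(f"max R-hat: {res.max_rhat():.3f}")
print(res.format_contrasts())
```

prints (abridged to the treated-ramet row):

```
max R-hat: 1.011
group    y1:interc  y1:slope  y2:interc  y2:slope  y3:interc  y3:slope
meja_d0  0.47(*)    -0.52(*)  -2.54***   0.56      -0.98***   0.14
```

Read: grazing on MeJA-treated ramets fell most strongly in year 2 — the
intercept contrast −2.54 means roughly 13× lower odds of a leaf being
grazed than control at that year's first census — the same multiannual
pattern injected by the generator (`truth.true_contrast("grazed_ratio", "meja_d0", 2)` → −2.67).
`res.summary()` gives per-parameter posterior means, sds, credible
intervals and R̂; `res.density_report()` flags non-unimodal posteriors.

The command line mirrors the workflow:

```bash
ramets simulate --scenario field-effects --seed 1 --out obs.csv
ramets fit obs.csv --response dry_mass --profile test --seed 1 --out-dir out/
ramets run-all obs.csv --seed 1 --out-dir out/      # all five responses
ramets recover --scenario null --replicates 20      # type-I calibration
```

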