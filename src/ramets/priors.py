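"""Prior distributions and MCMC run settings.

The analysis protocol uses deliberately uninformative priors:

* treatment-group intercepts and seasonal slopes: Normal(0, precision 0.001),
  i.e. a standard deviation of about 31.6 on the link scale.  The protocol's
  description of this prior as "standard deviation of 0.001" is read as the
  precision parameterization used by BUGS/JAGS-style samplers — a literal
  sd of 0.001 would be an extremely informative prior, contradicting the
  stated intent.  ``coef_sd_is_literal=True`` switches to the literal
  reading for sensitivity analysis.
* random-intercept standard deviation sigma_u ~ Uniform(0, 100).
* residual / observation-level scales: "the inverse of a uniform
  distribution between 0 and 100" — implemented as sigma ~ Uniform(0, 100)
  with precision sigma**-2 (default).  The alternative literal reading
  (precision = 1/Uniform(0, 100)) is available via
  ``precision_is_inverse_uniform=True``.
* zero-inflation probability psi ~ Uniform(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["PriorSpec", "McmcSettings", "FULL_PROFILE", "TEST_PROFILE"]


@dataclass(frozen=True)
class PriorSpec:
    coef_mean: float = 0.0
    coef_precision: float = 0.001
    coef_sd_is_literal: bool = False  # read "sd 0.001" literally
    ranef_sd_upper: float = 100.0  # sigma_u ~ U(0, upper)
    scale_sd_upper: float = 100.0  # sigma_eps, sigma_resid ~ U(0, upper)
    precision_is_inverse_uniform: bool = False  # precision = 1/U(0,100) reading

    @property
    def coef_sd(self) -> float:
        """Prior standard deviation of intercept/slope coefficients."""
        if self.coef_sd_is_literal:
            return self.coef_precision  # the number is an sd in this reading
        return self.coef_precision ** -0.5


@dataclass(frozen=True)
class McmcSettings:
    """Chain-run bookkeeping: chains, iterations, adaptation discard, thinning.

    ``retained_per_chain`` draws survive per chain:
    ``(n_iter - n_adapt_discard) / thin``.
    """

    n_chains: int = 4
    n_iter: int = 200_000
    n_adapt_discard: int = 100_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_adapt_discard:
            raise ValueError("n_iter must exceed n_adapt_discard")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.n_adapt_discard) % self.thin:
            raise ValueError("(n_iter - n_adapt_discard) must be divisible by thin")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.n_adapt_discard) // self.thin

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain

    def with_seed(self, seed: int) -> "McmcSettings":
        return replace(self, seed=int(seed))


#: The full analysis protocol: 4 chains x 200,000 iterations, first 100,000
#: discarded as adaptation, every 20th retained -> 20,000 posterior draws.
FULL_PROFILE = McmcSettings(n_chains=4, n_iter=200_000, n_adapt_discard=100_000, thin=20)

#: Desk-scale profile used by the test-suite and worked examples:
#: 4 chains x 7,000 iterations, 2,000 discarded, thin 5 -> 4,000 draws.
TEST_PROFILE = McmcSettings(n_chains=4, n_iter=7_000, n_adapt_discard=2_000, thin=5)
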