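"""Chain bookkeeping, seeded reproducibility, and posterior-correctness oracles."""

import numpy as np
import pytest

from ramets.model import Design, build_design, response_spec
from ramets.priors import FULL_PROFILE, McmcSettings, PriorSpec
from ramets.sampler import sample_posterior
from tests.conftest import QUICK


def _one_cell_gaussian_design(y: np.ndarray) -> Design:
    """Minimal one-cell Gaussian design (one group, one year, no slope)."""
    spec = response_spec("dry_mass", groups=("control",), years=(1,),
                         has_seasonal_slope=False)
    n = len(y)
    z = np.zeros(n, dtype=np.intp)
    return Design(
        spec=spec, y=np.asarray(y, dtype=float), t=np.zeros(n), cell=z, ramet=z,
        block=z, trials=None, cell_labels=[("control", 1)], ramet_ids=["r0"],
        block_ids=["b0"],
    )


class TestBookkeeping:
    def test_full_protocol_retains_20000(self):
        # 4 chains x (200,000 - 100,000) / 20 = 20,000 final posterior draws
        assert FULL_PROFILE.retained_per_chain == 5000
        assert FULL_PROFILE.retained_total == 20000

    def test_dry_run_draw_counting(self):
        settings = McmcSettings(n_chains=4, n_iter=120, n_adapt_discard=20, thin=5, seed=3)
        d = _one_cell_gaussian_design(np.random.default_rng(0).normal(0, 1, 30))
        s = sample_posterior(d, None, PriorSpec(), settings)
        assert settings.retained_per_chain == 20
        for p in s.parameters:
            assert s.get(p).shape == (4, 20)
        assert s.n_draws_total == settings.retained_total == 80

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iter=100, n_adapt_discard=100)
        with pytest.raises(ValueError):
            McmcSettings(n_iter=101, n_adapt_discard=50, thin=2)


class TestDeterminism:
    def test_same_seed_is_bit_identical(self, small_df):
        d = build_design(small_df, response_spec("browsed_shoots"))
        s1 = sample_posterior(d, None, PriorSpec(), QUICK)
        s2 = sample_posterior(d, None, PriorSpec(), QUICK)
        for p in s1.parameters:
            np.testing.assert_array_equal(s1.get(p), s2.get(p))

    def test_different_seed_differs(self, small_df):
        d = build_design(small_df, response_spec("dry_mass"))
        s1 = sample_posterior(d, None, PriorSpec(), QUICK)
        s2 = sample_posterior(d, None, PriorSpec(), QUICK.with_seed(99))
        assert not np.array_equal(s1.get("sigma_u"), s2.get("sigma_u"))


class TestConjugateOracle:
    def test_normal_mean_matches_closed_form(self):
        """With known residual sd and no random-effect freedom, the cell mean's
        posterior is conjugate-normal; MCMC must match it within 3 MCSE."""
        rng = np.random.default_rng(314)
        n, sigma = 80, 1.0
        y = rng.normal(1.7, sigma, n)
        d = _one_cell_gaussian_design(y)
        pri = PriorSpec()
        settings = McmcSettings(n_chains=4, n_iter=6000, n_adapt_discard=2000, thin=2, seed=8)
        s = sample_posterior(d, None, pri, settings,
                             fixed={"sigma_resid": sigma, "sigma_u": 1e-8})
        draws = s.get("alpha[control,1]", flat=True)

        tau0 = 1.0 / pri.coef_sd**2  # 0.001
        post_prec = tau0 + n / sigma**2
        post_mean = (y.sum() / sigma**2) / post_prec
        post_sd = post_prec**-0.5

        ess = _effective_sample_size(s.get("alpha[control,1]"))
        mcse_mean = draws.std(ddof=1) / np.sqrt(ess)
        mcse_sd = draws.std(ddof=1) * np.sqrt(0.5 / max(ess - 1, 1))
        assert abs(draws.mean() - post_mean) < 3 * mcse_mean
        assert abs(draws.std(ddof=1) - post_sd) < 3 * mcse_sd


def _effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-based ESS (initial positive sequence estimator)."""
    m, n = x.shape
    ess = 0.0
    for c in range(m):
        v = x[c] - x[c].mean()
        acf = np.correlate(v, v, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * v.var())
        tau = 1.0
        for k in range(1, n // 2):
            if acf[k] < 0.05:
                break
            tau += 2.0 * acf[k]
        ess += n / tau
    return ess


class TestPriorSampling:
    def test_prior_only_reproduces_priors(self, small_df):
        d = build_design(small_df, response_spec("browsed_shoots"))
        settings = McmcSettings(n_chains=4, n_iter=4100, n_adapt_discard=100, thin=4, seed=21)
        s = sample_posterior(d, None, PriorSpec(), settings, prior_only=True)
        n = s.n_draws_total
        # sigma_u ~ U(0,100): mean 50, sd 100/sqrt(12)
        se = (100 / np.sqrt(12)) / np.sqrt(n)
        assert abs(np.mean(s.get("sigma_u", flat=True)) - 50.0) < 4 * se
        # psi ~ U(0,1)
        assert abs(np.mean(s.get("psi", flat=True)) - 0.5) < 4 * (1 / np.sqrt(12 * n))
        # alpha ~ N(0, 31.62)
        a = s.get("alpha[control,1]", flat=True)
        assert abs(a.std(ddof=1) - 31.6227766) < 4 * 31.62 / np.sqrt(2 * n)


class TestMonitoring:
    def test_monitor_u_retains_ramet_intercepts(self, small_df):
        d = build_design(small_df, response_spec("dry_mass"))
        s = sample_posterior(d, None, PriorSpec(), QUICK,
                             monitor=["alpha", "sigma_u", "u"])
        u_params = [p for p in s.parameters if p.startswith("u[")]
        assert len(u_params) == d.n_ramets
        assert not any(p.startswith("beta") for p in s.parameters)
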