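"""Design construction, linear predictor and likelihood contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import expit

from ramets.data import records_to_frame
from ramets.model import (
    Design,
    ParameterVector,
    build_design,
    linear_predictor,
    log_prior,
    obs_loglik,
    response_spec,
    zip_logpmf,
)
from ramets.priors import PriorSpec
from tests.test_data import _obs


def _theta_for(design, rng=None, **kw):
    rng = rng or np.random.default_rng(0)
    spec = design.spec
    return ParameterVector(
        alpha=rng.normal(0, 1, design.n_cells),
        beta=rng.normal(0, 0.5, design.n_cells) if spec.has_seasonal_slope else None,
        u=rng.normal(0, 0.4, design.n_ramets),
        sigma_u=0.4,
        eps=rng.normal(0, 0.3, design.n_obs) if spec.overdispersed else None,
        sigma_eps=0.3 if spec.overdispersed else None,
        psi=0.7 if spec.zero_inflated else None,
        sigma_resid=0.8 if spec.family == "gaussian" else None,
        **kw,
    )


class TestBuildDesign:
    def test_means_parameterization_counts(self, field_like_df):
        d = build_design(field_like_df, response_spec("dry_mass"))
        # 6 groups x 3 years -> 18 intercepts and, with slopes on, 18 slopes
        assert d.n_cells == 18
        assert len(d.cell_labels) == 18
        assert d.spec.has_seasonal_slope

    def test_flowers_one_row_per_ramet_year(self, field_like_df):
        d = build_design(field_like_df, response_spec("flowers"))
        per_ramet_year = pd.DataFrame({"ramet": d.ramet, "t": d.t, "cell": d.cell})
        # one record per live ramet-year: the last census only, so no
        # (ramet, cell) pair appears twice and no slope applies
        assert not per_ramet_year.duplicated(["ramet", "cell"]).any()
        assert not d.spec.has_seasonal_slope

    def test_zero_trials_excluded_and_counted(self):
        rows = [_obs(), _obs(ramet_id="Z", n_leaves=0, n_grazed_leaves=0)]
        d = build_design(records_to_frame(rows), response_spec("grazed_ratio"))
        assert d.n_obs == 1
        assert d.exclusions["zero_trials"] == 1

    def test_control_neighbors_excluded_by_default(self, field_like_df):
        d = build_design(field_like_df, response_spec("dry_mass"))
        groups = {d.cell_labels[c][0] for c in d.cell}
        assert "control_d1" not in groups
        d2 = build_design(
            field_like_df, response_spec("dry_mass", include_control_neighbors=True)
        )
        assert d2.n_obs > d.n_obs
        assert any(g.startswith("control_d") for g, _ in d2.cell_labels)

    def test_dead_rows_excluded_and_counted(self, field_like_df):
        d = build_design(field_like_df, response_spec("dry_mass"))
        n_dead = int((~field_like_df["alive"].astype(bool)).sum())
        assert n_dead > 0  # mortality produced unbalanced panels
        assert d.exclusions["dead_or_missing"] > 0

    def test_pure_function_of_inputs(self, field_like_df):
        d1 = build_design(field_like_df, response_spec("browsed_shoots"))
        d2 = build_design(field_like_df, response_spec("browsed_shoots"))
        np.testing.assert_array_equal(d1.y, d2.y)
        np.testing.assert_array_equal(d1.cell, d2.cell)
        np.testing.assert_array_equal(d1.ramet, d2.ramet)

    def test_empty_usable_set_raises(self):
        df = records_to_frame([_obs(alive=False, height_cm=None, stem_diameter_mm=None)])
        with pytest.raises(ValueError, match="no usable"):
            build_design(df, response_spec("dry_mass"))

    def test_unknown_treatment_raises(self):
        df = records_to_frame([_obs()])
        df.loc[0, "treatment"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            build_design(df, response_spec("dry_mass"))

    def test_season_time_codings(self, small_df):
        slot = build_design(small_df, response_spec("dry_mass"))
        days = build_design(small_df, response_spec("dry_mass", season_time_coding="days"))
        assert set(np.unique(slot.t)) == {0.0, 0.5, 1.0}
        assert set(np.unique(days.t)) == {0.0, 30.0 / 72.0, 1.0}


class TestLinearPredictor:
    def test_all_zero_parameters_give_zero(self, field_like_df):
        d = build_design(field_like_df, response_spec("grazed_ratio"))
        theta = ParameterVector(
            alpha=np.zeros(d.n_cells), beta=np.zeros(d.n_cells),
            u=np.zeros(d.n_ramets), sigma_u=1.0, eps=np.zeros(d.n_obs), sigma_eps=1.0,
        )
        assert np.all(linear_predictor(theta, d) == 0.0)

    def test_slope_annihilated_at_t_zero(self, field_like_df):
        d = build_design(field_like_df, response_spec("grazed_ratio"))
        theta = _theta_for(d)
        eta = linear_predictor(theta, d)
        first = d.t == 0.0
        expected = theta.alpha[d.cell] + theta.u[d.ramet] + theta.eps
        np.testing.assert_allclose(eta[first], expected[first], rtol=0, atol=1e-12)

    def test_matches_bruteforce_summation(self, field_like_df):
        d = build_design(field_like_df, response_spec("browsed_shoots"))
        theta = _theta_for(d, rng=np.random.default_rng(5))
        eta = linear_predictor(theta, d)
        for j in [0, 7, d.n_obs // 2, d.n_obs - 1]:
            brute = (
                theta.alpha[d.cell[j]]
                + theta.beta[d.cell[j]] * d.t[j]
                + theta.u[d.ramet[j]]
                + theta.eps[j]
            )
            assert eta[j] == pytest.approx(brute, abs=1e-12)


class TestObsLoglik:
    def test_zip_with_psi_one_is_plain_poisson(self):
        y = np.arange(0, 12, dtype=float)
        lograte = np.full_like(y, np.log(2.3))
        np.testing.assert_allclose(
            zip_logpmf(y, lograte, psi=1.0),
            stats.poisson.logpmf(y, 2.3),
            rtol=1e-12,
        )

    def test_zip_closed_form_at_zero(self):
        # psi=0.5 and e^{-lambda}=0.5: P(0) = 0.5 + 0.5*0.5 = 0.75
        lp = zip_logpmf(np.array([0.0]), np.log(np.log(2.0)) * np.ones(1), psi=0.5)
        assert np.exp(lp[0]) == pytest.approx(0.75, abs=1e-12)

    def test_zip_pmf_sums_to_one(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            psi = rng.uniform(0.05, 1.0)
            lam = rng.uniform(0.1, 30.0)
            y = np.arange(0, 400, dtype=float)
            total = np.exp(zip_logpmf(y, np.full_like(y, np.log(lam)), psi)).sum()
            assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("response", ["dry_mass", "grazed_ratio", "browsed_shoots"])
    def test_density_normalizes_over_response_domain(self, small_df, response):
        d = build_design(small_df, response_spec(response))
        theta = _theta_for(d, rng=np.random.default_rng(9))
        j = 3
        sub = _single_row_design(d, j)
        theta_j = _slice_theta(theta, d, j)
        if response == "dry_mass":
            def dens(v):
                sub.y[0] = v
                return float(np.exp(obs_loglik(theta_j, sub)[0]))
            total, _ = quad(dens, -30, 30, limit=200)
        else:
            hi = int(sub.trials[0]) if response == "grazed_ratio" else 400
            total = 0.0
            for v in range(hi + 1):
                sub.y[0] = v
                total += float(np.exp(obs_loglik(theta_j, sub)[0]))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_illegal_counts_raise(self, small_df):
        d = build_design(small_df, response_spec("grazed_ratio"))
        theta = _theta_for(d)
        d.y[0] = d.trials[0] + 1
        with pytest.raises(ValueError, match="exceed"):
            obs_loglik(theta, d)


def _single_row_design(d, j):
    return Design(
        spec=d.spec, y=d.y[[j]].copy(), t=d.t[[j]], cell=d.cell[[j]],
        ramet=d.ramet[[j]], block=d.block[[j]],
        trials=None if d.trials is None else d.trials[[j]],
        cell_labels=d.cell_labels, ramet_ids=d.ramet_ids, block_ids=d.block_ids,
    )


def _slice_theta(theta, d, j):
    return ParameterVector(
        alpha=theta.alpha, beta=theta.beta, u=theta.u, sigma_u=theta.sigma_u,
        eps=None if theta.eps is None else theta.eps[[j]],
        sigma_eps=theta.sigma_eps, psi=theta.psi, sigma_resid=theta.sigma_resid,
    )


class TestLogPrior:
    def test_coefficient_prior_maximized_at_mean(self, small_df):
        d = build_design(small_df, response_spec("dry_mass"))
        pri = PriorSpec()
        base = _theta_for(d)
        at_mode = _theta_for(d)
        at_mode.alpha = np.zeros_like(base.alpha)
        # zeroing the intercepts can only raise the prior (all else equal)
        assert log_prior(at_mode, pri) >= log_prior(base, pri)

    def test_out_of_support_scale_is_minus_inf(self, small_df):
        d = build_design(small_df, response_spec("dry_mass"))
        theta = _theta_for(d)
        theta.sigma_u = 101.0
        assert log_prior(theta, PriorSpec()) == -np.inf
        theta.sigma_u = -1.0
        assert log_prior(theta, PriorSpec()) == -np.inf

    def test_term_by_term_summation_oracle(self, small_df):
        d = build_design(small_df, response_spec("browsed_shoots"))
        pri = PriorSpec()
        theta = _theta_for(d, rng=np.random.default_rng(17))
        total = log_prior(theta, pri)
        sd = pri.coef_sd
        expected = (
            stats.norm.logpdf(theta.alpha, 0, sd).sum()
            + stats.norm.logpdf(theta.beta, 0, sd).sum()
            - np.log(pri.ranef_sd_upper)
            + stats.norm.logpdf(theta.u, 0, theta.sigma_u).sum()
            - np.log(pri.scale_sd_upper)
            + stats.norm.logpdf(theta.eps, 0, theta.sigma_eps).sum()
        )
        assert total == pytest.approx(expected, rel=1e-12)

    def test_precision_vs_literal_prior_reading(self):
        # default: "0.001" is a precision -> sd = 1/sqrt(0.001)
        assert PriorSpec().coef_sd == pytest.approx(31.6227766, rel=1e-6)
        assert PriorSpec(coef_sd_is_literal=True).coef_sd == 0.001
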