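"""Posterior sampling for the census GLMMs.

The sampler is an adaptive Metropolis-within-Gibbs scheme written directly
in numpy.  Each parameter block is updated componentwise with a Gaussian
random-walk proposal whose scale is tuned toward a 44% acceptance rate
during the adaptation phase (all adaptation iterations are discarded, so the
retained chain is a fixed-kernel Markov chain).  Conditionally conjugate
pieces are Gibbs-sampled exactly: the zero-inflation latent "on" states and
their probability psi, and the observation-level effects on rows whose count
process is currently "off" (their full conditional is the prior).

Two extra Metropolis moves target the weakly identified directions that
make componentwise updates of hierarchical models mix slowly:

* a *group shift* that moves a whole treatment group's intercepts and the
  opposite shift onto its ramet random intercepts (the likelihood is exactly
  invariant along this direction; only the priors decide), and
* a *cell shift* that trades a cell intercept against the observation-level
  effects of its rows, for overdispersed models.

Chain protocol: ``n_chains`` independent chains of ``n_iter`` iterations;
the first ``n_adapt_discard`` are discarded as adaptation, every ``thin``-th
of the remainder is retained.  Everything is deterministic given the seed
(one ``numpy.random.SeedSequence`` spawned per chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Design, ModelSpec, ParameterVector
from .priors import McmcSettings, PriorSpec

__all__ = ["PosteriorSamples", "sample_posterior", "InitializationError", "SamplingError"]

_TARGET_ACCEPT = 0.44  # optimal-ish for componentwise random walks


class InitializationError(RuntimeError):
    """The posterior was non-finite at every attempted starting point."""


class SamplingError(RuntimeError):
    """The chain stopped moving (all proposals rejected over a long window)."""


@dataclass
class PosteriorSamples:
    """Retained posterior draws, indexed (chain, draw) per parameter."""

    draws: dict[str, np.ndarray]
    settings: McmcSettings
    spec: ModelSpec
    cell_labels: list[tuple[str, int]]
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def n_draws_total(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    def get(self, name: str, flat: bool = False) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1) if flat else a

    def rhat(self) -> dict[str, float]:
        """Gelman-Rubin potential scale reduction factor per parameter."""
        from .diagnostics import gelman_rubin

        return {p: gelman_rubin(self, p) for p in self.draws}

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy export: one row per (parameter, chain, draw index)."""
        frames = []
        for p, a in self.draws.items():
            nc, nd = a.shape
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": p,
                        "chain": np.repeat(np.arange(nc), nd),
                        "draw": np.tile(np.arange(nd), nc),
                        "value": a.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# likelihood kernels (normalizing constants that cancel in MH are dropped)
# ---------------------------------------------------------------------------


def _make_row_kernel(design: Design):
    """Return f(eta, z) -> per-row log-likelihood kernel for the family."""
    spec = design.spec
    y = design.y
    if spec.family == "gaussian":
        def kern(eta, z, sigma_resid):
            r = y - eta
            return -0.5 * r * r / (sigma_resid * sigma_resid)
    elif spec.family == "binomial":
        n = design.trials

        def kern(eta, z, sigma_resid):
            return y * eta - n * np.logaddexp(0.0, eta)
    else:  # poisson, optionally gated by the zero-inflation state z
        def kern(eta, z, sigma_resid):
            with np.errstate(over="ignore"):
                ll = y * eta - np.exp(eta)
            if z is not None:
                ll = np.where(z, ll, 0.0)
            return ll

    return kern


class _AdaptiveScale:
    """Per-component proposal scale with decaying Robbins-Monro tuning."""

    def __init__(self, shape, init=0.3):
        self.s = np.full(shape, float(init))

    def adapt(self, accepted, it):
        lr = min(0.25, 5.0 / (1.0 + 0.05 * it))
        self.s *= np.exp(lr * 0.05 * (np.asarray(accepted, dtype=float) - _TARGET_ACCEPT))
        np.clip(self.s, 1e-5, 50.0, out=self.s)


def _cell_link_means(design: Design) -> np.ndarray:
    """Empirical per-cell means on the link scale (start values)."""
    spec = design.spec
    C = design.n_cells
    cnt = np.bincount(design.cell, minlength=C).astype(float)
    ysum = np.bincount(design.cell, weights=design.y, minlength=C)
    with np.errstate(invalid="ignore", divide="ignore"):
        if spec.family == "gaussian":
            m = np.where(cnt > 0, ysum / np.maximum(cnt, 1.0), 0.0)
        elif spec.family == "binomial":
            nsum = np.bincount(design.cell, weights=design.trials, minlength=C)
            p = (ysum + 0.5) / (nsum + 1.0)
            m = np.log(p / (1.0 - p))
        else:
            m = np.log(ysum / np.maximum(cnt, 1.0) + 0.05)
    return np.where(np.isfinite(m), m, 0.0)



def _prior_only_chain(design, priors, settings, rng, record, fixed):
    """Exact ancestral draws from the joint prior, one per retained slot."""
    spec = design.spec
    C, R = design.n_cells, design.n_ramets
    coef_sd, coef_mean = priors.coef_sd, priors.coef_mean
    for _ in range(settings.retained_per_chain):
        sigma_u = fixed.get("sigma_u", rng.uniform(0.0, priors.ranef_sd_upper))
        record["alpha"].append(coef_mean + coef_sd * rng.standard_normal(C))
        if spec.has_seasonal_slope:
            record["beta"].append(coef_mean + coef_sd * rng.standard_normal(C))
        record["u"].append(sigma_u * rng.standard_normal(R))
        record["sigma_u"].append(float(sigma_u))
        if spec.overdispersed:
            record["sigma_eps"].append(
                float(fixed.get("sigma_eps", rng.uniform(0.0, priors.scale_sd_upper)))
            )
        if spec.family == "gaussian":
            record["sigma_resid"].append(
                float(fixed.get("sigma_resid", rng.uniform(0.0, priors.scale_sd_upper)))
            )
        if spec.zero_inflated:
            record["psi"].append(float(rng.uniform(0.0, 1.0)))


def _run_chain(design: Design, priors: PriorSpec, settings: McmcSettings,
               rng: np.random.Generator, record: dict[str, list],
               prior_only: bool = False, fixed: dict[str, float] | None = None):
    fixed = fixed or {}
    spec = design.spec
    y, cell, ramet, t = design.y, design.cell, design.ramet, design.t
    N, C, R = design.n_obs, design.n_cells, design.n_ramets
    G = len(spec.groups)
    Y = len(spec.years)
    if prior_only:
        # the prior factorizes ancestrally, so prior "sampling" is exact
        # i.i.d. ancestral draws with the same retention bookkeeping
        _prior_only_chain(design, priors, settings, rng, record, fixed)
        return
    kern = _make_row_kernel(design)

    has_beta = spec.has_seasonal_slope
    has_eps = spec.overdispersed
    has_zi = spec.zero_inflated
    gaussian = spec.family == "gaussian"

    coef_sd = priors.coef_sd
    coef_mean = priors.coef_mean
    sd_u_hi = priors.ranef_sd_upper
    sd_s_hi = priors.scale_sd_upper

    # group index of each ramet (each ramet belongs to exactly one group)
    group_of_ramet = np.zeros(R, dtype=np.intp)
    group_of_ramet[ramet] = cell // Y
    cell_group = np.arange(C) // Y

    # ----- start values: empirical cell means with per-chain jitter -------
    base_alpha = _cell_link_means(design)
    for _attempt in range(10):
        alpha = base_alpha + 0.3 * rng.standard_normal(C)
        beta = 0.2 * rng.standard_normal(C) if has_beta else None
        u = 0.1 * rng.standard_normal(R)
        sigma_u = fixed.get("sigma_u", float(np.exp(rng.normal(np.log(0.5), 0.3))))
        eps = 0.1 * rng.standard_normal(N) if has_eps else None
        sigma_eps = fixed.get("sigma_eps", float(np.exp(rng.normal(np.log(0.5), 0.3)))) if has_eps else None
        if gaussian:
            resid = y - alpha[cell]
            sigma_resid = fixed.get(
                "sigma_resid", float(np.std(resid) + 0.1) * float(np.exp(rng.normal(0, 0.2)))
            )
        else:
            sigma_resid = None
        if has_zi:
            z = (y > 0) | (rng.random(N) < 0.5)
            psi = float(np.clip(np.mean(y > 0) + rng.normal(0, 0.05), 0.05, 0.95))
        else:
            z, psi = None, None

        def eta_now():
            e = alpha[cell] + u[ramet]
            if has_beta:
                e = e + beta[cell] * t
            if has_eps:
                e = e + eps
            return e

        if np.isfinite(np.sum(kern(eta_now(), z, sigma_resid))):
            break
    else:
        raise InitializationError("posterior non-finite at all attempted start values")

    # ----- adaptive proposal scales ---------------------------------------
    s_alpha = _AdaptiveScale(C)
    s_beta = _AdaptiveScale(C) if has_beta else None
    s_u = _AdaptiveScale(R, init=0.2)
    s_eps = _AdaptiveScale(N, init=0.3) if has_eps else None
    s_gshift = _AdaptiveScale(G, init=0.2)
    s_cshift = _AdaptiveScale(C, init=0.2) if has_eps else None
    s_sig_u = _AdaptiveScale(())
    s_sig_eps = _AdaptiveScale(()) if has_eps else None
    s_sig_res = _AdaptiveScale(()) if gaussian else None

    n_adapt = settings.n_adapt_discard
    thin = settings.thin
    moved = 0  # stall detection over the sampling phase

    for it in range(settings.n_iter):
        adapting = it < n_adapt
        eta = eta_now()
        ll_row = kern(eta, z, sigma_resid)

        # --- alpha (componentwise, grouped by cell) -----------------------
        prop = s_alpha.s * rng.standard_normal(C)
        ll_new = kern(eta + prop[cell], z, sigma_resid)
        d_cell = np.bincount(cell, weights=ll_new - ll_row, minlength=C)
        d_cell += -0.5 * ((alpha + prop - coef_mean) ** 2 - (alpha - coef_mean) ** 2) / coef_sd**2
        acc = np.log(rng.random(C)) < d_cell
        alpha += np.where(acc, prop, 0.0)
        if adapting:
            s_alpha.adapt(acc, it)
        moved += int(acc.sum())
        eta = eta_now()
        ll_row = kern(eta, z, sigma_resid)

        # --- beta ----------------------------------------------------------
        if has_beta:
            prop = s_beta.s * rng.standard_normal(C)
            ll_new = kern(eta + prop[cell] * t, z, sigma_resid)
            d_cell = np.bincount(cell, weights=ll_new - ll_row, minlength=C)
            d_cell += -0.5 * ((beta + prop - coef_mean) ** 2 - (beta - coef_mean) ** 2) / coef_sd**2
            acc = np.log(rng.random(C)) < d_cell
            beta += np.where(acc, prop, 0.0)
            if adapting:
                s_beta.adapt(acc, it)
            moved += int(acc.sum())
            eta = eta_now()
            ll_row = kern(eta, z, sigma_resid)

        # --- u (ramet random intercepts) -----------------------------------
        prop = s_u.s * rng.standard_normal(R)
        ll_new = kern(eta + prop[ramet], z, sigma_resid)
        d_r = np.bincount(ramet, weights=ll_new - ll_row, minlength=R)
        d_r += -0.5 * ((u + prop) ** 2 - u**2) / sigma_u**2
        acc = np.log(rng.random(R)) < d_r
        u += np.where(acc, prop, 0.0)
        if adapting:
            s_u.adapt(acc, it)
        moved += int(acc.sum())
        eta = eta_now()
        ll_row = kern(eta, z, sigma_resid)

        # --- eps (observation-level effects) -------------------------------
        if has_eps:
            if has_zi:
                off = ~z
                # "off" rows: full conditional is the prior
                eps[off] = sigma_eps * rng.standard_normal(int(off.sum()))
                eta = eta_now()
                ll_row = kern(eta, z, sigma_resid)
            prop = s_eps.s * rng.standard_normal(N)
            ll_new = kern(eta + prop, z, sigma_resid)
            d = ll_new - ll_row - 0.5 * ((eps + prop) ** 2 - eps**2) / sigma_eps**2
            acc = np.log(rng.random(N)) < d
            eps += np.where(acc, prop, 0.0)
            if adapting:
                s_eps.adapt(acc, it)
            moved += int(acc.sum())
            eta = eta_now()
            ll_row = kern(eta, z, sigma_resid)

        # --- group shift: alpha[g,:] + d, u[ramets of g] - d ---------------
        d_g = s_gshift.s * rng.standard_normal(G)
        d_alpha = d_g[cell_group]
        pa = -0.5 * ((alpha + d_alpha - coef_mean) ** 2 - (alpha - coef_mean) ** 2) / coef_sd**2
        d_u_shift = d_g[group_of_ramet]
        pu = -0.5 * ((u - d_u_shift) ** 2 - u**2) / sigma_u**2
        d_tot = np.bincount(cell_group, weights=pa, minlength=G)
        d_tot += np.bincount(group_of_ramet, weights=pu, minlength=G)
        acc = np.log(rng.random(G)) < d_tot
        alpha += np.where(acc[cell_group], d_alpha, 0.0)
        u -= np.where(acc[group_of_ramet], d_u_shift, 0.0)
        if adapting:
            s_gshift.adapt(acc, it)

        # --- cell shift: alpha[c] + d, eps[rows of c] - d ------------------
        if has_eps:
            d_c = s_cshift.s * rng.standard_normal(C)
            pa = -0.5 * ((alpha + d_c - coef_mean) ** 2 - (alpha - coef_mean) ** 2) / coef_sd**2
            d_eps = d_c[cell]
            pe = -0.5 * ((eps - d_eps) ** 2 - eps**2) / sigma_eps**2
            d_tot = pa + np.bincount(cell, weights=pe, minlength=C)
            acc = np.log(rng.random(C)) < d_tot
            alpha += np.where(acc, d_c, 0.0)
            eps -= np.where(acc[cell], d_eps, 0.0)
            if adapting:
                s_cshift.adapt(acc, it)

        # --- scale parameters (random walk on log sigma) -------------------
        def _update_sigma(sig, ssq, nterm, scale_obj, upper):
            lsig = np.log(sig)
            lprop = lsig + scale_obj.s * rng.standard_normal()
            sprop = float(np.exp(lprop))
            if sprop >= upper:
                acc1 = False
            else:
                # log target in sigma + Jacobian of the log transform
                cur = -nterm * lsig - 0.5 * ssq / sig**2 + lsig
                new = -nterm * lprop - 0.5 * ssq / sprop**2 + lprop
                acc1 = np.log(rng.random()) < new - cur
            if adapting:
                scale_obj.adapt(1.0 if acc1 else 0.0, it)
            return (sprop if acc1 else sig), acc1

        if "sigma_u" not in fixed:
            sigma_u, a1 = _update_sigma(sigma_u, float(np.sum(u * u)), R, s_sig_u, sd_u_hi)
            moved += int(a1)
        if has_eps and "sigma_eps" not in fixed:
            sigma_eps, a1 = _update_sigma(sigma_eps, float(np.sum(eps * eps)), N, s_sig_eps, sd_s_hi)
            moved += int(a1)
        if gaussian and "sigma_resid" not in fixed:
            resid = y - eta
            sigma_resid, a1 = _update_sigma(
                sigma_resid, float(np.sum(resid * resid)), N, s_sig_res, sd_s_hi
            )
            moved += int(a1)

        # --- zero-inflation latents and psi (exact Gibbs) ------------------
        if has_zi:
            lam = np.exp(np.clip(eta, -700, 700))
            with np.errstate(over="ignore"):
                p_on = psi * np.exp(-lam)
                p_on = p_on / (p_on + (1.0 - psi))
            z = (y > 0) | (rng.random(N) < p_on)
            psi = float(rng.beta(1.0 + z.sum(), 1.0 + N - z.sum()))

        # --- retention and stall detection ---------------------------------
        if not adapting:
            k = it - n_adapt
            if (k + 1) % thin == 0:
                record["alpha"].append(alpha.copy())
                if has_beta:
                    record["beta"].append(beta.copy())
                record["u"].append(u.copy())
                record["sigma_u"].append(sigma_u)
                if has_eps:
                    record["sigma_eps"].append(sigma_eps)
                if gaussian:
                    record["sigma_resid"].append(sigma_resid)
                if has_zi:
                    record["psi"].append(psi)
            if (k + 1) % 2000 == 0:
                if moved == 0:
                    raise SamplingError("no proposal accepted over a 2000-iteration window")
                moved = 0


def sample_posterior(design: Design, spec: ModelSpec | None, priors: PriorSpec,
                     settings: McmcSettings, monitor: Sequence[str] | None = None,
                     prior_only: bool = False,
                     fixed: dict[str, float] | None = None) -> PosteriorSamples:
    """Sample the posterior of a census GLMM.

    Parameters
    ----------
    design : Design
        Built by :func:`ramets.model.build_design`.
    spec : ModelSpec or None
        Defaults to ``design.spec``.
    priors, settings
        Prior specification and chain protocol.
    monitor : sequence of str, optional
        Parameter blocks to retain.  Default: cell intercepts/slopes and the
        scalar hyperparameters (``alpha``, ``beta``, ``sigma_u``,
        ``sigma_eps``, ``sigma_resid``, ``psi`` as applicable).  Add ``"u"``
        to also retain the per-ramet random intercepts.
    prior_only : bool
        Drop the likelihood and sample the joint prior instead (prior
        predictive checking); the design only supplies the model structure.
    fixed : dict, optional
        Hyperparameters to hold at known values instead of sampling them
        (keys among ``sigma_u``, ``sigma_eps``, ``sigma_resid``); useful
        for oracle checks against closed-form posteriors.

    Returns
    -------
    PosteriorSamples
        ``settings.n_chains * (n_iter - n_adapt_discard) / thin`` retained
        draws per parameter, bit-reproducible for a fixed seed.
    """
    spec = spec or design.spec
    base = ["alpha", "sigma_u"]
    if spec.has_seasonal_slope:
        base.append("beta")
    if spec.overdispersed:
        base.append("sigma_eps")
    if spec.family == "gaussian":
        base.append("sigma_resid")
    if spec.zero_inflated:
        base.append("psi")
    monitor = list(monitor) if monitor is not None else base

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    per_chain: list[dict[str, list]] = []
    for c in range(settings.n_chains):
        rec: dict[str, list] = {k: [] for k in set(base) | {"u"}}
        _run_chain(design, priors, settings, np.random.default_rng(seeds[c]), rec,
                   prior_only=prior_only, fixed=fixed)
        per_chain.append(rec)

    nd = settings.retained_per_chain
    draws: dict[str, np.ndarray] = {}

    def _stack(key):
        return np.stack([np.asarray(per_chain[c][key]) for c in range(settings.n_chains)])

    for key in monitor:
        if key not in per_chain[0] or not per_chain[0][key]:
            continue
        arr = _stack(key)  # (chains, draws) or (chains, draws, k)
        if arr.ndim == 2:
            draws[key] = arr
        elif key == "alpha" or key == "beta":
            for k, (g, yr) in enumerate(design.cell_labels):
                draws[f"{key}[{g},{yr}]"] = arr[:, :, k]
        elif key == "u":
            for k, rid in enumerate(design.ramet_ids):
                draws[f"u[{rid}]"] = arr[:, :, k]

    for a in draws.values():
        assert a.shape == (settings.n_chains, nd)

    return PosteriorSamples(
        draws=draws, settings=settings, spec=spec,
        cell_labels=list(design.cell_labels), exclusions=dict(design.exclusions),
    )


def theta_from_draw(samples: PosteriorSamples, design: Design, chain: int, draw: int) -> ParameterVector:
    """Assemble a ParameterVector from one retained draw (monitored blocks only)."""
    d = samples.draws
    alpha = np.array([d[f"alpha[{g},{yr}]"][chain, draw] for g, yr in design.cell_labels])
    beta = None
    if design.spec.has_seasonal_slope:
        beta = np.array([d[f"beta[{g},{yr}]"][chain, draw] for g, yr in design.cell_labels])
    u = np.zeros(design.n_ramets)
    for k, rid in enumerate(design.ramet_ids):
        key = f"u[{rid}]"
        if key in d:
            u[k] = d[key][chain, draw]
    return ParameterVector(
        alpha=alpha, beta=beta, u=u,
        sigma_u=float(d["sigma_u"][chain, draw]),
        sigma_eps=float(d["sigma_eps"][chain, draw]) if "sigma_eps" in d else None,
        psi=float(d["psi"][chain, draw]) if "psi" in d else None,
        sigma_resid=float(d["sigma_resid"][chain, draw]) if "sigma_resid" in d else None,
    )
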