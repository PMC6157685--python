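"""Means-parameterized GLMM specification, design building and likelihoods.

Each of the five census responses is modelled by a generalized linear mixed
model in a "means parameterization": every treatment-group x study-year
combination gets its own intercept (and, for within-season responses, its
own seasonal time slope) on the link scale, rather than deviations from a
reference level.  The linear predictor for observation j of ramet i in
group-year cell c is

    eta_j = alpha[c] + beta[c] * t_j + u_i (+ eps_j)

with u_i ~ Normal(0, sigma_u^2) a ramet-level random intercept (repeated
measures) and eps_j ~ Normal(0, sigma_eps^2) an observation-level random
effect absorbing overdispersion in the binomial and Poisson families.
Families and links are fixed per response:

================  =========  ========  =====  =============  ===========
response          family     link      OLRE   zero-inflated  seas. slope
================  =========  ========  =====  =============  ===========
dry_mass          gaussian   identity  no     no             yes
grazed_ratio      binomial   logit     yes    no             yes
browsed_shoots    poisson    log       yes    yes            yes
flowers           poisson    log       yes    no             no
berries           poisson    log       yes    no             no
================  =========  ========  =====  =============  ===========

Dry mass enters on the log2 scale produced by the allometric equation
(:mod:`ramets.allometry`); the grazed-leaf ratio is Binomial with
successes = grazed leaves and trials = leaves; zero inflation mixes a
point mass at zero with the Poisson: an observation-level Bernoulli(psi)
"on" state gates the count process.  Flower and berry counts are analyzed
once per season from the last census, so seasonal slopes do not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

from . import allometry
from .priors import PriorSpec

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "Design",
    "RESPONSES",
    "DEFAULT_GROUPS",
    "response_spec",
    "build_design",
    "linear_predictor",
    "obs_loglik",
    "log_prior",
    "CensusGLMM",
]

DEFAULT_GROUPS = ("control", "meja_d0", "meja_d1", "meja_d2", "meja_d3", "meja_d4")
CONTROL_NEIGHBOR_GROUPS = ("control_d1", "control_d2", "control_d3", "control_d4")

_FAMILY_LINK = {"gaussian": "identity", "binomial": "logit", "poisson": "log"}

#: Canonical (family, overdispersed, zero_inflated, has_seasonal_slope) per response.
RESPONSES: dict[str, tuple[str, bool, bool, bool]] = {
    "dry_mass": ("gaussian", False, False, True),
    "grazed_ratio": ("binomial", True, False, True),
    "browsed_shoots": ("poisson", True, True, True),
    "flowers": ("poisson", True, False, False),
    "berries": ("poisson", True, False, False),
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one response model.

    ``season_time_coding`` maps the three census occasions to a season-time
    covariate: ``"slot"`` codes them as {0, 0.5, 1}; ``"days"`` codes them
    proportionally to the year-1 census days {0, 30/72, 1}.
    ``include_control_neighbors`` adds the untreated neighbors on control
    transects as extra groups (they are excluded from fitting by default:
    every reported comparison is against the control at distance 0).
    ``include_block`` adds a block-level random intercept; it is off by
    default because block effects were not identifiable under the field
    design's unbalanced later-year panels.
    """

    response: str
    family: str
    link: str
    overdispersed: bool
    zero_inflated: bool
    has_seasonal_slope: bool
    groups: tuple[str, ...] = DEFAULT_GROUPS
    years: tuple[int, ...] = (1, 2, 3)
    season_time_coding: str = "slot"
    include_control_neighbors: bool = False
    include_block: bool = False

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if _FAMILY_LINK.get(self.family) != self.link:
            raise ValueError(f"family {self.family!r} requires link {_FAMILY_LINK.get(self.family)!r}")
        if self.zero_inflated and self.family != "poisson":
            raise ValueError("zero inflation is only supported for the poisson family")
        if self.response in ("flowers", "berries") and (self.zero_inflated or self.has_seasonal_slope):
            raise ValueError("flower/berry models have no zero inflation and no seasonal slope")
        if self.season_time_coding not in ("slot", "days"):
            raise ValueError("season_time_coding must be 'slot' or 'days'")
        if self.include_control_neighbors and not set(CONTROL_NEIGHBOR_GROUPS) <= set(self.groups):
            object.__setattr__(self, "groups", tuple(self.groups) + CONTROL_NEIGHBOR_GROUPS)

    @property
    def season_time_map(self) -> dict[int, float]:
        if self.season_time_coding == "slot":
            return {1: 0.0, 2: 0.5, 3: 1.0}
        return {1: 0.0, 2: 30.0 / 72.0, 3: 1.0}


def response_spec(response: str, **overrides) -> ModelSpec:
    """Canonical ModelSpec for one of the five census responses."""
    family, olre, zi, slope = RESPONSES[response]
    spec = ModelSpec(
        response=response,
        family=family,
        link=_FAMILY_LINK[family],
        overdispersed=olre,
        zero_inflated=zi,
        has_seasonal_slope=slope,
    )
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class Design:
    """Per-observation model arrays built from a validated census table.

    ``cell[j] = group_index * n_years + year_index`` indexes the group-year
    combination of observation j; ``cell_labels`` maps the index back to a
    (group, year) pair.  ``trials`` is present only for the binomial family
    (successes are in ``y``).  ``exclusions`` counts rows dropped for each
    documented reason.
    """

    spec: ModelSpec
    y: np.ndarray
    t: np.ndarray
    cell: np.ndarray
    ramet: np.ndarray
    block: np.ndarray
    trials: np.ndarray | None
    cell_labels: list[tuple[str, int]]
    ramet_ids: list[str]
    block_ids: list[str]
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels)

    @property
    def n_ramets(self) -> int:
        return len(self.ramet_ids)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export of the design for audit."""
        df = pd.DataFrame(
            {
                "group": [self.cell_labels[c][0] for c in self.cell],
                "year": [self.cell_labels[c][1] for c in self.cell],
                "season_time": self.t,
                "ramet_id": [self.ramet_ids[i] for i in self.ramet],
                "block_id": [self.block_ids[b] for b in self.block],
                "y": self.y,
            }
        )
        if self.trials is not None:
            df["trials"] = self.trials
        return df


def _group_of(treatment: str, distance: int, include_control_neighbors: bool) -> str | None:
    if treatment == "meja":
        return f"meja_d{distance}"
    if treatment == "control":
        if distance == 0:
            return "control"
        return f"control_d{distance}" if include_control_neighbors else None
    raise ValueError(f"unknown treatment label {treatment!r}")


def build_design(df: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the per-observation design for one response model.

    Rows are dropped (and counted in ``Design.exclusions``) when the ramet
    is dead or the response fields are null, when binomial trials are zero,
    when the group is not modelled (control-transect neighbors by default),
    or — for flower/berry models — when the census is not the last of the
    year.  Raises ``ValueError`` on an empty usable set or an unknown
    treatment label.
    """
    excl = {"dead_or_missing": 0, "zero_trials": 0, "unmodelled_group": 0, "other": 0}
    year_index = {y: k for k, y in enumerate(spec.years)}
    tmap = spec.season_time_map

    rows = []
    for r in df.itertuples(index=False):
        g = _group_of(str(r.treatment), int(r.distance_class), spec.include_control_neighbors)
        if g is None or g not in spec.groups:
            excl["unmodelled_group"] += 1
            continue
        if int(r.year) not in year_index or int(r.census) not in tmap:
            excl["other"] += 1
            continue
        if not spec.has_seasonal_slope and int(r.census) != max(tmap):
            # flowers/berries: annual records from the last census only
            continue
        alive = (not pd.isna(r.alive)) and bool(r.alive)
        if not alive:
            excl["dead_or_missing"] += 1
            continue
        yv, trials = _response_value(r, spec)
        if yv is None:
            excl["dead_or_missing"] += 1
            continue
        if trials == 0:
            excl["zero_trials"] += 1
            continue
        rows.append((g, int(r.year), tmap[int(r.census)], str(r.ramet_id), str(r.block_id), yv, trials))

    if not rows:
        raise ValueError("no usable observations for this model specification")

    groups = list(spec.groups)
    years = list(spec.years)
    cell_labels = [(g, y) for g in groups for y in years]
    cell_of = {lab: k for k, lab in enumerate(cell_labels)}
    ramet_ids = sorted({r[3] for r in rows})
    block_ids = sorted({r[4] for r in rows})
    ramet_of = {rid: i for i, rid in enumerate(ramet_ids)}
    block_of = {bid: i for i, bid in enumerate(block_ids)}

    y = np.array([r[5] for r in rows], dtype=float)
    t = np.array([r[2] for r in rows], dtype=float)
    cell = np.array([cell_of[(r[0], r[1])] for r in rows], dtype=np.intp)
    ramet = np.array([ramet_of[r[3]] for r in rows], dtype=np.intp)
    block = np.array([block_of[r[4]] for r in rows], dtype=np.intp)
    trials = None
    if spec.family == "binomial":
        trials = np.array([r[6] for r in rows], dtype=float)

    return Design(
        spec=spec, y=y, t=t, cell=cell, ramet=ramet, block=block, trials=trials,
        cell_labels=cell_labels, ramet_ids=ramet_ids, block_ids=block_ids, exclusions=excl,
    )


def _response_value(r, spec: ModelSpec):
    """Extract (response value, trials) from one table row; None when unusable."""
    if spec.response == "dry_mass":
        ds, h, as_ = r.stem_diameter_mm, r.height_cm, r.n_shoots
        if pd.isna(ds) or pd.isna(h) or pd.isna(as_) or ds <= 0 or h <= 0:
            return None, None
        return allometry.log2_dry_mass(float(ds), float(h), int(as_)), None
    if spec.response == "grazed_ratio":
        k, n = r.n_grazed_leaves, r.n_leaves
        if pd.isna(k) or pd.isna(n):
            return None, None
        return float(k), int(n)
    col = {"browsed_shoots": "n_browsed_shoots", "flowers": "n_flowers", "berries": "n_berries"}[spec.response]
    v = getattr(r, col)
    if pd.isna(v):
        return None, None
    return float(v), None


# ---------------------------------------------------------------------------
# parameters, linear predictor, likelihood, prior
# ---------------------------------------------------------------------------


@dataclass
class ParameterVector:
    """One point in parameter space for a given design.

    Link-scale cell intercepts ``alpha`` (and slopes ``beta`` when the model
    has seasonal slopes), ramet random intercepts ``u`` with scale
    ``sigma_u``, observation-level effects ``eps`` with scale ``sigma_eps``
    (overdispersed models), zero-inflation "on" probability ``psi`` and the
    Gaussian residual scale ``sigma_resid``.
    """

    alpha: np.ndarray
    beta: np.ndarray | None
    u: np.ndarray
    sigma_u: float
    eps: np.ndarray | None = None
    sigma_eps: float | None = None
    psi: float | None = None
    sigma_resid: float | None = None
    b_block: np.ndarray | None = None
    sigma_block: float | None = None


def linear_predictor(theta: ParameterVector, design: Design) -> np.ndarray:
    """Link-scale linear predictor eta for every design row."""
    eta = theta.alpha[design.cell] + theta.u[design.ramet]
    if theta.beta is not None:
        eta = eta + theta.beta[design.cell] * design.t
    if theta.eps is not None:
        eta = eta + theta.eps
    if theta.b_block is not None:
        eta = eta + theta.b_block[design.block]
    return eta


def zip_logpmf(y: np.ndarray, log_rate: np.ndarray, psi: float) -> np.ndarray:
    """Zero-inflated Poisson log-pmf: (1-psi)*1{y=0} + psi*Poisson(y; e^eta)."""
    y = np.asarray(y, dtype=float)
    lam = np.exp(log_rate)
    pois = y * log_rate - lam - gammaln(y + 1.0)
    with np.errstate(divide="ignore"):
        out = np.log(psi) + pois
        at_zero = np.logaddexp(np.log1p(-psi) if psi < 1 else -np.inf, np.log(psi) - lam)
    return np.where(y == 0, at_zero, out)


def obs_loglik(theta: ParameterVector, design: Design, spec: ModelSpec | None = None) -> np.ndarray:
    """Per-observation log-likelihood at theta (normalized densities).

    Gaussian: Normal(y; eta, sigma_resid); binomial: Binomial(k; n,
    logit^-1(eta)); Poisson: Poisson(y; e^eta), mixed with a point mass at
    zero when the model is zero-inflated.  Raises on illegal responses
    (negative counts, successes exceeding trials).
    """
    spec = spec or design.spec
    eta = linear_predictor(theta, design)
    y = design.y
    if spec.family == "gaussian":
        return stats.norm.logpdf(y, loc=eta, scale=theta.sigma_resid)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if spec.family == "binomial":
        n = design.trials
        if np.any(y > n):
            raise ValueError("successes exceed trials")
        return stats.binom.logpmf(y, n, expit(eta))
    if spec.zero_inflated:
        return zip_logpmf(y, eta, float(theta.psi))
    return stats.poisson.logpmf(y, np.exp(eta))


def log_prior(theta: ParameterVector, priors: PriorSpec, spec: ModelSpec | None = None) -> float:
    """Joint log prior density, including the hierarchical u and eps terms.

    Out-of-support values (scales outside their uniform ranges, psi outside
    [0, 1]) return ``-inf`` rather than raising.
    """
    sd = priors.coef_sd
    lp = float(np.sum(stats.norm.logpdf(theta.alpha, priors.coef_mean, sd)))
    if theta.beta is not None:
        lp += float(np.sum(stats.norm.logpdf(theta.beta, priors.coef_mean, sd)))
    if not 0.0 < theta.sigma_u < priors.ranef_sd_upper:
        return -np.inf
    lp += -np.log(priors.ranef_sd_upper)
    lp += float(np.sum(stats.norm.logpdf(theta.u, 0.0, theta.sigma_u)))
    for scale in (theta.sigma_eps, theta.sigma_resid, theta.sigma_block):
        if scale is not None:
            if not 0.0 < scale < priors.scale_sd_upper:
                return -np.inf
            lp += -np.log(priors.scale_sd_upper)
    if theta.eps is not None:
        lp += float(np.sum(stats.norm.logpdf(theta.eps, 0.0, theta.sigma_eps)))
    if theta.b_block is not None:
        lp += float(np.sum(stats.norm.logpdf(theta.b_block, 0.0, theta.sigma_block)))
    if theta.psi is not None:
        if not 0.0 <= theta.psi <= 1.0:
            return -np.inf
    return lp


# ---------------------------------------------------------------------------
# model object (statsmodels-style surface)
# ---------------------------------------------------------------------------


class CensusGLMM:
    """A means-parameterized GLMM for one census response.

    Parameters
    ----------
    data : pandas.DataFrame
        Validated long-format census table (see :mod:`ramets.data`).
    spec : ModelSpec or str
        Full specification, or a response name (``"dry_mass"``,
        ``"grazed_ratio"``, ``"browsed_shoots"``, ``"flowers"``,
        ``"berries"``) to use the canonical specification.
    priors : PriorSpec, optional

    Examples
    --------
    >>> from ramets import CensusGLMM, simulate_dataset, scenario_field_effects
    >>> df, truth = simulate_dataset(scenario_field_effects(seed=1))
    >>> res = CensusGLMM(df, "dry_mass").fit(seed=1)
    >>> res.max_rhat() < 1.1
    True
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | str, priors: PriorSpec | None = None):
        if isinstance(spec, str):
            spec = response_spec(spec)
        self.data = data
        self.spec = spec
        self.priors = priors or PriorSpec()
        self.design = build_design(data, spec)

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | str, priors: PriorSpec | None = None) -> "CensusGLMM":
        from .data import read_observations

        return cls(read_observations(path), spec, priors)

    def fit(self, settings=None, seed: int | None = None, monitor: Sequence[str] | None = None):
        """Draw from the posterior and return a :class:`~ramets.results.GLMMResults`."""
        from .priors import TEST_PROFILE
        from .results import GLMMResults
        from .sampler import sample_posterior

        settings = settings or TEST_PROFILE
        if seed is not None:
            settings = settings.with_seed(seed)
        samples = sample_posterior(self.design, self.spec, self.priors, settings, monitor=monitor)
        return GLMMResults(self, samples)
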