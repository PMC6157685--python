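"""Convergence and posterior-shape diagnostics.

Convergence is screened with the Gelman-Rubin potential scale reduction
factor (PSRF, "R-hat"): for m chains of n draws each, with W the mean
within-chain variance and B/n the variance of the chain means, the pooled
variance estimate is V = (n-1)/n * W + B/n and R-hat = sqrt(V / W).  Values
below 1.1 are accepted, following common practice for this protocol.

Posterior shape is screened by a kernel-density multimodality heuristic
standing in for the visual density-plot check: a Gaussian KDE is evaluated
on a grid and local maxima with prominence above a fraction of the global
maximum are counted; more than one such mode raises an advisory flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "gelman_rubin",
    "check_convergence",
    "ConvergenceReport",
    "posterior_density_report",
    "DensityReport",
    "RHAT_THRESHOLD",
]

RHAT_THRESHOLD = 1.1


def gelman_rubin(samples, parameter: str | None = None) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``samples`` may be a :class:`~ramets.sampler.PosteriorSamples` (with
    ``parameter`` naming the draws) or a 2-D array of shape
    (n_chains, n_draws).  Requires at least 2 chains and 10 draws per chain.
    Returns ``inf`` for the degenerate case of constant, unequal chains.
    """
    if parameter is not None and hasattr(samples, "get"):
        x = np.asarray(samples.get(parameter), dtype=float)
    else:
        x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected draws of shape (n_chains, n_draws)")
    m, n = x.shape
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin diagnostic requires at least 10 draws per chain")
    chain_means = x.mean(axis=1)
    W = float(np.mean(x.var(axis=1, ddof=1)))
    B_over_n = float(np.var(chain_means, ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else float("inf")
    V = (n - 1) / n * W + B_over_n
    return float(np.sqrt(V / W))


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat against the acceptance threshold."""

    rhat: dict[str, float]
    threshold: float = RHAT_THRESHOLD

    @property
    def failed(self) -> list[str]:
        return [p for p, r in self.rhat.items() if not r < self.threshold]

    @property
    def passed(self) -> bool:
        return not self.failed

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "max_rhat": self.max_rhat,
            "passed": self.passed,
            "failed_parameters": self.failed,
            "rhat": self.rhat,
        }


def check_convergence(samples, threshold: float = RHAT_THRESHOLD) -> ConvergenceReport:
    """R-hat screen over every monitored parameter: pass iff all < threshold."""
    return ConvergenceReport(rhat=samples.rhat(), threshold=threshold)


@dataclass
class DensityReport:
    """KDE summaries and multimodality flags per parameter."""

    n_modes: dict[str, int]
    summaries: dict[str, dict[str, float]]
    flagged: list[str] = field(default_factory=list)
    plot_files: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flagged


def count_modes(draws: np.ndarray, rel_prominence: float = 0.08, gridsize: int = 512) -> int:
    """Number of prominent local maxima of a Gaussian KDE of the draws.

    The prominence threshold is relative to the global density maximum, and
    the KDE uses Scott's rule, so the decision is invariant to affine
    rescaling of the draws.
    """
    x = np.asarray(draws, dtype=float).reshape(-1)
    if np.ptp(x) == 0:
        return 1
    kde = gaussian_kde(x)
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, gridsize)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=rel_prominence * dens.max())
    return max(int(len(peaks)), 1)


def posterior_density_report(samples, rel_prominence: float = 0.08,
                             plot_dir=None) -> DensityReport:
    """Density summary and multimodality screen for every monitored parameter.

    Parameters with more than one prominent KDE mode are flagged (the flag
    is advisory: it marks posteriors that would have failed the visual
    "unimodal, no shoulders" check).  When ``plot_dir`` is given, a density
    plot per parameter is written there as PNG.
    """
    n_modes: dict[str, int] = {}
    summaries: dict[str, dict[str, float]] = {}
    plot_files: list[str] = []
    for p in samples.parameters:
        x = samples.get(p, flat=True)
        n_modes[p] = count_modes(x, rel_prominence=rel_prominence)
        q = np.quantile(x, [0.025, 0.5, 0.975])
        summaries[p] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "q2.5": float(q[0]),
            "median": float(q[1]),
            "q97.5": float(q[2]),
        }
        if plot_dir is not None:
            plot_files.append(_density_plot(x, p, plot_dir))
    flagged = [p for p, k in n_modes.items() if k > 1]
    return DensityReport(n_modes=n_modes, summaries=summaries, flagged=flagged,
                         plot_files=plot_files)


def _density_plot(x: np.ndarray, name: str, plot_dir) -> str:
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 256)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(grid, kde(grid))
    ax.set_title(name)
    ax.set_xlabel("value")
    ax.set_ylabel("posterior density")
    safe = name.replace("[", "_").replace("]", "").replace(",", "_")
    out = pathlib.Path(plot_dir) / f"density_{safe}.png"
    fig.tight_layout()
    fig.savefig(out, dpi=100)
    plt.close(fig)
    return str(out)
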