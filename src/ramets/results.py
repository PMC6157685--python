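"""Results container for fitted census GLMMs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contrasts import ContrastResult, contrast_table, format_table
from .diagnostics import (
    ConvergenceReport,
    DensityReport,
    check_convergence,
    posterior_density_report,
)
from .sampler import PosteriorSamples

__all__ = ["GLMMResults"]


class GLMMResults:
    """Posterior draws plus diagnostics and contrasts for one fitted model.

    Returned by :meth:`ramets.model.CensusGLMM.fit`; carries the retained
    :class:`~ramets.sampler.PosteriorSamples` and exposes posterior
    summaries, the Gelman-Rubin convergence screen, the density-shape
    screen, and the MeJA-vs-control contrast table.
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.spec = model.spec
        self.samples = samples

    # ----- posterior summaries --------------------------------------------

    def posterior_mean(self, parameter: str) -> float:
        return float(np.mean(self.samples.get(parameter, flat=True)))

    def posterior_sd(self, parameter: str) -> float:
        return float(np.std(self.samples.get(parameter, flat=True), ddof=1))

    def credible_interval(self, parameter: str, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed posterior credible interval."""
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.samples.get(parameter, flat=True), [a, 1.0 - a])
        return float(lo), float(hi)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd, equal-tailed interval and R-hat per parameter."""
        rhat = self.samples.rhat()
        rows = []
        for p in self.samples.parameters:
            x = self.samples.get(p, flat=True)
            a = (1.0 - level) / 2.0
            lo, hi = np.quantile(x, [a, 1.0 - a])
            rows.append(
                {
                    "parameter": p,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                    f"ci{level:.0%}_low": float(lo),
                    f"ci{level:.0%}_high": float(hi),
                    "rhat": rhat[p],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # ----- diagnostics -----------------------------------------------------

    def convergence(self, threshold: float = 1.1) -> ConvergenceReport:
        return check_convergence(self.samples, threshold=threshold)

    def max_rhat(self) -> float:
        return self.convergence().max_rhat

    def density_report(self, plot_dir=None) -> DensityReport:
        return posterior_density_report(self.samples, plot_dir=plot_dir)

    # ----- contrasts --------------------------------------------------------

    def contrasts(self, control: str = "control") -> list[ContrastResult]:
        """MeJA-group-vs-control posterior contrasts with significance tiers."""
        return contrast_table(self.samples, self.spec, control=control)

    def contrast_frame(self, control: str = "control") -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.contrasts(control=control)])

    def format_contrasts(self, control: str = "control") -> str:
        return format_table(self.contrasts(control=control))

    # ----- plots ------------------------------------------------------------

    def plot_slopes(self, path=None):
        """Fitted seasonal trends (posterior-mean intercept + slope) per cell."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        spec = self.spec
        fig, axes = plt.subplots(1, len(spec.years), figsize=(3.2 * len(spec.years), 3),
                                 sharey=True, squeeze=False)
        tgrid = np.array([0.0, 0.5, 1.0])
        for ax, yr in zip(axes[0], spec.years):
            for g in spec.groups:
                a = self.posterior_mean(f"alpha[{g},{yr}]")
                b = 0.0
                if spec.has_seasonal_slope:
                    b = self.posterior_mean(f"beta[{g},{yr}]")
                ax.plot(tgrid, a + b * tgrid, marker="o", label=g)
            ax.set_title(f"year {yr}")
            ax.set_xlabel("season time")
        axes[0][0].set_ylabel(f"{spec.response} (link scale)")
        axes[0][-1].legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig

    def __repr__(self) -> str:
        s = self.samples
        return (
            f"<GLMMResults {self.spec.response}: {len(s.parameters)} parameters, "
            f"{s.n_chains} chains x {s.n_draws_per_chain} draws>"
        )
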