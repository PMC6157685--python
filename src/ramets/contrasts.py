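"""Posterior contrasts between MeJA groups and the control.

The significance procedure works directly on posterior draws: for each
MeJA group, year and component (intercept or seasonal slope), the control
group's draws are subtracted draw-by-draw from the MeJA group's draws
within the same joint MCMC run, and the fractions of the difference draws
below and above zero are computed.  Positive effects mean the MeJA-side
ramets had the higher value (or steeper seasonal slope) than the control
at distance 0.

Stars are assigned from the smaller tail fraction.  The reported two-sided
tail probability is ``2 * min(frac_below, frac_above)`` and the tiers are
``*** < 0.001``, ``** < 0.01``, ``* < 0.05``, ``(*) < 0.1``, else ``ns``.
Both raw fractions are always carried in the result so a one-sided reading
can be recovered.  Exact zeros are counted separately and split evenly
between the two sides (relevant only for degenerate inputs).  No
multiplicity correction is applied across the many contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TIERS",
    "ContrastResult",
    "posterior_difference",
    "classify",
    "contrast_table",
    "format_table",
]

#: (two-sided threshold, star label), ordered from most to least stringent.
TIERS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
    (0.1, "(*)"),
)


@dataclass(frozen=True)
class ContrastResult:
    """One MeJA-group-vs-control comparison."""

    group: str
    year: int
    component: str  # "intercept" or "slope"
    effect: float  # posterior mean of the difference, link scale
    frac_below: float
    frac_above: float
    frac_zero: float
    p_tail: float  # 2 * min tail fraction (zeros split evenly)
    tier: str

    @property
    def significant(self) -> bool:
        return self.tier != "ns"


def posterior_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise difference a - b of paired posterior draws.

    Both arrays must come from the same joint posterior sample (identical
    (chain, draw) indexing); shapes must match exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"draw arrays must have equal shape, got {a.shape} vs {b.shape}")
    return a - b


def classify(diff: np.ndarray, group: str = "", year: int = 0,
             component: str = "intercept",
             tiers: tuple[tuple[float, str], ...] = TIERS) -> ContrastResult:
    """Classify a difference sample into a significance tier.

    ``p_tail = 2 * min(frac_below, frac_above)`` (exact zeros split evenly
    between the sides); the tier is the most stringent threshold that
    ``p_tail`` falls under, else ``ns``.
    """
    d = np.asarray(diff, dtype=float).reshape(-1)
    if d.size == 0:
        raise ValueError("empty difference sample")
    n = d.size
    frac_below = float(np.sum(d < 0)) / n
    frac_above = float(np.sum(d > 0)) / n
    frac_zero = 1.0 - frac_below - frac_above
    p_tail = 2.0 * min(frac_below + frac_zero / 2.0, frac_above + frac_zero / 2.0)
    tier = "ns"
    for thr, label in sorted(tiers):
        if p_tail < thr:
            tier = label
            break
    return ContrastResult(
        group=group, year=year, component=component,
        effect=float(np.mean(d)), frac_below=frac_below, frac_above=frac_above,
        frac_zero=frac_zero, p_tail=p_tail, tier=tier,
    )


def contrast_table(samples, spec=None, control: str = "control") -> list[ContrastResult]:
    """All MeJA-group-vs-control contrasts for one fitted model.

    One result per (MeJA group, year, component); slope components are
    omitted for models without seasonal slopes (flowers/berries), matching
    the NA entries of the reported effect tables.  Raises if the control
    group is absent from the samples.
    """
    spec = spec or samples.spec
    groups = [g for g in spec.groups if g != control]
    years = list(spec.years)
    components = [("intercept", "alpha")]
    if spec.has_seasonal_slope:
        components.append(("slope", "beta"))

    if f"alpha[{control},{years[0]}]" not in samples.draws:
        raise ValueError(f"control group {control!r} not present in posterior samples")

    out: list[ContrastResult] = []
    for g in groups:
        for yr in years:
            for comp, prefix in components:
                key_g = f"{prefix}[{g},{yr}]"
                key_c = f"{prefix}[{control},{yr}]"
                if key_g not in samples.draws:
                    continue
                diff = posterior_difference(
                    samples.get(key_g, flat=True), samples.get(key_c, flat=True)
                )
                out.append(classify(diff, group=g, year=yr, component=comp))
    if not out:
        raise ValueError("no MeJA groups present in posterior samples")
    return out


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def format_table(results: list[ContrastResult], years=None) -> str:
    """Plain-text effect table: intercept/slope columns per year, stars
    attached, NA where seasonal slopes are not applicable."""
    df = contrasts_to_frame(results)
    years = years or sorted(df["year"].unique())
    groups = list(dict.fromkeys(df["group"]))
    has_slope = (df["component"] == "slope").any()

    def cell(g, yr, comp):
        sel = df[(df["group"] == g) & (df["year"] == yr) & (df["component"] == comp)]
        if sel.empty:
            return "NA"
        r = sel.iloc[0]
        star = "" if r["tier"] == "ns" else r["tier"]
        return f"{r['effect']:.2f}{star}"

    header = ["group"]
    for yr in years:
        header.append(f"y{yr}:interc")
        if has_slope:
            header.append(f"y{yr}:slope")
    lines = ["\t".join(header)]
    for g in groups:
        row = [g]
        for yr in years:
            row.append(cell(g, yr, "intercept"))
            if has_slope:
                row.append(cell(g, yr, "slope"))
        lines.append("\t".join(row))
    return "\n".join(lines)
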