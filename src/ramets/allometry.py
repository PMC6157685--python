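"""Nondestructive dry-mass estimation for bilberry ramets.

Ramet dry mass is estimated from three field-measurable size variables —
stem diameter at ground level (DS, mm), ramet height (H, cm) and the number
of annual shoots (AS) — through a published log-linear allometric equation:

    log2(DM) = 1.41700*log2(DS) + 0.97104*log2(H) + 0.44153*log2(AS + 1) - 7.52070

The coefficients come from a prior destructive-harvest calibration study and
are treated as fixed constants here; they are not re-estimated.  The +1
inside the shoot-count term makes AS = 0 a legal input.  The dry-mass unit
is whatever unit the calibration used ("dry-mass units" throughout this
package); only ratios and link-scale differences matter for the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "COEF_DIAMETER",
    "COEF_HEIGHT",
    "COEF_SHOOTS",
    "INTERCEPT",
    "SizeMeasures",
    "log2_dry_mass",
    "dry_mass",
    "solve_diameter",
]

COEF_DIAMETER = 1.41700
COEF_HEIGHT = 0.97104
COEF_SHOOTS = 0.44153
INTERCEPT = -7.52070


@dataclass(frozen=True)
class SizeMeasures:
    """Size measurements of one ramet at one census.

    Attributes
    ----------
    stem_diameter_mm : float
        Stem diameter at ground level (DS), millimetres.  Must be > 0.
    height_cm : float
        Ramet height from ground to crown (H), centimetres.  Must be > 0.
    n_shoots : int
        Number of annual shoots (AS).  Must be >= 0.
    """

    stem_diameter_mm: float
    height_cm: float
    n_shoots: int

    def __post_init__(self) -> None:
        if not self.stem_diameter_mm > 0:
            raise ValueError(f"stem_diameter_mm must be > 0, got {self.stem_diameter_mm}")
        if not self.height_cm > 0:
            raise ValueError(f"height_cm must be > 0, got {self.height_cm}")
        if self.n_shoots < 0:
            raise ValueError(f"n_shoots must be >= 0, got {self.n_shoots}")


def log2_dry_mass(stem_diameter_mm, height_cm=None, n_shoots=None):
    """log2 dry mass predicted from size measures.

    Accepts scalars, arrays, or a single :class:`SizeMeasures` as the first
    argument.  Raises ``ValueError`` when diameter or height is not strictly
    positive (log undefined) or shoot count is negative.
    """
    if isinstance(stem_diameter_mm, SizeMeasures):
        m = stem_diameter_mm
        stem_diameter_mm, height_cm, n_shoots = m.stem_diameter_mm, m.height_cm, m.n_shoots
    ds = np.asarray(stem_diameter_mm, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    as_ = np.asarray(n_shoots, dtype=float)
    if np.any(ds <= 0) or np.any(h <= 0):
        raise ValueError("stem diameter and height must be strictly positive")
    if np.any(as_ < 0):
        raise ValueError("shoot count must be non-negative")
    out = (
        COEF_DIAMETER * np.log2(ds)
        + COEF_HEIGHT * np.log2(h)
        + COEF_SHOOTS * np.log2(as_ + 1.0)
        + INTERCEPT
    )
    return out if out.ndim else float(out)


def dry_mass(stem_diameter_mm, height_cm=None, n_shoots=None):
    """Dry mass (2 raised to :func:`log2_dry_mass`); strictly positive."""
    out = np.exp2(log2_dry_mass(stem_diameter_mm, height_cm, n_shoots))
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def solve_diameter(target_log2_dm, height_cm, n_shoots):
    """Invert the allometry for stem diameter at a target log2 dry mass.

    Used by the synthetic-data generator to back-solve plausible size
    measures from a simulated dry mass.  Vectorized.
    """
    h = np.asarray(height_cm, dtype=float)
    as_ = np.asarray(n_shoots, dtype=float)
    if np.any(h <= 0) or np.any(as_ < 0):
        raise ValueError("height must be > 0 and shoot count >= 0")
    log2_ds = (
        np.asarray(target_log2_dm, dtype=float)
        - COEF_HEIGHT * np.log2(h)
        - COEF_SHOOTS * np.log2(as_ + 1.0)
        - INTERCEPT
    ) / COEF_DIAMETER
    out = np.exp2(log2_ds)
    return out if out.ndim else float(out)
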