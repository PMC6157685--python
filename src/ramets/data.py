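"""Observation data model and long-format census table I/O.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per ramet per census (long format, chosen to match repeated-measures
modelling), using the column schema in :data:`SCHEMA`.  A lightweight
:class:`RametObservation` dataclass is provided for single-record use.

Design conventions
------------------
* Dead ramets keep their rows with ``alive=False`` and null measurements;
  model fitting drops the null rows, which is how ramet mortality produces
  increasingly unbalanced panels in later study years.
* Time within a season is carried as ``days_since_treatment`` (year-1
  censuses at 0/30/72 days; later years map their three census occasions to
  the same slots).  Calendar dates are not stored.
* Berry counts start at the second census of year 1 (they were not counted
  at the very first census), so ``n_berries`` must be null at
  (year 1, census 1).
* CSV on disk: UTF-8, comma-separated, header row, null encoded as an
  empty field.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA",
    "COLUMNS",
    "RametObservation",
    "FormatError",
    "ValidationError",
    "read_observations",
    "write_observations",
    "validate_observations",
    "records_to_frame",
    "frame_to_records",
]

#: Column -> pandas dtype of the long-format census table, in file order.
SCHEMA: dict[str, str] = {
    "block_id": "string",
    "transect_id": "string",
    "treatment": "string",  # {"control", "meja"}, assigned per transect
    "distance_class": "int64",  # 0 treated/reference, 1: 10-40cm ... 4: 400-530cm
    "ramet_id": "string",
    "year": "int64",  # study year, 1-based
    "census": "int64",  # within-season occasion, 1..3
    "days_since_treatment": "int64",
    "height_cm": "float64",
    "stem_diameter_mm": "float64",
    "n_shoots": "Int64",
    "n_leaves": "Int64",
    "n_grazed_leaves": "Int64",
    "n_browsed_shoots": "Int64",
    "n_flowers": "Int64",
    "n_berries": "Int64",
    "alive": "boolean",
}

COLUMNS: tuple[str, ...] = tuple(SCHEMA)

TREATMENTS = ("control", "meja")
COUNT_COLUMNS = (
    "n_shoots",
    "n_leaves",
    "n_grazed_leaves",
    "n_browsed_shoots",
    "n_flowers",
    "n_berries",
)


class FormatError(ValueError):
    """The file does not have the documented column set."""


class ValidationError(ValueError):
    """One or more rows violate a data-model invariant.

    ``errors`` holds ``(row_index, message)`` pairs; row indices refer to
    0-based positions in the table (header excluded).
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        shown = "; ".join(f"row {i}: {m}" for i, m in errors[:20])
        more = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{len(errors)} invalid row(s): {shown}{more}")


@dataclass
class RametObservation:
    """One ramet at one census occasion."""

    block_id: str
    transect_id: str
    treatment: str
    distance_class: int
    ramet_id: str
    year: int
    census: int
    days_since_treatment: int
    height_cm: float | None
    stem_diameter_mm: float | None
    n_shoots: int | None
    n_leaves: int | None
    n_grazed_leaves: int | None
    n_browsed_shoots: int | None
    n_flowers: int | None
    n_berries: int | None
    alive: bool


def records_to_frame(records: Iterable[RametObservation]) -> pd.DataFrame:
    """Build a schema-conformant DataFrame from RametObservation records."""
    names = [f.name for f in dataclass_fields(RametObservation)]
    rows = [{n: getattr(r, n) for n in names} for r in records]
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return _coerce(df)


def frame_to_records(df: pd.DataFrame) -> list[RametObservation]:
    """Convert a schema-conformant DataFrame to RametObservation records."""
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        for k, v in d.items():
            if v is pd.NA or (isinstance(v, float) and np.isnan(v)):
                d[k] = None
            elif SCHEMA.get(k) == "Int64" and v is not None:
                d[k] = int(v)
        out.append(RametObservation(**d))
    return out


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=list(COLUMNS))
    return df.astype(SCHEMA)


def validate_observations(df: pd.DataFrame) -> list[tuple[int, str]]:
    """Check every row against the data-model invariants.

    Returns ``(row_index, message)`` pairs for offending rows; an empty list
    means the table is valid.  Checks performed:

    * ``treatment`` in {control, meja}; ``distance_class`` in 0..4;
      ``census`` in 1..3; ``year`` >= 1; ``days_since_treatment`` >= 0
    * all counts >= 0; ``n_grazed_leaves <= n_leaves`` where both present
    * ``height_cm > 0`` and ``stem_diameter_mm > 0`` on rows with
      ``alive=True`` (dead rows may be null)
    * ``n_berries`` null at (year 1, census 1)
    * mortality is absorbing: once a ramet is recorded dead it stays dead
      at every later census
    """
    errs: list[tuple[int, str]] = []

    def flag(mask: pd.Series, msg: str) -> None:
        for i in np.flatnonzero(np.asarray(mask.fillna(False), dtype=bool)):
            errs.append((int(i), msg))

    flag(~df["treatment"].isin(TREATMENTS), "treatment must be 'control' or 'meja'")
    flag(~df["distance_class"].between(0, 4), "distance_class must be in 0..4")
    flag(~df["census"].between(1, 3), "census must be in 1..3")
    flag(df["year"] < 1, "year must be >= 1")
    flag(df["days_since_treatment"] < 0, "days_since_treatment must be >= 0")
    for col in COUNT_COLUMNS:
        flag(df[col] < 0, f"{col} must be >= 0")
    both = df["n_grazed_leaves"].notna() & df["n_leaves"].notna()
    flag(both & (df["n_grazed_leaves"] > df["n_leaves"]), "n_grazed_leaves exceeds n_leaves")
    alive = df["alive"].fillna(False).astype(bool)
    flag(alive & ~(df["height_cm"] > 0), "height_cm must be > 0 for live ramets")
    flag(alive & ~(df["stem_diameter_mm"] > 0), "stem_diameter_mm must be > 0 for live ramets")
    flag(
        (df["year"] == 1) & (df["census"] == 1) & df["n_berries"].notna(),
        "n_berries must be null at (year 1, census 1)",
    )

    # absorbing mortality: sort each ramet's rows by (year, census) and make
    # sure alive never switches back from False to True
    order = df.assign(_pos=np.arange(len(df))).sort_values(["ramet_id", "year", "census"])
    for _, g in order.groupby("ramet_id", sort=False):
        a = g["alive"].fillna(False).astype(bool).to_numpy()
        bad = np.flatnonzero(~a[:-1] & a[1:])
        for j in bad:
            errs.append((int(g["_pos"].iloc[j + 1]), "ramet recorded alive after death"))
    errs.sort(key=lambda e: e[0])
    return errs


def read_observations(path, *, validate: bool = True) -> pd.DataFrame:
    """Read a long-format census CSV, validating the data-model invariants.

    Raises :class:`FormatError` if the header does not contain the
    documented columns, and :class:`ValidationError` (listing offending
    rows) if any row violates an invariant.
    """
    df = pd.read_csv(path, dtype={"block_id": str, "transect_id": str, "ramet_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = _coerce(df)
    if validate:
        errs = validate_observations(df)
        if errs:
            raise ValidationError(errs)
    return df


def write_observations(df_or_records, path) -> None:
    """Write observations to CSV (documented header, stable column order).

    Accepts a schema-conformant DataFrame or an iterable of
    :class:`RametObservation`.  An empty collection yields a header-only
    file.  Nulls are written as empty fields.
    """
    if isinstance(df_or_records, pd.DataFrame):
        df = _coerce(df_or_records.copy())
    else:
        df = records_to_frame(df_or_records)
    df.to_csv(path, index=False)
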