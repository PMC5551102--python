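"""Tabular input/output: individual flowering observations and species traits.

Two tables drive the analysis.  The observation table holds one row per
individual plant (species, stem diameter in cm, whether it bore flowers,
optionally its sex).  The species trait table holds one row per species:
family, sex expression (dioecious/cosexual), leaf habit (deciduous/evergreen),
fruit type (fleshy/dry), the 95th percentile of measured stem diameters
(a robust stand-in for maximum size), the sample size, and — once estimated —
the relative size at which half the individuals flower (``s50``).

A transcription of the 30-species study table is bundled with the package and
returned by :func:`load_study_table`.

Both tables are plain :class:`pandas.DataFrame` objects; the functions here
validate the schema and the enum levels on the way in and out.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

OBS_COLUMNS = ("species", "diameter_cm", "flowered")
TRAIT_COLUMNS = (
    "species",
    "family",
    "s50",
    "sex_expression",
    "leaf_habit",
    "fruit_type",
    "dbh95_cm",
    "n_obs",
)

SEX_EXPRESSION_LEVELS = frozenset({"dioecious", "cosexual"})
LEAF_HABIT_LEVELS = frozenset({"deciduous", "evergreen"})
FRUIT_TYPE_LEVELS = frozenset({"fleshy", "dry"})
SEX_LEVELS = frozenset({"male", "female", "unknown"})

_BOOL_MAP = {
    "0": False, "1": True,
    "true": True, "false": False,
}


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")


def _parse_flowered(values: pd.Series) -> np.ndarray:
    out = np.empty(len(values), dtype=bool)
    for i, v in enumerate(values):
        if isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
            continue
        key = str(v).strip().lower()
        if key not in _BOOL_MAP:
            raise ValidationError(
                f"cannot parse flowered value {v!r} in row {i} "
                "(accepted: 0, 1, true, false)"
            )
        out[i] = _BOOL_MAP[key]
    return out


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an individual-level observation CSV.

    Required columns: ``species``, ``diameter_cm``, ``flowered`` (0/1 or
    true/false).  Optional column ``sex`` with levels male/female/unknown;
    missing entries become ``unknown``.  Row order is preserved.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty observation file: {path}") from exc
    _require_columns(df, OBS_COLUMNS, path)

    species = df["species"].astype(str)
    if (species.str.strip() == "").any():
        row = int(np.argmax((species.str.strip() == "").to_numpy()))
        raise ValidationError(f"empty species id in row {row}")

    diam = pd.to_numeric(df["diameter_cm"], errors="coerce").to_numpy(dtype=float)
    bad = ~(diam > 0)
    if bad.any():
        row = int(np.argmax(bad))
        raise ValidationError(
            f"non-positive or unparseable diameter_cm in row {row} "
            f"(value {df['diameter_cm'].iloc[row]!r})"
        )

    flowered = _parse_flowered(df["flowered"])

    if "sex" in df.columns:
        sex = df["sex"].fillna("unknown").astype(str).str.strip().str.lower()
        unknown = set(sex) - SEX_LEVELS
        if unknown:
            raise ValidationError(f"unknown sex value(s): {sorted(unknown)}")
    else:
        sex = pd.Series(["unknown"] * len(df))

    return pd.DataFrame(
        {
            "species": species.to_numpy(),
            "diameter_cm": diam,
            "flowered": flowered,
            "sex": sex.to_numpy(),
        }
    )


def write_observations(table: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table as CSV (flowered encoded 0/1)."""
    out = table.copy()
    out["flowered"] = out["flowered"].astype(int)
    out.to_csv(path, index=False)


def _check_enum(values: pd.Series, levels: frozenset, column: str) -> pd.Series:
    cleaned = values.astype(str).str.strip().str.lower()
    bad = set(cleaned) - levels
    if bad:
        raise ValidationError(
            f"invalid {column} value(s) {sorted(bad)}; "
            f"allowed: {sorted(levels)}"
        )
    return cleaned


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a species trait CSV with the :data:`TRAIT_COLUMNS` schema.

    ``s50`` may be empty (fitting may not have happened yet); every other
    field is required.  A ``genus`` column is derived as the first token of
    the species id.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty trait file: {path}") from exc
    _require_columns(df, TRAIT_COLUMNS, path)

    species = df["species"].astype(str).str.strip()
    if species.duplicated().any():
        dupes = sorted(species[species.duplicated()].unique())
        raise ValidationError(f"duplicate species id(s): {dupes}")

    sex = _check_enum(df["sex_expression"], SEX_EXPRESSION_LEVELS, "sex_expression")
    leaf = _check_enum(df["leaf_habit"], LEAF_HABIT_LEVELS, "leaf_habit")
    fruit = _check_enum(df["fruit_type"], FRUIT_TYPE_LEVELS, "fruit_type")

    dbh95 = pd.to_numeric(df["dbh95_cm"]).to_numpy(dtype=float)
    if not (dbh95 > 0).all():
        raise ValidationError("dbh95_cm must be positive for every species")
    n_obs = pd.to_numeric(df["n_obs"]).to_numpy()
    if not ((n_obs >= 1) & (n_obs == n_obs.astype(int))).all():
        raise ValidationError("n_obs must be a positive integer for every species")
    s50 = pd.to_numeric(df["s50"], errors="coerce").to_numpy(dtype=float)
    if np.any(s50[~np.isnan(s50)] <= 0):
        raise ValidationError("s50, where present, must be positive")

    return pd.DataFrame(
        {
            "species": species.to_numpy(),
            "family": df["family"].astype(str).str.strip().to_numpy(),
            "genus": species.str.split("_").str[0].to_numpy(),
            "s50": s50,
            "sex_expression": sex.to_numpy(),
            "leaf_habit": leaf.to_numpy(),
            "fruit_type": fruit.to_numpy(),
            "dbh95_cm": dbh95,
            "n_obs": n_obs.astype(int),
        }
    )


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trait table as CSV (``genus`` is derived, so not written)."""
    cols = [c for c in TRAIT_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def load_study_table() -> pd.DataFrame:
    """Return the bundled 30-species study table.

    Eleven dioecious and nineteen cosexual woody species from a temperate
    evergreen broad-leaved forest (Kasugayama, Japan), spanning 26 genera in
    18 families, with the published per-species relative size at onset of
    flowering (s50), 95th-percentile stem diameter and sample size.
    """
    with resources.as_file(
        resources.files("precocity.data").joinpath("table1_species.csv")
    ) as p:
        return read_trait_table(p)
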