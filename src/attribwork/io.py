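"""Tidy-CSV readers/writers, packaged reference tables, and schema checks.

All tabular interfaces are UTF-8 CSV with "." decimals and exact documented
headers.  Numbers are serialized at full precision; presentation rounding is
applied only when formatting reports.
"""

from __future__ import annotations

import hashlib
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "load_table1_fixture",
    "load_region_lookup",
    "TABLE1_SHA256",
]


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


_ISO3_RE = re.compile(r"^[A-Z]{3}$")

#: schema name -> (required columns, key columns or None, iso3 columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...] | None]] = {
    "surveys": (("iso3", "year", "prevalence", "sample_size"), None),
    "envelopes": (("cause", "iso3", "year", "sex", "age_group", "measure", "value"),
                  ("cause", "iso3", "year", "sex", "age_group", "measure")),
    "population": (("iso3", "year", "sex", "age_group", "pop"), ("iso3", "year", "sex", "age_group")),
    "transfer_paf": (("pair_id", "iso3", "year", "paf"), ("pair_id", "iso3", "year")),
    "pairs": (("pair_id", "risk_factor", "outcome", "paf_mode", "rr_point", "rr_lo", "rr_hi"), ("pair_id",)),
    "regions": (("iso3", "region"), ("iso3",)),
    "exposure_surface": (("iso3", "year", "prevalence", "se_logit", "extrapolated"), ("iso3", "year")),
    "burden": (("pair_id", "risk_factor", "outcome", "iso3", "year", "sex", "age_group", "measure", "value"),
               ("pair_id", "iso3", "year", "sex", "age_group", "measure")),
    "burden_with_ur": (("pair_id", "year", "measure", "value", "ur_lower", "ur_upper"),
                       ("pair_id", "year", "measure")),
}

# sha256 of the packaged fixture file, pinned so silent edits are caught.
TABLE1_SHA256 = "7379f748a0a06c9e3a558008e10614162fb7507ba18e2b858ce890ef0ee10b74"

_TABLE1_NAME = "table1_who_ilo_2021.csv"
_REGIONS_NAME = "who_regions.csv"


def _check_schema(df: pd.DataFrame, schema: str, where: str) -> pd.DataFrame:
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    columns, keys = SCHEMAS[schema]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing columns {missing} for schema {schema!r}")
    if "iso3" in columns and len(df):
        bad = df.loc[~df["iso3"].astype(str).str.match(_ISO3_RE), "iso3"]
        if len(bad):
            raise SchemaError(
                f"{where}: non-ISO3 country code {bad.iloc[0]!r} at row {int(bad.index[0])}"
            )
    if keys and len(df):
        dup = df.duplicated(subset=list(keys))
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            key_vals = {k: df.iloc[row][k] for k in keys}
            raise SchemaError(f"{where}: duplicated key {key_vals} at row {row}")
    return df[list(columns) + [c for c in df.columns if c not in columns]]


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one tidy CSV table.

    An empty file with valid headers is an empty table, not an error.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    return _check_schema(df, schema, str(path))


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    """Validate and write one tidy CSV table (full-precision floats)."""
    path = Path(path)
    df = _check_schema(df, schema, str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def _packaged(name: str):
    return resources.files("attribwork.data").joinpath(name)


def load_region_lookup() -> dict[str, str]:
    """Packaged WHO-region lookup: iso3 -> {AFR, AMR, SEA, EUR, EMR, WPR}."""
    with resources.as_file(_packaged(_REGIONS_NAME)) as p:
        df = pd.read_csv(p)
    return dict(zip(df["iso3"], df["region"]))


class FixtureIntegrityError(RuntimeError):
    """The packaged reference table failed its integrity checks."""


def load_table1_fixture(verify_checksum: bool = True) -> pd.DataFrame:
    """Load the packaged global attributable-burden reference table.

    The table lists, for each of the 41 risk-outcome pairs, total attributable
    deaths and DALYs for 2000/2010/2016 plus rates per 100 000 working-age
    population, exactly as published.  Validates the checksum, the 41-row
    shape, non-negativity, and that the non-fatal outcomes (hearing loss,
    back/neck pain) carry zero deaths.
    """
    ref = _packaged(_TABLE1_NAME)
    raw = ref.read_bytes()
    if verify_checksum and hashlib.sha256(raw).hexdigest() != TABLE1_SHA256:
        raise FixtureIntegrityError("reference table checksum mismatch; file was modified")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    if len(df) != 41:
        raise FixtureIntegrityError(f"reference table must have 41 pairs, found {len(df)}")
    value_cols = [c for c in df.columns if c.startswith(("deaths_", "daly_"))]
    if (df[value_cols].to_numpy() < 0).any():
        raise FixtureIntegrityError("reference table contains negative values")
    nonfatal = df[df["outcome"].isin(["Other hearing loss", "Back and neck pain"])]
    death_counts = [c for c in value_cols if c.startswith("deaths_") and "rate" not in c]
    if (nonfatal[death_counts].to_numpy() != 0).any():
        raise FixtureIntegrityError("non-fatal outcomes must have zero deaths")
    return df


def table1_long(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reference table reshaped to tidy (pair_id, measure, year, value) rows."""
    if df is None:
        df = load_table1_fixture()
    rows = []
    for measure in ("deaths", "daly"):
        for year in (2000, 2010, 2016):
            col = f"{measure}_{year}"
            for r in df.itertuples(index=False):
                rows.append(
                    {
                        "pair_id": r.pair_id,
                        "risk_factor": r.risk_factor,
                        "outcome": r.outcome,
                        "measure": measure,
                        "year": year,
                        "value": float(getattr(r, col)),
                    }
                )
    return pd.DataFrame(rows)
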