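"""Validated CSV I/O for the survey and budget tables.

All interchange is plain CSV: UTF-8, decimal point, no thousands
separators, coordinates in WGS-84 decimal degrees, dates ISO-8601.
Readers validate the documented schema and unit ranges and report the
offending row on failure; writers serialize floats with six significant
digits or better.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A survey table violates its documented schema."""


def _read(path: str | Path, required: dict[str, str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        logger.warning("%s: empty table", path)
        return df
    for col, kind in required.items():
        if kind == "num" and not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"{path}: column {col!r} must be numeric")
    logger.info("read %s: %d rows", path, len(df))
    return df


def _check_range(df: pd.DataFrame, path, col: str, lo=None, hi=None,
                 strict_lo: bool = False) -> None:
    if df.empty:
        return
    bad = pd.Series(False, index=df.index)
    if lo is not None:
        bad |= df[col] <= lo if strict_lo else df[col] < lo
    if hi is not None:
        bad |= df[col] > hi
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: {col!r} out of range at row {row} (value "
            f"{df.loc[row, col]!r})")


def read_benthic(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"site_id": "str", "year": "num", "transect_id": "str",
                      "taxon": "str", "cover_pct": "num"})
    _check_range(df, path, "cover_pct", lo=0, hi=100)
    return df


def read_fish(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"survey_id": "str", "lat": "num", "lon": "num",
                      "habitat": "str", "depth_m": "num", "year": "num",
                      "species": "str", "phase": "str",
                      "fork_length_cm": "num", "count": "num",
                      "area_m2": "num"})
    _check_range(df, path, "count", lo=0)
    _check_range(df, path, "area_m2", lo=0, strict_lo=True)
    return df


def read_urchins(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"site_id": "str", "density_m2": "num"})
    _check_range(df, path, "density_m2", lo=0)
    return df


def read_sponges(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"site_id": "str", "species": "str",
                      "area_m2_per_m2": "num"})
    _check_range(df, path, "area_m2_per_m2", lo=0)
    return df


def read_substrate(path: str | Path) -> pd.DataFrame:
    df = _read(path, {"site_id": "str", "consolidated_fraction": "num"})
    _check_range(df, path, "consolidated_fraction", lo=0, hi=1)
    return df


def read_sites(path: str | Path) -> pd.DataFrame:
    return _read(path, {"site_id": "str", "subregion": "str",
                        "habitat": "str", "lat": "num", "lon": "num"})


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")
    logger.info("wrote %s: %d rows", path, len(df))
    return path
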