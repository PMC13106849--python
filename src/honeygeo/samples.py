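"""Core data model for honey eDNA samples and mtDNA lineage patterns.

A honey sample pools DNA from every colony that contributed nectar, so a
single sample can amplify one, two or all three of the major *Apis
mellifera* maternal lineages (A, African; C, South-Eastern European; M,
Northern/Western European).  The non-empty subset of ``{A, C, M}``
detected in a sample is its *lineage pattern* (or profile), the unit of
observation for every downstream analysis.

This module provides pattern parsing and canonicalisation, the sample
table reader/writer, deduplication of redundant same-beekeeper-same-year
samples into "unique" samples, frequency tabulation by arbitrary grouping
keys, the historical time-window labelling, and a plain grid-density
export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LineagePattern",
    "HoneySample",
    "PatternParseError",
    "PATTERNS",
    "CODINGS",
    "MACRO_REGIONS",
    "parse_pattern",
    "load_region_map",
    "read_samples",
    "write_samples",
    "dedup_unique",
    "tabulate",
    "assign_time_window",
    "round_half_up",
    "format_percent",
    "grid_density",
]

#: The seven possible lineage patterns, in canonical (alphabetical) form.
PATTERNS: tuple[str, ...] = ("A", "AC", "ACM", "AM", "C", "CM", "M")

#: The five macro-regions of the study design.
MACRO_REGIONS: tuple[str, ...] = ("North", "Central", "South", "Sicily", "Sardinia")

LINEAGES = ("A", "C", "M")


class PatternParseError(ValueError):
    """Raised when a lineage-pattern token cannot be parsed."""


@dataclass(frozen=True)
class LineagePattern:
    """A non-empty subset of the three mtDNA lineages detected in one sample."""

    contains_a: bool
    contains_c: bool
    contains_m: bool

    def __post_init__(self) -> None:
        if not (self.contains_a or self.contains_c or self.contains_m):
            raise PatternParseError("a lineage pattern must contain at least one lineage")

    @property
    def lineages(self) -> frozenset[str]:
        return frozenset(
            l for l, f in zip(LINEAGES, (self.contains_a, self.contains_c, self.contains_m)) if f
        )

    @property
    def canonical(self) -> str:
        """Sorted-string serialization, e.g. ``"AC"`` or ``"ACM"``."""
        return "".join(sorted(self.lineages))

    @property
    def diversity(self) -> int:
        """Number of distinct lineages (1-3)."""
        return int(self.contains_a) + int(self.contains_c) + int(self.contains_m)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


@dataclass(frozen=True)
class HoneySample:
    """One georeferenced, dated honey record with its lineage pattern."""

    sample_id: str
    beekeeper_id: str
    year: int
    latitude: float
    longitude: float
    region: str
    macro_region: str
    pattern: LineagePattern


def parse_pattern(token: str, row: object | None = None) -> LineagePattern:
    """Parse a lineage-pattern token into canonical form.

    Tokens are case- and order-insensitive (``"acm"``, ``"MCA"`` and
    ``"ACM"`` are the same pattern).  Empty tokens, letters outside
    ``{A, C, M}`` and duplicated letters are rejected; ``row`` (if given)
    names the offending sample row in the error message.
    """
    where = "" if row is None else f" (sample row {row!r})"
    if not isinstance(token, str) or not token.strip():
        raise PatternParseError(f"empty lineage pattern token{where}")
    letters = [ch.upper() for ch in token.strip()]
    bad = sorted(set(letters) - set(LINEAGES))
    if bad:
        raise PatternParseError(
            f"invalid lineage letter(s) {''.join(bad)!r} in pattern {token!r}{where}"
        )
    if len(letters) != len(set(letters)):
        raise PatternParseError(f"duplicated lineage letter in pattern {token!r}{where}")
    s = set(letters)
    return LineagePattern("A" in s, "C" in s, "M" in s)


# ---------------------------------------------------------------------------
# Binary codings of patterns (the outcome definitions used throughout).
# "contains-A-or-M" is the complement of "only-C": every non-{C} pattern
# carries at least one of A, M.
CODINGS: Mapping[str, "callable"] = {
    "contains-A": lambda p: "A" in p,
    "contains-C": lambda p: "C" in p,
    "contains-M": lambda p: "M" in p,
    "only-A": lambda p: p == "A",
    "only-C": lambda p: p == "C",
    "only-M": lambda p: p == "M",
    "contains-A-or-M": lambda p: p != "C",
}


def load_region_map(path: str | Path | None = None) -> dict[str, str]:
    """Return the ``region -> macro_region`` lookup.

    By default the packaged Italian table is used; a custom YAML file with
    the same macro-region -> [regions] layout can be supplied instead.
    """
    if path is None:
        text = (resources.files("honeygeo") / "data" / "regions_italy.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    mapping: dict[str, str] = {}
    for macro, regions in raw.items():
        for region in regions:
            if region in mapping:
                raise ValueError(f"region {region!r} listed under two macro-regions")
            mapping[region] = macro
    return mapping


REQUIRED_COLUMNS = (
    "sample_id",
    "beekeeper_id",
    "year",
    "latitude",
    "longitude",
    "region",
    "pattern",
)


def _validate(df: pd.DataFrame, region_map: Mapping[str, str] | None) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing required column(s): {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["beekeeper_id"] = df["beekeeper_id"].astype(str)
    df["year"] = df["year"].astype(int)
    df["latitude"] = df["latitude"].astype(float)
    df["longitude"] = df["longitude"].astype(float)
    df["pattern"] = [
        parse_pattern(tok, row=sid).canonical
        for tok, sid in zip(df["pattern"], df["sample_id"])
    ]
    if "macro_region" not in df.columns or df["macro_region"].isna().any():
        lookup = dict(region_map) if region_map is not None else load_region_map()
        unknown = sorted(set(df["region"]) - set(lookup))
        if unknown:
            raise ValueError(
                f"cannot derive macro_region: unknown region name(s) {unknown}; "
                "provide a macro_region column or a region map"
            )
        df["macro_region"] = df["region"].map(lookup)
    out_lat = ~df["latitude"].between(35.0, 48.0)
    out_lon = ~df["longitude"].between(6.0, 19.0)
    if (out_lat | out_lon).any():
        warnings.warn(
            f"{int((out_lat | out_lon).sum())} sample(s) fall outside the Italian "
            "coordinate window (lat 35-48, lon 6-19)",
            stacklevel=3,
        )
    return df


def read_samples(
    path: str | Path,
    region_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a honey-sample table from CSV or TSV (autodetected by extension).

    Validates the schema, canonicalises patterns, derives ``macro_region``
    from ``region`` when absent, and soft-warns on coordinates outside the
    Italian window.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    return _validate(df, region_map)


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)


def dedup_unique(df: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Reduce to "unique" samples: one per (beekeeper, year), chosen at random.

    Redundant samples (the same beekeeper in the same production year) are
    collapsed by retaining exactly one row per pair, drawn uniformly with
    the given seed.  Rows from distinct years of the same beekeeper are all
    kept.  The output preserves the input row order and is deterministic
    given the seed; the operation is idempotent.
    """
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    groups = df.groupby(["beekeeper_id", "year"], sort=True).indices
    for key in sorted(groups):
        idx = groups[key]
        chosen.append(int(idx[rng.integers(len(idx))]))
    return df.iloc[sorted(chosen)].copy()


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero at the given number of decimals.

    Used for every reported percentage so that printed values follow a
    single documented convention (banker's rounding is never applied to
    output percentages).
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(count: int, total: int) -> float:
    """Percentage in the study's reporting convention.

    One decimal (half-up); values below 1% are reported at two decimals so
    that rare patterns are not rounded to zero.
    """
    pct = 100.0 * count / total
    return round_half_up(pct, 2) if pct < 1.0 else round_half_up(pct, 1)


def tabulate(df: pd.DataFrame, group_by: Sequence[str] | None = None) -> pd.DataFrame:
    """Frequency table of lineage patterns by arbitrary grouping keys.

    For each observed group the table reports the total sample count, the
    count/proportion of each of the seven exact patterns, and the
    count/proportion/reported-percentage of each derived binary coding
    (``contains-A`` ... ``only-M`` and ``contains-A-or-M``).  Groups with
    zero samples are omitted, never zero-filled.  ``group_by=None`` (or an
    empty list) produces a single overall row.

    Proportions are exact; the ``pct_*`` columns follow the one-decimal
    (two decimals below 1%) half-up reporting convention.
    """
    if len(df) == 0:
        raise ValueError("cannot tabulate an empty sample collection")
    group_by = list(group_by or [])
    unknown = [k for k in group_by if k not in df.columns]
    if unknown:
        raise ValueError(f"unknown grouping key(s): {unknown}")

    def summarize(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        row: dict[str, object] = {"n": n}
        counts = g["pattern"].value_counts()
        for pat in PATTERNS:
            c = int(counts.get(pat, 0))
            row[f"n_{pat}"] = c
            row[f"prop_{pat}"] = c / n
        for name, pred in CODINGS.items():
            c = int(g["pattern"].map(pred).sum())
            key = name.replace("-", "_")
            row[f"n_{key}"] = c
            row[f"prop_{key}"] = c / n
            row[f"pct_{key}"] = format_percent(c, n)
        return pd.Series(row)

    if not group_by:
        return summarize(df).to_frame().T.reset_index(drop=True)
    out = (
        df.groupby(group_by, sort=True, observed=True)
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    return out


_WINDOWS = ((1986, 1999, "1986-1999"), (2000, 2009, "2000-2009"), (2010, 2017, "2010-2017"))


def assign_time_window(year: int) -> str:
    """Time-window label for a production year.

    Historical samples are grouped into three windows (1986-1999,
    2000-2009, 2010-2017); years of the main six-year study period
    (2018-2023) are labelled by their literal year.
    """
    year = int(year)
    if not 1986 <= year <= 2023:
        raise ValueError(f"year {year} outside the supported range 1986-2023")
    for lo, hi, label in _WINDOWS:
        if lo <= year <= hi:
            return label
    return str(year)


def grid_density(
    df: pd.DataFrame,
    coding: str = "contains-A",
    cell: float = 0.25,
) -> pd.DataFrame:
    """Counts of coding-positive samples per ``cell``-degree grid cell.

    A plain-text stand-in for GIS density maps: one row per occupied cell
    with its south-west corner coordinates, the total number of samples
    and the number matching the coding.
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    pred = CODINGS[coding]
    lat0 = np.floor(df["latitude"] / cell) * cell
    lon0 = np.floor(df["longitude"] / cell) * cell
    flag = df["pattern"].map(pred).astype(int)
    out = (
        pd.DataFrame({"lat_cell": lat0.round(6), "lon_cell": lon0.round(6), "hit": flag})
        .groupby(["lat_cell", "lon_cell"], sort=True)
        .agg(n=("hit", "size"), n_coding=("hit", "sum"))
        .reset_index()
    )
    return out
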