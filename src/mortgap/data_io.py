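"""Stratified mortality tables: schema, I/O, aggregation, and ESP-2013 weights.

The unit of data exchanged between all pipeline stages is a long-format table
of death counts and person-years exposures over a stratification grid of
(cause, sex, age group, calendar year, region, deprivation band).  Deprivation
is ranked by the income domain of the national deprivation index, either as
deciles (1 = most deprived 10%) or quintiles (1 = most deprived 20%).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "REGION_ALIASES",
    "LC_AGE_GROUPS",
    "BC_AGE_GROUPS",
    "StratumKey",
    "MortalityTable",
    "ESPWeights",
    "SchemaError",
    "read_mortality_table",
    "write_mortality_table",
    "deciles_to_quintiles",
    "aggregate_over",
    "esp2013_weights",
    "age_groups_for",
]

#: Canonical lowercase tokens for the nine English regions.
REGIONS: tuple[str, ...] = (
    "north_east",
    "north_west",
    "yorkshire_humber",
    "east_midlands",
    "west_midlands",
    "east",
    "london",
    "south_east",
    "south_west",
)

#: Alias map from common spellings to canonical region tokens.
REGION_ALIASES: dict[str, str] = {
    "north east": "north_east",
    "north west": "north_west",
    "yorkshire and the humber": "yorkshire_humber",
    "yorkshire and humber": "yorkshire_humber",
    "east midlands": "east_midlands",
    "west midlands": "west_midlands",
    "east of england": "east",
    "east": "east",
    "london": "london",
    "south east": "south_east",
    "south west": "south_west",
}

#: Age-at-death bands modelled for lung cancer (trachea/bronchus/lung).
LC_AGE_GROUPS: tuple[str, ...] = (
    "45-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85-89",
)

#: Age-at-death bands modelled for female breast cancer.
BC_AGE_GROUPS: tuple[str, ...] = (
    "35-39", "40-44", "45-49", "50-54", "55-59", "60-64",
    "65-69", "70-74", "75-79", "80-84", "85-89",
)

CAUSES = ("LC", "BC")
SEXES = ("F", "M")

#: Deterministic on-disk column order.
COLUMNS = ("cause", "sex", "age_group", "year", "region", "deprivation",
           "deaths", "exposure")


class SchemaError(ValueError):
    """A mortality table violated its schema or invariants."""


def age_groups_for(cause: str) -> tuple[str, ...]:
    """Return the modelled age-band labels for a cause (``LC`` or ``BC``)."""
    if cause == "LC":
        return LC_AGE_GROUPS
    if cause == "BC":
        return BC_AGE_GROUPS
    raise SchemaError(f"unknown cause {cause!r}; expected one of {CAUSES}")


def canonical_region(name: str) -> str:
    """Map a region spelling to its canonical lowercase token."""
    token = str(name).strip().lower().replace("-", " ")
    token_us = token.replace(" ", "_")
    if token_us in REGIONS:
        return token_us
    if token in REGION_ALIASES:
        return REGION_ALIASES[token]
    raise SchemaError(
        f"unknown region {name!r}; allowed: {', '.join(REGIONS)}"
    )


class StratumKey(NamedTuple):
    """One cell of the stratification grid."""

    cause: str
    sex: str
    age_group: str
    year: int
    region: str
    deprivation: int

    def validate(self, granularity: str = "quintile") -> None:
        if self.cause not in CAUSES:
            raise SchemaError(f"unknown cause {self.cause!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if self.cause == "BC" and self.sex != "F":
            raise SchemaError("breast-cancer strata are restricted to sex 'F'")
        allowed_ages = age_groups_for(self.cause)
        if self.age_group not in allowed_ages:
            raise SchemaError(
                f"age group {self.age_group!r} not valid for {self.cause}; "
                f"allowed: {', '.join(allowed_ages)}"
            )
        if self.region not in REGIONS:
            raise SchemaError(
                f"unknown region {self.region!r}; allowed: {', '.join(REGIONS)}"
            )
        n_bands = 10 if granularity == "decile" else 5
        if not 1 <= self.deprivation <= n_bands:
            raise SchemaError(
                f"deprivation {self.deprivation} outside 1..{n_bands} "
                f"({granularity} granularity)"
            )


@dataclass
class MortalityTable:
    """Death counts and exposures on a stratification grid.

    ``data`` is a long-format DataFrame with columns
    cause, sex, age_group, year, region, deprivation, deaths, exposure.
    """

    data: pd.DataFrame
    deprivation_granularity: str = "quintile"  # or "decile"

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if len(df) == 0:
            warnings.warn("empty mortality table (no grid cells)", stacklevel=3)
            return
        if (df["deaths"] < 0).any():
            bad = df.index[df["deaths"] < 0][0]
            raise SchemaError(f"negative deaths in row {bad}: field 'deaths'")
        if (df["exposure"] <= 0).any():
            bad = df.index[df["exposure"] <= 0][0]
            raise SchemaError(
                f"non-positive exposure in row {bad}: field 'exposure'"
            )
        key_cols = list(COLUMNS[:6])
        dup = df.duplicated(subset=key_cols)
        if dup.any():
            key = StratumKey(*df.loc[dup.idxmax(), key_cols])
            raise SchemaError(f"duplicate stratum {key}")
        for row in df.itertuples(index=False):
            StratumKey(row.cause, row.sex, row.age_group, int(row.year),
                       row.region, int(row.deprivation)).validate(
                self.deprivation_granularity)

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cause(self) -> str:
        return str(self.data["cause"].iloc[0]) if len(self.data) else ""

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.data["year"].unique())) if len(self.data) else ()

    def crude_rates(self) -> pd.Series:
        """Crude death rate m = D / E per row."""
        return self.data["deaths"] / self.data["exposure"]

    def completeness_report(self, expected_grid: pd.DataFrame | None = None
                            ) -> dict[str, int]:
        """Audit grid completeness against the cross-product of observed levels.

        Returns counts of expected, present, and missing cells; never imputes.
        """
        df = self.data
        if expected_grid is None:
            if len(df) == 0:
                return {"expected": 0, "present": 0, "missing": 0}
            levels = [df[c].unique() for c in COLUMNS[:6]]
            expected = int(np.prod([len(v) for v in levels]))
        else:
            expected = len(expected_grid)
        present = len(df)
        return {"expected": expected, "present": present,
                "missing": expected - present}

    def sorted(self) -> "MortalityTable":
        """Return a copy in canonical row order."""
        df = self.data.copy()
        cause = self.cause or "LC"
        ages = list(age_groups_for(cause)) if cause in CAUSES else None
        if ages is not None:
            df["_age"] = df["age_group"].map({a: i for i, a in enumerate(ages)})
        else:
            df["_age"] = df["age_group"]
        df["_reg"] = df["region"].map({r: i for i, r in enumerate(REGIONS)})
        df = df.sort_values(
            ["cause", "sex", "_age", "year", "_reg", "deprivation"],
            kind="mergesort").drop(columns=["_age", "_reg"])
        return MortalityTable(df.reset_index(drop=True),
                              self.deprivation_granularity)

    def equals(self, other: "MortalityTable") -> bool:
        a = self.sorted().data.reset_index(drop=True)
        b = other.sorted().data.reset_index(drop=True)
        if len(a) != len(b):
            return False
        return bool(
            a[list(COLUMNS[:7])].equals(b[list(COLUMNS[:7])])
            and np.allclose(a["exposure"], b["exposure"], rtol=0, atol=1e-9)
        )


@dataclass
class ESPWeights:
    """ESP-2013 standard-population weights for a set of age bands.

    Weights are renormalised to sum to 1 over the requested bands.
    """

    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise SchemaError("ESP weights must be positive")
        total = sum(self.weights.values())
        self.weights = {a: w / total for a, w in self.weights.items()}

    def as_array(self, age_groups: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[a] for a in age_groups])


def _load_esp_table() -> dict[str, float]:
    with resources.files("mortgap.data").joinpath(
            "esp2013_weights.csv").open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["age_group"], df["esp_count"].astype(float)))


_ESP_TABLE: dict[str, float] | None = None


def esp2013_weights(age_groups: Sequence[str]) -> ESPWeights:
    """ESP-2013 weights for ``age_groups``, renormalised to sum to 1.

    The combined 45-54 band carries the sum of the 45-49 and 50-54 counts.
    """
    global _ESP_TABLE
    if _ESP_TABLE is None:
        _ESP_TABLE = _load_esp_table()
    unknown = [a for a in age_groups if a not in _ESP_TABLE]
    if unknown:
        raise SchemaError(
            f"no ESP-2013 weight for age group(s) {unknown}; "
            f"supported: {sorted(_ESP_TABLE)}"
        )
    return ESPWeights({a: _ESP_TABLE[a] for a in age_groups})


# ---------------------------------------------------------------------------
# I/O

DEFAULT_SCHEMA: dict[str, str] = {c: c for c in COLUMNS}


def read_mortality_table(path: str | Path,
                         schema: Mapping[str, str] | None = None
                         ) -> MortalityTable:
    """Read a long-format delimited mortality table.

    ``schema`` maps canonical column names to the file's column names, for
    files whose headers differ from the package default.  Malformed rows
    raise :class:`SchemaError` naming the row and field; region spellings are
    canonicalised through the alias map.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, comment="#")
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    df = df[list(COLUMNS)]
    if len(df) == 0:
        warnings.warn(f"{path}: header-only file, empty grid", stacklevel=2)
        return MortalityTable(df)
    df["region"] = df["region"].map(canonical_region)
    for col, typ in (("year", int), ("deprivation", int), ("deaths", int)):
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} not {typ.__name__}: {exc}")
    df["exposure"] = df["exposure"].astype(float)
    granularity = "decile" if df["deprivation"].max() > 5 else "quintile"
    return MortalityTable(df, granularity)


def write_mortality_table(table: MortalityTable, path: str | Path) -> Path:
    """Write a table in canonical column order and row sort; round-trips."""
    path = Path(path)
    df = table.sorted().data[list(COLUMNS)]
    df.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Aggregation

def deciles_to_quintiles(table: MortalityTable) -> MortalityTable:
    """Collapse deprivation deciles pairwise into quintiles.

    Deciles (1,2) form quintile 1 (most deprived 20%), ..., (9,10) form
    quintile 5.  Deaths and exposures are summed within each pair; totals are
    conserved exactly.
    """
    if table.deprivation_granularity != "decile":
        raise SchemaError("input table is already at quintile granularity")
    df = table.data.copy()
    df["quintile"] = (df["deprivation"] + 1) // 2
    group_cols = ["cause", "sex", "age_group", "year", "region", "quintile"]
    counts = df.groupby(group_cols, sort=False)["deprivation"].nunique()
    orphans = counts[counts != 2]
    if len(orphans):
        raise SchemaError(
            f"missing decile partner for cell {orphans.index[0]}: "
            f"found {orphans.iloc[0]} decile(s), expected 2"
        )
    out = (df.groupby(group_cols, sort=False)[["deaths", "exposure"]]
             .sum().reset_index()
             .rename(columns={"quintile": "deprivation"}))
    return MortalityTable(out[list(COLUMNS)], "quintile").sorted()


def aggregate_over(table: MortalityTable,
                   dims: Iterable[str] = ()) -> MortalityTable:
    """Sum deaths and exposures over the stratification dims in ``dims``.

    ``dims`` is a subset of {"deprivation", "region", "age_group"}.  Dropped
    dimensions are replaced by a single pooled level ("all" / 0).  Empty
    ``dims`` returns the input unchanged with a warning.
    """
    dims = set(dims)
    allowed = {"deprivation", "region", "age_group"}
    if not dims <= allowed:
        raise SchemaError(f"cannot aggregate over {sorted(dims - allowed)}")
    if not dims:
        warnings.warn("aggregate_over with empty dims is the identity",
                      stacklevel=2)
        return table
    df = table.data.copy()
    keep = [c for c in COLUMNS[:6] if c not in dims]
    out = df.groupby(keep, sort=False)[["deaths", "exposure"]].sum().reset_index()
    # pooled placeholder levels keep the schema rectangular
    if "deprivation" in dims:
        out["deprivation"] = 0
    if "region" in dims:
        out["region"] = "all"
    if "age_group" in dims:
        out["age_group"] = "all"
    out = out[list(COLUMNS)]
    # pooled levels are outside the per-cause label lists, so bypass
    # per-row key validation while keeping count/exposure checks
    pooled = MortalityTable.__new__(MortalityTable)
    pooled.data = out.reset_index(drop=True)
    pooled.deprivation_granularity = table.deprivation_granularity
    if (out["deaths"] < 0).any() or (out["exposure"] <= 0).any():
        raise SchemaError("aggregation produced invalid counts")
    return pooled
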