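"""Hospital case-table processing: loading, sub-dataset filters with audit
counts, demography, season assignment, and bite-type composition.

The table schema follows the five analysis variables of the hospital register:
age and sex of the victim, bite date, location (district/sub-district text and
optional coordinates), and a five-category clinically assigned bite type
(cobra, green pit viper, krait, non-envenoming, other envenoming).

Season defaults match the study area's calendar: hot summer March-June,
monsoon/rainy July-October, winter November-February.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from snakerisk.simulate import BITE_TYPES

__all__ = [
    "SeasonDefinition",
    "load_cases",
    "write_cases",
    "subdataset",
    "demography",
    "seasonal_summary",
    "bite_type_shares",
    "admin_counts",
]

COLUMNS = ("age", "sex", "bite_date", "bite_type", "district", "subdistrict",
           "longitude", "latitude")
SEXES = ("male", "female")

DEFAULT_MONTH_SEASONS = {
    1: "winter", 2: "winter", 3: "summer", 4: "summer", 5: "summer", 6: "summer",
    7: "rainy", 8: "rainy", 9: "rainy", 10: "rainy", 11: "winter", 12: "winter",
}
SEASON_ORDER = ("summer", "rainy", "winter")


@dataclass
class SeasonDefinition:
    """Mapping of calendar month (1-12) to season name."""

    month_to_season: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_MONTH_SEASONS)
    )

    def __post_init__(self) -> None:
        if sorted(self.month_to_season) != list(range(1, 13)):
            raise ValueError("every month 1-12 must map to exactly one season")

    @property
    def seasons(self) -> list[str]:
        seen: list[str] = []
        for m in range(1, 13):
            s = self.month_to_season[m]
            if s not in seen:
                seen.append(s)
        return seen


def load_cases(path, format: str | None = None,
               column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a case table from CSV or XLSX.

    ``column_map`` renames source columns to the canonical schema
    (``{"source name": "age", ...}``). Blank entries become missing; unknown
    bite-type strings raise with the offending values listed; row count is
    preserved.
    """
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown case-table format {format!r}")
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = [c for c in ("age", "sex", "bite_date", "bite_type") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: unmappable required columns: {missing_cols}")
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[list(COLUMNS)].copy()
    # normalize blanks and categorical strings
    for c in ("sex", "bite_type", "district", "subdistrict"):
        s = df[c].astype("string").str.strip()
        s = s.replace("", pd.NA)
        df[c] = s.str.lower() if c in ("sex", "bite_type") else s
    bad_types = sorted(set(df["bite_type"].dropna()) - set(BITE_TYPES))
    if bad_types:
        raise ValueError(f"{path}: unknown bite_type values: {bad_types}")
    bad_sex = sorted(set(df["sex"].dropna()) - set(SEXES))
    if bad_sex:
        raise ValueError(f"{path}: unknown sex values: {bad_sex}")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if (df["age"].dropna() < 0).any():
        raise ValueError(f"{path}: negative ages present")
    df["bite_date"] = pd.to_datetime(df["bite_date"], errors="coerce", format="mixed")
    for c in ("longitude", "latitude"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def write_cases(df: pd.DataFrame, path) -> None:
    """Write a case table as CSV in the canonical column order."""
    out = df.copy()
    out = out[[c for c in COLUMNS if c in out.columns]]
    out.to_csv(path, index=False)


def subdataset(df: pd.DataFrame, required_fields) -> tuple[pd.DataFrame, dict]:
    """Keep rows where every required field is present.

    Returns the filtered table and an audit mapping with the input size, the
    kept count, and per-field counts of rows missing that field. Filters are
    idempotent and monotone (more required fields never keep more rows).
    """
    required = list(required_fields)
    unknown = set(required) - set(df.columns)
    if unknown:
        raise KeyError(f"required fields not in schema: {sorted(unknown)}")
    keep = pd.Series(True, index=df.index)
    audit = {"n_input": len(df)}
    for f in required:
        miss = df[f].isna()
        audit[f"missing_{f}"] = int(miss.sum())
        keep &= ~miss
    audit["n_kept"] = int(keep.sum())
    audit["n_dropped"] = len(df) - audit["n_kept"]
    return df[keep].copy(), audit


def demography(df: pd.DataFrame, age_bin_width: int = 10, age_cap: int = 60) -> dict:
    """Sex shares/counts plus an age-group pyramid by sex.

    Shares are over rows with non-missing sex; the pyramid covers rows with
    both sex and age, in decadal bins 0-9, 10-19, ..., with a terminal
    ``{age_cap}+`` bin.
    """
    sexed = df[df["sex"].notna()]
    if len(sexed) == 0:
        raise ValueError("no records with sex information")
    counts = sexed["sex"].value_counts().to_dict()
    n = len(sexed)
    shares = {s: counts.get(s, 0) / n for s in SEXES}
    both = sexed[sexed["age"].notna()].copy()
    edges = list(range(0, age_cap + age_bin_width, age_bin_width)) + [np.inf]
    labels = [f"{lo}-{lo + age_bin_width - 1}" for lo in range(0, age_cap, age_bin_width)]
    labels.append(f"{age_cap}+")
    both["age_group"] = pd.cut(both["age"], bins=edges, labels=labels,
                               right=False, include_lowest=True)
    pyramid = (
        both.groupby(["age_group", "sex"], observed=False).size().unstack(fill_value=0)
        .reindex(labels)
    )
    for s in SEXES:
        if s not in pyramid.columns:
            pyramid[s] = 0
    return {
        "n_sexed": n,
        "counts": {s: int(counts.get(s, 0)) for s in SEXES},
        "shares": shares,
        "pyramid": pyramid[list(SEXES)],
    }


def seasonal_summary(
    df: pd.DataFrame,
    seasons: SeasonDefinition | None = None,
    by_bite_type: bool = False,
) -> dict:
    """Per-season counts and shares over dated records.

    Records with no (or unparseable) bite date are excluded and reported in
    the audit. With ``by_bite_type`` a season x type cross-table is added;
    its margins equal the unconditional counts.
    """
    seasons = seasons or SeasonDefinition()
    dated = df[df["bite_date"].notna()].copy()
    audit = {"n_input": len(df), "n_dated": len(dated),
             "n_undated": len(df) - len(dated)}
    months = dated["bite_date"].dt.month
    dated["season"] = months.map(seasons.month_to_season)
    order = [s for s in SEASON_ORDER if s in seasons.seasons] or seasons.seasons
    counts = dated["season"].value_counts().reindex(order, fill_value=0)
    n = len(dated)
    out = {
        "audit": audit,
        "counts": counts.astype(int).to_dict(),
        "shares": (counts / n).to_dict() if n else {s: np.nan for s in order},
    }
    if by_bite_type:
        typed = dated[dated["bite_type"].notna()]
        table = pd.crosstab(typed["season"], typed["bite_type"]).reindex(
            index=order, columns=list(BITE_TYPES), fill_value=0
        )
        out["by_bite_type"] = table
    return out


def bite_type_shares(df: pd.DataFrame, denominator: str = "all_records") -> dict:
    """Mean yearly share of each bite type.

    Shares are computed within each calendar year of the bite date against
    the chosen denominator — ``all_records`` (all typed records that year) or
    ``envenoming_only`` (typed records excluding non-envenoming bites) — then
    averaged across years with at least one qualifying record.
    """
    if denominator not in ("all_records", "envenoming_only"):
        raise ValueError("denominator must be 'all_records' or 'envenoming_only'")
    sub = df[df["bite_date"].notna() & df["bite_type"].notna()].copy()
    sub["year"] = sub["bite_date"].dt.year
    per_year = pd.crosstab(sub["year"], sub["bite_type"]).reindex(
        columns=list(BITE_TYPES), fill_value=0
    )
    if denominator == "envenoming_only":
        denom = per_year.drop(columns="non_envenoming").sum(axis=1)
    else:
        denom = per_year.sum(axis=1)
    keep = denom > 0
    per_year, denom = per_year[keep], denom[keep]
    if len(per_year) == 0:
        return {t: np.nan for t in BITE_TYPES}
    yearly = per_year.div(denom, axis=0)
    return yearly.mean(axis=0).to_dict()


def admin_counts(df: pd.DataFrame, level: str = "district") -> pd.DataFrame:
    """Case counts per district or sub-district (tabular stand-in for the
    map-by-administrative-unit figure)."""
    if level not in ("district", "subdistrict"):
        raise ValueError("level must be 'district' or 'subdistrict'")
    sub = df[df[level].notna()]
    out = sub[level].value_counts().rename("n_cases").rename_axis(level).reset_index()
    return out.sort_values(["n_cases", level], ascending=[False, True]).reset_index(drop=True)
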