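"""Reading, validation and restructuring of longitudinal weed-coverage surveys.

A survey records, once per site and year, the ordinal coverage level of a
weed (0 = absent, 1 = low <20%, 2 = medium 20-50%, 3 = high >50%) together
with the management covariates of that year: farmland use (six categories),
whether the field was irrigated the previous summer, whether sowing was
delayed, and optionally the mean December-April temperature.

The analysis operates on *transition pairs*: for each site, consecutive
observations (year t-1 -> year t) paired with the covariates of the
destination year t.  Covariates always attach to the destination year
because they describe the management applied between the two observations.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "LEVEL_LABELS",
    "LAND_USES",
    "SURVEY_COLUMNS",
    "SurveyFormatError",
    "SurveyRecord",
    "Dataset",
    "ValidationReport",
    "read_survey_csv",
    "write_dataset",
    "validate_dataset",
    "build_transition_pairs",
    "write_transition_pairs",
]

#: Ordinal coverage levels and their field labels.
LEVELS = (0, 1, 2, 3)
LEVEL_LABELS = {0: "absent", 1: "low", 2: "medium", 3: "high"}

#: Closed set of farmland-use tokens (treatment baseline is wheat).
LAND_USES = (
    "wheat",
    "barley",
    "other_crop",
    "paddy_rice",
    "fallow_managed",
    "fallow_unmanaged",
)

#: Canonical survey CSV columns, in order.
SURVEY_COLUMNS = (
    "site_id",
    "year",
    "coverage",
    "land_use",
    "irrigation",
    "delayed_sowing",
    "temp_dec_apr",
)

_MANDATORY = SURVEY_COLUMNS[:-1]  # temp_dec_apr is optional

YEAR_MIN, YEAR_MAX = 1900, 2100


class SurveyFormatError(ValueError):
    """Raised for fatal survey-file problems (missing columns, duplicate keys)."""


@dataclass(frozen=True)
class SurveyRecord:
    """One site x year observation."""

    site_id: str
    year: int
    coverage: int
    land_use: str
    irrigation: int
    delayed_sowing: int
    temp_dec_apr: float | None = None


@dataclass
class Dataset:
    """A validated collection of survey records backed by a DataFrame.

    ``row_errors`` lists rows that were rejected during parsing, as
    ``(row_number, message)`` with 1-based data-row numbers.
    """

    df: pd.DataFrame
    row_errors: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[SurveyRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            t = row.temp_dec_apr
            out.append(
                SurveyRecord(
                    site_id=str(row.site_id),
                    year=int(row.year),
                    coverage=int(row.coverage),
                    land_use=str(row.land_use),
                    irrigation=int(row.irrigation),
                    delayed_sowing=int(row.delayed_sowing),
                    temp_dec_apr=None if pd.isna(t) else float(t),
                )
            )
        return out

    @property
    def n_sites(self) -> int:
        return self.df["site_id"].nunique()


@dataclass
class ValidationReport:
    """Pure report on a dataset; never modifies it."""

    n_records: int
    n_sites: int
    empty: bool
    duplicate_keys: list[tuple[str, int]]
    gaps: dict[str, list[tuple[int, int]]]  # site -> [(year_before_gap, gap_length)]
    unknown_land_use: list[str]
    n_missing_temperature: int
    site_year_spans: dict[str, tuple[int, int]]

    @property
    def ok(self) -> bool:
        return not (self.duplicate_keys or self.unknown_land_use)


def _coerce_row(row: Mapping, rownum: int) -> SurveyRecord:
    site_id = str(row["site_id"]).strip()
    if not site_id or site_id.lower() == "nan":
        raise ValueError("empty site_id")
    year = int(row["year"])
    if not YEAR_MIN <= year <= YEAR_MAX:
        raise ValueError(f"year {year} outside [{YEAR_MIN}, {YEAR_MAX}]")
    coverage = int(row["coverage"])
    if coverage not in LEVELS:
        raise ValueError(f"coverage {coverage} outside 0-3")
    land_use = str(row["land_use"]).strip()
    if land_use not in LAND_USES:
        raise ValueError(f"unknown land_use token {land_use!r}")
    irrigation = int(row["irrigation"])
    delayed = int(row["delayed_sowing"])
    if irrigation not in (0, 1) or delayed not in (0, 1):
        raise ValueError("irrigation and delayed_sowing must be coded 0/1")
    temp = row.get("temp_dec_apr")
    if temp is None or (isinstance(temp, float) and np.isnan(temp)) or str(temp).strip() == "":
        temp_val: float | None = None
    else:
        temp_val = float(temp)
    return SurveyRecord(site_id, year, coverage, land_use, irrigation, delayed, temp_val)


def _records_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.site_id, r.year, r.coverage, r.land_use, r.irrigation, r.delayed_sowing,
             np.nan if r.temp_dec_apr is None else r.temp_dec_apr)
            for r in records
        ],
        columns=list(SURVEY_COLUMNS),
    )
    if df.empty:
        df = pd.DataFrame(columns=list(SURVEY_COLUMNS))
    return df


def dataset_from_records(records: Iterable[SurveyRecord]) -> Dataset:
    """Build a Dataset directly from records, enforcing key uniqueness."""
    df = _records_to_frame(records)
    dup = df.duplicated(subset=["site_id", "year"])
    if dup.any():
        keys = df.loc[dup, ["site_id", "year"]].itertuples(index=False, name=None)
        raise SurveyFormatError(f"duplicate (site_id, year) keys: {sorted(set(keys))}")
    return Dataset(df.sort_values(["site_id", "year"]).reset_index(drop=True))


def read_survey_csv(path: str | Path | _io.IOBase,
                    column_map: Mapping[str, str] | None = None) -> Dataset:
    """Read a survey CSV into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file (comma-separated, UTF-8, header row required, "." decimal
        point, binary columns coded 0/1).
    column_map
        Optional mapping from canonical names to the file's column names,
        e.g. ``{"site_id": "Site ID"}``.

    Rows that fail row-level validation (e.g. coverage outside 0-3) are
    collected in ``Dataset.row_errors``; missing mandatory columns and
    duplicate (site, year) keys are fatal.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise SurveyFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "temp_dec_apr" not in raw.columns:
        raw["temp_dec_apr"] = np.nan

    records: list[SurveyRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(raw.to_dict(orient="records"), start=1):
        try:
            records.append(_coerce_row(row, i))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append((i, str(exc)))

    ds = dataset_from_records(records)  # raises on duplicate keys
    ds.row_errors = errors
    return ds


def write_dataset(ds: Dataset, path: str | Path | _io.IOBase) -> None:
    """Write a dataset back to the canonical survey CSV format.

    Round-trips with :func:`read_survey_csv` field for field.
    """
    out = ds.df.copy()
    out.to_csv(path, index=False)


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report duplicates, per-site year gaps, unknown tokens and missing data."""
    df = ds.df
    dup_mask = df.duplicated(subset=["site_id", "year"], keep=False)
    duplicates = sorted(
        set(df.loc[dup_mask, ["site_id", "year"]].itertuples(index=False, name=None))
    )
    gaps: dict[str, list[tuple[int, int]]] = {}
    spans: dict[str, tuple[int, int]] = {}
    for site, grp in df.groupby("site_id", sort=True):
        years = np.sort(grp["year"].astype(int).to_numpy())
        spans[str(site)] = (int(years[0]), int(years[-1]))
        diffs = np.diff(years)
        site_gaps = [
            (int(years[k]), int(d - 1)) for k, d in enumerate(diffs) if d > 1
        ]
        if site_gaps:
            gaps[str(site)] = site_gaps
    unknown = sorted(set(df["land_use"]) - set(LAND_USES))
    return ValidationReport(
        n_records=len(df),
        n_sites=df["site_id"].nunique(),
        empty=df.empty,
        duplicate_keys=duplicates,
        gaps=gaps,
        unknown_land_use=unknown,
        n_missing_temperature=int(df["temp_dec_apr"].isna().sum()),
        site_year_spans=spans,
    )


#: Columns of the transition-pair table.
PAIR_COLUMNS = (
    "site_id",
    "year",
    "from_level",
    "to_level",
    "land_use",
    "irrigation",
    "delayed_sowing",
    "temp_dec_apr",
    "gap",
)


def build_transition_pairs(ds: Dataset, max_gap: int = 1) -> pd.DataFrame:
    """Form (previous level, current level, covariates) transition pairs.

    For every site, each ordered couple of records (t-g, t) with
    ``1 <= g <= max_gap`` and no intermediate observation forms one pair.
    Covariates are taken from the destination year t.  By default only
    consecutive years pair up (``max_gap=1``); observations separated by a
    gap are dropped rather than silently bridged.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    rows = []
    for site, grp in ds.df.groupby("site_id", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].astype(int).to_numpy()
        cov = grp["coverage"].astype(int).to_numpy()
        for k in range(1, len(years)):
            g = years[k] - years[k - 1]
            if 1 <= g <= max_gap:
                dest = grp.iloc[k]
                rows.append(
                    (
                        str(site),
                        int(years[k]),
                        int(cov[k - 1]),
                        int(cov[k]),
                        dest["land_use"],
                        int(dest["irrigation"]),
                        int(dest["delayed_sowing"]),
                        dest["temp_dec_apr"],
                        int(g),
                    )
                )
    pairs = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    if pairs.empty:
        pairs = pd.DataFrame(columns=list(PAIR_COLUMNS))
    return pairs


def write_transition_pairs(pairs: pd.DataFrame, path: str | Path | _io.IOBase) -> None:
    pairs.to_csv(path, index=False)
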