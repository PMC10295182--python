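"""Data model and CSV I/O for benthic survey tables.

Four input tables drive the analysis: a station table with environmental
covariates, a stations x taxa community matrix of grab-sample abundances,
a long-format video-annotation table (one row per observed seafloor
feature), and a sieve table with retained masses per mesh.  All tables are
plain CSV (comma-separated, UTF-8, header row, "." decimal mark) and are
joined exclusively on the station id, an opaque string key.

Missing optional covariates are carried as explicit ``None``/NaN and never
imputed; the modelling stage decides about exclusion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageClass",
    "SUBSTRATE_FEATURES",
    "SEDIMENT_TYPES",
    "HETEROGENEITY_CLASSES",
    "SEASONS",
    "TAXON_GROUPS",
    "FeatureProfile",
    "StationCovariates",
    "CommunityMatrix",
    "SchemaError",
    "ValidationIssue",
    "ValidationReport",
    "read_station_table",
    "write_station_table",
    "read_community_csv",
    "write_community_csv",
    "read_video_csv",
    "write_video_csv",
    "read_sieve_csv",
    "write_sieve_csv",
    "validate_dataset",
]


class SchemaError(ValueError):
    """A table violates its documented schema (bad label, duplicate key, ...)."""


class CoverageClass(enum.IntEnum):
    """Ordinal seafloor-coverage class of one substrate feature.

    The order encodes increasing coverage: absent, occasional (<1% of the
    seafloor), frequent (1-10%), dense (10-50%), very dense (>=50%).
    """

    ABSENT = 0
    OCCASIONAL = 1
    FREQUENT = 2
    DENSE = 3
    VERY_DENSE = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "CoverageClass":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise SchemaError(
                f"unknown coverage class {label!r}; expected one of "
                f"{[c.label for c in cls]}"
            ) from None


#: The nine admissible seafloor feature classes scored in a video transect.
SUBSTRATE_FEATURES: tuple[str, ...] = (
    "large_boulders",
    "cobble_small_boulders",
    "coarse_gravel",
    "fine_gravel",
    "coarse_medium_sand",
    "fine_sand",
    "mud",
    "bivalve_shells",
    "shell_gravel",
)

#: Sediment types derived from the median grain size d50.
SEDIMENT_TYPES: tuple[str, ...] = ("mud", "fine_sand", "medium_sand", "coarse")

#: Ordinal substrate-heterogeneity classes ("GeoClass"), none < low < medium < high.
HETEROGENEITY_CLASSES: tuple[str, ...] = ("none", "low", "medium", "high")

SEASONS: tuple[str, ...] = ("spring", "summer")

TAXON_GROUPS: tuple[str, ...] = ("polychaete", "mollusc", "crustacean", "other")


@dataclass
class FeatureProfile:
    """Coverage class per seafloor feature for one station's video transect.

    Every one of the nine features is present in ``coverage``; features not
    annotated default to absent.  A valid transect has at least one
    non-absent feature (otherwise nothing of the seabed was observable).
    """

    station: str
    coverage: dict[str, CoverageClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.coverage) - set(SUBSTRATE_FEATURES)
        if unknown:
            raise SchemaError(f"unknown substrate feature(s) {sorted(unknown)}")
        full = {f: CoverageClass.ABSENT for f in SUBSTRATE_FEATURES}
        full.update({f: CoverageClass(c) for f, c in self.coverage.items()})
        self.coverage = full

    @property
    def n_nonabsent(self) -> int:
        return sum(1 for c in self.coverage.values() if c != CoverageClass.ABSENT)


@dataclass
class StationCovariates:
    """Environmental covariates for a single station (one sampling event)."""

    station: str
    depth_m: float
    salinity_psu: float
    year: int
    season: str
    slope_deg: float | None = None
    bpi: float | None = None
    sediment_type: str | None = None
    geoclass: str | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.depth_m) and self.depth_m <= 0:
            raise SchemaError(f"station {self.station}: depth must be positive")
        if not np.isnan(self.salinity_psu) and self.salinity_psu <= 0:
            raise SchemaError(f"station {self.station}: salinity must be positive")
        if self.season not in SEASONS:
            raise SchemaError(
                f"station {self.station}: season {self.season!r} not in {SEASONS}"
            )
        if self.sediment_type is not None and self.sediment_type not in SEDIMENT_TYPES:
            raise SchemaError(
                f"station {self.station}: sediment_type {self.sediment_type!r} "
                f"not in {SEDIMENT_TYPES}"
            )
        if self.geoclass is not None and self.geoclass not in HETEROGENEITY_CLASSES:
            raise SchemaError(
                f"station {self.station}: geoclass {self.geoclass!r} "
                f"not in {HETEROGENEITY_CLASSES}"
            )


@dataclass
class CommunityMatrix:
    """Stations x taxa abundance counts per 0.1 m2 grab sample.

    ``counts`` is an integer DataFrame indexed by station id with one column
    per taxon.  ``taxon_groups`` optionally maps taxon id to a coarse group
    label (polychaete / mollusc / crustacean / other).
    """

    counts: pd.DataFrame
    taxon_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise SchemaError(f"duplicated taxon column(s): {dupes}")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise SchemaError(f"duplicated station row(s): {dupes}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise SchemaError("community matrix must be numeric")
        if np.any(arr < 0):
            raise SchemaError("negative abundance in community matrix")
        if np.any(arr != np.floor(arr)):
            raise SchemaError("fractional abundance in community matrix")
        self.counts = self.counts.astype(int)
        self.counts.index.name = "station"

    @property
    def stations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# station table


_STATION_COLUMNS = (
    "station",
    "depth_m",
    "salinity_psu",
    "year",
    "season",
    "slope_deg",
    "bpi",
    "sediment_type",
    "geoclass",
)


def read_station_table(
    path: str | Path, year_range: tuple[int, int] = (1990, 2100)
) -> list[StationCovariates]:
    """Read stations.csv into a list of :class:`StationCovariates`.

    Required columns: station, depth_m, salinity_psu, year, season.
    Optional: slope_deg, bpi, sediment_type, geoclass.  Duplicate station
    ids, non-numeric depth/salinity and out-of-vocabulary categories are
    rejected with the offending row/value named.
    """
    df = pd.read_csv(path, dtype={"station": str})
    required = {"station", "depth_m", "salinity_psu", "year", "season"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"stations table missing column(s) {sorted(missing)}")
    if df["station"].duplicated().any():
        dupes = df.loc[df["station"].duplicated(), "station"].tolist()
        raise SchemaError(f"duplicate station id(s) {dupes}")
    records: list[StationCovariates] = []
    for i, row in df.iterrows():
        for col in ("depth_m", "salinity_psu"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"row {i + 2}: non-numeric {col} value {row[col]!r}"
                ) from None
        year = int(row["year"])
        if not (year_range[0] <= year <= year_range[1]):
            raise SchemaError(f"row {i + 2}: year {year} outside {year_range}")

        def _opt(col: str, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        records.append(
            StationCovariates(
                station=str(row["station"]),
                depth_m=float(row["depth_m"]),
                salinity_psu=float(row["salinity_psu"]),
                year=year,
                season=str(row["season"]),
                slope_deg=_opt("slope_deg"),
                bpi=_opt("bpi"),
                sediment_type=_opt("sediment_type", str),
                geoclass=_opt("geoclass", str),
            )
        )
    return records


def write_station_table(records: Iterable[StationCovariates], path: str | Path) -> None:
    rows = [{c: getattr(r, c) for c in _STATION_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=list(_STATION_COLUMNS)).to_csv(path, index=False)


def stations_frame(records: Iterable[StationCovariates]) -> pd.DataFrame:
    """Covariates as a DataFrame indexed by station id."""
    df = pd.DataFrame([vars(r) for r in records])
    return df.set_index("station")


# ---------------------------------------------------------------------------
# community matrix


def read_community_csv(path: str | Path) -> CommunityMatrix:
    """Read community.csv (first column station, remaining columns taxa).

    Missing cells are treated as zero.  Negative or fractional abundances
    and duplicated taxon columns are rejected.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if header and header[0] != "station":
        raise SchemaError("community table must have 'station' as first column")
    dupes = [c for c in set(header) if header.count(c) > 1]
    if dupes:
        raise SchemaError(f"duplicated taxon column(s): {sorted(dupes)}")
    df = pd.read_csv(path, dtype={"station": str})
    counts = df.set_index("station").fillna(0)
    return CommunityMatrix(counts=counts)


def write_community_csv(matrix: CommunityMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("station").to_csv(path)


# ---------------------------------------------------------------------------
# video table


def read_video_csv(path: str | Path) -> list[FeatureProfile]:
    """Read video.csv (station, feature, coverage; long format).

    Features not listed for a station default to absent.  Unknown feature
    or coverage labels and conflicting duplicate (station, feature) rows
    are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"station", "feature", "coverage"} - set(df.columns)
    if missing:
        raise SchemaError(f"video table missing column(s) {sorted(missing)}")
    dup = df.duplicated(subset=["station", "feature"])
    if dup.any():
        pairs = df.loc[dup, ["station", "feature"]].to_records(index=False).tolist()
        raise SchemaError(f"conflicting duplicate video annotation(s): {pairs}")
    profiles: list[FeatureProfile] = []
    for station, grp in df.groupby("station", sort=False):
        coverage: dict[str, CoverageClass] = {}
        for _, row in grp.iterrows():
            feat = row["feature"]
            if feat not in SUBSTRATE_FEATURES:
                raise SchemaError(
                    f"station {station}: unknown substrate feature {feat!r}"
                )
            coverage[feat] = CoverageClass.from_label(row["coverage"])
        profiles.append(FeatureProfile(station=str(station), coverage=coverage))
    return profiles


def write_video_csv(profiles: Iterable[FeatureProfile], path: str | Path) -> None:
    """Write profiles in long format; absent features are omitted."""
    rows = [
        {"station": p.station, "feature": f, "coverage": c.label}
        for p in profiles
        for f, c in p.coverage.items()
        if c != CoverageClass.ABSENT
    ]
    pd.DataFrame(rows, columns=["station", "feature", "coverage"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# sieve table


def read_sieve_csv(path: str | Path) -> pd.DataFrame:
    """Read sieves.csv (station, mesh_um, retained_g) with basic validation."""
    df = pd.read_csv(path, dtype={"station": str})
    missing = {"station", "mesh_um", "retained_g"} - set(df.columns)
    if missing:
        raise SchemaError(f"sieve table missing column(s) {sorted(missing)}")
    if (df["mesh_um"] <= 0).any():
        raise SchemaError("non-positive mesh size in sieve table")
    if (df["retained_g"] < 0).any():
        raise SchemaError("negative retained mass in sieve table")
    if df.duplicated(subset=["station", "mesh_um"]).any():
        raise SchemaError("duplicate (station, mesh) pair in sieve table")
    return df


def write_sieve_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[["station", "mesh_um", "retained_g"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cross-table validation


@dataclass
class ValidationIssue:
    level: str  # "warning" | "error"
    code: str
    station: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "warning"]

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "error"]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(
    stations: Sequence[StationCovariates],
    community: CommunityMatrix,
    profiles: Sequence[FeatureProfile],
    sieves: pd.DataFrame,
) -> ValidationReport:
    """Cross-table consistency report for the four input tables.

    Flags stations missing from any table (warnings) and stations whose
    sieve-derived sediment type conflicts with a user-declared
    ``sediment_type`` (errors) — the analogue of rejecting samples whose
    granulometry disagrees with the on-board sediment description.
    Report-returning; never raises.  Idempotent and independent of row
    order (issues are sorted).
    """
    from . import granulometry

    report = ValidationReport()
    station_ids = {s.station for s in stations}
    community_ids = set(community.stations)
    profile_ids = {p.station for p in profiles}
    sieve_ids = set(sieves["station"]) if len(sieves) else set()

    tables = {
        "stations": station_ids,
        "community": community_ids,
        "video": profile_ids,
        "sieves": sieve_ids,
    }
    universe = station_ids | community_ids | profile_ids | sieve_ids
    for name, ids in tables.items():
        for sid in sorted(universe - ids):
            report.issues.append(
                ValidationIssue(
                    level="warning",
                    code=f"missing_{name}" if name != "video" else "missing_profile",
                    station=sid,
                    message=f"station {sid} absent from {name} table",
                )
            )

    declared = {s.station: s.sediment_type for s in stations if s.sediment_type}
    for sid in sorted(set(declared) & sieve_ids):
        sub = sieves[sieves["station"] == sid]
        try:
            curve = granulometry.cumulative_curve(sub)
            summary = granulometry.fit_sshape(curve)
        except (ValueError, SchemaError):
            continue
        if summary.sediment_type != declared[sid]:
            report.issues.append(
                ValidationIssue(
                    level="error",
                    code="sediment_mismatch",
                    station=sid,
                    message=(
                        f"station {sid}: declared sediment {declared[sid]!r} but "
                        f"sieve-derived d50 {summary.d50_um:.0f} um implies "
                        f"{summary.sediment_type!r}"
                    ),
                )
            )
    report.issues.sort(key=lambda i: (i.code, i.station))
    return report
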