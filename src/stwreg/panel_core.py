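"""Core data model for long-format space-time pollution panels.

A panel holds one record per (location, week): planar coordinates, an
integer week index, five criteria-pollutant predictors (SO2, NO2, PM10,
O3 in µg/m³; CO in mg/m³) and the PM2.5 response (µg/m³).  All modelling
stages in this package consume :class:`PanelDataset`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PREDICTORS = ("SO2", "NO2", "PM10", "CO", "O3")
RESPONSE = "PM25"

#: default units of the six pollutants
UNITS = {
    "SO2": "ug/m3",
    "NO2": "ug/m3",
    "PM10": "ug/m3",
    "CO": "mg/m3",
    "O3": "ug/m3",
    "PM25": "ug/m3",
}

#: mapping logical column -> default CSV header name
DEFAULT_SCHEMA = {
    "city_id": "city_id",
    "city_name": "city_name",
    "x": "x",
    "y": "y",
    "week": "week",
    "so2": "so2",
    "no2": "no2",
    "pm10": "pm10",
    "co": "co",
    "o3": "o3",
    "pm25": "pm25",
}

_LOGICAL_TO_CANON = {
    "city_id": "location_id",
    "city_name": "name",
    "x": "x",
    "y": "y",
    "week": "t",
    "so2": "SO2",
    "no2": "NO2",
    "pm10": "PM10",
    "co": "CO",
    "o3": "O3",
    "pm25": "PM25",
}


class PanelError(ValueError):
    """Base error for panel validation problems."""


class SchemaError(PanelError):
    """A required column is missing from the input file."""


class DuplicateRecordError(PanelError):
    """The same (location, week) pair occurs more than once."""


class ParseError(PanelError):
    """A cell could not be interpreted as a number."""


class InsufficientDataError(PanelError):
    """Too few records remain to fit any model."""


@dataclass(frozen=True)
class Location:
    """A monitoring city: integer id, name and planar coordinates.

    Coordinates are Euclidean in an arbitrary but dataset-consistent
    length unit; geographic projection is the caller's responsibility.
    """

    id: int
    name: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.id < 0:
            raise PanelError(f"location id must be >= 0, got {self.id}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise PanelError(f"non-finite coordinates for location {self.id}")


@dataclass
class PanelDataset:
    """Long-format space-time panel, sorted by (location_id, t).

    ``records`` is a DataFrame with columns ``location_id``, ``t``, the
    predictors and the response; per-record coordinates are looked up
    from ``locations``.
    """

    locations: list[Location]
    records: pd.DataFrame
    predictor_names: tuple[str, ...] = PREDICTORS
    response_name: str = RESPONSE
    units: dict[str, str] = field(default_factory=lambda: dict(UNITS))

    def __post_init__(self) -> None:
        ids = [loc.id for loc in self.locations]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate location ids")
        self.records = self.records.sort_values(
            ["location_id", "t"], kind="stable"
        ).reset_index(drop=True)
        dup = self.records.duplicated(subset=["location_id", "t"])
        if dup.any():
            offenders = self.records.loc[dup, ["location_id", "t"]]
            raise DuplicateRecordError(
                "duplicated (location, week) pairs: "
                + ", ".join(f"({r.location_id}, {r.t})" for r in offenders.itertuples())
            )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def p(self) -> int:
        """Number of regression coefficients including the intercept."""
        return len(self.predictor_names) + 1

    @property
    def y(self) -> np.ndarray:
        return self.records[self.response_name].to_numpy(float)

    def design_matrix(self) -> np.ndarray:
        """n × p design with a leading intercept column."""
        X = self.records[list(self.predictor_names)].to_numpy(float)
        return np.column_stack([np.ones(len(X)), X])

    def coords(self) -> np.ndarray:
        """Per-record (x, y), shape n × 2."""
        lut = {loc.id: (loc.x, loc.y) for loc in self.locations}
        return np.array([lut[i] for i in self.records["location_id"]], float)

    def times(self) -> np.ndarray:
        return self.records["t"].to_numpy(float)

    def location_index(self) -> np.ndarray:
        """Per-record index into ``self.locations`` (0-based)."""
        order = {loc.id: j for j, loc in enumerate(self.locations)}
        return np.array([order[i] for i in self.records["location_id"]], int)

    def fingerprint(self) -> str:
        """Stable digest of the numeric content, used to detect that
        several fits were produced from the same dataset."""
        h = hashlib.sha256()
        cols = ["location_id", "t", *self.predictor_names, self.response_name]
        h.update(np.ascontiguousarray(self.records[cols].to_numpy(float)).tobytes())
        return h.hexdigest()[:16]


# ----------------------------------------------------------------------
# I/O


def load_panel(path: str | Path, schema: dict[str, str] | None = None) -> PanelDataset:
    """Read a long-format CSV into a validated :class:`PanelDataset`.

    ``schema`` maps the logical column names (keys of
    :data:`DEFAULT_SCHEMA`) to the actual CSV headers; omitted keys use
    the defaults.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    missing = [schema[k] for k in DEFAULT_SCHEMA if schema[k] not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    numeric = [k for k in DEFAULT_SCHEMA if k != "city_name"]
    for key in numeric:
        col = schema[key]
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"non-numeric value in column '{col}' at file row {row}")
        raw[col] = coerced.astype(float)
    df = raw.rename(columns={schema[k]: _LOGICAL_TO_CANON[k] for k in DEFAULT_SCHEMA})
    df = df[list(_LOGICAL_TO_CANON.values())]

    locs = (
        df[["location_id", "name", "x", "y"]]
        .drop_duplicates(subset="location_id")
        .sort_values("location_id")
    )
    locations = [
        Location(int(r.location_id), str(r.name), float(r.x), float(r.y))
        for r in locs.itertuples()
    ]
    records = df[["location_id", "t", *PREDICTORS, RESPONSE]].copy()
    records["location_id"] = records["location_id"].astype(int)
    records["t"] = records["t"].astype(int)
    return PanelDataset(locations=locations, records=records)


def write_panel(ds: PanelDataset, path: str | Path) -> None:
    """Write a panel back to the long-format CSV read by :func:`load_panel`."""
    lut = {loc.id: loc for loc in ds.locations}
    out = pd.DataFrame(
        {
            "city_id": ds.records["location_id"],
            "city_name": [lut[i].name for i in ds.records["location_id"]],
            "x": [lut[i].x for i in ds.records["location_id"]],
            "y": [lut[i].y for i in ds.records["location_id"]],
            "week": ds.records["t"],
            "so2": ds.records["SO2"],
            "no2": ds.records["NO2"],
            "pm10": ds.records["PM10"],
            "co": ds.records["CO"],
            "o3": ds.records["O3"],
            "pm25": ds.records["PM25"],
        }
    )
    out.to_csv(path, index=False, float_format="%.12g")


def validate_panel(ds: PanelDataset) -> tuple[PanelDataset, int]:
    """Drop records with missing values and re-assert all invariants.

    Returns the cleaned dataset and the number of dropped records.
    Idempotent: validating a clean dataset is the identity.
    """
    cols = [*ds.predictor_names, ds.response_name]
    keep = ds.records[cols].notna().all(axis=1) & np.isfinite(
        ds.records[cols].to_numpy(float).sum(axis=1)
    )
    dropped = int((~keep).sum())
    records = ds.records.loc[keep].reset_index(drop=True)
    if len(records) < ds.p + 2:
        raise InsufficientDataError(
            f"only {len(records)} records remain; need at least {ds.p + 2}"
        )
    clean = PanelDataset(
        locations=list(ds.locations),
        records=records,
        predictor_names=ds.predictor_names,
        response_name=ds.response_name,
        units=dict(ds.units),
    )
    return clean, dropped


# ----------------------------------------------------------------------
# Air-quality grading


@dataclass(frozen=True)
class AqiGrade:
    grade: str
    lower: float
    upper: float


#: PM2.5 annual-mean grade breakpoints (µg/m³), Chinese ambient standard
_GRADE_BOUNDS = [
    ("I", 0.0, 35.0),
    ("II", 35.0, 75.0),
    ("III", 75.0, 115.0),
    ("IV", 115.0, 150.0),
    ("V", 150.0, 250.0),
    ("VI", 250.0, float("inf")),
]


def aqi_grade(pm25_annual: float) -> AqiGrade:
    """Grade an annual PM2.5 concentration (µg/m³) on the I–VI scale.

    Boundary values belong to the lower grade (grade I is "≤ 35").
    """
    if not np.isfinite(pm25_annual) or pm25_annual <= 0:
        raise PanelError(f"PM2.5 concentration must be positive, got {pm25_annual}")
    for grade, lo, hi in _GRADE_BOUNDS:
        if pm25_annual <= hi:
            return AqiGrade(grade=grade, lower=lo, upper=hi)
    raise AssertionError("unreachable")


# ----------------------------------------------------------------------
# Result serialization


def write_results(obj, path: str | Path) -> None:
    """Persist a fit object: per-record tables as CSV, summaries as JSON.

    Local fits (anything with a per-record ``coef`` matrix) become a CSV
    with one row per record; global fits and comparison tables become
    JSON via their ``to_dict`` method.
    """
    path = Path(path)
    if hasattr(obj, "coef") and getattr(obj, "coef") is not None:
        coef = np.asarray(obj.coef)
        if coef.size == 0:
            raise PanelError("refusing to write an empty local fit")
        names = list(getattr(obj, "coef_names", [f"b{j}" for j in range(coef.shape[1])]))
        df = pd.DataFrame(coef, columns=names)
        df["fitted"] = obj.fitted
        df["residual"] = obj.residuals
        df.to_csv(path, index=False, float_format="%.12g")
    elif hasattr(obj, "to_dict"):
        with open(path, "w") as fh:
            json.dump(obj.to_dict(), fh, indent=2, default=_json_default)
            fh.write("\n")
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
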