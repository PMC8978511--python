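"""Domain types, file I/O, distance geometry and panel validation.

The unit of analysis is an egocentric star network: one hub country (the
operator's home network) exchanging daily origin-destination (OD) flows with
a set of counterpart countries.  Three tables describe a study:

* a location table (``id,name,lat,lon,population``) giving the masses and
  centroid geometry every spatial-interaction model needs,
* a flow panel (``date,origin,destination,flow``) of daily OD counts,
* a stringency panel (``date,location,si``) of daily policy-severity indices
  on the 0-100 scale of the Oxford Stringency Index.

All dates are ISO-8601 calendar dates; there is no time of day.  A missing
(date, pair) record means a flow of zero, matching device-counting semantics.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CoordinateRangeError,
    DuplicateIdError,
    DuplicateRecordError,
    InvalidPopulationError,
    NegativeFlowError,
    SelfLoopError,
    StarConstraintError,
    StringencyRangeError,
    UnknownLocationError,
    ValidationError,
)

EARTH_RADIUS_KM = 6371.0

Direction = Literal["incoming", "outgoing", "both"]


# ---------------------------------------------------------------------------
# locations


@dataclass(frozen=True)
class Location:
    """A country (or region) with centroid coordinates and population mass."""

    id: str
    name: str
    lat: float
    lon: float
    population: int

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise CoordinateRangeError(f"latitude {self.lat} of {self.id!r} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise CoordinateRangeError(f"longitude {self.lon} of {self.id!r} outside [-180, 180]")
        if self.population <= 0 or int(self.population) != self.population:
            raise InvalidPopulationError(
                f"population of {self.id!r} must be a positive integer, got {self.population}"
            )


class LocationTable:
    """Ordered collection of :class:`Location` with a designated hub.

    Backed by a DataFrame indexed by location id with columns
    ``name, lat, lon, population``.
    """

    def __init__(self, locations: Iterable[Location], hub_id: str):
        locations = list(locations)
        ids = [loc.id for loc in locations]
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        if dupes:
            raise DuplicateIdError(f"duplicate location id(s): {dupes}")
        if hub_id not in ids:
            raise UnknownLocationError(f"hub id {hub_id!r} not in location table")
        self.hub_id = hub_id
        self._df = pd.DataFrame(
            {
                "name": [loc.name for loc in locations],
                "lat": [float(loc.lat) for loc in locations],
                "lon": [float(loc.lon) for loc in locations],
                "population": [int(loc.population) for loc in locations],
            },
            index=pd.Index(ids, name="id"),
        )

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def ids(self) -> list[str]:
        return list(self._df.index)

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, loc_id: str) -> bool:
        return loc_id in self._df.index

    def population(self, loc_id: str) -> int:
        self._require(loc_id)
        return int(self._df.at[loc_id, "population"])

    @property
    def populations(self) -> pd.Series:
        return self._df["population"]

    def coords(self, loc_id: str) -> tuple[float, float]:
        self._require(loc_id)
        return float(self._df.at[loc_id, "lat"]), float(self._df.at[loc_id, "lon"])

    def _require(self, loc_id: str) -> None:
        if loc_id not in self._df.index:
            raise UnknownLocationError(f"unknown location id {loc_id!r}")

    @property
    def counterpart_ids(self) -> list[str]:
        """All ids except the hub."""
        return [i for i in self._df.index if i != self.hub_id]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self._df.reset_index().to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LocationTable)
            and self.hub_id == other.hub_id
            and self._df.equals(other._df)
        )


def load_locations(path, hub_id: str | None = None) -> LocationTable:
    """Read a ``id,name,lat,lon,population`` CSV into a validated table.

    If *hub_id* is omitted the first row is taken as the hub.
    """
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    _require_columns(df, ["id", "name", "lat", "lon", "population"], path)
    locations = [
        Location(
            id=row.id,
            name=row.name,
            lat=float(row.lat),
            lon=float(row.lon),
            population=int(row.population)
            if float(row.population) == int(row.population)
            else float(row.population),
        )
        for row in df.itertuples(index=False)
    ]
    if hub_id is None:
        hub_id = locations[0].id
    return LocationTable(locations, hub_id=hub_id)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], source) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# flows


@dataclass(frozen=True)
class FlowRecord:
    """One dated OD observation: count of devices moving origin -> destination."""

    date: _dt.date
    origin: str
    destination: str
    flow: int


class FlowPanel:
    """A collection of dated OD flow records.

    Validation enforces: no self loops, non-negative integer flows, at most
    one record per (date, origin, destination).  With ``star_hub`` set, every
    record must touch the hub on exactly one side (egocentric constraint);
    pass ``star_hub=None`` for general OD matrices.
    """

    COLUMNS = ["date", "origin", "destination", "flow"]

    def __init__(
        self,
        records: pd.DataFrame | Iterable[FlowRecord],
        direction: Direction = "both",
        star_hub: str | None = None,
    ):
        if isinstance(records, pd.DataFrame):
            df = records.loc[:, self.COLUMNS].copy()
        else:
            records = list(records)
            df = pd.DataFrame(
                [(r.date, r.origin, r.destination, r.flow) for r in records],
                columns=self.COLUMNS,
            )
        df["date"] = _as_dates(df["date"])
        df["origin"] = df["origin"].astype(str)
        df["destination"] = df["destination"].astype(str)

        flows = pd.to_numeric(df["flow"])
        if (flows < 0).any():
            bad = df.loc[flows < 0].iloc[0]
            raise NegativeFlowError(f"negative flow {bad.flow} on {bad.date} {bad.origin}->{bad.destination}")
        if not np.allclose(flows, np.round(flows)):
            raise NegativeFlowError("flows must be integer counts")
        df["flow"] = flows.round().astype(np.int64)

        loops = df["origin"] == df["destination"]
        if loops.any():
            bad = df.loc[loops].iloc[0]
            raise SelfLoopError(f"self-loop {bad.origin}->{bad.destination} on {bad.date}")
        dup = df.duplicated(subset=["date", "origin", "destination"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise DuplicateRecordError(
                f"duplicate record for ({bad.date}, {bad.origin}, {bad.destination})"
            )
        if star_hub is not None:
            touches = (df["origin"] == star_hub) ^ (df["destination"] == star_hub)
            if not touches.all():
                bad = df.loc[~touches].iloc[0]
                raise StarConstraintError(
                    f"record {bad.origin}->{bad.destination} on {bad.date} does not touch hub "
                    f"{star_hub!r} on exactly one side"
                )
        self._df = df.sort_values(["date", "origin", "destination"]).reset_index(drop=True)
        self.direction: Direction = direction
        self.star_hub = star_hub

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def dates(self) -> list[_dt.date]:
        return sorted(self._df["date"].unique())

    @property
    def date_range(self) -> tuple[_dt.date, _dt.date]:
        d = self._df["date"]
        return d.min(), d.max()

    def restrict(self, direction: Direction, hub_id: str) -> "FlowPanel":
        """Sub-panel of flows into (incoming) or out of (outgoing) the hub."""
        if direction == "both":
            return self
        if direction == "incoming":
            mask = self._df["destination"] == hub_id
        elif direction == "outgoing":
            mask = self._df["origin"] == hub_id
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return FlowPanel(self._df.loc[mask], direction=direction, star_hub=self.star_hub)

    def to_csv(self, path) -> None:
        out = self._df.copy()
        out["date"] = out["date"].map(_dt.date.isoformat)
        out.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, FlowPanel) and self._df.equals(other._df)


def load_flows(path, hub_id: str | None = None, direction: Direction = "both") -> FlowPanel:
    """Read a ``date,origin,destination,flow`` CSV into a validated panel.

    With *hub_id* given, the egocentric star constraint is enforced.
    """
    df = pd.read_csv(path, dtype={"origin": str, "destination": str})
    _require_columns(df, FlowPanel.COLUMNS, path)
    return FlowPanel(df, direction=direction, star_hub=hub_id)


# ---------------------------------------------------------------------------
# stringency


class StringencyPanel:
    """Per-country daily policy-severity index on the 0-100 scale."""

    COLUMNS = ["date", "location", "si"]

    def __init__(self, records: pd.DataFrame):
        df = records.loc[:, self.COLUMNS].copy()
        df["date"] = _as_dates(df["date"])
        df["location"] = df["location"].astype(str)
        df["si"] = pd.to_numeric(df["si"]).astype(float)
        out_of_range = (df["si"] < 0) | (df["si"] > 100)
        if out_of_range.any():
            bad = df.loc[out_of_range].iloc[0]
            raise StringencyRangeError(
                f"stringency {bad.si} for {bad.location} on {bad.date} outside [0, 100]"
            )
        dup = df.duplicated(subset=["date", "location"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise DuplicateRecordError(f"duplicate stringency record ({bad.date}, {bad.location})")
        self._df = df.sort_values(["date", "location"]).reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def lookup(self) -> pd.Series:
        """Series of si indexed by (date, location) for fast joins."""
        return self._df.set_index(["date", "location"])["si"]

    def to_csv(self, path) -> None:
        out = self._df.copy()
        out["date"] = out["date"].map(_dt.date.isoformat)
        out.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, StringencyPanel) and self._df.equals(other._df)


def load_stringency(path) -> StringencyPanel:
    df = pd.read_csv(path, dtype={"location": str})
    _require_columns(df, StringencyPanel.COLUMNS, path)
    return StringencyPanel(df)


# ---------------------------------------------------------------------------
# geometry


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6371.0 km.

    Accepts scalars or broadcastable arrays of coordinates in degrees.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


class DistanceMatrix:
    """Symmetric matrix of great-circle distances (km) indexed by location id."""

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValidationError("distance matrix shape does not match id list")
        self.ids = list(ids)
        self.values = values
        self._pos = {i: k for k, i in enumerate(self.ids)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        try:
            return float(self.values[self._pos[i], self._pos[j]])
        except KeyError as exc:
            raise UnknownLocationError(f"unknown location id {exc.args[0]!r}") from None

    def row(self, loc_id: str) -> np.ndarray:
        if loc_id not in self._pos:
            raise UnknownLocationError(f"unknown location id {loc_id!r}")
        return self.values[self._pos[loc_id]]


def distance_matrix(locations: LocationTable) -> DistanceMatrix:
    """All-pairs haversine distances for a location table (needs >= 2 rows)."""
    if len(locations) < 2:
        raise ValidationError("distance matrix requires at least 2 locations")
    lat = locations.df["lat"].to_numpy()
    lon = locations.df["lon"].to_numpy()
    values = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(values, 0.0)
    # enforce exact symmetry against floating round-off
    values = (values + values.T) / 2.0
    return DistanceMatrix(locations.ids, values)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_daily_total(
    panel: FlowPanel,
    direction: Direction,
    hub_id: str,
    date_range: tuple[_dt.date, _dt.date] | None = None,
) -> pd.Series:
    """Total daily flow summed over all counterpart countries.

    Returns a Series indexed by calendar date.  Days inside *date_range*
    (default: the panel's own span) with no records count as zero, matching
    device-counting semantics.  An empty panel yields an empty series.
    """
    sub = panel.restrict(direction, hub_id)
    if len(sub) == 0:
        return pd.Series(dtype=np.int64, name="total")
    totals = sub.df.groupby("date")["flow"].sum()
    start, end = date_range if date_range is not None else (totals.index.min(), totals.index.max())
    idx = [d.date() for d in pd.date_range(start, end, freq="D")]
    return totals.reindex(idx, fill_value=0).rename("total")


def load_reference_series(path) -> pd.Series:
    """Read a ``date,count`` CSV (e.g. daily air-passenger arrivals)."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "count"], path)
    dates = _as_dates(df["date"])
    return pd.Series(pd.to_numeric(df["count"]).to_numpy(dtype=float), index=list(dates), name="count")


def align_series(x: pd.Series, y: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Require identical date sets; return the two series as aligned arrays."""
    if set(x.index) != set(y.index):
        only_x = sorted(set(x.index) - set(y.index))[:3]
        only_y = sorted(set(y.index) - set(x.index))[:3]
        raise AlignmentError(f"date sets differ (e.g. {only_x} vs {only_y})")
    idx = sorted(x.index)
    return x.loc[idx].to_numpy(dtype=float), y.loc[idx].to_numpy(dtype=float)


def _as_dates(col: pd.Series) -> pd.Series:
    if len(col) and isinstance(col.iloc[0], _dt.date) and not isinstance(col.iloc[0], _dt.datetime):
        return col
    return pd.to_datetime(col).dt.date
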