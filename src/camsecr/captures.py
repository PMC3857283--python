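"""Camera-trap capture records: domain model, I/O and capture-array building.

A *station* is one paired camera set-up treated as a single trap: the two
cameras exist only to photograph both flanks of a passing animal, so left-
and right-flank photographs of the same individual at the same station on
the same survey day collapse to one capture *event*.  Events are binned into
daily *occasions* (one trap night = one occasion) and assembled into the
binary capture array ``y[i, j, k]`` (individual x trap x occasion) that the
spatial capture-recapture model consumes, together with the trap-specific
prior-capture indicator ``C[i, j, k]`` used by the behavioural-response
(model "Mb") term.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TrapStation",
    "PhotoRecord",
    "CaptureEvent",
    "Individual",
    "CaptureArray",
    "BehaviouralIndicator",
    "DesignReport",
    "CaptureFormatError",
    "ReferentialError",
    "read_captures",
    "read_deployment",
    "write_deployment",
    "dedupe_photos",
    "build_capture_array",
    "prior_capture_indicator",
    "trap_nights",
    "validate_design",
    "load_individual_table",
    "individual_from_id",
]


class CaptureFormatError(ValueError):
    """A delimited-text input file does not match the expected dialect."""


class ReferentialError(ValueError):
    """A record refers to a station or individual that is not defined."""


@dataclass(frozen=True)
class TrapStation:
    """One paired camera station; coordinates are planar km (e.g. UTM / 1000)."""

    station_id: str
    x: float
    y: float
    #: per-occasion availability, 1 = camera pair operating that night
    active: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"station {self.station_id}: non-finite coordinates")
        if self.active is not None:
            object.__setattr__(
                self, "active", np.asarray(self.active, dtype=np.int8)
            )


@dataclass(frozen=True)
class PhotoRecord:
    """A single timestamped photograph (minute resolution)."""

    station_id: str
    timestamp: _dt.datetime
    species: str = "leopard"
    individual_id: str | None = None
    flank: str = "unknown"  # left | right | unknown


@dataclass(frozen=True)
class CaptureEvent:
    """A deduplicated capture: one (individual, station, occasion-day)."""

    individual_id: str
    station_id: str
    occasion: int  # 1-based survey day


@dataclass(frozen=True)
class Individual:
    individual_id: str
    age_class: str  # adult | juvenile
    sex: str  # female | male

    def __post_init__(self):
        if self.age_class not in ("adult", "juvenile"):
            raise ValueError(f"bad age_class {self.age_class!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"bad sex {self.sex!r}")


def individual_from_id(individual_id: str) -> Individual:
    """Decode an A/J + F/M prefixed id (AF1, JM2, ...) into an Individual."""
    prefix = individual_id[:2].upper()
    age = {"A": "adult", "J": "juvenile"}.get(prefix[:1])
    sex = {"F": "female", "M": "male"}.get(prefix[1:2])
    if age is None or sex is None:
        raise ValueError(f"id {individual_id!r} has no A/J+F/M prefix")
    return Individual(individual_id, age, sex)


@dataclass
class CaptureArray:
    """Binary capture tensor with its index tables.

    ``y[i, j, k] = 1`` iff individual ``i`` was captured at trap ``j`` on
    occasion ``k``.  Rows/columns are sorted lexicographically by id so a
    given event set always produces the same array.
    """

    y: np.ndarray  # (n, J, K) uint8
    individual_ids: list[str]
    trap_ids: list[str]
    n_occasions: int
    #: (J, 2) planar km trap coordinates, same row order as trap_ids
    trap_xy: np.ndarray = None
    #: (J, K) 0/1 effort mask (trap active on occasion); None = always active
    effort: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.uint8)
        if self.y.ndim != 3:
            raise ValueError("y must be individual x trap x occasion")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y entries must be 0/1")
        if self.y.shape[0] and (self.y.sum(axis=(1, 2)) == 0).any():
            raise ValueError("every individual must have at least one capture")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_traps(self) -> int:
        return self.y.shape[1]


@dataclass
class BehaviouralIndicator:
    """``C[i, j, k] = 1`` iff i was caught in trap j on some occasion < k."""

    C: np.ndarray  # (n, J, K) uint8


# ---------------------------------------------------------------------------
# reading / writing the three-file delimited-text dialect
# ---------------------------------------------------------------------------

_SPACECAP_CAPTURE_COLS = {"LOC_ID", "ANIMAL_ID", "SO"}


def read_captures(
    path,
    survey_start: _dt.date | None = None,
    known_stations: set[str] | None = None,
) -> list[PhotoRecord]:
    """Read an animal-capture file into photo records.

    Two dialects are accepted:

    * ``LOC_ID, ANIMAL_ID, SO`` -- one row per capture with a 1-based
      sampling occasion; the timestamp is reconstructed as noon of
      ``survey_start + (SO - 1)`` days (``survey_start`` defaults to day 1
      of an anonymous calendar).
    * ``station, datetime, species, individual, flank`` -- raw timestamped
      photographs.

    Unparseable rows raise :class:`CaptureFormatError` naming the line
    number; ids absent from ``known_stations`` (when given) raise
    :class:`ReferentialError`.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    start = survey_start or _dt.date(2000, 1, 1)
    records: list[PhotoRecord] = []
    if _SPACECAP_CAPTURE_COLS <= cols:
        for line, row in enumerate(df.itertuples(index=False), start=2):
            try:
                so = int(row.SO)
            except (TypeError, ValueError):
                raise CaptureFormatError(f"line {line}: bad occasion {row.SO!r}")
            ts = _dt.datetime.combine(
                start + _dt.timedelta(days=so - 1), _dt.time(12, 0)
            )
            records.append(
                PhotoRecord(str(row.LOC_ID), ts, "leopard", str(row.ANIMAL_ID))
            )
    elif {"station", "datetime", "species"} <= cols:
        for line, row in enumerate(df.itertuples(index=False), start=2):
            try:
                ts = pd.Timestamp(row.datetime).to_pydatetime()
            except (TypeError, ValueError):
                raise CaptureFormatError(f"line {line}: bad datetime {row.datetime!r}")
            ind = getattr(row, "individual", None)
            ind = None if pd.isna(ind) else str(ind)
            flank = str(getattr(row, "flank", "unknown") or "unknown")
            records.append(
                PhotoRecord(str(row.station), ts, str(row.species), ind, flank)
            )
    else:
        raise CaptureFormatError(
            "expected columns LOC_ID/ANIMAL_ID/SO or station/datetime/species; "
            f"got {sorted(cols)}"
        )
    if known_stations is not None:
        unknown = {r.station_id for r in records} - set(known_stations)
        if unknown:
            raise ReferentialError(
                f"capture file references undeployed stations: {sorted(unknown)}"
            )
    return records


def read_deployment(path, units: str = "km") -> list[TrapStation]:
    """Read a trap-deployment file: ``LOC_ID, X, Y`` then one binary column
    per occasion.  ``units='m'`` converts metre coordinates to km."""
    df = pd.read_csv(path)
    required = {"LOC_ID", "X", "Y"}
    if not required <= set(df.columns):
        raise CaptureFormatError(f"deployment file must have columns {sorted(required)}")
    occ_cols = [c for c in df.columns if c not in required]
    scale = 1e-3 if units == "m" else 1.0
    stations = []
    for row in df.itertuples(index=False):
        active = np.array([int(getattr(row, c)) for c in occ_cols], dtype=np.int8)
        if not np.isin(active, (0, 1)).all():
            raise CaptureFormatError(f"station {row.LOC_ID}: activity flags must be 0/1")
        stations.append(
            TrapStation(str(row.LOC_ID), float(row.X) * scale, float(row.Y) * scale, active)
        )
    if len({s.station_id for s in stations}) != len(stations):
        raise CaptureFormatError("duplicate LOC_ID in deployment file")
    return stations


def write_deployment(stations: list[TrapStation], path) -> None:
    rows = []
    for s in stations:
        row = {"LOC_ID": s.station_id, "X": s.x, "Y": s.y}
        row.update({f"D{k + 1}": int(a) for k, a in enumerate(s.active)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_individual_table() -> pd.DataFrame:
    """The packaged individual roster (id, age/sex class, capture totals)."""
    with resources.files("camsecr.data").joinpath("table1_individuals.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# photos -> events -> capture array
# ---------------------------------------------------------------------------

def dedupe_photos(
    photos: list[PhotoRecord], survey_start: _dt.date | None = None
) -> list[CaptureEvent]:
    """Collapse flank photographs to one event per (individual, station, day).

    Both cameras of a pair may fire, and an animal may linger, so several
    photographs routinely document a single nightly visit.  Occasions are
    1-based calendar days counted from ``survey_start`` (default: the date of
    the earliest photo).
    """
    if any(p.individual_id is None for p in photos):
        raise ValueError("dedupe_photos requires individual_id on every photo")
    if not photos:
        return []
    start = survey_start or min(p.timestamp for p in photos).date()
    seen: set[tuple[str, str, int]] = set()
    events = []
    for p in sorted(photos, key=lambda p: p.timestamp):
        occ = (p.timestamp.date() - start).days + 1
        key = (p.individual_id, p.station_id, occ)
        if key not in seen:
            seen.add(key)
            events.append(CaptureEvent(*key))
    return events


def build_capture_array(
    events: list[CaptureEvent],
    stations: list[TrapStation],
    individuals: list[Individual] | None = None,
    adults_only: bool = False,
    n_occasions: int | None = None,
) -> CaptureArray:
    """Assemble the binary capture tensor from deduplicated events.

    ``individuals`` supplies age/sex labels; if omitted they are decoded from
    the A/J+F/M id prefix.  With ``adults_only`` juveniles are dropped (the
    density model is fitted to the adult population).  Events on occasions
    when the trap was inactive are an error.
    """
    if not events:
        raise ValueError("no capture events: cannot build a capture array")
    if individuals is None:
        individuals = [individual_from_id(i) for i in sorted({e.individual_id for e in events})]
    by_id = {ind.individual_id: ind for ind in individuals}
    missing = {e.individual_id for e in events} - set(by_id)
    if missing:
        raise ReferentialError(f"events reference unknown individuals: {sorted(missing)}")
    keep = {
        i for i, ind in by_id.items() if not (adults_only and ind.age_class == "juvenile")
    }
    events = [e for e in events if e.individual_id in keep]
    if not events:
        raise ValueError("no events remain after age filtering")

    trap_ids = sorted(s.station_id for s in stations)
    trap_index = {t: j for j, t in enumerate(trap_ids)}
    unknown_traps = {e.station_id for e in events} - set(trap_index)
    if unknown_traps:
        raise ReferentialError(f"events reference unknown stations: {sorted(unknown_traps)}")

    K = n_occasions or max(len(s.active) for s in stations if s.active is not None)
    ind_ids = sorted({e.individual_id for e in events})
    ind_index = {i: n for n, i in enumerate(ind_ids)}

    active = np.ones((len(trap_ids), K), dtype=np.int8)
    st_by_id = {s.station_id: s for s in stations}
    for t, j in trap_index.items():
        if st_by_id[t].active is not None:
            active[j, : len(st_by_id[t].active)] = st_by_id[t].active

    y = np.zeros((len(ind_ids), len(trap_ids), K), dtype=np.uint8)
    bad = []
    for e in events:
        if not 1 <= e.occasion <= K:
            bad.append(e)
            continue
        j = trap_index[e.station_id]
        if not active[j, e.occasion - 1]:
            bad.append(e)
            continue
        y[ind_index[e.individual_id], j, e.occasion - 1] = 1
    if bad:
        raise ValueError(f"events on inactive traps or out-of-range occasions: {bad}")
    trap_xy = np.array([[st_by_id[t].x, st_by_id[t].y] for t in trap_ids])
    return CaptureArray(y, ind_ids, trap_ids, K, trap_xy, active)


def prior_capture_indicator(arr: CaptureArray) -> BehaviouralIndicator:
    """C[i,j,k] = 1 iff individual i was captured in trap j before occasion k."""
    y = arr.y
    C = np.zeros_like(y)
    if y.shape[2] > 1:
        C[:, :, 1:] = np.maximum.accumulate(y[:, :, :-1], axis=2)
    return BehaviouralIndicator(C)


def trap_nights(stations: list[TrapStation]) -> int:
    """Total station-occasions of effort; a paired station counts once per night."""
    return int(sum(int(np.sum(s.active)) for s in stations))


# ---------------------------------------------------------------------------
# survey-design validation
# ---------------------------------------------------------------------------

@dataclass
class DesignReport:
    spacing_violations: list[tuple[str, float]]
    coverage_violations: list[tuple[float, float, int]]
    nearest_neighbour_km: dict[str, float]

    @property
    def spacing_ok(self) -> bool:
        return not self.spacing_violations

    @property
    def coverage_ok(self) -> bool:
        return not self.coverage_violations

    @property
    def ok(self) -> bool:
        return self.spacing_ok and self.coverage_ok


def validate_design(
    stations: list[TrapStation],
    min_spacing_km: float = 1.7,
    max_spacing_km: float = 3.5,
    coverage_area_km2: float = 9.0,
    min_stations: int = 2,
    coverage_step_km: float = 0.5,
) -> DesignReport:
    """Check station spacing and coverage against the survey-design rules.

    Spacing: each station's nearest-neighbour distance must lie in
    [min, max] km (too close wastes effort, too far risks a gap that could
    hold a whole home range).  Coverage: an axis-aligned square of
    ``coverage_area_km2`` slid at ``coverage_step_km`` over the station
    bounding box must always contain at least ``min_stations`` stations, so
    no home-range-sized hole is uncovered.  Identical coordinates are
    flagged as spacing violations, not fatal errors.
    """
    if len(stations) < 2:
        raise ValueError("need at least 2 stations to validate a design")
    xy = np.array([[s.x, s.y] for s in stations])
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    spacing_violations = [
        (s.station_id, float(nn[i]))
        for i, s in enumerate(stations)
        if not (min_spacing_km <= nn[i] <= max_spacing_km)
    ]

    side = float(np.sqrt(coverage_area_km2))
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    coverage_violations = []
    # window origins clamped so windows stay on the trap bounding box
    xs = np.arange(x0, max(x1 - side, x0) + 1e-9, coverage_step_km)
    ys = np.arange(y0, max(y1 - side, y0) + 1e-9, coverage_step_km)
    for wx in xs:
        for wy in ys:
            inside = (
                (xy[:, 0] >= wx)
                & (xy[:, 0] <= wx + side)
                & (xy[:, 1] >= wy)
                & (xy[:, 1] <= wy + side)
            )
            if inside.sum() < min_stations:
                coverage_violations.append((float(wx), float(wy), int(inside.sum())))
    return DesignReport(
        spacing_violations,
        coverage_violations,
        {s.station_id: float(nn[i]) for i, s in enumerate(stations)},
    )
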