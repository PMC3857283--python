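"""Prey relative-abundance indices from camera-trap photo streams.

Two simple indices summarise how often and how quickly each species turns
up on camera:

* capture frequency — independent photographic events per 100 camera days;
* RAI (capture-effort index) — whole survey days until the species' first
  photograph, 0 meaning it was photographed on day one (low effort, high
  relative abundance).

An *independent event* follows the standard one-hour rule: a photo counts
if the previous photo at that station was of a different species, or the
previous same-species photo is more than the independence window away.
Filtering is per station, since non-independence is about the same animal
lingering at one camera.
"""

from __future__ import annotations

import datetime as _dt

import pandas as pd

from .captures import PhotoRecord

__all__ = ["independent_events", "capture_frequency", "rai_score", "rai_table"]


def independent_events(
    photos: list[PhotoRecord],
    window_hours: float = 1.0,
    compare: str = "previous_photo",
) -> dict[str, list[PhotoRecord]]:
    """Filter a photo stream to independent events, per species.

    ``compare`` selects what the one-hour clock is measured against:
    ``"previous_photo"`` (default) times against the last same-species
    *photograph* at the station, ``"previous_event"`` against the last
    same-species *independent event*.
    """
    if compare not in ("previous_photo", "previous_event"):
        raise ValueError("compare must be 'previous_photo' or 'previous_event'")
    window = _dt.timedelta(hours=window_hours)
    events: dict[str, list[PhotoRecord]] = {}
    by_station: dict[str, list[PhotoRecord]] = {}
    for p in sorted(photos, key=lambda p: p.timestamp):
        by_station.setdefault(p.station_id, []).append(p)
    for recs in by_station.values():
        last_photo_species: str | None = None
        last_same: dict[str, _dt.datetime] = {}
        for p in recs:
            ref = last_same.get(p.species)
            independent = (
                ref is None
                or last_photo_species != p.species
                or p.timestamp - ref > window
            )
            if independent:
                events.setdefault(p.species, []).append(p)
                if compare == "previous_event":
                    last_same[p.species] = p.timestamp
            if compare == "previous_photo":
                last_same[p.species] = p.timestamp
            last_photo_species = p.species
    for sp in events:
        events[sp].sort(key=lambda p: p.timestamp)
    return events


def capture_frequency(events, camera_days: float) -> float:
    """Independent events per 100 camera days of effort."""
    if camera_days <= 0:
        raise ValueError("camera_days must be positive")
    n = len(events)
    return 100.0 * n / camera_days


def rai_score(
    photos: list[PhotoRecord], species: str, survey_start: _dt.date
) -> int | None:
    """Whole days of effort until the species' first photograph.

    0 means photographed on the survey's first day; ``None`` means the
    species was never detected (explicitly not a number).
    """
    times = [p.timestamp for p in photos if p.species == species]
    if not times:
        return None
    first = min(times)
    if first.date() < survey_start:
        raise ValueError("photo precedes the survey start")
    return (first.date() - survey_start).days


def rai_table(
    photos: list[PhotoRecord],
    camera_days: float,
    survey_start: _dt.date,
    window_hours: float = 1.0,
    exclude_species: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-species capture frequency and RAI, sorted by frequency (desc).

    ``exclude_species`` drops e.g. the focal predator from a prey table.
    """
    keep = [p for p in photos if p.species not in exclude_species]
    ev = independent_events(keep, window_hours)
    rows = [
        {
            "species": sp,
            "capture_frequency": capture_frequency(ev[sp], camera_days),
            "rai": rai_score(keep, sp, survey_start),
        }
        for sp in ev
    ]
    df = pd.DataFrame(rows, columns=["species", "capture_frequency", "rai"])
    return df.sort_values(
        ["capture_frequency", "species"], ascending=[False, True]
    ).reset_index(drop=True)
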