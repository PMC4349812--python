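"""Same-day track reconstruction for mammals sighted at longline hauls.

If one group of animals could physically have produced several sightings at
different hauls on the same day, those sightings chain into a *potential
track*.  The chaining rule: within a day, sightings are taken in haul order
and linked whenever consecutive positions are within a distance threshold
(default 50 km, an approximate orca daily travel distance); a larger gap
starts a new chain.  Days with a single sighting, and singleton chains left
after splitting, yield no track.
"""

from __future__ import annotations

import datetime as dt
import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import LonglineSetRecord, Species
from .spatial import DEFAULT_AREAS, AreaScheme, assign_area, haversine_km
from .stats import records_to_frame

__all__ = [
    "Ordering",
    "TrackConfig",
    "ObservationPoint",
    "PotentialTrack",
    "species_observation_points",
    "build_daily_tracks",
    "track_summary",
]


class Ordering(enum.Enum):
    HAUL_TIME = "haul_time"  # order key = haul order within (vessel, date)
    RECORD_ORDER = "record_order"


@dataclass(frozen=True)
class TrackConfig:
    """``retain_singletons`` keeps length-1 chains as degenerate tracks for
    accounting (the chain count is then monotone non-increasing in
    ``max_link_km``, since raising the threshold can only merge chains);
    by default they are discarded and every track has >= 2 sightings."""

    max_link_km: float = 50.0
    ordering: Ordering = Ordering.HAUL_TIME
    retain_singletons: bool = False

    def __post_init__(self) -> None:
        if self.max_link_km <= 0:
            raise ValueError("max_link_km must be positive")


@dataclass(frozen=True)
class ObservationPoint:
    """One sighting of the tracked species at a hauled set."""

    set_id: str
    date: dt.date
    lat: float
    lon: float
    order_key: float = 0.0
    vessel_id: str = ""


@dataclass(frozen=True)
class PotentialTrack:
    """An ordered same-day chain of >= 2 sightings, consecutive pairs within
    the link threshold."""

    date: dt.date
    points: tuple[ObservationPoint, ...]
    total_path_km: float

    @property
    def n_links(self) -> int:
        return len(self.points) - 1


def species_observation_points(
    records: Sequence[LonglineSetRecord], species: Species = Species.ORCA
) -> list[ObservationPoint]:
    """Extract sighting points of one species from screened records, keyed
    for HAUL_TIME ordering."""
    return [
        ObservationPoint(
            set_id=rec.set_id,
            date=rec.date,
            lat=rec.lat,
            lon=rec.lon,
            order_key=float(rec.haul_order),
            vessel_id=rec.vessel_id,
        )
        for rec in records
        if rec.has(species)
    ]


def build_daily_tracks(
    observations: Iterable[ObservationPoint],
    config: TrackConfig = TrackConfig(),
) -> list[PotentialTrack]:
    """Chain same-day sightings into potential tracks.

    Per date, sightings are sorted by the order key (ties broken
    deterministically by set_id, with a warning) and a new chain starts
    whenever the next sighting is more than ``max_link_km`` from the previous
    one.  Chains of length one — including days with a single sighting —
    are discarded.
    """
    by_date: dict[dt.date, list[ObservationPoint]] = {}
    for obs in observations:
        by_date.setdefault(obs.date, []).append(obs)

    tracks: list[PotentialTrack] = []
    dup_days = 0
    for date in sorted(by_date):
        day = by_date[date]
        if len(day) < 2:
            continue  # singular observation per day: no track
        if config.ordering is Ordering.HAUL_TIME:
            if len({o.order_key for o in day}) < len(day):
                dup_days += 1
            day = sorted(day, key=lambda o: (o.order_key, o.set_id))
        # RECORD_ORDER keeps input order (stable)
        chains: list[list[ObservationPoint]] = [[day[0]]]
        for prev, cur in zip(day, day[1:]):
            if haversine_km((prev.lat, prev.lon), (cur.lat, cur.lon)) <= config.max_link_km:
                chains[-1].append(cur)
            else:
                chains.append([cur])
        for chain in chains:
            if len(chain) < 2 and not config.retain_singletons:
                continue  # isolated observation after a split: discarded
            path = sum(
                haversine_km((a.lat, a.lon), (b.lat, b.lon))
                for a, b in zip(chain, chain[1:])
            )
            tracks.append(
                PotentialTrack(date=date, points=tuple(chain), total_path_km=float(path))
            )
    if dup_days:
        warnings.warn(
            f"duplicate order keys on {dup_days} day(s), tie-broken by set_id",
            stacklevel=2,
        )
    return tracks


def track_summary(
    tracks: Sequence[PotentialTrack],
    scheme: AreaScheme = DEFAULT_AREAS,
) -> pd.DataFrame:
    """Aggregate tracks per (date, area): count, mean path length and number
    of distinct vessels involved.  A track's area is taken from its first
    sighting's position."""
    rows = []
    for track in tracks:
        first = track.points[0]
        rows.append(
            {
                "date": track.date,
                "area": assign_area(first.lat, first.lon, scheme).value,
                "path_km": track.total_path_km,
                "vessels": frozenset(p.vessel_id for p in track.points if p.vessel_id),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["date", "area", "n_tracks", "mean_path_km", "n_vessels"])
    frame = pd.DataFrame(rows)
    out = frame.groupby(["date", "area"]).agg(
        n_tracks=("path_km", "size"),
        mean_path_km=("path_km", "mean"),
        n_vessels=("vessels", lambda sets: len(frozenset().union(*sets))),
    )
    return out.reset_index()
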