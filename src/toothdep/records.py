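"""Observer-record data model, CSV reader/writer and consistency screening.

The atomic unit of the whole pipeline is one hauled longline set, carried by
:class:`LonglineSetRecord`: where and when it was hauled, the effort (hooks),
the toothfish catch mass, whether a scientific observer was present, and any
marine-mammal observations attached to the haul.  Mammal observations are
flattened in the CSV to per-species count/feeding columns (``orca_n``,
``orca_feeding``, ...) because observer data arrive one row per set.

Coordinates are signed decimal degrees (south and west negative); dates are
ISO-8601.  Season membership and spatial bins are always derived, never
stored in the input table.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Species",
    "MammalObservation",
    "LonglineSetRecord",
    "RowError",
    "SchemaError",
    "ScreeningRules",
    "ScreeningReport",
    "read_sets",
    "write_sets",
    "screen_sets",
    "REGION_LAT",
    "REGION_LON",
]

#: Latitude / longitude bounds of the study region (53-56 S, 34-45 W),
#: i.e. the statistical reporting area around South Georgia.
REGION_LAT = (-56.0, -53.0)
REGION_LON = (-45.0, -34.0)


class Species(enum.Enum):
    """Marine-mammal species recorded at longline hauls.

    The three focal species are the ones abundant enough to analyse; every
    other species string in raw data maps to ``OTHER`` and is removed from
    records at screening time.
    """

    ORCA = "orca"
    SPERM_WHALE = "sperm_whale"
    FUR_SEAL = "fur_seal"
    OTHER = "other"


#: Species kept by default screening rules.
FOCAL_SPECIES = (Species.ORCA, Species.SPERM_WHALE, Species.FUR_SEAL)


@dataclass(frozen=True)
class MammalObservation:
    """One species' observation at a single haul: head count and feeding flag."""

    species: Species
    count: int
    feeding: bool

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"observation count must be >= 1, got {self.count}")


@dataclass
class LonglineSetRecord:
    """One hauled longline set with catch, effort, position and observations."""

    set_id: str
    vessel_id: str
    cruise_id: str
    date: dt.date
    haul_order: int
    lat: float
    lon: float
    hooks: int
    catch_kg: float
    observed: bool
    observations: list[MammalObservation] = field(default_factory=list)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated record invariant."""
        if self.hooks < 1:
            raise ValueError(f"hooks must be >= 1, got {self.hooks}")
        if self.catch_kg < 0:
            raise ValueError(f"catch_kg must be >= 0, got {self.catch_kg}")
        seen: set[Species] = set()
        for obs in self.observations:
            if obs.species in seen:
                raise ValueError(f"duplicate observation for {obs.species.value}")
            seen.add(obs.species)

    # -- observation accessors -------------------------------------------------

    def observation_for(self, species: Species) -> MammalObservation | None:
        for obs in self.observations:
            if obs.species is species:
                return obs
        return None

    def has(self, species: Species) -> bool:
        return self.observation_for(species) is not None

    def is_feeding(self, species: Species) -> bool:
        obs = self.observation_for(species)
        return obs is not None and obs.feeding

    @property
    def year(self) -> int:
        return self.date.year

    @property
    def month(self) -> int:
        return self.date.month


class SchemaError(ValueError):
    """The input table is missing a mandatory column."""


@dataclass(frozen=True)
class RowError:
    """A structured per-row parse failure (1-based line number in the file)."""

    line: int
    message: str


_BASE_COLUMNS = [
    "set_id",
    "vessel_id",
    "cruise_id",
    "date",
    "haul_order",
    "lat",
    "lon",
    "hooks",
    "catch_kg",
    "observed",
]

_SPECIES_COLUMNS = {
    Species.ORCA: ("orca_n", "orca_feeding"),
    Species.SPERM_WHALE: ("sperm_whale_n", "sperm_whale_feeding"),
    Species.FUR_SEAL: ("fur_seal_n", "fur_seal_feeding"),
    Species.OTHER: ("other_n", "other_feeding"),
}

CSV_COLUMNS = _BASE_COLUMNS + [c for pair in _SPECIES_COLUMNS.values() for c in pair]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(text: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _parse_row(row: dict[str, str]) -> LonglineSetRecord:
    observations = []
    for species, (n_col, feed_col) in _SPECIES_COLUMNS.items():
        n_text = (row.get(n_col) or "").strip()
        n = int(n_text) if n_text else 0
        if n > 0:
            observations.append(
                MammalObservation(species, n, _parse_bool(row.get(feed_col) or ""))
            )
    record = LonglineSetRecord(
        set_id=row["set_id"].strip(),
        vessel_id=row["vessel_id"].strip(),
        cruise_id=row["cruise_id"].strip(),
        date=dt.date.fromisoformat(row["date"].strip()),
        haul_order=int(row["haul_order"]),
        lat=float(row["lat"]),
        lon=float(row["lon"]),
        hooks=int(row["hooks"]),
        catch_kg=float(row["catch_kg"]),
        observed=_parse_bool(row["observed"]),
        observations=observations,
    )
    record.validate()
    return record


def read_sets(path: str | Path) -> tuple[list[LonglineSetRecord], list[RowError]]:
    """Read longline-set records from a CSV file.

    Returns ``(records, errors)``: every input row is either parsed into a
    record or reported as a :class:`RowError` with its 1-based line number.
    A missing mandatory column raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    records: list[LonglineSetRecord] = []
    errors: list[RowError] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        for column in _BASE_COLUMNS:
            if column not in header:
                raise SchemaError(f"missing mandatory column: {column!r}")
        for row in reader:
            line = reader.line_num
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line=line, message=str(exc)))
    return records, errors


def write_sets(records: Iterable[LonglineSetRecord], path: str | Path) -> None:
    """Write records to CSV with the documented flattened column schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row: list[object] = [
                rec.set_id,
                rec.vessel_id,
                rec.cruise_id,
                rec.date.isoformat(),
                rec.haul_order,
                repr(rec.lat),
                repr(rec.lon),
                rec.hooks,
                repr(rec.catch_kg),
                int(rec.observed),
            ]
            for species in _SPECIES_COLUMNS:
                obs = rec.observation_for(species)
                row.extend([obs.count, int(obs.feeding)] if obs else [0, 0])
            writer.writerow(row)


# -- screening -----------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningRules:
    """Consistency screening applied before any analysis.

    Unobserved hauls carry no reliable mammal information and are dropped;
    so are records from years with known data inconsistencies (the first
    year of full observer coverage, by default).  Non-focal species
    observations are stripped from retained records; optionally whole sets
    carrying them can be dropped instead.
    """

    excluded_years: frozenset[int] = frozenset({1996})
    require_observed: bool = True
    strip_other_species: bool = True
    drop_sets_with_other: bool = False


@dataclass(frozen=True)
class ScreeningReport:
    """Reconciled accounting of screening drops: counts always sum to input."""

    n_input: int
    n_dropped_unobserved: int
    n_dropped_year: int
    n_dropped_species: int
    n_retained: int
    n_other_obs_removed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_dropped_unobserved
            + self.n_dropped_year
            + self.n_dropped_species
        )
        if total != self.n_input:
            raise ValueError("screening report counts do not reconcile")


def screen_sets(
    records: Sequence[LonglineSetRecord],
    rules: ScreeningRules = ScreeningRules(),
) -> tuple[list[LonglineSetRecord], ScreeningReport]:
    """Apply screening rules; never fails, only drops (reasons are ordered:
    unobserved, then excluded year, then species)."""
    kept: list[LonglineSetRecord] = []
    n_unobserved = n_year = n_species = n_other_obs = 0
    for rec in records:
        if rules.require_observed and not rec.observed:
            n_unobserved += 1
            continue
        if rec.year in rules.excluded_years:
            n_year += 1
            continue
        has_other = rec.has(Species.OTHER)
        if has_other and rules.drop_sets_with_other:
            n_species += 1
            continue
        if has_other and rules.strip_other_species:
            n_other_obs += 1
            rec = replace(
                rec,
                observations=[
                    o for o in rec.observations if o.species is not Species.OTHER
                ],
            )
        kept.append(rec)
    report = ScreeningReport(
        n_input=len(records),
        n_dropped_unobserved=n_unobserved,
        n_dropped_year=n_year,
        n_dropped_species=n_species,
        n_retained=len(kept),
        n_other_obs_removed=n_other_obs,
    )
    return kept, report
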