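"""Catch-rate and depredation statistics.

Everything here works on screened :class:`~toothdep.records.LonglineSetRecord`
lists, converted internally to a flat pandas frame with spatial bins attached
(:func:`records_to_frame`).  The statistics are:

* CPUE (kg of toothfish per hook) and OPUE (animals observed per longline set
  within a spatial group) — the two normalised rates everything else builds on;
* scenario-stratified mean catch rates (a scenario is a predicate over
  presence/feeding of the three focal species);
* a stratified label-permutation test for the presence effect on CPUE, the
  in-scope replacement for full mixed-model inference;
* per-cell depredation percentage on the 10 km grid and hot-spot detection
  (cells exceeding the mean + 1 SD of valid cells);
* spatio-temporally nearest unaffected-line matching;
* the annual interaction summary table with its average and total rows;
* the fishing-intensity vs orca-interaction correlation.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import LonglineSetRecord, Species
from .spatial import (
    DEFAULT_AREAS,
    DEFAULT_GRID,
    AreaScheme,
    CellId,
    GridSpec,
    Resolution,
    assign_area,
    assign_halfdeg_box,
    assign_km_cell,
    haversine_km,
)

__all__ = [
    "cpue",
    "g_per_hook",
    "round_half_up",
    "records_to_frame",
    "ScenarioState",
    "ScenarioSpec",
    "ScenarioError",
    "default_scenarios",
    "opue",
    "scenario_cpue",
    "PresenceEffectResult",
    "presence_effect_test",
    "CellDepredationStat",
    "cell_depredation",
    "HotspotResult",
    "detect_hotspots",
    "MatchResult",
    "match_nearest_unaffected",
    "annual_summary",
    "append_average_total",
    "CorrelationResult",
    "intensity_interaction_correlation",
]

_FOCAL = (Species.FUR_SEAL, Species.SPERM_WHALE, Species.ORCA)


def cpue(catch_kg, hooks):
    """Catch per unit effort in kg/hook. Vectorised; hooks must be >= 1."""
    hooks_arr = np.asarray(hooks)
    if np.any(hooks_arr < 1):
        raise ValueError("hooks must be >= 1")
    out = np.asarray(catch_kg, dtype=float) / hooks_arr
    return float(out) if np.ndim(out) == 0 else out


def g_per_hook(kg_per_hook):
    """Reporting helper: convert kg/hook to g/hook."""
    out = np.asarray(kg_per_hook, dtype=float) * 1000.0
    return float(out) if np.ndim(out) == 0 else out


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, as used in the report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def records_to_frame(
    records: Sequence[LonglineSetRecord],
    grid: GridSpec = DEFAULT_GRID,
    scheme: AreaScheme = DEFAULT_AREAS,
    *,
    spatial: bool = True,
) -> pd.DataFrame:
    """Flatten records to one row per set, with per-species presence/feeding
    columns and (optionally) area / box / 10 km cell assignments.

    Out-of-region sets get null spatial columns rather than failing."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "set_id": rec.set_id,
            "vessel_id": rec.vessel_id,
            "cruise_id": rec.cruise_id,
            "date": pd.Timestamp(rec.date),
            "year": rec.year,
            "month": rec.month,
            "haul_order": rec.haul_order,
            "lat": rec.lat,
            "lon": rec.lon,
            "hooks": rec.hooks,
            "catch_kg": rec.catch_kg,
            "cpue": rec.catch_kg / rec.hooks,
            "observed": rec.observed,
        }
        for species in _FOCAL:
            obs = rec.observation_for(species)
            row[f"{species.value}_n"] = obs.count if obs else 0
            row[f"{species.value}_present"] = obs is not None
            row[f"{species.value}_feeding"] = bool(obs and obs.feeding)
        if spatial:
            box = assign_halfdeg_box(rec.lat, rec.lon, grid, strict=False)
            cell = assign_km_cell(rec.lat, rec.lon, grid, strict=False)
            row["area"] = (
                assign_area(rec.lat, rec.lon, scheme, grid).value
                if grid.in_region(rec.lat, rec.lon)
                else None
            )
            row["box_i"] = box.i if box else None
            row["box_j"] = box.j if box else None
            row["cell_i"] = cell.i if cell else None
            row["cell_j"] = cell.j if cell else None
        rows.append(row)
    return pd.DataFrame(rows)


# -- scenarios -----------------------------------------------------------------


class ScenarioError(ValueError):
    """Contradictory or malformed scenario specification."""


class ScenarioState(enum.Enum):
    """Per-species constraint in a catch-rate scenario.

    FEEDING implies present; NOT_FEEDING means present and not feeding;
    ANY places no constraint."""

    PRESENT = "present"
    ABSENT = "absent"
    FEEDING = "feeding"
    NOT_FEEDING = "not_feeding"
    ANY = "any"


@dataclass(frozen=True)
class ScenarioSpec:
    """A predicate over the three focal species; a set matches iff all three
    per-species constraints hold."""

    orca: ScenarioState = ScenarioState.ANY
    sperm_whale: ScenarioState = ScenarioState.ANY
    fur_seal: ScenarioState = ScenarioState.ANY
    name: str = ""

    def state_for(self, species: Species) -> ScenarioState:
        return {
            Species.ORCA: self.orca,
            Species.SPERM_WHALE: self.sperm_whale,
            Species.FUR_SEAL: self.fur_seal,
        }[species]

    @classmethod
    def from_constraints(
        cls, constraints: dict[str, Sequence[str] | str], name: str = ""
    ) -> "ScenarioSpec":
        """Build from e.g. ``{"orca": "present", "fur_seal": ["feeding"]}``;
        listing both ``absent`` and ``feeding`` for one species is
        contradictory and raises :class:`ScenarioError`."""
        kwargs: dict[str, ScenarioState] = {}
        for key, value in constraints.items():
            states = [value] if isinstance(value, str) else list(value)
            parsed = {ScenarioState(s) for s in states}
            if ScenarioState.ABSENT in parsed and parsed & {
                ScenarioState.PRESENT,
                ScenarioState.FEEDING,
                ScenarioState.NOT_FEEDING,
            }:
                raise ScenarioError(f"contradictory constraints for {key}: {states}")
            if len(parsed - {ScenarioState.ANY}) > 1:
                raise ScenarioError(f"multiple constraints for {key}: {states}")
            remaining = parsed - {ScenarioState.ANY}
            kwargs[key] = remaining.pop() if remaining else ScenarioState.ANY
        return cls(name=name, **kwargs)

    def matches(self, record: LonglineSetRecord) -> bool:
        for species in _FOCAL:
            state = self.state_for(species)
            present = record.has(species)
            feeding = record.is_feeding(species)
            if state is ScenarioState.PRESENT and not present:
                return False
            if state is ScenarioState.ABSENT and present:
                return False
            if state is ScenarioState.FEEDING and not feeding:
                return False
            if state is ScenarioState.NOT_FEEDING and not (present and not feeding):
                return False
        return True

    def mask(self, frame: pd.DataFrame) -> pd.Series:
        """Vectorised match over a :func:`records_to_frame` frame."""
        out = pd.Series(True, index=frame.index)
        for species in _FOCAL:
            state = self.state_for(species)
            present = frame[f"{species.value}_present"]
            feeding = frame[f"{species.value}_feeding"]
            if state is ScenarioState.PRESENT:
                out &= present
            elif state is ScenarioState.ABSENT:
                out &= ~present
            elif state is ScenarioState.FEEDING:
                out &= feeding
            elif state is ScenarioState.NOT_FEEDING:
                out &= present & ~feeding
        return out


def default_scenarios(pairwise: bool = True) -> dict[str, ScenarioSpec]:
    """The default scenario catalogue: no-mammals, each species marginally
    present / feeding / not-feeding / absent, and (optionally) pairwise
    present/absent combinations.  The catalogue size is a consequence of the
    requested combinations, not a fixed constant."""
    A = ScenarioState
    catalogue: dict[str, ScenarioSpec] = {
        "no_mammals": ScenarioSpec(A.ABSENT, A.ABSENT, A.ABSENT, name="no_mammals")
    }
    for species in _FOCAL:
        for state in (A.PRESENT, A.FEEDING, A.NOT_FEEDING, A.ABSENT):
            name = f"{species.value}_{state.value}"
            catalogue[name] = ScenarioSpec(
                name=name, **{species.value: state}
            )
    if pairwise:
        pairs = [
            (Species.ORCA, Species.SPERM_WHALE),
            (Species.ORCA, Species.FUR_SEAL),
            (Species.SPERM_WHALE, Species.FUR_SEAL),
        ]
        for a, b in pairs:
            for sa, sb in ((A.PRESENT, A.PRESENT), (A.PRESENT, A.ABSENT), (A.ABSENT, A.PRESENT)):
                name = f"{a.value}_{sa.value}__{b.value}_{sb.value}"
                catalogue[name] = ScenarioSpec(
                    name=name, **{a.value: sa, b.value: sb}
                )
    return catalogue


# -- rate tables ---------------------------------------------------------------

_GROUP_COLS = {"box": ["box_i", "box_j"], "area": ["area"], "cell": ["cell_i", "cell_j"]}


def opue(
    records: Sequence[LonglineSetRecord],
    species: Species,
    grouping: str = "box",
    period: str = "month",
    grid: GridSpec = DEFAULT_GRID,
    scheme: AreaScheme = DEFAULT_AREAS,
    *,
    numerator: str = "animals",
) -> pd.DataFrame:
    """Observations per unit effort: animals of ``species`` per longline set,
    per spatial group and period.  Groups with zero sets are simply absent.

    ``numerator="events"`` counts observation events (sets with the species)
    instead of animals."""
    if grouping not in _GROUP_COLS:
        raise ValueError(f"grouping must be one of {sorted(_GROUP_COLS)}")
    if period not in ("month", "year"):
        raise ValueError("period must be 'month' or 'year'")
    frame = records_to_frame(records, grid, scheme)
    if frame.empty:
        return pd.DataFrame(
            columns=_GROUP_COLS[grouping] + [period, "n_sets", "n_animals", "opue"]
        )
    keys = _GROUP_COLS[grouping] + [period]
    col = f"{species.value}_n" if numerator == "animals" else f"{species.value}_present"
    grouped = frame.groupby(keys, dropna=True).agg(
        n_sets=("set_id", "size"), n_animals=(col, "sum")
    )
    grouped["opue"] = grouped["n_animals"] / grouped["n_sets"]
    return grouped.reset_index()


def scenario_cpue(
    records: Sequence[LonglineSetRecord],
    scenario: ScenarioSpec,
    grouping: str | None = "area",
    grid: GridSpec = DEFAULT_GRID,
    scheme: AreaScheme = DEFAULT_AREAS,
) -> pd.DataFrame:
    """Mean CPUE (kg/hook) with n over sets matching the scenario, per
    spatial group (or overall when ``grouping`` is None)."""
    frame = records_to_frame(records, grid, scheme)
    if frame.empty:
        return pd.DataFrame(columns=["mean_cpue", "n"])
    sub = frame[scenario.mask(frame)]
    if grouping is None:
        return pd.DataFrame(
            {"mean_cpue": [sub["cpue"].mean() if len(sub) else np.nan], "n": [len(sub)]}
        )
    if grouping not in _GROUP_COLS:
        raise ValueError(f"grouping must be None or one of {sorted(_GROUP_COLS)}")
    grouped = sub.groupby(_GROUP_COLS[grouping], dropna=True).agg(
        mean_cpue=("cpue", "mean"), n=("cpue", "size")
    )
    return grouped.reset_index()


# -- permutation test ----------------------------------------------------------


@dataclass(frozen=True)
class PresenceEffectResult:
    observed_diff: float  # mean CPUE(present) - mean CPUE(absent), kg/hook
    p_value: float
    n_permutations: int
    n_present: int
    n_absent: int
    n_strata: int
    n_strata_dropped: int


def presence_effect_test(
    records: Sequence[LonglineSetRecord],
    species: Species,
    n_permutations: int = 999,
    seed: int | None = None,
    grid: GridSpec = DEFAULT_GRID,
    scheme: AreaScheme = DEFAULT_AREAS,
) -> PresenceEffectResult:
    """Permutation test of the species-presence effect on CPUE.

    The presence flag is permuted within (area, month) strata, holding the
    spatio-temporal structure of effort fixed; the statistic is the pooled
    mean CPUE difference (present minus absent).  Two-sided p-value with the
    +1 add-one correction.  Strata containing a single presence class carry
    no information about the label and are dropped with a warning.
    """
    frame = records_to_frame(records, grid, scheme)
    flag_col = f"{species.value}_present"
    keep_parts = []
    n_dropped = 0
    for _, part in frame.groupby(["area", "month"], dropna=True):
        if part[flag_col].nunique() < 2 or len(part) < 2:
            n_dropped += 1
            continue
        keep_parts.append(part)
    if not keep_parts:
        raise ValueError("no stratum contains both presence classes")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} single-class (area, month) strata dropped", stacklevel=2
        )
    data = pd.concat(keep_parts)
    values = data["cpue"].to_numpy()
    labels = data[flag_col].to_numpy(dtype=bool)
    strata = data.groupby(["area", "month"], dropna=True).indices

    def diff(lab: np.ndarray) -> float:
        return values[lab].mean() - values[~lab].mean()

    observed = diff(labels)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    idx_groups = [np.asarray(ix) for ix in strata.values()]
    for _ in range(n_permutations):
        for ix in idx_groups:
            perm[ix] = labels[ix][rng.permutation(len(ix))]
        if abs(diff(perm)) >= abs(observed):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PresenceEffectResult(
        observed_diff=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        n_present=int(labels.sum()),
        n_absent=int((~labels).sum()),
        n_strata=len(idx_groups),
        n_strata_dropped=n_dropped,
    )


# -- per-cell depredation and hot spots ---------------------------------------


@dataclass(frozen=True)
class CellDepredationStat:
    """Depredation percentage of one 10 km cell (for one month, or pooled).

    ``pct_depredation`` is the percent CPUE difference between orca-absent
    and orca-present sets, defined only when both strata hold more than
    ``min_sets`` sets and the orca-absent mean is positive (``valid``)."""

    cell: CellId
    month: int | None
    n_orca_sets: int
    n_clean_sets: int
    cpue_orca: float
    cpue_clean: float
    valid: bool
    pct_depredation: float | None


def cell_depredation(
    records: Sequence[LonglineSetRecord],
    grid: GridSpec = DEFAULT_GRID,
    month: int | None = None,
    *,
    per_month: bool = False,
    min_sets: int = 4,
    pooled_hooks: bool = False,
) -> list[CellDepredationStat]:
    """Per-10 km-cell depredation percentage:
    ``100 * (mean CPUE of orca-absent sets - mean CPUE of orca-present sets)
    / mean CPUE of orca-absent sets``.

    ``month`` restricts to one calendar month; ``per_month=True`` instead
    computes one stat per cell-month.  A cell is ``valid`` only when both
    strata hold at least ``min_sets`` sets (default: more than 3) and the
    orca-absent mean is positive; invalid cells are flagged, never dropped.
    ``pooled_hooks`` switches the stratum rate to total catch / total hooks.
    """
    frame = records_to_frame(records, grid)
    if month is not None:
        frame = frame[frame["month"] == month]
    out: list[CellDepredationStat] = []
    if frame.empty:
        return out
    keys = ["cell_i", "cell_j"] + (["month"] if per_month else [])
    for key, part in frame.groupby(keys, dropna=True):
        if not per_month:
            key = (*key, month)
        ci, cj, m = int(key[0]), int(key[1]), key[2]
        orca = part[part["orca_present"]]
        clean = part[~part["orca_present"]]
        if pooled_hooks:
            mean_orca = (
                orca["catch_kg"].sum() / orca["hooks"].sum() if len(orca) else np.nan
            )
            mean_clean = (
                clean["catch_kg"].sum() / clean["hooks"].sum() if len(clean) else np.nan
            )
        else:
            mean_orca = orca["cpue"].mean() if len(orca) else np.nan
            mean_clean = clean["cpue"].mean() if len(clean) else np.nan
        valid = (
            len(orca) >= min_sets and len(clean) >= min_sets and mean_clean > 0
        )
        pct = (
            float(100.0 * (mean_clean - mean_orca) / mean_clean) if valid else None
        )
        out.append(
            CellDepredationStat(
                cell=CellId(Resolution.KM10, ci, cj),
                month=int(m) if m is not None and not pd.isna(m) else None,
                n_orca_sets=len(orca),
                n_clean_sets=len(clean),
                cpue_orca=float(mean_orca) if len(orca) else float("nan"),
                cpue_clean=float(mean_clean) if len(clean) else float("nan"),
                valid=bool(valid),
                pct_depredation=pct,
            )
        )
    return out


@dataclass(frozen=True)
class HotspotResult:
    hotspots: tuple[CellDepredationStat, ...]
    thresholds: dict[int | None, float]  # per month: mean + 1 sample SD


def detect_hotspots(stats: Iterable[CellDepredationStat]) -> HotspotResult:
    """Cells whose depredation percentage exceeds the mean + 1 sample SD of
    valid cells, computed separately within each month (pooled stats, with
    month None, form their own group).  Months with fewer than two valid
    cells yield no hot spots (with a warning)."""
    by_month: dict[int | None, list[CellDepredationStat]] = {}
    for stat in stats:
        if stat.valid:
            by_month.setdefault(stat.month, []).append(stat)
    hotspots: list[CellDepredationStat] = []
    thresholds: dict[int | None, float] = {}
    for month, group in by_month.items():
        if len(group) < 2:
            warnings.warn(
                f"month {month}: fewer than 2 valid cells, no hot-spot threshold",
                stacklevel=2,
            )
            continue
        pcts = np.array([s.pct_depredation for s in group])
        threshold = float(pcts.mean() + pcts.std(ddof=1))
        thresholds[month] = threshold
        hotspots.extend(s for s in group if s.pct_depredation > threshold)
    hotspots.sort(key=lambda s: (s.month is not None, s.month or 0, s.cell))
    return HotspotResult(hotspots=tuple(hotspots), thresholds=thresholds)


# -- nearest unaffected line ---------------------------------------------------


@dataclass(frozen=True)
class MatchResult:
    match: LonglineSetRecord
    distance_km: float
    day_diff: int
    cost: float  # distance_km + km_per_day * |day_diff|
    pct_reduction: float | None  # None when the matched line's CPUE is zero


def match_nearest_unaffected(
    target: LonglineSetRecord,
    candidates: Sequence[LonglineSetRecord],
    km_per_day: float = 25.0,
) -> MatchResult:
    """Match a depredated set to the spatially and temporally nearest
    unaffected set, minimising ``haversine_km + km_per_day * |days apart|``
    (ties broken by set_id), and report the percent CPUE reduction
    ``100 * (CPUE_match - CPUE_target) / CPUE_match``."""
    if not candidates:
        raise LookupError("no candidate unaffected sets")
    if km_per_day < 0:
        raise ValueError("km_per_day must be >= 0")
    best: tuple[float, str] | None = None
    best_parts: tuple[LonglineSetRecord, float, int] | None = None
    for cand in candidates:
        dist = haversine_km((target.lat, target.lon), (cand.lat, cand.lon))
        days = abs((cand.date - target.date).days)
        cost = dist + km_per_day * days
        key = (cost, cand.set_id)
        if best is None or key < best:
            best = key
            best_parts = (cand, dist, days)
    assert best_parts is not None
    match, dist, days = best_parts
    cpue_match = match.catch_kg / match.hooks
    cpue_target = target.catch_kg / target.hooks
    pct = (
        float(100.0 * (cpue_match - cpue_target) / cpue_match)
        if cpue_match > 0
        else None
    )
    return MatchResult(
        match=match,
        distance_km=float(dist),
        day_diff=days,
        cost=float(best[0]),
        pct_reduction=pct,
    )


# -- annual summary ------------------------------------------------------------

_COUNT_COLUMNS = [
    "fur_seal_sets",
    "sperm_whale_sets",
    "orca_sets",
    "no_mammal_sets",
    "fur_seal_n",
    "sperm_whale_n",
    "orca_n",
]
_RATE_COLUMNS = [
    "fur_seal_pct",
    "sperm_whale_pct",
    "orca_pct",
    "fur_seal_ratio",
    "sperm_whale_ratio",
    "orca_ratio",
]


def annual_summary(records: Sequence[LonglineSetRecord]) -> pd.DataFrame:
    """Per-year interaction summary: sets with at least one observation per
    species, total animals per species, percentage of observed sets with each
    species, animals per observed set, and no-mammal set counts.  Percentages
    and ratios are rounded half-up to 2 decimals for reporting."""
    frame = records_to_frame(records, spatial=False)
    rows = []
    for year, part in frame.groupby("year"):
        total = len(part)
        row: dict[str, object] = {"year": int(year)}
        any_present = pd.Series(False, index=part.index)
        for species in _FOCAL:
            present = part[f"{species.value}_present"]
            any_present |= present
            n_sets = int(present.sum())
            n_animals = int(part[f"{species.value}_n"].sum())
            row[f"{species.value}_sets"] = n_sets
            row[f"{species.value}_n"] = n_animals
            row[f"{species.value}_pct"] = round_half_up(100.0 * n_sets / total, 2)
            row[f"{species.value}_ratio"] = round_half_up(n_animals / total, 2)
        row["no_mammal_sets"] = int((~any_present).sum())
        rows.append(row)
    columns = ["year"] + _COUNT_COLUMNS + _RATE_COLUMNS
    return pd.DataFrame(rows, columns=columns).sort_values("year", ignore_index=True)


def append_average_total(yearly: pd.DataFrame) -> pd.DataFrame:
    """Append the report table's ``average`` and ``total`` rows to a per-year
    summary: averages are column-wise arithmetic means of the yearly values
    rounded half-up to 2 decimals; totals are exact sums of the count
    columns (rate columns stay empty in the total row).

    Averaging is done in decimal arithmetic on the yearly values as printed,
    so the output is exactly reproducible from a published table."""
    numeric = [c for c in yearly.columns if c != "year"]
    n_years = len(yearly)
    avg_row: dict[str, object] = {"year": "average"}
    for col in numeric:
        total = sum(Decimal(str(v)) for v in yearly[col])
        avg_row[col] = float(
            (total / n_years).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        )
    total_row: dict[str, object] = {"year": "total"}
    for col in numeric:
        total_row[col] = int(yearly[col].sum()) if col in _COUNT_COLUMNS else np.nan
    out = yearly.copy()
    out["year"] = out["year"].astype(object)
    return pd.concat(
        [out, pd.DataFrame([avg_row, total_row], columns=yearly.columns)],
        ignore_index=True,
    )


# -- intensity vs interaction correlation --------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n_cells: int
    undefined: bool = False  # zero variance in either variable


def intensity_interaction_correlation(
    records: Sequence[LonglineSetRecord],
    grid: GridSpec = DEFAULT_GRID,
    month: int | None = None,
) -> CorrelationResult:
    """Pearson correlation, across 10 km cells in one month, between fishing
    intensity (longlines per cell) and orca interaction rate (orcas per
    longline per cell).  A lack of correlation argues against hauling sound
    as the primary attractant."""
    frame = records_to_frame(records, grid)
    if month is not None:
        frame = frame[frame["month"] == month]
    cells = frame.groupby(["cell_i", "cell_j"], dropna=True).agg(
        n_lines=("set_id", "size"), n_orcas=("orca_n", "sum")
    )
    cells = cells[cells["n_lines"] > 0]
    if len(cells) < 3:
        raise ValueError("need at least 3 cells with effort for a correlation")
    x = cells["n_lines"].to_numpy(dtype=float)
    y = (cells["n_orcas"] / cells["n_lines"]).to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), len(cells), undefined=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(cells))
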