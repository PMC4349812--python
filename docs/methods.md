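# Methods

## Data model and screening

One record is one hauled longline set: date, position (signed decimal
degrees, south/west negative), hooks, toothfish catch mass (kg), an
observer-present flag, and at most one observation per mammal species
(count ≥ 1 plus a feeding flag). Screening drops sets hauled without a
scientific observer (mammal information is unreliable there) and sets from
excluded years (default: 1996, the first year of full observer coverage,
known for data inconsistencies). Species outside the three focal ones
(orca, sperm whale, Antarctic fur seal) are mapped to `OTHER` at parse time
and their observations stripped at screening; the affected sets are
retained as no-mammal sets, since only the observations, not the hauls, are
out of scope. An optional rule drops such sets entirely; only then does the
species drop counter in the screening report become non-zero. Screening
counts always reconcile: retained + dropped(by reason) = input.

Multi-line deployments are not modelled: one record is one set. Where a
fleet deploys 1–3 lines per set, the table is assumed to already be
per-set.

## Spatial frame

Two grids, both over the fixed study region 53–56°S / 34–45°W:

- **0.5° × 1° boxes** for seasonal abundance (OPUE) maps; indices are
  0-based from the south-west corner.
- **10 × 10 km squares** for catch-rate work, via a local equirectangular
  projection `x = (lon − lon₀)·111.320·cos lat₀`,
  `y = (lat − lat₀)·110.574` km around a configurable origin (default
  −54.5, −39.5). Over a 3° latitudinal span the scale distortion is below
  ~2%, which is negligible against a 10 km cell; the projection is a
  plain function and can be swapped.

All binning is half-open `[low, high)` with ties to the larger index; the
outer region edge is closed into the last cell so the grids tile the region
exactly (verified by a 0.05° scan in the tests). Great-circle distances use
the haversine formula with Earth radius 6371.0 km, checked against an
independent implementation to under a metre.

The five named areas (Shag Rocks, North West, North East, South West,
South East) have no published boundary coordinates; the default scheme is
an explicit approximation: Shag Rocks west of 40°W, the remainder split
north/south at 54.4°S and west/east at 36.5°W, ties to the north/east.
The scheme is a dataclass and fully configurable; all area-stratified
results are relative to the configured scheme.

## Catch-rate statistics

- **CPUE** is kg of toothfish per hook; figures and summaries report
  g/hook (×1000).
- **OPUE** divides animals observed (default numerator; an `events`
  option counts sets instead — the annual table's animals-per-set ratio
  motivates the animal-count default) by sets in the group, removing the
  bias of uneven fishing effort.
- **Scenarios** are predicates over the three species' states
  (present / absent / feeding / not-feeding / any); a set matches iff all
  three hold. The default catalogue holds the no-mammal scenario, the four
  marginal states per species and pairwise present/absent combinations
  (22 named scenarios); the catalogue is data, not a constant.
- **Stratum means, not pooled rates**: "% CPUE difference" compares means
  of per-set CPUE between strata, matching catch-*rate* language; a
  pooled total-catch/total-hooks variant is available behind a flag.
- **Presence effect**: instead of mixed-model inference (out of scope),
  a label-permutation test shuffles the presence flag within (area, month)
  strata, holding the spatio-temporal allocation of effort fixed;
  two-sided p with add-one correction; single-class strata are dropped
  with a warning.

## Per-cell depredation and hot spots

Per 10 km cell (one month, or the pooled season):

```
pct = 100 · (mean CPUE of orca-absent sets − mean CPUE of orca-present sets)
          / mean CPUE of orca-absent sets
```

A cell is *valid* only when both strata hold more than 3 sets (the
threshold applies to both strata — the conservative reading — and is a
parameter) and the orca-absent mean is positive. Invalid cells are flagged,
never silently dropped. Presence, not the observed feeding flag, defines
the depredated stratum: catch rates are depressed whenever orcas are
present, while the feeding flag is the noisier part of the observation
process.

Hot spots are valid cells whose percentage exceeds the mean plus one
*sample* (n−1) standard deviation of valid cells, computed separately per
month (pooled stats form their own group); months with fewer than two valid
cells yield no threshold. The detection is invariant to cell ordering and
to invalid cells.

Nearest-unaffected matching minimises
`haversine(km) + w·|Δdays|` with `w = 25 km/day` by default; the weight is
a package choice (no published metric exists) and is configurable; ties
break on set id. The match reports `100·(CPUE_match − CPUE_target)/CPUE_match`.

The fishing-intensity/orca-interaction check is a Pearson correlation
across 10 km cells in a month between lines per cell and orcas per line per
cell (≥ 3 cells required; zero variance flags the result undefined).

## Annual summary arithmetic

Per year: sets with ≥ 1 observation and total animals per species, the
percentage of observed sets with each species and animals per observed set
(both rounded half-up to 2 dp for reporting), plus no-mammal sets. The
appended *average* row is the column-wise arithmetic mean of the yearly
values as printed, computed in decimal arithmetic and rounded half-up to
2 dp; the *total* row is the exact integer sum of the count columns. Doing
the average on printed 2-dp values makes the rows exactly reproducible from
a published table; the 16-year published summary ships as package data and
is the fixture for this arithmetic.

## Track chaining

Within one day, sightings of one species are ordered by haul order (ties
broken by set id) and chained while consecutive positions are ≤ 50 km
apart — an approximate orca daily travel distance, configurable. Days with
a single sighting yield nothing, and singleton chains left by a split are
discarded by default; retaining them (an accounting option) makes the chain
count provably non-increasing in the link threshold, since raising it can
only merge chains. The number of length-≥2 tracks alone is *not* monotone:
two isolated sightings become one track once the gap closes. Cross-vessel
links are allowed by default (the same pod can visit two vessels).

## Energetics

Fixed daily toothfish requirements (female 100 kg/day, male 124 kg/day) and
an energy density of 184 kcal/100 g raw toothfish for unit conversion.
`coverage_fraction` divides a per-orca daily depredation take by the
sex-weighted requirement; it is linear in the take and decreasing in the
male fraction. Whether a population could live off depredation depends on
population size and total loss, which are inputs — the package asserts no
population-level band.

## Synthetic fishery

The generator emulates the observer dataset's structure: a mid-April to
mid-September season; vessels performing a bounded random walk pulled
toward a preferred ground chosen with probability proportional to area base
catch rates (233–300 g/hook by area), so fleet and predators co-occur;
hooks per set lognormal with median 7,000 clamped to [1,000, 36,000];
multiplicative lognormal catch noise (σ = 0.4, mean-corrected) with a small
zero-catch probability; 87% observer coverage; pods drifting along monthly
waypoints (orca groups of 8–10 on the north coast in May/June moving to
Shag Rocks by August; sperm whale pairs; fur seal groups) with daily jitter
bounded by a travel distance (default 50 km), some pods snapping to the
nearest vessel. An encounter is a set within the species' encounter radius
of a pod; orcas always feed on encounter and remove a fraction δ of the
true catch (default 0.5 — affected lines typically lose half or more),
while the recorded feeding *flag* is Bernoulli(0.9). All draws come from a
single seeded generator; one seed fixes the season exactly, and the ground
truth (true catch, δ applied, pod identities, per-set minimum pod
distances) is returned with the records.

Calibration to target per-species interaction rates (orca 4.7%, sperm
whale 25%, fur seal 8.9% of sets) exploits that an encounter is a
threshold on distances that do not depend on the radius: the per-set
minimum-distance distribution of a pilot season (two pooled ~5,000-set
pilots, to damp one season's fleet–pod geometry) gives the encounter
fraction as an exact monotone step function of the radius, solved at the
target quantile and verified on an independent fresh pilot (re-solved on
pooled distances on failure, up to 4 rounds).

What the generator does **not** emulate: oceanography and prey fields
(krill), inter-annual structure (one season per run), gear differences
beyond hook counts, vessel economics or avoidance behaviour, and
non-multiplicative or selective depredation. Passing recovery tests show
the estimators are unbiased under the generator's multiplicative,
spatially clustered loss model — not that real depredation follows it.

### Problem sizes and presets

`small` ≈ 600 sets (fixtures), `default` ≈ 1,800 sets (one realistic
season), `paper-scale` ≈ 30,000 sets (the full dataset's order of
magnitude), `recovery` ≈ 6,000 sets on one dense ~55 × 80 km ground with
two resident pods so 10 km cells accumulate ≥ 20 sets in both strata, and
`calibration` ≈ 5,200 sets region-wide with a roamy fleet (more vessels,
fewer sets each, weaker home-ground pull) to keep encounter fractions
stable between runs. Recovery runs use pooled-season cells
(`month=None`): at realistic monthly effort a per-month split cannot reach
20 sets per stratum per cell without inflating the fleet.

## Numerical choices

- Rounding for report tables: decimal half-up at 2 dp (matching the
  published table's presentation); averages computed in `Decimal`.
- Sample (n−1) SD for hot-spot thresholds.
- Permutation p-values use the +1 correction; fixed seeds make them exact
  to rerun.
- Degenerate inputs are flagged rather than guessed: zero-CPUE matches,
  zero-variance correlations, < 2 valid hot-spot cells.

## Known limitations

- The five-area boundaries are an approximation; results by area depend on
  the configured scheme.
- The lognormal catch distribution is an assumption; the real per-set
  distribution is unknown (confidential data).
- The permutation test replaces, and is not equivalent to, mixed-model
  inference with vessel/observer random effects.
- Track chains are *potential* tracks: photographic identity of the
  animals is outside scope, so chains are an upper bound on single-group
  movements.
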