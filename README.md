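# toothdep

Spatio-temporal analysis of marine-mammal depredation on demersal longline
fisheries, built around the Patagonian toothfish (*Dissostichus
eleginoides*) fishery of the South Georgia shelf (CCAMLR Subarea 48.3,
34–45°W / 53–56°S). Orcas (*Orcinus orca*), sperm whales (*Physeter
macrocephalus*) and Antarctic fur seals (*Arctocephalus gazella*) take
hooked fish while longlines are hauled; the package quantifies where, when
and how much catch is lost, from per-set scientific-observer records.

It is intended for fisheries scientists and observers working with per-set
catch/effort tables who need reproducible depredation-rate estimates, and it
ships a synthetic fishery simulator so that every stage can be tested
without access to confidential observer data.

## What it computes

The atomic input is one hauled longline set: position, date, hooks, catch
mass, and per-species mammal counts with feeding flags. On screened records
the package derives:

- **CPUE** `= catch (kg) / hooks` and **OPUE** `= animals observed / sets`
  per 0.5°×1° box or per named area (Shag Rocks, North West, North East,
  South West, South East), per month or year.
- **Scenario-stratified catch rates**: mean CPUE over sets matching a
  predicate on each species' presence/feeding state (e.g. *orca feeding*,
  *no mammals*), with a stratified permutation test for the presence effect.
- **Per-cell depredation percentage** on a 10×10 km grid:
  `100 · (CPUE_no-orca − CPUE_orca) / CPUE_no-orca`, valid only where both
  strata exceed 3 sets; **hot spots** are cells above the mean + 1 SD of
  valid cells in a month.
- **Nearest-unaffected-line matching**: percent CPUE reduction of a
  depredated set against the spatio-temporally closest orca-free set.
- **Annual interaction summary** (sets and animals per species, percentage
  of sets with interactions, animals per set) with exact average/total rows.
- **Same-day orca tracks**: sightings chained when consecutive same-day
  positions are within 50 km (an orca's approximate daily travel distance).
- **Orca energetics**: daily toothfish requirement (female 100 kg/day, male
  124 kg/day; 184 kcal/100 g raw toothfish) and the fraction covered by a
  given depredation take.

## Worked example

```python
from toothdep.simulate import simulate_season, default_config
from toothdep.records import screen_sets, Species
from toothdep.stats import (cell_depredation, detect_hotspots,
                            scenario_cpue, default_scenarios, g_per_hook)
from toothdep.tracks import build_daily_tracks, species_observation_points

sim = simulate_season(default_config(seed=1))       # one synthetic season
records, report = screen_sets(sim.records)          # drop unobserved sets
print(f"retained {report.n_retained} of {report.n_input} sets")

clean = scenario_cpue(records, default_scenarios()["no_mammals"], grouping=None).iloc[0]
orca = scenario_cpue(records, default_scenarios()["orca_present"], grouping=None).iloc[0]
print(f"no-mammal CPUE: {g_per_hook(clean.mean_cpue):.0f} g/hook (n={clean.n:.0f})")
print(f"orca-present CPUE: {g_per_hook(orca.mean_cpue):.0f} g/hook (n={orca.n:.0f})")

stats = cell_depredation(records)
hot = detect_hotspots(stats)
print(f"{sum(s.valid for s in stats)} valid 10 km cells, "
      f"{len(hot.hotspots)} hot spots (threshold {hot.thresholds[None]:.1f}%)")

tracks = build_daily_tracks(species_observation_points(records, Species.ORCA))
print(f"{len(tracks)} same-day orca tracks")
```

prints

```
retained 1576 of 1824 sets
no-mammal CPUE: 271 g/hook (n=558)
orca-present CPUE: 144 g/hook (n=229)
4 valid 10 km cells, 1 hot spots (threshold 60.7%)
89 same-day orca tracks
```

Mammal-free sets average 271 g of toothfish per hook while sets with orcas
alongside average 144 g/hook — the simulated pods remove half of the catch
when they feed, and the stratified comparison recovers that loss. One 10 km
cell exceeds the hot-spot threshold, and the vessel-following pod leaves 89
same-day track chains.

The same chain is available from a shell:

```bash
toothdep run --preset small --seed 7 --out results/run
```

which writes every stage table (`sets.csv`, `screened.csv`, `annual.csv`,
`cells.csv`, `hotspots.csv`, `tracks.csv`, ...) plus a `manifest.json` with
a checksum per output; re-running with the same seed reproduces the
checksums exactly.

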