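import datetime as dt

import numpy as np
import pytest

from toothdep.records import Species, screen_sets
from toothdep.simulate import (
    PodSpec,
    SimulationConfig,
    recovery_config,
    simulate_season,
)
from toothdep.spatial import Area, CellId, Resolution
from toothdep.stats import (
    CellDepredationStat,
    ScenarioError,
    ScenarioSpec,
    ScenarioState,
    annual_summary,
    append_average_total,
    cell_depredation,
    cpue,
    default_scenarios,
    detect_hotspots,
    g_per_hook,
    intensity_interaction_correlation,
    match_nearest_unaffected,
    opue,
    presence_effect_test,
    records_to_frame,
    round_half_up,
    scenario_cpue,
)

from conftest import make_record

ORCA = Species.ORCA


class TestCpue:
    def test_arithmetic(self):
        assert cpue(2100.0, 7000) == pytest.approx(0.30)
        assert cpue(0.0, 5000) == 0.0
        assert g_per_hook(0.30) == pytest.approx(300.0)

    def test_zero_hooks_rejected(self):
        with pytest.raises(ValueError):
            cpue(100.0, 0)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(4.72625, 4.73), (0.3725, 0.37), (1328.625, 1328.63), (2.5e-3, 0.0)],
    )
    def test_half_up_two_decimals(self, value, expected):
        assert round_half_up(value, 2) == expected


class TestOpue:
    def test_single_box_animals_per_set(self):
        records = [
            make_record(set_id=f"S{i}", obs=[(ORCA, 4, False)] if i < 3 else [])
            for i in range(15)
        ]
        table = opue(records, ORCA, grouping="box", period="month")
        assert len(table) == 1
        assert table.iloc[0]["opue"] == pytest.approx(12 / 15)

    def test_absent_species_gives_zero_rates(self):
        records = [make_record(set_id=f"S{i}") for i in range(6)]
        table = opue(records, Species.SPERM_WHALE)
        assert (table["opue"] == 0).all()

    def test_events_numerator_counts_sets_not_animals(self):
        records = [
            make_record(set_id="S1", obs=[(ORCA, 9, True)]),
            make_record(set_id="S2"),
        ]
        table = opue(records, ORCA, numerator="events")
        assert table.iloc[0]["opue"] == pytest.approx(0.5)

    def test_stationary_pod_peaks_in_its_box(self):
        # effort spread over a 2x2 block of boxes; the pod sits at the centre
        # of one box with reach (jitter + radius) well inside it
        pod_lat, pod_lon = -54.25, -37.5
        config = SimulationConfig(
            seed=5,
            lat_min=-54.5,
            lat_max=-53.5,
            lon_min=-38.0,
            lon_max=-36.0,
            n_vessels=8,
            sets_per_vessel_day=2,
            vessel_step_km=25.0,
            vessel_anchor_pull=0.02,
            pods=(PodSpec(ORCA, ((5, pod_lat, pod_lon),), 8, 10, daily_travel_max_km=8.0),),
            encounter_radius_km={ORCA: 15.0},
        )
        records, _ = screen_sets(simulate_season(config).records)
        table = opue(records, ORCA, grouping="box", period="year")
        table = table[table["n_sets"] >= 20]  # rate stable only with effort
        best = table.loc[table["opue"].idxmax()]
        from toothdep.spatial import assign_halfdeg_box

        pod_box = assign_halfdeg_box(pod_lat, pod_lon)
        assert (best["box_i"], best["box_j"]) == (pod_box.i, pod_box.j)


class TestScenarios:
    def test_all_any_equals_unstratified_mean(self, small_season):
        records, _ = screen_sets(small_season.records)
        table = scenario_cpue(records, ScenarioSpec(), grouping=None)
        frame = records_to_frame(records)
        assert table.iloc[0]["mean_cpue"] == pytest.approx(frame["cpue"].mean())
        assert table.iloc[0]["n"] == len(records)

    def test_all_absent_counts_no_mammal_sets(self):
        records = [
            make_record(set_id=f"S{i}", obs=[(ORCA, 8, True)] if i < 6 else [])
            for i in range(10)
        ]
        spec = ScenarioSpec(
            ScenarioState.ABSENT, ScenarioState.ABSENT, ScenarioState.ABSENT
        )
        table = scenario_cpue(records, spec, grouping=None)
        assert table.iloc[0]["n"] == 4

    def test_contradictory_constraints_rejected(self):
        with pytest.raises(ScenarioError):
            ScenarioSpec.from_constraints({"orca": ["absent", "feeding"]})

    def test_default_catalogue_contains_core_scenarios(self):
        catalogue = default_scenarios()
        assert "no_mammals" in catalogue
        assert "orca_feeding" in catalogue
        assert len(catalogue) > 20
        assert len(default_scenarios(pairwise=False)) == 13

    def test_simulated_multiplicative_effect_recovered_from_scenario_means(self):
        sim = simulate_season(recovery_config(seed=9, delta=0.5))
        records, _ = screen_sets(sim.records)
        orca = scenario_cpue(
            records, ScenarioSpec(orca=ScenarioState.PRESENT), grouping=None
        ).iloc[0]
        clean = scenario_cpue(
            records, default_scenarios()["no_mammals"], grouping=None
        ).iloc[0]
        assert orca["mean_cpue"] / clean["mean_cpue"] == pytest.approx(0.5, abs=0.06)


class TestPresenceEffect:
    def test_constant_cpue_gives_p_near_one(self):
        records = [
            make_record(
                set_id=f"S{i}",
                catch_kg=2100.0,
                obs=[(ORCA, 8, True)] if i % 3 == 0 else [],
            )
            for i in range(30)
        ]
        result = presence_effect_test(records, ORCA, n_permutations=199, seed=0)
        assert result.observed_diff == 0.0
        assert result.p_value == 1.0

    def test_simulated_depredation_effect_detected(self):
        sim = simulate_season(recovery_config(seed=2, delta=0.4))
        records, _ = screen_sets(sim.records)
        result = presence_effect_test(records, ORCA, n_permutations=199, seed=1)
        assert result.observed_diff < 0  # orca presence lowers catch rates
        assert result.p_value < 0.01

    def test_permutation_p_value_reproducible(self, small_season):
        records, _ = screen_sets(small_season.records)
        first = presence_effect_test(records, ORCA, n_permutations=99, seed=42)
        second = presence_effect_test(records, ORCA, n_permutations=99, seed=42)
        assert first == second


class TestCellDepredation:
    def _records_for_cell(self, n_orca, n_clean, cpue_orca=0.15, cpue_clean=0.30):
        records = []
        for i in range(n_orca):
            records.append(
                make_record(
                    set_id=f"O{i}", catch_kg=cpue_orca * 7000, obs=[(ORCA, 8, True)]
                )
            )
        for i in range(n_clean):
            records.append(make_record(set_id=f"C{i}", catch_kg=cpue_clean * 7000))
        return records

    def test_hand_arithmetic_fifty_percent(self):
        stats = cell_depredation(self._records_for_cell(5, 5))
        assert len(stats) == 1
        stat = stats[0]
        assert stat.valid
        assert stat.pct_depredation == pytest.approx(50.0)
        assert stat.n_orca_sets == 5 and stat.n_clean_sets == 5

    def test_three_orca_sets_is_not_enough(self):
        stat = cell_depredation(self._records_for_cell(3, 10))[0]
        assert not stat.valid and stat.pct_depredation is None

    def test_zero_clean_mean_invalidates_cell(self):
        stat = cell_depredation(self._records_for_cell(5, 5, cpue_clean=0.0))[0]
        assert not stat.valid

    def test_pooled_hooks_variant_weighs_by_effort(self):
        records = self._records_for_cell(5, 5)
        pooled = cell_depredation(records, pooled_hooks=True)[0]
        assert pooled.pct_depredation == pytest.approx(50.0)

    def test_recovers_simulated_delta_within_five_points(self):
        for delta in (0.2, 0.6):
            sim = simulate_season(recovery_config(seed=4, delta=delta))
            records, _ = screen_sets(sim.records)
            stats = cell_depredation(records, min_sets=20)
            pcts = [s.pct_depredation for s in stats if s.valid]
            assert len(pcts) >= 5
            assert abs(float(np.mean(pcts)) - 100 * delta) < 5


class TestHotspots:
    def _stat(self, pct, i=0, j=0, valid=True, month=None):
        return CellDepredationStat(
            cell=CellId(Resolution.KM10, i, j),
            month=month,
            n_orca_sets=5,
            n_clean_sets=5,
            cpue_orca=0.15,
            cpue_clean=0.30,
            valid=valid,
            pct_depredation=pct if valid else None,
        )

    def test_mean_plus_sample_sd_threshold(self):
        stats = [self._stat(p, j=k) for k, p in enumerate([10, 12, 11, 50])]
        result = detect_hotspots(stats)
        assert result.thresholds[None] == pytest.approx(40.27, abs=0.01)
        assert [s.pct_depredation for s in result.hotspots] == [50]

    def test_all_equal_cells_yield_no_hotspots(self):
        stats = [self._stat(20.0, j=k) for k in range(4)]
        assert detect_hotspots(stats).hotspots == ()

    def test_invariant_to_ordering_and_invalid_cells(self):
        stats = [self._stat(p, j=k) for k, p in enumerate([10, 12, 11, 50])]
        noisy = [self._stat(999, j=9, valid=False)] + stats[::-1]
        assert detect_hotspots(noisy) == detect_hotspots(stats)

    def test_single_valid_cell_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning):
            result = detect_hotspots([self._stat(30.0)])
        assert result.hotspots == () and result.thresholds == {}

    def test_months_thresholded_separately(self):
        may = [self._stat(p, j=k, month=5) for k, p in enumerate([10, 12, 11, 50])]
        june = [self._stat(p, j=k, month=6) for k, p in enumerate([60, 62, 61, 100])]
        result = detect_hotspots(may + june)
        assert set(result.thresholds) == {5, 6}
        assert sorted(s.pct_depredation for s in result.hotspots) == [50, 100]


class TestNearestUnaffected:
    def test_single_candidate_is_matched(self):
        target = make_record(set_id="T", catch_kg=0.01 * 7000, obs=[(ORCA, 8, True)])
        cand = make_record(set_id="C", catch_kg=0.30 * 7000, lat=-54.2)
        result = match_nearest_unaffected(target, [cand])
        assert result.match is cand
        assert result.pct_reduction == pytest.approx(100 * (0.30 - 0.01) / 0.30)

    def test_zero_cpue_match_flagged_undefined(self):
        target = make_record(set_id="T", obs=[(ORCA, 8, True)])
        cand = make_record(set_id="C", catch_kg=0.0)
        assert match_nearest_unaffected(target, [cand]).pct_reduction is None

    def test_empty_candidates_raise_lookup_error(self):
        with pytest.raises(LookupError):
            match_nearest_unaffected(make_record(), [])

    @pytest.mark.parametrize("km_per_day", [0.0, 10.0, 25.0, 100.0])
    def test_matches_exhaustive_oracle(self, km_per_day):
        rng = np.random.default_rng(13)
        target = make_record(set_id="T", date=dt.date(2010, 6, 15))
        candidates = [
            make_record(
                set_id=f"C{i}",
                date=dt.date(2010, 6, int(rng.integers(1, 29))),
                lat=float(rng.uniform(-56, -53)),
                lon=float(rng.uniform(-45, -34)),
            )
            for i in range(100)
        ]
        from toothdep.spatial import haversine_km

        costs = [
            (
                haversine_km((target.lat, target.lon), (c.lat, c.lon))
                + km_per_day * abs((c.date - target.date).days),
                c.set_id,
            )
            for c in candidates
        ]
        expected_id = min(costs)[1]
        result = match_nearest_unaffected(target, candidates, km_per_day)
        assert result.match.set_id == expected_id


class TestAnnualSummary:
    def test_small_fixture_percentages(self):
        records = [
            make_record(set_id=f"S{i}", obs=[(ORCA, 9, True)] if i < 2 else [])
            for i in range(10)
        ]
        table = annual_summary(records)
        row = table.iloc[0]
        assert row["orca_sets"] == 2
        assert row["orca_pct"] == 20.00
        assert row["orca_n"] == 18
        assert row["orca_ratio"] == 1.80
        assert row["no_mammal_sets"] == 8

    def test_totals_are_exact_sums_and_averages_are_two_dp_means(self):
        records = []
        k = 0
        for year, n_sets, n_orca in [(2010, 10, 3), (2011, 20, 5)]:
            for i in range(n_sets):
                records.append(
                    make_record(
                        set_id=f"S{k}",
                        date=dt.date(year, 6, 1),
                        obs=[(ORCA, 2, False)] if i < n_orca else [],
                    )
                )
                k += 1
        table = append_average_total(annual_summary(records))
        total = table[table["year"] == "total"].iloc[0]
        avg = table[table["year"] == "average"].iloc[0]
        assert total["orca_sets"] == 8
        assert total["no_mammal_sets"] == 22
        assert avg["orca_sets"] == pytest.approx(4.0)
        # yearly pcts 30.00 and 25.00 -> mean 27.50
        assert avg["orca_pct"] == pytest.approx(27.50)


class TestIntensityCorrelation:
    def _records(self, orca_counts_per_cell, sets_per_cell):
        # one cell per distinct longitude slot, 10 km apart
        records = []
        k = 0
        for c, (n_sets, n_orcas) in enumerate(zip(sets_per_cell, orca_counts_per_cell)):
            lon = -44.8 + c * 0.2  # ~13 km spacing: one 10 km cell per slot
            for i in range(n_sets):
                obs = [(ORCA, 1, False)] if i < n_orcas else []
                records.append(
                    make_record(set_id=f"S{k}", lat=-54.45, lon=lon, obs=obs)
                )
                k += 1
        return records

    def test_interaction_rate_growing_with_effort_gives_strong_positive_r(self):
        sets = [2, 4, 8, 16, 32, 64]
        orcas = [0, 1, 4, 8, 24, 64]  # per-line rate rises with effort
        result = intensity_interaction_correlation(self._records(orcas, sets))
        assert result.r > 0.9 and result.p_value < 0.05

    def test_constant_interaction_rate_is_degenerate(self):
        sets = [4, 8, 16]
        orcas = [0, 0, 0]
        result = intensity_interaction_correlation(self._records(orcas, sets))
        assert result.undefined

    def test_two_cells_violate_precondition(self):
        with pytest.raises(ValueError):
            intensity_interaction_correlation(self._records([1, 1], [4, 4]))

    def test_constant_underlying_rate_gives_small_correlation(self):
        # orcas placed proportional to effort (binomial per set): the
        # per-line rate is then independent of intensity in expectation
        rng = np.random.default_rng(17)
        sets = [int(s) for s in rng.integers(5, 30, size=50)]
        orcas = [int(rng.binomial(s, 0.3)) for s in sets]
        result = intensity_interaction_correlation(self._records(orcas, sets))
        assert abs(result.r) < 0.35
        assert result.p_value > 0.01
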