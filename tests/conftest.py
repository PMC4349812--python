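import datetime as dt

import pytest

from toothdep.records import LonglineSetRecord, MammalObservation, Species


def make_record(
    set_id="S1",
    date=dt.date(2010, 6, 15),
    lat=-54.0,
    lon=-37.0,
    hooks=7000,
    catch_kg=2100.0,
    observed=True,
    vessel_id="V01",
    haul_order=1,
    obs=(),
):
    """Terse record builder; ``obs`` is (species, count, feeding) triples."""
    return LonglineSetRecord(
        set_id=set_id,
        vessel_id=vessel_id,
        cruise_id="C01-2010",
        date=date,
        haul_order=haul_order,
        lat=lat,
        lon=lon,
        hooks=hooks,
        catch_kg=catch_kg,
        observed=observed,
        observations=[MammalObservation(s, n, f) for s, n, f in obs],
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_season():
    """One deterministic fixture-scale simulated season, shared read-only."""
    from toothdep.simulate import simulate_season, small_config

    return simulate_season(small_config(seed=11))


ORCA = Species.ORCA
SPERM = Species.SPERM_WHALE
SEAL = Species.FUR_SEAL
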