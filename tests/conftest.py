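import pytest

import nitrocalc as nc


@pytest.fixture(scope="session")
def wg_params() -> nc.RunParameters:
    """Wet-granulation NDSRI setup: MW 400 g/mol, 29 % conversion."""
    return nc.RunParameters(nitrosamine_mw=400.0, conversion_fraction=0.29)


@pytest.fixture(scope="session")
def case_studies() -> dict[str, nc.Formulation]:
    return nc.case_study_formulations()


@pytest.fixture(scope="session")
def desk_db() -> nc.NitriteDatabase:
    """Tier-A documented values plus zero placeholders for the excipients
    whose levels are not individually documented. Zero placeholders cancel
    exactly in any comparison that leaves those ingredients untouched."""
    db = nc.load_packaged_db()
    for name in ("microcrystalline cellulose", "lactose", "povidone",
                 "magnesium stearate", "hypromellose", "silicon dioxide",
                 "sodium stearyl fumarate"):
        db.add(nc.NitriteStats.constant(name, 0.0, source="placeholder"))
    return db


@pytest.fixture()
def synthetic_pair():
    """Seeded (formulation, db) pair with every excipient resolvable."""
    spec = nc.FixtureSpec(seed=42, n_ingredients=6)
    return nc.generate_formulation(spec), nc.generate_nitrite_db(spec)
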