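import pytest
from hypothesis import settings

import hazmix as hx

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return hx.load_builtin_taxonomy()


def _substance(cas, name, oel_ppm=None, classes=(), mw=None, oels=None,
               synthetic=False):
    if oels is None:
        oels = {}
        if oel_ppm is not None:
            oels["eight_hour"] = hx.OELValue("eight_hour", oel_ppm, "ppm")
    return hx.Substance(cas=cas, name=name, oels=oels,
                        class_ids=frozenset(classes), molecular_weight=mw,
                        synthetic=synthetic)


@pytest.fixture(scope="session")
def toy_db():
    """Four real-CAS solvents with hand-set OELs covering the engine paths."""
    subs = [
        _substance("71-43-2", "Benzene", oel_ppm=1.0,
                   classes={"hematopoietic_system_disruption",
                            "carcinogenicity_mutagenicity",
                            "central_nervous_system_damage"},
                   mw=78.11),
        _substance("108-88-3", "Toluene", oel_ppm=20.0,
                   classes={"central_nervous_system_damage", "ocular_damage",
                            "ototoxicity", "developmental_damage"},
                   mw=92.14),
        _substance("67-64-1", "Acetone", oel_ppm=500.0,
                   classes={"central_nervous_system_damage", "ocular_damage",
                            "upper_airway_damage"},
                   mw=58.08),
        # ceiling-only limit: exercises the OEL fallback path
        _substance("7664-41-7", "Ammonia",
                   oels={"ceiling": hx.OELValue("ceiling", 50.0, "ppm")},
                   classes={"upper_airway_damage", "ocular_damage"},
                   mw=17.03),
    ]
    return hx.SubstanceDatabase(jurisdiction="TEST", oel_name="test 8 h OEL",
                                substances={s.cas: s for s in subs})


@pytest.fixture(scope="session")
def synth_db():
    return hx.generate_substance_db(hx.GeneratorSpec(n_substances=40, seed=7))


@pytest.fixture(scope="session")
def case_study():
    return hx.case_study_fixture()


def quantitative_scenario(pairs, unit="ppm"):
    """Build a quantitative scenario from (cas, concentration) pairs."""
    return hx.MixtureScenario(
        records=tuple(hx.ExposureRecord(cas=c, concentration=v, unit=unit)
                      for c, v in pairs),
        mode="quantitative")
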