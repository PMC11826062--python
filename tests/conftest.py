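import pytest

import serpenergy as sp


@pytest.fixture(scope="session")
def db():
    return sp.default_thermo()


@pytest.fixture(scope="session")
def field_samples():
    """The bundled per-site measured chemistry."""
    return sp.datasets.load_fluid_chemistry()


@pytest.fixture(scope="session")
def site_energetics():
    """The bundled published affinity/supply table."""
    return sp.datasets.load_site_energetics()


@pytest.fixture(scope="session")
def by_site(field_samples):
    return {s.site_id: s for s in field_samples}


@pytest.fixture
def type2_sample():
    """A fully measured hyperalkaline Type II fluid."""
    return sp.FluidSample(
        site_id="T2",
        fluid_type=sp.FluidType.TYPE2,
        ph=11.4,
        temperature=30.0,
        si=2e-6,
        dic=4e-5,
        h2=2e-4,
        ch4=3e-4,
        formate_total=2e-6,
        acetate_total=2e-6,
    )
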