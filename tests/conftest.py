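import numpy as np
import pytest

from enashift import (
    DynamicParams,
    FoodWeb,
    GroupSpec,
    calibrate,
    make_baltic_fixture,
    neutral_forcing,
    solve_missing_ee,
)


@pytest.fixture(scope="session")
def baltic():
    """The 21-group Baltic-like fixture (web + dynamic params)."""
    return make_baltic_fixture()


@pytest.fixture(scope="session")
def baltic_model(baltic):
    web, params = baltic
    return calibrate(web, params)


@pytest.fixture(scope="session")
def baltic_equilibrium(baltic, baltic_model):
    """33-year neutral run of the fixture with yearly flow networks."""
    web, _ = baltic
    forcing = neutral_forcing(web, range(1974, 2007))
    traj = baltic_model.simulate(forcing)
    nets = baltic_model.annual_flow_snapshots(traj)
    return forcing, traj, nets


def _toy_groups(consumer_qb=50.0, consumer_pb=5.0, producer_ee=0.5):
    return [
        GroupSpec(name="algae", role="producer", B=10.0, PB=10.0, EE=producer_ee),
        GroupSpec(
            name="grazer",
            role="consumer",
            B=1.0,
            PB=consumer_pb,
            QB=consumer_qb,
            EE=0.0,
            GS=0.2,
            diet={"algae": 1.0},
        ),
        GroupSpec(name="detritus", role="detritus", B=5.0, PB=0.0),
    ]


@pytest.fixture
def toy_web():
    """Producer (B=10, PB=10, EE=0.5) fully consumed by one grazer (QB=50)."""
    return FoodWeb(_toy_groups())


@pytest.fixture
def toy_web_overgrazed():
    """Same toy but grazer QB=60: predation exceeds allocated production."""
    return FoodWeb(_toy_groups(consumer_qb=60.0))


@pytest.fixture
def chain_web():
    """producer -> herbivore (TL 2) -> predator eating 50/50 herbivore+producer."""
    groups = [
        GroupSpec(name="plant", role="producer", B=100.0, PB=50.0),
        GroupSpec(
            name="herb", role="consumer", B=10.0, PB=10.0, QB=50.0, GS=0.2,
            diet={"plant": 1.0},
        ),
        GroupSpec(
            name="pred", role="consumer", B=1.0, PB=2.0, QB=10.0, GS=0.2,
            diet={"herb": 0.5, "plant": 0.5},
        ),
        GroupSpec(name="det", role="detritus", B=10.0, PB=0.0),
    ]
    return solve_missing_ee(FoodWeb(groups))


@pytest.fixture
def simple_model():
    """Small calibrated dynamic model without stanzas (3 living groups)."""
    groups = [
        GroupSpec(name="plant", role="producer", B=50.0, PB=60.0),
        GroupSpec(
            name="grazer", role="consumer", B=5.0, PB=8.0, QB=30.0, GS=0.25,
            diet={"plant": 1.0}, landings={"f": 4.0},
        ),
        GroupSpec(
            name="pred", role="consumer", B=1.0, PB=1.5, QB=6.0, GS=0.2,
            diet={"grazer": 1.0}, landings={"f": 0.3},
        ),
        GroupSpec(name="det", role="detritus", B=30.0, PB=0.0),
    ]
    web = solve_missing_ee(FoodWeb(groups, fleets=["f"]))
    return web, calibrate(web, DynamicParams())


def perm_web(web: FoodWeb, perm: list[int]) -> FoodWeb:
    """The same web with groups re-ordered (for invariance checks)."""
    return FoodWeb(
        [web.groups[i] for i in perm],
        fleets=list(web.fleets),
        detritus_routing=dict(web.detritus_routing),
    )


def assert_close(a, b, rtol=1e-9, atol=0.0):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol)
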