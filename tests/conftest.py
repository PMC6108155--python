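import numpy as np
import pytest

from mmspar import (
    DemandUnit,
    Scene,
    SceneSpec,
    SupplySite,
    TravelTimeMatrix,
    default_modes,
    generate_scene,
)
from mmspar.sensitivity import build_grid, run_grid

CAR_GRID = build_grid(140, 320, 13)
BUS_GRID = build_grid(440, 1040, 13)


@pytest.fixture
def two_mode_unit_scene():
    """One site (C=10), one unit (100 car @ 5 car-min, 50 bus @ 45 bus-min)."""
    return Scene(
        supply=[SupplySite("s0", 10.0)],
        demand=[DemandUnit("u0", {"car": 100.0, "bus": 50.0})],
        matrices={
            "car": TravelTimeMatrix("car", {("u0", "s0"): 5.0}),
            "bus": TravelTimeMatrix("bus", {("u0", "s0"): 45.0}),
        },
    )


def random_scene(seed, n_sites=10, n_units=20, modes=("car", "bus")):
    """Small random scene with sparse, independently drawn travel times."""
    rng = np.random.default_rng(seed)
    supply = [
        SupplySite(f"s{i}", float(rng.integers(0, 8))) for i in range(n_sites)
    ]
    demand = [
        DemandUnit(
            f"u{k}",
            {m: float(rng.integers(0, 300)) for m in modes},
        )
        for k in range(n_units)
    ]
    matrices = {}
    for m in modes:
        entries = {}
        for k in range(n_units):
            for i in range(n_sites):
                if rng.uniform() < 0.7:
                    entries[(f"u{k}", f"s{i}")] = float(rng.uniform(0, 80))
        matrices[m] = TravelTimeMatrix(m, entries)
    return Scene(supply=supply, demand=demand, matrices=matrices)


@pytest.fixture(scope="session")
def default_scene():
    """The full-size fixed-seed synthetic scene (543 units x 293 sites)."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def default_grid_run(default_scene):
    """The 13 x 13 coefficient sweep on the default scene (169 cells)."""
    return run_grid(
        default_scene,
        default_modes(),
        {"car": CAR_GRID, "bus": BUS_GRID},
    )
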