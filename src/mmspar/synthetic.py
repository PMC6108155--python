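"""Reproducible synthetic scenes for the multi-modal access model.

A scene mimics the structure of a mid-sized car-oriented metro area: a
dense urban core holding most of the supply, bus service confined to the
core, car travel faster than bus on every pair, and a car-dominant mode
split.  Travel times come from planar geometry — the access model only
consumes origin-destination minutes, so network realism is irrelevant to
its correctness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .access import DemandUnit, ModeSpec, Scene, SupplySite, TravelTimeMatrix
from .decay import BUS_SCHEME, CAR_SCHEME

__all__ = ["SceneSpec", "generate_scene", "scene_summary", "default_modes"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic scene generator.

    Distances are planar kilometres, speeds km/min, times minutes.  The
    defaults are sized to echo a study area of ~293 supply addresses and
    543 demand units averaging ~1600 residents, with bus service limited
    to the core and a majority of units beyond any 60-min bus catchment.
    """

    n_supply: int = 293
    n_demand: int = 543
    region_size: float = 70.0  # square region side, km
    core_radius: float = 8.0
    supply_core_fraction: float = 0.75
    demand_core_fraction: float = 0.45
    bus_service_radius: float = 11.0
    car_speed: float = 0.8  # 48 km/h
    bus_speed: float = 0.28  # ~17 km/h incl. stops
    bus_overhead: float = 12.0  # walk + wait, minutes
    car_time_noise_sd: float = 0.08  # lognormal sigma on car times
    vehicle_ownership_core: float = 0.85
    vehicle_ownership_periphery: float = 0.97
    mean_unit_population: float = 1600.0
    # suburban gradient: core units are smaller, periphery units larger
    population_core_factor: float = 0.55
    population_periphery_factor: float = 1.3
    mean_capacity: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_supply < 1 or self.n_demand < 1:
            raise ValueError("need at least one supply site and one demand unit")
        if not (self.car_speed > 0 and self.bus_speed > 0):
            raise ValueError("speeds must be positive")
        if self.bus_speed >= self.car_speed:
            raise ValueError("bus must be slower than car")
        if self.bus_overhead < 0:
            raise ValueError("bus overhead must be non-negative")
        for p in (self.vehicle_ownership_core, self.vehicle_ownership_periphery):
            if not 0 <= p <= 1:
                raise ValueError(f"ownership probability {p} outside [0, 1]")
        if self.population_core_factor <= 0 or self.population_periphery_factor <= 0:
            raise ValueError("population factors must be positive")
        if not (
            0 < self.core_radius
            <= self.bus_service_radius
            <= self.region_size / 2 * math.sqrt(2)
        ):
            raise ValueError(
                "need 0 < core_radius <= bus_service_radius <= region extent"
            )
        if not (0 <= self.supply_core_fraction <= 1):
            raise ValueError("supply_core_fraction outside [0, 1]")
        if not (0 <= self.demand_core_fraction <= 1):
            raise ValueError("demand_core_fraction outside [0, 1]")


def _points(rng, n: int, core_fraction: float, spec: SceneSpec) -> np.ndarray:
    """n planar points: a core cluster plus a uniform background."""
    n_core = int(round(n * core_fraction))
    # uniform over the core disc (centre of the region)
    r = spec.core_radius * np.sqrt(rng.uniform(size=n_core))
    theta = rng.uniform(0, 2 * np.pi, size=n_core)
    core = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    half = spec.region_size / 2
    background = rng.uniform(-half, half, size=(n - n_core, 2))
    return np.vstack([core, background])


def generate_scene(spec: SceneSpec) -> Scene:
    """Draw a scene from the spec; byte-identical for identical specs.

    Car times are Euclidean distance over car speed with mild lognormal
    noise (capped so a car trip can never exceed the bus trip for the same
    pair); bus times are a fixed overhead plus distance over bus speed and
    exist only when both endpoints lie within the bus service radius.
    """
    rng = np.random.default_rng(spec.seed)

    supply_xy = _points(rng, spec.n_supply, spec.supply_core_fraction, spec)
    demand_xy = _points(rng, spec.n_demand, spec.demand_core_fraction, spec)

    capacities = np.maximum(1, rng.poisson(spec.mean_capacity, size=spec.n_supply))

    dist_to_centre = np.hypot(demand_xy[:, 0], demand_xy[:, 1])
    in_core = dist_to_centre <= spec.core_radius
    pop_mean = spec.mean_unit_population * np.where(
        in_core, spec.population_core_factor, spec.population_periphery_factor
    )
    populations = rng.poisson(pop_mean)
    ownership = np.where(
        in_core, spec.vehicle_ownership_core, spec.vehicle_ownership_periphery
    )
    pop_car = rng.binomial(populations, ownership)
    pop_bus = populations - pop_car

    supply = [
        SupplySite(f"s{i:03d}", float(capacities[i]), *supply_xy[i])
        for i in range(spec.n_supply)
    ]
    demand = [
        DemandUnit(
            f"u{k:03d}",
            {"car": float(pop_car[k]), "bus": float(pop_bus[k])},
            *demand_xy[k],
        )
        for k in range(spec.n_demand)
    ]

    diff = demand_xy[:, None, :] - supply_xy[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])

    bus_time = spec.bus_overhead + dist / spec.bus_speed
    noise = np.exp(rng.normal(0.0, spec.car_time_noise_sd, size=dist.shape))
    car_time = np.minimum(dist / spec.car_speed * noise, bus_time * 0.999)

    supply_in_service = (
        np.hypot(supply_xy[:, 0], supply_xy[:, 1]) <= spec.bus_service_radius
    )
    demand_in_service = dist_to_centre <= spec.bus_service_radius
    bus_defined = demand_in_service[:, None] & supply_in_service[None, :]

    car_entries = {}
    bus_entries = {}
    for k in range(spec.n_demand):
        uid = demand[k].id
        for i in range(spec.n_supply):
            sid = supply[i].id
            car_entries[(uid, sid)] = float(car_time[k, i])
            if bus_defined[k, i]:
                bus_entries[(uid, sid)] = float(bus_time[k, i])

    return Scene(
        supply=supply,
        demand=demand,
        matrices={
            "car": TravelTimeMatrix("car", car_entries),
            "bus": TravelTimeMatrix("bus", bus_entries),
        },
    )


def default_modes(beta_car: float = 140.0, beta_bus: float = 440.0) -> list[ModeSpec]:
    """Case-study mode setup: 30-min car / 60-min bus stepped catchments."""
    return [
        ModeSpec("car", 30.0, CAR_SCHEME, beta_car),
        ModeSpec("bus", 60.0, BUS_SCHEME, beta_bus),
    ]


def scene_summary(scene: Scene, modes: list[ModeSpec]) -> dict:
    """Per-mode reachability report at each mode's catchment threshold.

    For each mode: the fraction of demand units with no supply site inside
    the catchment, and the mean number of reachable sites among units that
    can reach at least one.
    """
    report: dict = {"n_supply": len(scene.supply), "n_demand": len(scene.demand)}
    for spec in modes:
        matrix = scene.matrices[spec.name]
        counts = []
        for unit in scene.demand:
            n = sum(
                1
                for site in scene.supply
                if (t := matrix.get(unit.id, site.id)) is not None
                and t <= spec.threshold
            )
            counts.append(n)
        counts = np.asarray(counts)
        reachable = counts > 0
        report[spec.name] = {
            "threshold_min": spec.threshold,
            "unreachable_fraction": float(np.mean(~reachable)),
            "mean_reachable_sites": (
                float(counts[reachable].mean()) if reachable.any() else 0.0
            ),
        }
    return report
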