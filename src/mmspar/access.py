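"""Multi-modal floating-catchment access scores (SPAI) and ratios (SPAR).

Three steps:

1. each supply site's capacity is divided by its decay-weighted reachable
   demand, summed over every transport mode, giving a supply-to-demand
   ratio ``R_i``;
2. each demand unit sums the weighted ratios of the sites it can reach per
   mode (mode-specific SPAI) and across modes (integrated SPAI);
3. each SPAI vector is divided by its study-area mean, giving SPAR vectors
   whose mean is 1 by construction.

The classic single-mode enhanced two-step floating catchment area (E2SFCA)
score is the one-mode special case and is provided as a baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decay import OUTSIDE, SubzoneScheme, gaussian_weight, subzone_of

__all__ = [
    "SupplySite",
    "DemandUnit",
    "ModeSpec",
    "TravelTimeMatrix",
    "Scene",
    "AccessResult",
    "supply_ratio_multimodal",
    "spai_multimodal",
    "spar",
    "run_access",
    "e2sfca_single_mode",
    "compile_scene",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SupplySite:
    """A supply location with a non-negative service capacity."""

    id: str
    capacity: float
    x: float | None = None
    y: float | None = None

    def __post_init__(self):
        if self.capacity < 0:
            raise ValueError(f"site {self.id!r}: capacity must be >= 0")


@dataclass(frozen=True)
class DemandUnit:
    """A demand location with per-mode population counts."""

    id: str
    populations: Mapping[str, float]
    x: float | None = None
    y: float | None = None

    def __post_init__(self):
        for mode, p in self.populations.items():
            if p < 0:
                raise ValueError(f"unit {self.id!r}: population for {mode!r} < 0")

    @property
    def total_population(self) -> float:
        return float(sum(self.populations.values()))


@dataclass(frozen=True)
class ModeSpec:
    """One transport mode: catchment threshold, sub-zone scheme, coefficient.

    The threshold must equal the scheme's last breakpoint so that the
    catchment and the sub-zone banding agree.
    """

    name: str
    threshold: float
    scheme: SubzoneScheme
    beta: float
    continuous: bool = False

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError(f"mode {self.name!r}: beta must be positive")
        if self.threshold != self.scheme.threshold:
            raise ValueError(
                f"mode {self.name!r}: threshold {self.threshold} != scheme "
                f"threshold {self.scheme.threshold}"
            )

    def with_beta(self, beta: float) -> "ModeSpec":
        return ModeSpec(self.name, self.threshold, self.scheme, beta, self.continuous)


class TravelTimeMatrix:
    """Sparse origin-destination travel times for one mode.

    ``entries`` maps ``(demand_id, supply_id)`` to minutes; an absent pair is
    unreachable.  The same entry serves both model steps (demand->site and
    site->demand), so an asymmetric interpretation is not representable.
    """

    def __init__(self, mode: str, entries: Mapping[tuple[str, str], float]):
        for (k, i), t in entries.items():
            if t < 0:
                raise ValueError(f"negative travel time for ({k!r}, {i!r}): {t}")
        self.mode = mode
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, demand_id: str, supply_id: str) -> float | None:
        return self.entries.get((demand_id, supply_id))


@dataclass
class Scene:
    """Model inputs: supply sites, demand units, per-mode OD matrices."""

    supply: list[SupplySite]
    demand: list[DemandUnit]
    matrices: dict[str, TravelTimeMatrix]

    def __post_init__(self):
        site_ids = [s.id for s in self.supply]
        unit_ids = [u.id for u in self.demand]
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate supply site ids")
        if len(set(unit_ids)) != len(unit_ids):
            raise ValueError("duplicate demand unit ids")
        for mode, matrix in self.matrices.items():
            if matrix.mode != mode:
                raise ValueError(f"matrix keyed {mode!r} labelled {matrix.mode!r}")

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.supply]

    @property
    def unit_ids(self) -> list[str]:
        return [u.id for u in self.demand]

    def population_matrix(self, modes: Sequence[str]) -> np.ndarray:
        """(n_units, n_modes) array of per-mode populations."""
        return np.array(
            [[u.populations.get(m, 0.0) for m in modes] for u in self.demand],
            dtype=float,
        )


@dataclass
class AccessResult:
    """Scores of one model run, aligned to the scene's id order."""

    unit_ids: list[str]
    site_ids: list[str]
    modes: list[str]
    site_ratios: np.ndarray  # (n_sites,)
    spai_by_mode: pd.DataFrame  # index unit id, one column per mode
    spai_integrated: pd.Series
    spar_by_mode: pd.DataFrame
    spar_integrated: pd.Series
    no_access_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def mean_spai_by_mode(self) -> pd.Series:
        return self.spai_by_mode.mean(axis=0)

    @property
    def mean_spai_integrated(self) -> float:
        return float(self.spai_integrated.mean())


class _CompiledScene:
    """Dense per-mode weight machinery shared by the step-1/step-2 sums.

    For each mode a (n_units, n_sites) int array of 1-based sub-zone
    indices is built once (``OUTSIDE`` for unreachable or beyond-catchment
    pairs).  A weight matrix for any beta is then a lookup into the vector
    of sub-zone weights, which makes coefficient-grid sweeps cheap.
    """

    def __init__(self, scene: Scene, modes: Sequence[ModeSpec]):
        known = set(scene.matrices)
        wanted = {m.name for m in modes}
        if not wanted <= known:
            raise ValueError(
                f"no travel-time matrix for mode(s) {sorted(wanted - known)}"
            )
        extra = known - wanted
        if extra:
            logger.info("ignoring matrices for undeclared mode(s) %s", sorted(extra))
        self.scene = scene
        self.modes = list(modes)
        unit_pos = {u: n for n, u in enumerate(scene.unit_ids)}
        site_pos = {s: n for n, s in enumerate(scene.site_ids)}
        shape = (len(scene.demand), len(scene.supply))
        self.zone_index: dict[str, np.ndarray] = {}
        self.times: dict[str, np.ndarray] = {}
        for spec in modes:
            matrix = scene.matrices[spec.name]
            t = np.full(shape, np.nan)
            for (k, i), minutes in matrix.entries.items():
                if k not in unit_pos:
                    raise ValueError(
                        f"mode {spec.name!r}: unknown demand id {k!r} in OD matrix"
                    )
                if i not in site_pos:
                    raise ValueError(
                        f"mode {spec.name!r}: unknown supply id {i!r} in OD matrix"
                    )
                t[unit_pos[k], site_pos[i]] = minutes
            zones = np.full(shape, OUTSIDE, dtype=np.int64)
            defined = ~np.isnan(t)
            zones[defined] = subzone_of(t[defined], spec.scheme)
            self.zone_index[spec.name] = zones
            self.times[spec.name] = t

    def weight_matrix(self, spec: ModeSpec) -> np.ndarray:
        """(n_units, n_sites) decay weights; 0 outside the catchment."""
        zones = self.zone_index[spec.name]
        inside = zones != OUTSIDE
        w = np.zeros(zones.shape)
        if spec.continuous:
            t = self.times[spec.name]
            w[inside] = gaussian_weight(t[inside], spec.beta)
        else:
            zone_w = gaussian_weight(
                np.asarray(spec.scheme.representative_times), spec.beta
            )
            w[inside] = zone_w[zones[inside] - 1]
        return w


def _resolve(scene: Scene, modes: Sequence[ModeSpec], compiled=None) -> _CompiledScene:
    if compiled is not None:
        if compiled.scene is not scene or [m.name for m in compiled.modes] != [
            m.name for m in modes
        ]:
            raise ValueError("compiled scene does not match the given scene/modes")
        compiled.modes = list(modes)
        return compiled
    return _CompiledScene(scene, modes)


def supply_ratio_multimodal(
    scene: Scene, modes: Sequence[ModeSpec], compiled: _CompiledScene | None = None
) -> np.ndarray:
    """Step 1: per-site supply-to-demand ratio ``R_i``.

    The denominator of site i is the decay-weighted population reachable
    within each mode's catchment, summed over all modes.  Sites whose
    denominator is zero (nobody can reach them) get ratio 0 by convention.
    """
    comp = _resolve(scene, modes, compiled)
    capacities = np.array([s.capacity for s in scene.supply])
    pops = scene.population_matrix([m.name for m in modes])
    denom = np.zeros(len(scene.supply))
    for col, spec in enumerate(modes):
        denom += pops[:, col] @ comp.weight_matrix(spec)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(denom > 0, capacities / np.where(denom > 0, denom, 1.0), 0.0)
    return ratios


def spai_multimodal(
    site_ratios: np.ndarray,
    scene: Scene,
    modes: Sequence[ModeSpec],
    compiled: _CompiledScene | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Step 2: mode-specific and integrated SPAI per demand unit."""
    site_ratios = np.asarray(site_ratios, dtype=float)
    if site_ratios.shape != (len(scene.supply),):
        raise ValueError(
            f"got {site_ratios.shape[0] if site_ratios.ndim else 0} site ratios "
            f"for {len(scene.supply)} sites"
        )
    comp = _resolve(scene, modes, compiled)
    by_mode = {}
    for spec in modes:
        by_mode[spec.name] = comp.weight_matrix(spec) @ site_ratios
    spai = pd.DataFrame(by_mode, index=pd.Index(scene.unit_ids, name="unit_id"))
    integrated = spai.sum(axis=1)
    integrated.name = "integrated"
    return spai, integrated


def spar(scores: Sequence[float] | pd.Series) -> tuple[np.ndarray, float, bool]:
    """Step 3: scores divided by their mean.

    Returns ``(ratios, mean_score, no_access)``.  When every score is zero
    the mean is zero and the ratio is undefined; the ratios come back as
    zeros with ``no_access=True`` and a warning instead of a division error.
    """
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalise an empty score vector")
    if np.any(values < 0):
        raise ValueError("scores must be non-negative")
    mean = float(values.mean())
    if mean == 0.0:
        warnings.warn(
            "all scores are zero; SPAR is undefined and reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(values), 0.0, True
    return values / mean, mean, False


def run_access(
    scene: Scene, modes: Sequence[ModeSpec], compiled: _CompiledScene | None = None
) -> AccessResult:
    """All three steps on one scene; SPAR per mode and for the integrated score."""
    comp = _resolve(scene, modes, compiled)
    ratios = supply_ratio_multimodal(scene, modes, comp)
    spai, integrated = spai_multimodal(ratios, scene, modes, comp)

    flags: dict[str, bool] = {}
    spar_cols = {}
    for mode in spai.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s, _, flag = spar(spai[mode])
        spar_cols[mode] = s
        flags[mode] = flag
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s_int, _, flag_int = spar(integrated)
    flags["integrated"] = flag_int

    spar_df = pd.DataFrame(spar_cols, index=spai.index)
    spar_int = pd.Series(s_int, index=spai.index, name="integrated")
    return AccessResult(
        unit_ids=scene.unit_ids,
        site_ids=scene.site_ids,
        modes=[m.name for m in modes],
        site_ratios=ratios,
        spai_by_mode=spai,
        spai_integrated=integrated,
        spar_by_mode=spar_df,
        spar_integrated=spar_int,
        no_access_flags=flags,
    )


def e2sfca_single_mode(scene: Scene, mode: ModeSpec) -> AccessResult:
    """Classic single-mode baseline on the TOTAL population of each unit.

    Equivalent to the multi-modal pipeline run with one mode carrying the
    summed population, which is how it is implemented.
    """
    total = Scene(
        supply=scene.supply,
        demand=[
            DemandUnit(u.id, {mode.name: u.total_population}, u.x, u.y)
            for u in scene.demand
        ],
        matrices={mode.name: scene.matrices[mode.name]},
    )
    return run_access(total, [mode])


def compile_scene(scene: Scene, modes: Sequence[ModeSpec]) -> _CompiledScene:
    """Precompute sub-zone indices so repeated runs over betas are cheap."""
    return _CompiledScene(scene, modes)
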