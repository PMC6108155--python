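"""Impedance-coefficient sensitivity analysis.

Runs the access model over a Cartesian grid of per-mode Gaussian
coefficients, collects per-unit score vectors per grid cell, summarises
them (min/max/mean/SD/CV) and tests, with one-way ANOVA, whether scores
differ across coefficient choices.  The headline contrast: raw access
scores (SPAI) shift with the coefficient, while the normalised ratios
(SPAR) have mean 1 in every cell, so SPAR group means never differ and
every SPAR ANOVA returns F ~ 0, p = 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .access import AccessResult, ModeSpec, Scene, compile_scene, run_access

__all__ = [
    "AnovaOutcome",
    "SensitivityResult",
    "build_grid",
    "run_grid",
    "describe",
    "anova_oneway",
    "hypothesis_battery",
]

#: Score families summarised and tested, as (kind, mode) pairs.
SCORE_FAMILIES = ("spai", "spar")


@dataclass(frozen=True)
class AnovaOutcome:
    """One ANOVA row of the hypothesis battery."""

    hypothesis: str
    family: str  # e.g. "spai_car", "spar_integrated"
    grouped_by: str  # mode whose beta defines the groups
    fixed_mode: str | None  # non-focal mode held at fixed_beta, if any
    fixed_beta: float | None
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class SensitivityResult:
    """Grid of access results plus summaries and ANOVA outcomes."""

    modes: list[str]
    grids: dict[str, tuple[float, ...]]
    results: dict[tuple[float, ...], AccessResult]
    stats: pd.DataFrame  # per cell x family descriptive statistics
    anova: list[AnovaOutcome]

    @property
    def n_cells(self) -> int:
        return len(self.results)

    def scores_long(self) -> pd.DataFrame:
        """Tidy per-unit scores keyed by the beta of every mode."""
        frames = []
        for betas, result in self.results.items():
            frame = pd.DataFrame(
                {
                    "unit_id": result.unit_ids,
                    **{
                        f"spai_{m}": result.spai_by_mode[m].to_numpy()
                        for m in result.modes
                    },
                    "spai_integrated": result.spai_integrated.to_numpy(),
                    **{
                        f"spar_{m}": result.spar_by_mode[m].to_numpy()
                        for m in result.modes
                    },
                    "spar_integrated": result.spar_integrated.to_numpy(),
                }
            )
            for mode, beta in zip(self.modes, betas):
                frame.insert(0, f"beta_{mode}", beta)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "hypothesis": a.hypothesis,
                    "family": a.family,
                    "grouped_by": a.grouped_by,
                    "fixed_mode": a.fixed_mode,
                    "fixed_beta": a.fixed_beta,
                    "F": a.F,
                    "df_between": a.df_between,
                    "df_within": a.df_within,
                    "p": a.p,
                }
                for a in self.anova
            ]
        )


def build_grid(beta_min: float, beta_max: float, n_points: int) -> tuple[float, ...]:
    """``n_points`` equally spaced coefficients, endpoints included."""
    if n_points < 2:
        raise ValueError(f"need at least 2 grid points, got {n_points}")
    if not 0 < beta_min < beta_max:
        raise ValueError(f"need 0 < beta_min < beta_max, got [{beta_min}, {beta_max}]")
    return tuple(np.linspace(beta_min, beta_max, n_points).tolist())


def describe(scores: Sequence[float] | pd.Series) -> dict[str, float]:
    """min/max/mean/SD/CV of a score vector (sample SD, ddof=1).

    CV is SD / mean; with a zero mean it is reported as NaN.
    """
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise ValueError("cannot describe an empty score vector")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    cv = sd / mean if mean != 0 else float("nan")
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": mean,
        "sd": sd,
        "cv": cv,
    }


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: ``(F, df_between, df_within, p)``.

    Implemented from the sum-of-squares decomposition rather than delegated,
    so the degenerate all-constant case is well defined: zero between-group
    variance gives F = 0 and p = 1 even when the within-group variance is
    also zero.  An F statistic at or below 1e-10 is numerical noise (group
    means identical up to float summation error) and is reported with
    p = 1 exactly rather than the survival function's 1 - O(sqrt(F)).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    n_total = sum(a.size for a in arrays)
    grand_mean = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if ss_between == 0.0:
        return 0.0, df_between, df_within, 1.0
    if ss_within == 0.0:
        return float("inf"), df_between, df_within, 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    if F <= 1e-10:
        return float(F), df_between, df_within, 1.0
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), df_between, df_within, p


def run_grid(
    scene: Scene,
    mode_templates: Sequence[ModeSpec],
    grids: dict[str, Sequence[float]],
) -> SensitivityResult:
    """Run the access model for every combination of per-mode coefficients.

    ``mode_templates`` carry thresholds and sub-zone schemes; their beta is
    replaced by each grid value in turn.  Deterministic given the scene.
    """
    mode_names = [m.name for m in mode_templates]
    if set(grids) != set(mode_names):
        raise ValueError(
            f"grids given for {sorted(grids)} but modes are {sorted(mode_names)}"
        )
    for mode, grid in grids.items():
        if len(grid) == 0:
            raise ValueError(f"empty grid for mode {mode!r}")
        if any(b <= 0 for b in grid):
            raise ValueError(f"non-positive beta in grid for mode {mode!r}")

    compiled = compile_scene(scene, mode_templates)
    results: dict[tuple[float, ...], AccessResult] = {}
    stat_rows = []
    for betas in itertools.product(*(grids[m] for m in mode_names)):
        specs = [t.with_beta(b) for t, b in zip(mode_templates, betas)]
        result = run_access(scene, specs, compiled)
        results[betas] = result
        cell = dict(zip((f"beta_{m}" for m in mode_names), betas))
        for mode in mode_names:
            stat_rows.append(
                {**cell, "family": f"spai_{mode}", **describe(result.spai_by_mode[mode])}
            )
            stat_rows.append(
                {**cell, "family": f"spar_{mode}", **describe(result.spar_by_mode[mode])}
            )
        stat_rows.append(
            {**cell, "family": "spai_integrated", **describe(result.spai_integrated)}
        )
        stat_rows.append(
            {**cell, "family": "spar_integrated", **describe(result.spar_integrated)}
        )

    return SensitivityResult(
        modes=mode_names,
        grids={m: tuple(grids[m]) for m in mode_names},
        results=results,
        stats=pd.DataFrame(stat_rows),
        anova=[],
    )


def _family_scores(result: AccessResult, family: str) -> np.ndarray:
    kind, _, mode = family.partition("_")
    if mode == "integrated":
        series = result.spai_integrated if kind == "spai" else result.spar_integrated
    else:
        frame = result.spai_by_mode if kind == "spai" else result.spar_by_mode
        series = frame[mode]
    return series.to_numpy()


def hypothesis_battery(
    sensitivity: SensitivityResult,
    focal_modes: dict[str, str] | None = None,
) -> list[AnovaOutcome]:
    """ANOVA battery contrasting SPAI instability with SPAR stability.

    For each score family the battery runs (a) one ANOVA grouping per-unit
    scores by the family's focal mode's beta, pooling over the other mode's
    grid, and (b) one ANOVA per fixed focal beta, across the other mode's
    grid.  With two modes and both score kinds this is the paper-style
    12-hypothesis layout; the outcomes are also stored on ``sensitivity``.

    ``focal_modes`` maps family mode label -> focal grid mode (integrated
    scores default to the first mode).
    """
    modes = sensitivity.modes
    if len(modes) < 2 or any(len(g) < 2 for g in sensitivity.grids.values()):
        warnings.warn(
            "hypothesis battery needs >= 2 modes and >= 2 betas per grid; "
            "returning an empty battery",
            RuntimeWarning,
            stacklevel=2,
        )
        sensitivity.anova = []
        return []
    if focal_modes is None:
        focal_modes = {m: m for m in modes}
        focal_modes["integrated"] = modes[0]

    outcomes: list[AnovaOutcome] = []
    counter = itertools.count(1)
    for kind in SCORE_FAMILIES:
        for label in [*modes, "integrated"]:
            family = f"{kind}_{label}"
            focal = focal_modes[label]
            others = [m for m in modes if m != focal]
            other = others[0]  # two-mode battery
            focal_axis = modes.index(focal)
            other_axis = modes.index(other)

            # (a) group by focal beta, pooled over the other mode's grid
            pooled = []
            for beta in sensitivity.grids[focal]:
                obs = [
                    _family_scores(result, family)
                    for cell, result in sensitivity.results.items()
                    if cell[focal_axis] == beta
                ]
                pooled.append(np.concatenate(obs))
            F, df1, df2, p = anova_oneway(pooled)
            outcomes.append(
                AnovaOutcome(
                    f"H{next(counter)}", family, focal, None, None, F, df1, df2, p
                )
            )

            # (b) for each fixed focal beta, group across the other grid
            hyp = f"H{next(counter)}"
            for fixed_beta in sensitivity.grids[focal]:
                groups = []
                for beta in sensitivity.grids[other]:
                    obs = [
                        _family_scores(result, family)
                        for cell, result in sensitivity.results.items()
                        if cell[focal_axis] == fixed_beta
                        and cell[other_axis] == beta
                    ]
                    groups.append(np.concatenate(obs))
                F, df1, df2, p = anova_oneway(groups)
                outcomes.append(
                    AnovaOutcome(
                        hyp, family, other, focal, fixed_beta, F, df1, df2, p
                    )
                )
    sensitivity.anova = outcomes
    return outcomes
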