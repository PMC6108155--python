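"""CSV / YAML / GeoJSON input-output and run configuration.

File schemas
------------
supply CSV   ``id,capacity[,x,y]``
demand CSV   ``id,pop_<mode>...[,x,y]``
OD CSV       ``origin_id,dest_id,minutes`` (long format, one file per mode;
             an absent row means the pair is unreachable)
config YAML  mode definitions (threshold, breakpoints, representative
             times, beta or beta grid), weighting style, seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .access import (
    AccessResult,
    DemandUnit,
    ModeSpec,
    Scene,
    SupplySite,
    TravelTimeMatrix,
)
from .decay import SubzoneScheme, round_half_away
from .sensitivity import SensitivityResult

__all__ = [
    "SceneParseError",
    "RunConfig",
    "load_config",
    "read_scene",
    "write_scene",
    "write_access_result",
    "write_sensitivity_result",
    "write_manifest",
    "scene_to_geojson",
]


class SceneParseError(ValueError):
    """Schema violation in an input file, with file/row context."""


@dataclass
class RunConfig:
    """Parsed run configuration: mode specs plus optional per-mode beta grids."""

    modes: list[ModeSpec]
    beta_grids: dict[str, tuple[float, ...]]
    weighting: str = "stepped"  # or "continuous"
    seed: int = 0

    @property
    def mode_names(self) -> list[str]:
        return [m.name for m in self.modes]


DEFAULT_CONFIG: dict = {
    "weighting": "stepped",
    "seed": 0,
    "modes": {
        "car": {
            "threshold": 30,
            "breakpoints": [0, 10, 20, 30],
            "beta": 140,
            "beta_grid": {"min": 140, "max": 320, "n": 13},
        },
        "bus": {
            "threshold": 60,
            "breakpoints": [0, 10, 20, 30, 60],
            "beta": 440,
            "beta_grid": {"min": 440, "max": 1040, "n": 13},
        },
    },
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a YAML config; ``None`` gives the case-study defaults."""
    if path is None:
        raw = DEFAULT_CONFIG
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    weighting = raw.get("weighting", "stepped")
    if weighting not in ("stepped", "continuous"):
        raise SceneParseError(
            f"weighting must be 'stepped' or 'continuous', got {weighting!r}"
        )
    modes = []
    grids: dict[str, tuple[float, ...]] = {}
    for name, entry in raw["modes"].items():
        scheme = SubzoneScheme(
            entry["breakpoints"], entry.get("representative_times")
        )
        modes.append(
            ModeSpec(
                name=name,
                threshold=float(entry.get("threshold", scheme.threshold)),
                scheme=scheme,
                beta=float(entry["beta"]),
                continuous=(weighting == "continuous"),
            )
        )
        grid = entry.get("beta_grid")
        if grid is not None:
            grids[name] = tuple(
                np.linspace(grid["min"], grid["max"], grid["n"]).tolist()
            )
    return RunConfig(
        modes=modes,
        beta_grids=grids,
        weighting=weighting,
        seed=int(raw.get("seed", 0)),
    )


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SceneParseError(f"{path}: missing column(s) {missing}")


def read_scene(
    supply_path: str | Path,
    demand_path: str | Path,
    od_paths: Mapping[str, str | Path],
) -> Scene:
    """Load and validate a scene from its CSV files.

    ``od_paths`` maps mode name to the mode's long-format OD CSV.  Duplicate
    ids, negative values and OD rows naming unknown ids are rejected with
    messages citing file and row.
    """
    supply_df = pd.read_csv(supply_path, dtype={"id": str}, float_precision="round_trip")
    _require_columns(supply_df, ["id", "capacity"], supply_path)
    if supply_df["id"].duplicated().any():
        dupes = supply_df.loc[supply_df["id"].duplicated(), "id"].tolist()
        raise SceneParseError(f"{supply_path}: duplicate supply id(s) {dupes}")
    bad = supply_df.index[supply_df["capacity"] < 0]
    if len(bad):
        raise SceneParseError(
            f"{supply_path}: row {bad[0] + 2}: negative capacity"
        )

    demand_df = pd.read_csv(demand_path, dtype={"id": str}, float_precision="round_trip")
    _require_columns(demand_df, ["id"], demand_path)
    pop_cols = [c for c in demand_df.columns if c.startswith("pop_")]
    if not pop_cols:
        raise SceneParseError(f"{demand_path}: no pop_<mode> columns found")
    if demand_df["id"].duplicated().any():
        dupes = demand_df.loc[demand_df["id"].duplicated(), "id"].tolist()
        raise SceneParseError(f"{demand_path}: duplicate demand id(s) {dupes}")
    for col in pop_cols:
        bad = demand_df.index[demand_df[col] < 0]
        if len(bad):
            raise SceneParseError(
                f"{demand_path}: row {bad[0] + 2}: negative {col}"
            )

    has_xy_s = {"x", "y"} <= set(supply_df.columns)
    supply = [
        SupplySite(
            row["id"],
            float(row["capacity"]),
            float(row["x"]) if has_xy_s else None,
            float(row["y"]) if has_xy_s else None,
        )
        for _, row in supply_df.iterrows()
    ]
    has_xy_d = {"x", "y"} <= set(demand_df.columns)
    demand = [
        DemandUnit(
            row["id"],
            {c[len("pop_"):]: float(row[c]) for c in pop_cols},
            float(row["x"]) if has_xy_d else None,
            float(row["y"]) if has_xy_d else None,
        )
        for _, row in demand_df.iterrows()
    ]

    unit_ids = {u.id for u in demand}
    site_ids = {s.id for s in supply}
    matrices = {}
    for mode, od_path in od_paths.items():
        od = pd.read_csv(
            od_path,
            dtype={"origin_id": str, "dest_id": str},
            float_precision="round_trip",
        )
        _require_columns(od, ["origin_id", "dest_id", "minutes"], od_path)
        entries = {}
        for row_no, row in enumerate(od.itertuples(index=False), start=2):
            if row.origin_id not in unit_ids:
                raise SceneParseError(
                    f"{od_path}: row {row_no}: unknown demand id {row.origin_id!r}"
                )
            if row.dest_id not in site_ids:
                raise SceneParseError(
                    f"{od_path}: row {row_no}: unknown supply id {row.dest_id!r}"
                )
            if row.minutes < 0:
                raise SceneParseError(
                    f"{od_path}: row {row_no}: negative travel time"
                )
            entries[(row.origin_id, row.dest_id)] = float(row.minutes)
        matrices[mode] = TravelTimeMatrix(mode, entries)
    return Scene(supply=supply, demand=demand, matrices=matrices)


def write_scene(scene: Scene, outdir: str | Path) -> dict[str, Path]:
    """Write supply/demand/OD CSVs; returns the paths, keyed by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    has_xy = all(s.x is not None for s in scene.supply)
    supply_rows = [
        {"id": s.id, "capacity": s.capacity, **({"x": s.x, "y": s.y} if has_xy else {})}
        for s in scene.supply
    ]
    paths["supply"] = outdir / "supply.csv"
    pd.DataFrame(supply_rows).to_csv(paths["supply"], index=False)

    mode_names = sorted({m for u in scene.demand for m in u.populations})
    has_xy = all(u.x is not None for u in scene.demand)
    demand_rows = [
        {
            "id": u.id,
            **{f"pop_{m}": u.populations.get(m, 0.0) for m in mode_names},
            **({"x": u.x, "y": u.y} if has_xy else {}),
        }
        for u in scene.demand
    ]
    paths["demand"] = outdir / "demand.csv"
    pd.DataFrame(demand_rows).to_csv(paths["demand"], index=False)

    for mode, matrix in scene.matrices.items():
        rows = [
            {"origin_id": k, "dest_id": i, "minutes": t}
            for (k, i), t in sorted(matrix.entries.items())
        ]
        path = outdir / f"od_{mode}.csv"
        pd.DataFrame(rows, columns=["origin_id", "dest_id", "minutes"]).to_csv(
            path, index=False
        )
        paths[f"od_{mode}"] = path
    return paths


def write_access_result(result: AccessResult, outdir: str | Path) -> dict[str, Path]:
    """Scores and site-ratio CSVs with deterministic row/column order.

    Full-precision columns are accompanied by 3-decimal presentation
    columns (suffix ``_r3``, rounded half away from zero).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scores = pd.DataFrame({"id": result.unit_ids})
    for mode in result.modes:
        scores[f"spai_{mode}"] = result.spai_by_mode[mode].to_numpy()
    scores["spai_integrated"] = result.spai_integrated.to_numpy()
    for mode in result.modes:
        scores[f"spar_{mode}"] = result.spar_by_mode[mode].to_numpy()
    scores["spar_integrated"] = result.spar_integrated.to_numpy()
    for col in [c for c in scores.columns if c != "id"]:
        scores[f"{col}_r3"] = round_half_away(scores[col].to_numpy(), 3)
    scores = scores.sort_values("id", kind="stable")

    ratios = pd.DataFrame(
        {"id": result.site_ids, "ratio": result.site_ratios}
    ).sort_values("id", kind="stable")
    ratios["ratio_r3"] = round_half_away(ratios["ratio"].to_numpy(), 3)

    paths = {
        "scores": outdir / "scores.csv",
        "site_ratios": outdir / "site_ratios.csv",
    }
    scores.to_csv(paths["scores"], index=False)
    ratios.to_csv(paths["site_ratios"], index=False)
    return paths


def write_sensitivity_result(
    result: SensitivityResult, outdir: str | Path
) -> dict[str, Path]:
    """Long score table, descriptive statistics, and the ANOVA table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beta_cols = [f"beta_{m}" for m in result.modes]
    paths = {
        "scores": outdir / "sensitivity_scores.csv",
        "stats": outdir / "sensitivity_stats.csv",
        "anova": outdir / "sensitivity_anova.csv",
    }
    long = result.scores_long().sort_values([*beta_cols, "unit_id"], kind="stable")
    long.to_csv(paths["scores"], index=False)
    stats = result.stats.sort_values([*beta_cols, "family"], kind="stable")
    stats.to_csv(paths["stats"], index=False)
    result.anova_frame().to_csv(paths["anova"], index=False)
    return paths


def write_manifest(outdir: str | Path, **entries) -> Path:
    """Plain-text run manifest: config, seed, library versions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.txt"
    lines = [
        f"mmspar {__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}",
        f"pandas {pd.__version__}",
    ]
    for key, value in entries.items():
        lines.append(f"{key} {value}")
    path.write_text("\n".join(lines) + "\n")
    return path


def scene_to_geojson(
    scene: Scene,
    scores: pd.DataFrame | None = None,
    crs_note: str = "planar kilometres, non-geographic local frame",
) -> dict:
    """Demand units as a GeoJSON-style FeatureCollection of points.

    Coordinates are the scene's planar kilometres, not longitude/latitude,
    unless the caller supplies a CRS note saying otherwise.
    """
    features = []
    for unit in scene.demand:
        if unit.x is None or unit.y is None:
            continue
        props: dict = {"id": unit.id, **{f"pop_{m}": p for m, p in unit.populations.items()}}
        if scores is not None and unit.id in scores.index:
            props.update(
                {k: float(v) for k, v in scores.loc[unit.id].items()}
            )
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [unit.x, unit.y]},
                "properties": props,
            }
        )
    return {
        "type": "FeatureCollection",
        "crs_note": crs_note,
        "features": features,
    }


def dump_geojson(collection: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1)
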