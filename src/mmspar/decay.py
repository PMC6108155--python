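"""Gaussian travel impedance: decay weights, catchment sub-zones, coefficients.

The weighting model is a Gaussian kernel ``w = exp(-d**2 / beta)`` applied to
travel time ``d`` in minutes.  In the stepped (default) variant the catchment
is divided into travel-time sub-zones and every trip in a sub-zone receives
the weight evaluated at that sub-zone's representative (mean) travel time, so
weights are piecewise constant in travel time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubzoneScheme",
    "DecayParams",
    "OUTSIDE",
    "gaussian_weight",
    "subzone_of",
    "subzone_weight",
    "derive_beta",
    "weight_table",
    "round_half_away",
    "CAR_SCHEME",
    "BUS_SCHEME",
    "CAR_BETAS",
    "BUS_BETAS",
]

#: Sentinel returned by :func:`subzone_of` for times beyond the catchment.
OUTSIDE = -1


def round_half_away(x, decimals: int = 3):
    """Round with ties going away from zero (presentation convention).

    ``numpy.round`` rounds half to even; printed tables in common GIS
    tooling round half away from zero, so reported weights use this helper.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    rounded = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if rounded.ndim == 0:
        return float(rounded)
    return rounded


@dataclass(frozen=True)
class SubzoneScheme:
    """Ordered travel-time sub-zones of a catchment.

    Parameters
    ----------
    breakpoints
        Strictly increasing boundaries in minutes, starting at 0.  A scheme
        with breakpoints ``[0, 10, 20, 30]`` has three sub-zones
        ``[0, 10), [10, 20), [20, 30]``; the final sub-zone is closed so the
        catchment threshold itself is inside the catchment.
    representative_times
        One travel time per sub-zone at which the decay weight is evaluated.
        Defaults to the arithmetic midpoint of each sub-zone.
    """

    breakpoints: tuple[float, ...]
    representative_times: tuple[float, ...] = field(default=())

    def __init__(
        self,
        breakpoints: Sequence[float],
        representative_times: Sequence[float] | None = None,
    ):
        bp = tuple(float(b) for b in breakpoints)
        if len(bp) < 2:
            raise ValueError("scheme needs at least two breakpoints")
        if bp[0] != 0.0:
            raise ValueError(f"first breakpoint must be 0, got {bp[0]}")
        if any(b1 >= b2 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError(f"breakpoints must be strictly increasing: {bp}")
        if representative_times is None:
            rep = tuple((a + b) / 2.0 for a, b in zip(bp, bp[1:]))
        else:
            rep = tuple(float(t) for t in representative_times)
            if len(rep) != len(bp) - 1:
                raise ValueError(
                    f"{len(rep)} representative times for {len(bp) - 1} sub-zones"
                )
            for k, t in enumerate(rep):
                if not (bp[k] <= t <= bp[k + 1]):
                    raise ValueError(
                        f"representative time {t} outside sub-zone "
                        f"[{bp[k]}, {bp[k + 1]}]"
                    )
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "representative_times", rep)

    @property
    def n_subzones(self) -> int:
        return len(self.breakpoints) - 1

    @property
    def threshold(self) -> float:
        """Catchment limit in minutes (the last breakpoint)."""
        return self.breakpoints[-1]


@dataclass(frozen=True)
class DecayParams:
    """Gaussian impedance coefficient (beta, minutes squared)."""

    beta: float

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


def gaussian_weight(d, beta):
    """Gaussian decay weight ``exp(-d**2 / beta)``.

    ``d`` is a travel time in minutes (scalar or array, >= 0) and ``beta``
    the positive impedance coefficient.  The weight is 1 at d = 0 and
    decreases monotonically with d.
    """
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("travel time must be non-negative")
    w = np.exp(-(d**2) / beta)
    if w.ndim == 0:
        return float(w)
    return w


def subzone_of(t, scheme: SubzoneScheme):
    """1-based sub-zone index containing travel time ``t``, or ``OUTSIDE``.

    Sub-zones are left-closed and right-open except the last, which is
    closed at the catchment threshold.  Accepts scalars or arrays; arrays
    come back as an integer array with ``OUTSIDE`` (-1) marking times
    beyond the threshold.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("travel time must be non-negative")
    bp = np.asarray(scheme.breakpoints)
    # searchsorted(side="right") gives the left-closed/right-open banding
    idx = np.asarray(np.searchsorted(bp, t_arr, side="right"), dtype=np.int64)
    idx = np.where(t_arr == scheme.threshold, scheme.n_subzones, idx)
    idx = np.where(idx > scheme.n_subzones, OUTSIDE, idx)
    if idx.ndim == 0:
        return int(idx)
    return idx


def subzone_weight(t, scheme: SubzoneScheme, beta):
    """Stepped decay weight: Gaussian weight at the sub-zone mean time.

    Every travel time in a sub-zone gets the identical weight, evaluated at
    that sub-zone's representative time.  Raises ``ValueError`` for scalar
    times outside the catchment; in array form out-of-catchment entries get
    weight 0 (they contribute nothing to any sum).
    """
    zone = subzone_of(t, scheme)
    rep = np.asarray(scheme.representative_times)
    if np.ndim(zone) == 0:
        if zone == OUTSIDE:
            raise ValueError(
                f"travel time {t} is outside the {scheme.threshold}-min catchment"
            )
        return gaussian_weight(rep[zone - 1], beta)
    weights = np.zeros(np.shape(zone), dtype=float)
    inside = zone != OUTSIDE
    weights[inside] = gaussian_weight(rep[zone[inside] - 1], beta)
    return weights


def derive_beta(d_ref: float, w_crit: float) -> float:
    """Coefficient giving weight ``w_crit`` at travel time ``d_ref``.

    Inverts the Gaussian kernel: beta = -d_ref**2 / ln(w_crit).  Used to
    anchor the minimum coefficient of a sensitivity grid at a critical
    weight (typically 0.01 or 0.1) in the outermost sub-zone.
    """
    if not 0 < w_crit < 1:
        raise ValueError(f"critical weight must be in (0, 1), got {w_crit}")
    if not d_ref > 0:
        raise ValueError(f"reference time must be positive, got {d_ref}")
    return -(d_ref**2) / math.log(w_crit)


def weight_table(
    schemes: dict[str, SubzoneScheme],
    betas: dict[str, Sequence[float]],
    decimals: int | None = None,
) -> pd.DataFrame:
    """Per-(mode, beta, sub-zone) table of stepped decay weights.

    Returns a tidy frame with columns ``mode, beta, subzone, rep_time_min,
    weight``.  Weights are exact unless ``decimals`` is given, in which case
    they are rounded half-away-from-zero for presentation.
    """
    if set(schemes) != set(betas):
        raise ValueError(
            f"modes differ between schemes {sorted(schemes)} and betas {sorted(betas)}"
        )
    rows = []
    for mode, scheme in schemes.items():
        for beta in betas[mode]:
            if not beta > 0:
                raise ValueError(f"beta must be positive, got {beta} for {mode!r}")
            for z, t in enumerate(scheme.representative_times, start=1):
                rows.append((mode, float(beta), z, t, gaussian_weight(t, beta)))
    table = pd.DataFrame(
        rows, columns=["mode", "beta", "subzone", "rep_time_min", "weight"]
    )
    if decimals is not None:
        table["weight"] = round_half_away(table["weight"].to_numpy(), decimals)
    return table


# Case-study defaults: 30-min car catchment with three sub-zones, 60-min bus
# catchment with four; coefficient grids anchored at critical weight 0.01.
CAR_SCHEME = SubzoneScheme([0, 10, 20, 30])
BUS_SCHEME = SubzoneScheme([0, 10, 20, 30, 60])
CAR_BETAS = tuple(range(140, 321, 15))
BUS_BETAS = tuple(range(440, 1041, 50))
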