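"""Terrain stratification and the terrain distribution (dominance) index.

The basin is stratified by elevation, slope and aspect using fixed class
schemes (four elevation belts, five slope classes, five aspect sectors with a
flat class coded -1), or by data-driven Jenks natural breaks.  For each
vegetation-change type i and terrain stratum e the dominance index

    K = (S_ie / S_e) / (S_i / S)

compares the change type's share inside the stratum with its basin-wide
share: K > 1 marks dominance in that stratum, K = 1 an even spread, K < 1
under-representation.  The S_e/S-weighted mean of K over strata is exactly 1
for every change type.

``jenks_breaks`` is an exact Fisher-Jenks dynamic program minimising the
total within-class sum of squared deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ClassifiedGrid, Grid

__all__ = [
    "TerrainScheme",
    "ELEVATION_SCHEME",
    "SLOPE_SCHEME",
    "ASPECT_SCHEME",
    "jenks_breaks",
    "classify_terrain",
    "terrain_distribution_index",
]


@dataclass(frozen=True)
class TerrainScheme:
    """Exhaustive, mutually exclusive classes over one terrain variable.

    For ``elevation``/``slope``: ``edges`` are interior class boundaries,
    bins lower-edge inclusive, open-ended at both extremes.  For ``aspect``:
    ``windows`` maps each label to a list of [lo, hi) degree intervals, plus
    a flat class for cells coded -1.
    """

    variable: str
    labels: tuple
    edges: tuple = None
    windows: dict = None

    def __post_init__(self) -> None:
        if self.variable in ("elevation", "slope"):
            if self.edges is None or len(self.edges) != len(self.labels) - 1:
                raise ValueError("interval scheme needs len(labels)-1 interior edges")
            if not np.all(np.diff(self.edges) > 0):
                raise ValueError("edges must be strictly increasing")
        elif self.variable == "aspect":
            if self.windows is None:
                raise ValueError("aspect scheme needs angular windows")
            if "flat" not in {l.lower() for l in self.labels}:
                raise ValueError("aspect scheme must include a flat class")
        else:
            raise ValueError(f"unknown terrain variable {self.variable!r}")

    @property
    def classes(self) -> dict:
        return {i + 1: lab for i, lab in enumerate(self.labels)}


ELEVATION_SCHEME = TerrainScheme(
    variable="elevation",
    labels=("low elevation", "middle-low elevation", "middle elevation",
            "high elevation"),
    edges=(3500.0, 3800.0, 4200.0),
)

SLOPE_SCHEME = TerrainScheme(
    variable="slope",
    labels=("flat", "gently sloping", "sloping", "steeply sloping",
            "sharply sloping"),
    edges=(3.0, 7.0, 12.0, 18.0),
)

# symmetric half-degree-exact sectors, lower-edge inclusive
ASPECT_SCHEME = TerrainScheme(
    variable="aspect",
    labels=("flat", "shaded", "semishaded", "semipositive", "sunny"),
    windows={
        "shaded": [(0.0, 67.5), (337.5, 360.0)],
        "semishaded": [(67.5, 112.5), (292.5, 337.5)],
        "semipositive": [(112.5, 157.5), (247.5, 292.5)],
        "sunny": [(157.5, 247.5)],
    },
)


def jenks_breaks(values, n_classes: int):
    """Exact Fisher-Jenks natural breaks.

    Returns the ``n_classes + 1`` break values ``[min, b_1, ..., max]`` of
    the partition of the sorted values minimising the total within-class sum
    of squared deviations.  Deterministic dynamic program, O(k n^2).
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    k = int(n_classes)
    distinct = len(np.unique(x))
    if distinct < k:
        raise ValueError(f"need >= {k} distinct values, got {distinct}")
    if k < 1:
        raise ValueError("n_classes must be >= 1")
    # prefix sums for O(1) segment cost: cost of x[i..j] (inclusive)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i, j):
        # vectorized over arrays i<=j of equal shape
        cnt = j - i + 1
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot * tot / cnt

    idx = np.arange(n)
    # cost[j] = best cost of partitioning x[0..j] into m classes
    cost = seg_cost(np.zeros(n, dtype=int), idx)
    back = np.zeros((k, n), dtype=int)
    for m in range(1, k):
        new_cost = np.full(n, np.inf)
        for j in range(m, n):
            i = np.arange(m, j + 1)           # start index of last class
            cand = cost[i - 1] + seg_cost(i, np.full(len(i), j))
            best = int(np.argmin(cand))
            new_cost[j] = cand[best]
            back[m, j] = m + best
        cost = new_cost
    # recover class start indices
    breaks = [float(x[-1])]
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = back[m, j]
        breaks.append(float(x[i]))            # lower bound of class m
        j = i - 1
    breaks.append(float(x[0]))
    return list(reversed(breaks))


def classify_terrain(grid: Grid, scheme: TerrainScheme) -> ClassifiedGrid:
    """Label every unmasked cell of a terrain grid under ``scheme``."""
    vals = grid.values.astype(float)
    unmasked = vals[~grid.nodata_mask]
    if scheme.variable in ("elevation", "slope"):
        if scheme.variable == "slope" and unmasked.size and unmasked.min() < 0:
            raise ValueError("slope values must be non-negative")
        codes = (np.digitize(vals, np.asarray(scheme.edges), right=False) + 1)
    else:
        in_range = (unmasked == -1.0) | ((unmasked >= 0.0) & (unmasked < 360.0))
        if unmasked.size and not in_range.all():
            raise ValueError("aspect values must be -1 (flat) or in [0, 360)")
        codes = np.zeros(vals.shape, dtype=np.int64)
        label_to_code = {lab: c for c, lab in scheme.classes.items()}
        flat_label = next(l for l in scheme.labels if l.lower() == "flat")
        codes[vals == -1.0] = label_to_code[flat_label]
        for lab, wins in scheme.windows.items():
            for lo, hi in wins:
                codes[(vals >= lo) & (vals < hi)] = label_to_code[lab]
        if ((codes == 0) & ~grid.nodata_mask).any():
            raise ValueError("aspect scheme windows do not cover all values")
    out = grid.with_values(codes.astype(np.int64))
    return ClassifiedGrid(out, scheme.classes)


def terrain_distribution_index(change: ClassifiedGrid, terrain: ClassifiedGrid,
                               cell_area_km2: float) -> pd.DataFrame:
    """Dominance table K = (S_ie/S_e)/(S_i/S) per change type x stratum.

    Pixels masked in either layer are excluded everywhere, so the areas are
    internally consistent (sum_e S_ie = S_i, sum_e S_e = S).  Strata or
    change types with zero area yield NaN K.
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if not change.grid.same_geometry(terrain.grid):
        raise ValueError("change and terrain grids are not co-registered")
    valid = ~(change.grid.nodata_mask | terrain.grid.nodata_mask)
    ci = change.grid.values[valid]
    te = terrain.grid.values[valid]
    s_total = valid.sum() * cell_area_km2
    rows = []
    for c_code in change.codes:
        s_i = np.count_nonzero(ci == c_code) * cell_area_km2
        for t_code in terrain.codes:
            s_e = np.count_nonzero(te == t_code) * cell_area_km2
            s_ie = np.count_nonzero((ci == c_code) & (te == t_code)) * cell_area_km2
            if s_e > 0 and s_i > 0:
                k = (s_ie / s_e) / (s_i / s_total)
            else:
                k = np.nan
            rows.append((change.classes[c_code], terrain.classes[t_code],
                         s_ie, s_e, s_i, s_total, k))
    return pd.DataFrame(rows, columns=["change_type", "terrain_class",
                                       "S_ie_km2", "S_e_km2", "S_i_km2",
                                       "S_km2", "K"])
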