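"""Fractional vegetation cover from a vegetation-index time series.

The chain is: maximum-value compositing of sub-monthly EVI periods into
monthly layers, annual aggregation, percentile-based estimation of the pure
soil / pure vegetation endmembers, and the dimidiate (two-endmember linear
mixing) pixel model

    FVC = (EVI - EVI_soil) / (EVI_veg - EVI_soil),

clipped to [0, 1], followed by grading into five cover classes.

The endmembers are empirical cumulative-frequency percentiles of the unmasked
EVI values (default 0.5% for soil, 99.5% for vegetation): pixels at the dark
tail are treated as bare soil, pixels at the bright tail as full canopy.  By
default endmembers are estimated per-year from that year's annual-mean grid;
a pooled multi-year pair can be computed by passing a stack-wide grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import ClassifiedGrid, Grid, GridStack

__all__ = [
    "EndmemberPair",
    "FvcGradeScheme",
    "DEFAULT_GRADE_SCHEME",
    "monthly_composite",
    "annual_mean_evi",
    "annual_max_evi",
    "estimate_endmembers",
    "estimate_fvc",
    "classify_fvc",
]


@dataclass(frozen=True)
class EndmemberPair:
    """Pure-soil and pure-vegetation EVI endmembers with their provenance."""

    evi_soil: float
    evi_veg: float
    soil_percentile: float = 0.5
    veg_percentile: float = 99.5

    def __post_init__(self) -> None:
        if not (0 < self.soil_percentile < self.veg_percentile < 100):
            raise ValueError("percentiles must satisfy 0 < soil < veg < 100")
        if not self.evi_soil < self.evi_veg:
            raise ValueError(
                f"degenerate endmembers: evi_soil={self.evi_soil} !< evi_veg={self.evi_veg}")


@dataclass(frozen=True)
class FvcGradeScheme:
    """Ordered FVC class edges covering [0, 1] and their labels.

    Bins are lower-edge inclusive; the top bin additionally includes 1.0.
    """

    edges: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    labels: tuple = ("low coverage", "medium-low coverage", "medium coverage",
                     "medium-high coverage", "high coverage")

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) != len(self.labels) + 1:
            raise ValueError("need one more edge than labels")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")
        if e[0] != 0.0 or e[-1] != 1.0:
            raise ValueError("edges must cover [0, 1]")

    @property
    def classes(self) -> dict:
        return {i + 1: lab for i, lab in enumerate(self.labels)}


DEFAULT_GRADE_SCHEME = FvcGradeScheme()


def monthly_composite(evi_periods: GridStack) -> GridStack:
    """Maximum-value composite: per (year, month), keep the per-pixel maximum.

    Input timestamps are ``(year, month)`` or ``(year, month, period)``; all
    periods of one month collapse to a single ``(year, month)`` layer.  A
    pixel is masked only where every contributing period is masked.
    """
    groups: dict = {}
    for g, t in zip(evi_periods.grids, evi_periods.timestamps):
        if len(t) < 2:
            raise ValueError("monthly_composite needs (year, month[, period]) timestamps")
        groups.setdefault((t[0], t[1]), []).append(g)
    out_grids, out_ts = [], []
    for key in sorted(groups):
        members = groups[key]
        stack = np.ma.stack([m.masked() for m in members])
        comp = stack.max(axis=0)
        out_grids.append(members[0].with_values(
            np.ma.filled(comp, 0.0), extra_mask=np.ma.getmaskarray(comp)))
        # with_values ORs the member mask; rebuild cleanly instead
        out_grids[-1].nodata_mask = np.ma.getmaskarray(comp).copy()
        out_ts.append(key)
    return GridStack(out_grids, out_ts)


def _aggregate_year(monthly: GridStack, year: int, how: str) -> Grid:
    members = [g for g, t in zip(monthly.grids, monthly.timestamps) if t[0] == year]
    if not members:
        raise ValueError(f"no monthly layers found for year {year}")
    stack = np.ma.stack([m.masked() for m in members])
    agg = stack.mean(axis=0) if how == "mean" else stack.max(axis=0)
    out = members[0].with_values(np.ma.filled(agg, 0.0))
    out.nodata_mask = np.ma.getmaskarray(agg).copy()
    return out


def annual_mean_evi(monthly: GridStack, year: int) -> Grid:
    """Per-pixel arithmetic mean over the available months of ``year``."""
    return _aggregate_year(monthly, year, "mean")


def annual_max_evi(monthly: GridStack, year: int) -> Grid:
    """Per-pixel maximum over the months of ``year`` (annual-MVC variant)."""
    return _aggregate_year(monthly, year, "max")


def estimate_endmembers(evi: Grid, soil_percentile: float = 0.5,
                        veg_percentile: float = 99.5) -> EndmemberPair:
    """Endmembers as linear-interpolated empirical quantiles of unmasked EVI."""
    vals = evi.values[~evi.nodata_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cannot estimate endmembers from an all-masked grid")
    if vals.size < 200:
        warnings.warn(
            f"only {vals.size} unmasked cells; percentile endmembers are unstable",
            stacklevel=2)
    soil = float(np.percentile(vals, soil_percentile))
    veg = float(np.percentile(vals, veg_percentile))
    if not soil < veg:
        raise ValueError(
            f"degenerate EVI distribution: soil endmember {soil} >= veg endmember {veg}")
    return EndmemberPair(soil, veg, soil_percentile, veg_percentile)


def estimate_fvc(evi: Grid, endmembers: EndmemberPair) -> Grid:
    """Dimidiate pixel model: linear rescale between endmembers, clipped to [0,1]."""
    span = endmembers.evi_veg - endmembers.evi_soil
    fvc = np.clip((evi.values.astype(float) - endmembers.evi_soil) / span, 0.0, 1.0)
    out = evi.with_values(fvc)
    out.units = "fraction"
    return out


def classify_fvc(fvc: Grid, scheme: FvcGradeScheme = DEFAULT_GRADE_SCHEME) -> ClassifiedGrid:
    """Grade an FVC grid with lower-edge-inclusive bins; 1.0 joins the top bin."""
    vals = fvc.values
    unmasked = vals[~fvc.nodata_mask]
    if unmasked.size and (unmasked.min() < 0 or unmasked.max() > 1):
        raise ValueError("FVC values outside [0, 1]; clip before classification")
    edges = np.asarray(scheme.edges, dtype=float)
    codes = np.digitize(vals, edges[1:-1], right=False) + 1
    codes = np.where(vals >= 1.0, len(scheme.labels), codes).astype(np.int64)
    return ClassifiedGrid(fvc.with_values(codes), scheme.classes)
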