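"""Per-pixel trend and stability analysis of annual FVC series.

Trend magnitude is the Theil–Sen estimator (median of all pairwise slopes),
significance the Mann–Kendall Z statistic, and the two are combined into a
five-class typology:

    significant improvement     slope >= +0.0005 and |Z| >= 1.96
    insignificant improvement   slope >= +0.0005 and |Z| <  1.96
    stabilization               |slope| < 0.0005
    insignificant degradation   slope <= -0.0005 and |Z| <  1.96
    significant degradation     slope <= -0.0005 and |Z| >= 1.96

The residual cell (|slope| < 0.0005 with |Z| >= 1.96) is mapped to
stabilization.  Interannual stability is graded by the coefficient of
variation (sample sd / mean) into five fluctuation classes.  Lagged Pearson
correlation maps relate annual FVC to a climate driver shifted back 0-2
years.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import ClassifiedGrid, Grid, GridStack

__all__ = [
    "TREND_CLASSES",
    "CV_CLASSES",
    "TrendResult",
    "StabilityResult",
    "theil_sen_slope",
    "mann_kendall",
    "classify_trend",
    "coefficient_of_variation",
    "classify_cv",
    "trend_analysis",
    "stability_analysis",
    "lagged_correlation",
]

TREND_CLASSES = {
    1: "significant degradation",
    2: "insignificant degradation",
    3: "stabilization",
    4: "insignificant improvement",
    5: "significant improvement",
}

CV_CLASSES = {
    1: "Stabilization",
    2: "Slight Fluctuation",
    3: "Moderate Fluctuation",
    4: "High Fluctuation",
    5: "Wild Fluctuation",
}

CV_EDGES = (0.07, 0.17, 0.30, 0.50)


@dataclass
class TrendResult:
    slope: Grid
    s_stat: Grid
    var_s: Grid
    z: Grid
    trend_class: ClassifiedGrid


@dataclass
class StabilityResult:
    cv: Grid
    cv_class: ClassifiedGrid


# ---------------------------------------------------------------------------
# scalar engines
# ---------------------------------------------------------------------------

def _pair_indices(n: int):
    idx = np.array(list(itertools.combinations(range(n), 2)))
    return idx[:, 0], idx[:, 1]


def theil_sen_slope(series) -> float:
    """Median of all n(n-1)/2 pairwise slopes (x_j - x_i)/(j - i), i < j."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Theil-Sen slope needs at least 3 values")
    i, j = _pair_indices(n)
    return float(np.median((x[j] - x[i]) / (j - i)))


def mann_kendall(series, tie_correction: bool = False):
    """Mann–Kendall S, Var(S) and Z for an ordered series.

    S counts concordant minus discordant later-vs-earlier pairs.  The default
    variance is n(n-1)(2n+5)/18; the tie-corrected mode subtracts
    sum t(t-1)(2t+5)/18 over groups of tied values.  Z applies the +-1
    continuity correction and is 0 when S = 0.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("Mann-Kendall needs at least 2 values")
    if n < 8:
        warnings.warn("Mann-Kendall normal approximation is poor below n=8",
                      stacklevel=2)
    i, j = _pair_indices(n)
    s = int(np.sum(np.sign(x[j] - x[i])))
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_correction:
        _, counts = np.unique(x, return_counts=True)
        ties = counts[counts > 1]
        var_s -= float(np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    return s, float(var_s), float(z)


def classify_trend(slope: float, z: float, slope_threshold: float = 0.0005,
                   z_threshold: float = 1.96) -> int:
    """Map (Theil-Sen slope, MK Z) to one of the five trend classes."""
    if not (np.isfinite(slope) and np.isfinite(z)):
        raise ValueError("classify_trend requires finite slope and z")
    sig = abs(z) >= z_threshold
    if slope >= slope_threshold:
        return 5 if sig else 4
    if slope <= -slope_threshold:
        return 1 if sig else 2
    return 3


def coefficient_of_variation(series, eps: float = 1e-12) -> float:
    """Sample standard deviation (ddof=1) divided by the mean."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = x.mean()
    if mean <= eps:
        raise ValueError(f"mean {mean} <= eps; CV undefined")
    return float(x.std(ddof=1) / mean)


def classify_cv(cv: float) -> int:
    """Five fluctuation classes with lower-edge-inclusive bins above 0.07."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    return int(np.digitize(cv, CV_EDGES, right=False)) + 1


# ---------------------------------------------------------------------------
# raster wrappers (vectorized over pixels)
# ---------------------------------------------------------------------------

def _annual_cube(annual: GridStack):
    cube = annual.values_3d()          # (years, rows, cols) masked
    return cube, annual.grids[0]


def trend_analysis(annual: GridStack, slope_threshold: float = 0.0005,
                   z_threshold: float = 1.96, min_years: int = 3,
                   tie_correction: bool = False) -> TrendResult:
    """Theil–Sen + Mann–Kendall per pixel over an annual stack.

    Pixels with fewer than ``min_years`` unmasked years come out masked.
    Masked years inside a pixel's series are dropped pixel-wise; pairwise
    slopes use the actual year offsets.
    """
    cube, template = _annual_cube(annual)
    n, rows, cols = cube.shape
    data = cube.data.reshape(n, -1).astype(float)
    miss = np.ma.getmaskarray(cube).reshape(n, -1)
    npix = data.shape[1]

    i, j = _pair_indices(n)
    denom = (j - i).astype(float)[:, None]
    with np.errstate(invalid="ignore"):
        pair_slopes = (data[j] - data[i]) / denom
    pair_valid = ~(miss[i] | miss[j])
    pair_slopes = np.where(pair_valid, pair_slopes, np.nan)

    slope = np.full(npix, np.nan)
    complete = ~miss.any(axis=0)
    if complete.any():
        slope[complete] = np.median(pair_slopes[:, complete], axis=0)
    partial = ~complete & ((~miss).sum(axis=0) >= min_years)
    for p in np.flatnonzero(partial):           # rare path: gappy pixels
        slope[p] = np.nanmedian(pair_slopes[:, p])

    sign = np.sign(np.where(pair_valid, data[j] - data[i], 0.0))
    s = sign.sum(axis=0)
    n_eff = (~miss).sum(axis=0).astype(float)
    var_s = n_eff * (n_eff - 1) * (2 * n_eff + 5) / 18.0
    if tie_correction:
        for p in range(npix):
            vals = data[~miss[:, p], p]
            _, counts = np.unique(vals, return_counts=True)
            ties = counts[counts > 1]
            var_s[p] -= np.sum(ties * (ties - 1) * (2 * ties + 5)) / 18.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, (s - 1) / np.sqrt(var_s),
                     np.where(s < 0, (s + 1) / np.sqrt(var_s), 0.0))

    invalid = n_eff < min_years
    out_mask = invalid | ~np.isfinite(slope)
    classes = np.where(
        slope >= slope_threshold, np.where(np.abs(z) >= z_threshold, 5, 4),
        np.where(slope <= -slope_threshold,
                 np.where(np.abs(z) >= z_threshold, 1, 2), 3))
    classes = np.where(out_mask, 3, classes).astype(np.int64)

    def mk(arr, fill=np.nan):
        vals = np.where(out_mask, fill, arr).reshape(rows, cols)
        g = template.with_values(vals, extra_mask=out_mask.reshape(rows, cols))
        g.nodata_mask = out_mask.reshape(rows, cols).copy()
        return g

    return TrendResult(
        slope=mk(slope), s_stat=mk(s), var_s=mk(var_s), z=mk(z),
        trend_class=ClassifiedGrid(mk(classes, fill=3), dict(TREND_CLASSES)),
    )


def stability_analysis(annual: GridStack, eps: float = 1e-12) -> StabilityResult:
    """Coefficient of variation per pixel; masked where the mean FVC <= eps."""
    cube, template = _annual_cube(annual)
    mean = cube.mean(axis=0)
    sd = cube.std(axis=0, ddof=1)
    n_eff = (~np.ma.getmaskarray(cube)).sum(axis=0)
    bad = (np.ma.filled(mean, 0.0) <= eps) | (n_eff < 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.ma.filled(sd / mean, np.nan)
    cv = np.where(bad, np.nan, cv)
    mask = bad | ~np.isfinite(cv)
    cv_grid = template.with_values(np.where(mask, np.nan, cv))
    cv_grid.nodata_mask = mask.copy()
    codes = (np.digitize(np.where(mask, 0.0, cv), CV_EDGES) + 1).astype(np.int64)
    cls_grid = template.with_values(codes)
    cls_grid.nodata_mask = mask.copy()
    return StabilityResult(cv=cv_grid, cv_class=ClassifiedGrid(cls_grid, dict(CV_CLASSES)))


def lagged_correlation(fvc_annual: GridStack, driver_annual: GridStack,
                       lag_years: int = 0, min_pairs: int = 5):
    """Per-pixel Pearson r between FVC(year) and driver(year - lag).

    Returns (r, p) grids; p from the two-sided t test with n-2 df.
    """
    if lag_years < 0:
        raise ValueError("lag_years must be >= 0")
    fvc_years = {t[0]: g for g, t in zip(fvc_annual.grids, fvc_annual.timestamps)}
    drv_years = {t[0]: g for g, t in zip(driver_annual.grids, driver_annual.timestamps)}
    years = sorted(y for y in fvc_years if (y - lag_years) in drv_years)
    if len(years) < min_pairs:
        raise ValueError(
            f"only {len(years)} overlapping year pairs at lag {lag_years}; "
            f"need >= {min_pairs}")
    a = np.ma.stack([fvc_years[y].masked() for y in years]).astype(float)
    b = np.ma.stack([drv_years[y - lag_years].masked() for y in years]).astype(float)
    joint = np.ma.getmaskarray(a) | np.ma.getmaskarray(b)
    a = np.ma.MaskedArray(a.data, joint)
    b = np.ma.MaskedArray(b.data, joint)
    n = (~joint).sum(axis=0)
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    cov = (am * bm).sum(axis=0)
    denom = np.ma.sqrt((am ** 2).sum(axis=0) * (bm ** 2).sum(axis=0))
    r = np.ma.filled(cov / denom, np.nan)
    bad = (n < min_pairs) | ~np.isfinite(r)
    r = np.clip(np.where(bad, np.nan, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t_stat), np.maximum(n - 2, 1))
    p = np.where(bad, np.nan, p)
    template = fvc_annual.grids[0]
    r_grid = template.with_values(r, extra_mask=bad)
    r_grid.nodata_mask = bad.copy()
    p_grid = template.with_values(p, extra_mask=bad)
    p_grid.nodata_mask = bad.copy()
    return r_grid, p_grid
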