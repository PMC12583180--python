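"""Spatial stratified-heterogeneity attribution (factor and interaction detectors).

For a response y observed over N locations and a stratification into L
strata, the q statistic

    q = 1 - SSW / SST = 1 - (sum_h sum_i (y_hi - ybar_h)^2) / (sum_i (y_i - ybar)^2)

measures how much of y's spatial variance the stratification explains
(q in [0, 1]; refining a stratification never decreases q).  The factor
detector computes q with a significance test; the interaction detector
overlays two stratifications (Cartesian product of nonempty stratum
combinations) and classifies the joint q against the marginal ones into the
five standard interaction types.

Significance is the one-way ANOVA F test (F = [(N-L)/(L-1)] q/(1-q) against
central F(L-1, N-L)), which is exactly calibrated under a normal null; the
geodetector convention of referencing the same statistic to a noncentral F
with plug-in noncentrality is also reported (``p_value_ncf``), and a seeded
permutation test is available for tiny strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .terrain import jenks_breaks

__all__ = [
    "StratifiedFactor",
    "FactorResult",
    "InteractionResult",
    "INTERACTION_TYPES",
    "discretize",
    "from_categorical",
    "factor_q",
    "interaction_q",
    "rank_factors",
]

INTERACTION_TYPES = (
    "nonlinear weaken",
    "uni-variable weaken",
    "bivariable enhanced",
    "independent",
    "nonlinear enhanced",
)


@dataclass
class StratifiedFactor:
    """A named stratification: one integer stratum code per observation."""

    name: str
    strata: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        if self.strata.ndim != 1:
            raise ValueError("strata must be a 1-D code vector")

    @property
    def L(self) -> int:
        return len(np.unique(self.strata))


@dataclass
class FactorResult:
    name: str
    q: float
    F_stat: float
    p_value: float
    p_value_ncf: float
    N: int
    L: int
    sst: float
    ssw: float


@dataclass
class InteractionResult:
    pair: tuple
    q_n: float
    q_m: float
    q_nm: float
    interaction_type: str


def discretize(values, method: str = "jenks", n_classes: int = 5,
               name: str = "factor", max_jenks_n: int = 2000) -> StratifiedFactor:
    """Stratify a continuous vector by jenks / quantile / equal_interval.

    Jenks on more than ``max_jenks_n`` values runs on an evenly spaced
    order-statistic subsample (deterministic) before classifying everything;
    breaks are recorded in ``provenance``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("discretize requires finite values")
    k = int(n_classes)
    if len(np.unique(x)) < k:
        raise ValueError(f"need >= {k} distinct values to form {k} strata")
    if method == "jenks":
        sample = np.sort(x)
        if len(sample) > max_jenks_n:
            pick = np.linspace(0, len(sample) - 1, max_jenks_n).round().astype(int)
            sample = sample[np.unique(pick)]
        breaks = jenks_breaks(sample, k)
        interior = np.asarray(breaks[1:-1])
    elif method == "quantile":
        interior = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
    elif method == "equal_interval":
        interior = np.linspace(x.min(), x.max(), k + 1)[1:-1]
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    codes = np.digitize(x, interior, right=False)
    return StratifiedFactor(name, codes, provenance={
        "method": method, "n_classes": k, "breaks": [float(b) for b in interior]})


def from_categorical(values, name: str = "factor") -> StratifiedFactor:
    """Wrap a native categorical layer (integer codes) as a factor."""
    codes = np.asarray(values).ravel()
    _, dense = np.unique(codes, return_inverse=True)
    return StratifiedFactor(name, dense, provenance={"method": "categorical"})


def _sums_of_squares(y: np.ndarray, codes: np.ndarray):
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    ssw = 0.0
    groups = []
    for c in np.unique(codes):
        g = y[codes == c]
        groups.append(g)
        ssw += float(np.sum((g - g.mean()) ** 2))
    return sst, ssw, groups


def factor_q(y, factor: StratifiedFactor, min_stratum_size: int = 2) -> FactorResult:
    """q statistic of one stratification with significance.

    ``p_value`` is the central-F one-way ANOVA p; ``p_value_ncf`` references
    the same F statistic to a noncentral F with the plug-in noncentrality
    lambda = (1/sigma^2)[sum_h N_h ybar_h^2 - (sum_h sqrt(N_h) ybar_h)^2 / N]
    (the convention of the original geodetector software; markedly
    conservative under the null).
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(factor.strata):
        raise ValueError("y and factor must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    sst, ssw, groups = _sums_of_squares(y, factor.strata)
    if sst <= 0:
        raise ValueError("y is constant: q undefined (SST = 0)")
    n = len(y)
    l = len(groups)
    singletons = sum(1 for g in groups if len(g) < min_stratum_size)
    if singletons:
        warnings.warn(f"{factor.name}: {singletons} strata below "
                      f"min_stratum_size={min_stratum_size}", stacklevel=2)
    q = 1.0 - ssw / sst
    if l < 2 or n - l < 1:
        return FactorResult(factor.name, q, np.nan, np.nan, np.nan, n, l, sst, ssw)
    f_stat = (n - l) / (l - 1) * q / max(1.0 - q, 1e-300)
    p = float(stats.f.sf(f_stat, l - 1, n - l))
    sigma2 = sst / n
    nh = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    lam = (np.sum(nh * means ** 2)
           - np.sum(np.sqrt(nh) * means) ** 2 / n) / sigma2
    p_ncf = float(stats.ncf.sf(f_stat, l - 1, n - l, max(lam, 0.0)))
    return FactorResult(factor.name, float(q), float(f_stat), p, p_ncf,
                        n, l, sst, ssw)


def permutation_p(y, factor: StratifiedFactor, n_perm: int = 999,
                  seed: int = 0) -> float:
    """Permutation p-value for q (shuffle y relative to strata)."""
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    obs = factor_q(y, factor).q
    hits = 0
    for _ in range(n_perm):
        sst, ssw, _ = _sums_of_squares(rng.permutation(y), factor.strata)
        if 1.0 - ssw / sst >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _overlay(fa: StratifiedFactor, fb: StratifiedFactor) -> StratifiedFactor:
    ka = np.unique(fa.strata, return_inverse=True)[1]
    kb = np.unique(fb.strata, return_inverse=True)[1]
    combo = ka * (kb.max() + 1) + kb
    _, dense = np.unique(combo, return_inverse=True)
    return StratifiedFactor(f"{fa.name}*{fb.name}", dense,
                            provenance={"method": "overlay"})


def classify_interaction(q_n: float, q_m: float, q_nm: float,
                         rtol: float = 1e-9) -> str:
    """Five-way interaction typology with a relative tie tolerance.

    Exact equality (within tolerance) of q_nm to q_n + q_m maps to
    'independent'; ties with min/max fall into 'uni-variable weaken'.
    """
    tol = rtol * max(1.0, abs(q_n) + abs(q_m))
    lo, hi, tot = min(q_n, q_m), max(q_n, q_m), q_n + q_m
    if abs(q_nm - tot) <= tol:
        return "independent"
    if q_nm > tot:
        return "nonlinear enhanced"
    if q_nm > hi + tol:
        return "bivariable enhanced"
    if q_nm < lo - tol:
        return "nonlinear weaken"
    return "uni-variable weaken"


def interaction_q(y, factor_n: StratifiedFactor,
                  factor_m: StratifiedFactor) -> InteractionResult:
    """Interaction detector: q of the product overlay, typed against marginals."""
    y = np.asarray(y, dtype=float).ravel()
    q_n = factor_q(y, factor_n).q
    q_m = factor_q(y, factor_m).q
    overlay = _overlay(factor_n, factor_m)
    counts = np.bincount(overlay.strata)
    if np.all(counts[counts > 0] == 1):
        warnings.warn("overlay produced only singleton strata; q_nm -> 1 artifact",
                      stacklevel=2)
    q_nm = factor_q(y, overlay).q
    return InteractionResult((factor_n.name, factor_m.name), q_n, q_m, q_nm,
                             classify_interaction(q_n, q_m, q_nm))


def rank_factors(results) -> list:
    """Descending by q; ties broken alphabetically by name."""
    results = list(results)
    if not results:
        raise ValueError("no factor results to rank")
    return sorted(results, key=lambda r: (-r.q, r.name))


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [{"name": r.name, "q": r.q, "F": r.F_stat, "p": r.p_value,
          "p_ncf": r.p_value_ncf, "N": r.N, "L": r.L} for r in results])
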