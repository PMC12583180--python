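"""Partial least squares path modeling (PLS-SEM) from first principles.

Latent variables are estimated as standardized weighted composites of their
indicator blocks (reflective, mode A): outer weights are iterated against an
inner approximation of each latent (centroid / factor / path weighting
scheme) until the weights stabilise.  Inner path coefficients are then OLS
regressions of each endogenous latent's scores on its parents' scores; with
standardized scores these are standardized coefficients.

Quality metrics follow the usual composite-modeling conventions:
R^2 per endogenous latent, communality = squared loading per indicator,
AVE = mean communality per block, and GOF = sqrt(mean communality x mean R^2).
Effects decompose over the (acyclic) inner graph into direct (edge
coefficient), indirect (sum over multi-step directed paths of coefficient
products) and total = direct + indirect.  Significance of path coefficients
comes from an observation-resampling bootstrap with per-block sign alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSModelSpec",
    "PLSFit",
    "vif",
    "fit_pls_sem",
    "model_quality",
    "effects_decomposition",
    "bootstrap_significance",
]


@dataclass
class PLSModelSpec:
    """Blocks (latent -> ordered indicators), inner DAG edges, and scheme."""

    blocks: dict
    inner_paths: list
    scheme: str = "centroid"

    def __post_init__(self) -> None:
        if self.scheme not in ("centroid", "factor", "path"):
            raise ValueError(f"unknown inner weighting scheme {self.scheme!r}")
        seen = {}
        for latent, inds in self.blocks.items():
            if not inds:
                raise ValueError(f"latent {latent!r} has no indicators")
            for ind in inds:
                if ind in seen:
                    raise ValueError(
                        f"indicator {ind!r} appears in blocks {seen[ind]!r} and {latent!r}")
                seen[ind] = latent
        names = set(self.blocks)
        for src, dst in self.inner_paths:
            if src not in names or dst not in names:
                raise ValueError(f"path ({src!r}, {dst!r}) references unknown latent")
        self.topological_order()          # raises on cycles

    @property
    def latents(self) -> list:
        return list(self.blocks)

    @property
    def indicators(self) -> list:
        return [i for inds in self.blocks.values() for i in inds]

    def parents(self, latent) -> list:
        return [s for s, d in self.inner_paths if d == latent]

    def topological_order(self) -> list:
        order, seen, active = [], set(), set()

        def visit(node):
            if node in seen:
                return
            if node in active:
                raise ValueError("inner path graph contains a cycle")
            active.add(node)
            for p in self.parents(node):
                visit(p)
            active.discard(node)
            seen.add(node)
            order.append(node)

        for latent in self.blocks:
            visit(latent)
        return order

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModelSpec":
        return cls(blocks={k: list(v) for k, v in d["blocks"].items()},
                   inner_paths=[tuple(p) for p in d.get("paths", [])],
                   scheme=d.get("scheme", "centroid"))


@dataclass
class PLSFit:
    spec: PLSModelSpec
    outer_weights: dict          # indicator -> weight
    loadings: dict               # indicator -> correlation with own latent
    latent_scores: pd.DataFrame  # n x K, standardized
    path_coefficients: dict      # (source, target) -> standardized coefficient
    r_squared: dict              # endogenous latent -> R^2
    communality: dict            # indicator -> squared loading
    ave: dict                    # latent -> mean communality
    gof: float
    n_obs: int
    n_dropped: int
    iterations: int
    final_change: float
    converged: bool
    bootstrap: pd.DataFrame = None


def vif(data: pd.DataFrame, variables) -> dict:
    """Variance inflation factor of each listed variable against the others.

    ``VIF_j = 1/(1 - R^2_j)`` from OLS of variable j on the remaining
    variables.  Perfect collinearity is reported as ``inf`` with a warning.
    """
    variables = list(variables)
    x = data[variables].to_numpy(dtype=float)
    n, p = x.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} variables")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant columns: {bad}")
    z = (x - x.mean(axis=0)) / sd
    out = {}
    for j, name in enumerate(variables):
        others = np.delete(z, j, axis=1)
        if others.shape[1] == 0:
            out[name] = 1.0
            continue
        beta, *_ = np.linalg.lstsq(others, z[:, j], rcond=None)
        resid = z[:, j] - others @ beta
        r2 = 1.0 - resid @ resid / (z[:, j] @ z[:, j])
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"{name}: perfect collinearity (VIF -> inf)", stacklevel=2)
            out[name] = float("inf")
        else:
            out[name] = float(1.0 / (1.0 - r2))
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant indicator column; cannot standardize")
    return (x - x.mean(axis=0)) / sd


def _score(xblock: np.ndarray, w: np.ndarray) -> np.ndarray:
    y = xblock @ w
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate composite with zero variance")
    return (y - y.mean()) / sd


def fit_pls_sem(data: pd.DataFrame, spec: PLSModelSpec, tol: float = 1e-6,
                max_iter: int = 300) -> PLSFit:
    """Fit the PLS path model on an observation x indicator table.

    Rows with any missing indicator are dropped (listwise deletion, count
    recorded on the fit).  Non-convergence returns a flagged partial fit.
    """
    missing = [c for c in spec.indicators if c not in data.columns]
    if missing:
        raise ValueError(f"indicators absent from data: {missing}")
    frame = data[spec.indicators].astype(float)
    complete = ~frame.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    frame = frame.loc[complete]
    n = len(frame)
    if n <= len(spec.indicators):
        raise ValueError(f"need more observations ({n}) than indicators "
                         f"({len(spec.indicators)})")
    x = _standardize(frame.to_numpy())
    latents = spec.latents
    cols = {ind: j for j, ind in enumerate(spec.indicators)}
    block_idx = {lat: np.array([cols[i] for i in spec.blocks[lat]])
                 for lat in latents}
    neighbours = {lat: set() for lat in latents}
    for s, d in spec.inner_paths:
        neighbours[s].add(d)
        neighbours[d].add(s)

    weights = {lat: np.ones(len(spec.blocks[lat])) for lat in latents}
    scores = np.column_stack([_score(x[:, block_idx[lat]], weights[lat])
                              for lat in latents])
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # inner approximation
        corr = np.corrcoef(scores, rowvar=False).reshape(len(latents), len(latents))
        inner = np.zeros_like(scores)
        for a, lat in enumerate(latents):
            conn = [latents.index(nb) for nb in neighbours[lat]]
            if not conn:
                inner[:, a] = scores[:, a]     # isolated block: power iteration
                continue
            if spec.scheme == "centroid":
                e = np.sign(corr[a, conn])
                e[e == 0] = 1.0
            elif spec.scheme == "factor":
                e = corr[a, conn]
            else:                              # path scheme
                e = np.empty(len(conn))
                parents = spec.parents(lat)
                pidx = [latents.index(p) for p in parents]
                if pidx:
                    beta = np.linalg.solve(corr[np.ix_(pidx, pidx)],
                                           corr[pidx, a])
                for k, b in enumerate(conn):
                    if b in pidx:
                        e[k] = beta[pidx.index(b)]
                    else:
                        e[k] = corr[a, b]
            inner[:, a] = scores[:, conn] @ e
        # mode-A outer update: weight = cov(indicator, inner estimate)
        change = 0.0
        new_scores = np.empty_like(scores)
        for a, lat in enumerate(latents):
            z = inner[:, a]
            zsd = z.std(ddof=1)
            if zsd == 0:
                raise ValueError(f"inner estimate for {lat!r} degenerated")
            z = (z - z.mean()) / zsd
            w = x[:, block_idx[lat]].T @ z / (n - 1)
            if w @ weights[lat] < 0:           # keep orientation stable
                w = -w
            y = x[:, block_idx[lat]] @ w
            w = w / y.std(ddof=1)              # unit-variance composite
            change = max(change, float(np.max(np.abs(w - weights[lat]))))
            weights[lat] = w
            new_scores[:, a] = _score(x[:, block_idx[lat]], w)
        scores = new_scores
        if change < tol:
            break
    converged = change < tol
    if not converged:
        warnings.warn(f"PLS outer iteration did not converge in {max_iter} "
                      f"iterations (last change {change:.2e})", stacklevel=2)

    # sign convention: dominant loading positive per block
    loadings = {}
    for a, lat in enumerate(latents):
        lv = np.array([np.corrcoef(x[:, cols[i]], scores[:, a])[0, 1]
                       for i in spec.blocks[lat]])
        if lv[np.argmax(np.abs(lv))] < 0:
            weights[lat] = -weights[lat]
            scores[:, a] = -scores[:, a]
            lv = -lv
        for i, l in zip(spec.blocks[lat], lv):
            loadings[i] = float(l)

    score_df = pd.DataFrame(scores, columns=latents, index=frame.index)
    path_coefficients = {}
    r_squared = {}
    for lat in latents:
        parents = spec.parents(lat)
        if not parents:
            continue
        pidx = [latents.index(p) for p in parents]
        a = latents.index(lat)
        rpp = np.corrcoef(scores[:, pidx], rowvar=False).reshape(len(pidx), len(pidx))
        rpt = np.array([np.corrcoef(scores[:, p], scores[:, a])[0, 1] for p in pidx])
        try:
            beta = np.linalg.solve(rpp, rpt)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular inner regression for {lat!r}") from err
        for p, b in zip(parents, beta):
            path_coefficients[(p, lat)] = float(b)
        r_squared[lat] = float(beta @ rpt)

    communality = {i: float(l ** 2) for i, l in loadings.items()}
    ave = {lat: float(np.mean([communality[i] for i in spec.blocks[lat]]))
           for lat in latents}
    mean_comm = float(np.mean(list(communality.values())))
    gof = float(np.sqrt(mean_comm * np.mean(list(r_squared.values())))) \
        if r_squared else float("nan")

    outer_weights = {}
    for lat in latents:
        for i, w in zip(spec.blocks[lat], weights[lat]):
            outer_weights[i] = float(w)

    return PLSFit(spec=spec, outer_weights=outer_weights, loadings=loadings,
                  latent_scores=score_df, path_coefficients=path_coefficients,
                  r_squared=r_squared, communality=communality, ave=ave,
                  gof=gof, n_obs=n, n_dropped=n_dropped, iterations=it,
                  final_change=float(change), converged=converged)


# Explanatory-power bands for R^2 and GOF used in reporting
R2_BANDS = ((0.67, "Substantial explanatory power"),
            (0.33, "Moderate explanatory power"),
            (0.19, "Weak explanatory power"))
GOF_BANDS = ((0.36, "strong model fitting"),
             (0.25, "medium model fitting"),
             (0.10, "weak model fitting"))


def _band(value: float, bands) -> str:
    for threshold, label in bands:
        if value > threshold:
            return label
    return "negligible"


def model_quality(fit: PLSFit) -> pd.DataFrame:
    """Quality table: R^2 (with band), AVE per block, communality, GOF."""
    rows = []
    for lat, r2 in fit.r_squared.items():
        rows.append(("R2", lat, r2, _band(r2, R2_BANDS)))
    for lat, a in fit.ave.items():
        rows.append(("AVE", lat, a, "convergent validity >= 0.5" if a >= 0.5
                     else "below 0.5"))
    for ind, c in fit.communality.items():
        rows.append(("communality", ind, c, ""))
    rows.append(("GOF", "model", fit.gof, _band(fit.gof, GOF_BANDS)))
    return pd.DataFrame(rows, columns=["metric", "name", "value", "assessment"])


def effects_decomposition(fit: PLSFit) -> pd.DataFrame:
    """Direct / indirect / total effect per ordered latent pair.

    Total effect = sum over all directed paths of the product of edge
    coefficients (computed by accumulating powers of the coefficient matrix;
    exact on a DAG).  Indirect = total - direct.
    """
    latents = fit.spec.latents
    k = len(latents)
    b = np.zeros((k, k))
    for (src, dst), coef in fit.path_coefficients.items():
        b[latents.index(src), latents.index(dst)] = coef
    total = np.zeros((k, k))
    power = np.eye(k)
    for _ in range(k):
        power = power @ b
        total += power
    rows = []
    for i, src in enumerate(latents):
        for j, dst in enumerate(latents):
            if i == j or (b[i, j] == 0 and total[i, j] == 0):
                continue
            direct = b[i, j]
            rows.append((src, dst, direct, total[i, j] - direct, total[i, j]))
    return pd.DataFrame(rows, columns=["source", "target", "direct",
                                       "indirect", "total"])


def bootstrap_significance(data: pd.DataFrame, spec: PLSModelSpec,
                           n_boot: int = 500, seed: int = 0,
                           tol: float = 1e-6, max_iter: int = 300,
                           max_failure_rate: float = 0.10) -> pd.DataFrame:
    """Bootstrap standard errors, normal-reference p-values and percentile CIs
    for the inner path coefficients.

    Observations are resampled with replacement; each resample is refit and
    its blocks sign-aligned to the full-sample fit via the outer weights.
    p-values use the t-ratio (coefficient / bootstrap se) against a standard
    normal; the 2.5/97.5 percentile interval is reported alongside.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    full = fit_pls_sem(data, spec, tol=tol, max_iter=max_iter)
    paths = list(full.path_coefficients)
    rng = np.random.default_rng(seed)
    frame = data[spec.indicators].dropna()
    n = len(frame)
    draws = np.full((n_boot, len(paths)), np.nan)
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = frame.iloc[idx].reset_index(drop=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = fit_pls_sem(sample, spec, tol=tol, max_iter=max_iter)
            if not refit.converged:
                raise ValueError("non-convergent resample")
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        flip = {}
        for lat in spec.latents:
            w_full = np.array([full.outer_weights[i] for i in spec.blocks[lat]])
            w_boot = np.array([refit.outer_weights[i] for i in spec.blocks[lat]])
            flip[lat] = -1.0 if w_full @ w_boot < 0 else 1.0
        for j, (src, dst) in enumerate(paths):
            draws[b, j] = refit.path_coefficients[(src, dst)] * flip[src] * flip[dst]
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap resamples failed "
                           f"(> {max_failure_rate:.0%}); model too unstable")
    rows = []
    for j, (src, dst) in enumerate(paths):
        d = draws[~np.isnan(draws[:, j]), j]
        coef = full.path_coefficients[(src, dst)]
        se = float(d.std(ddof=1))
        t_ratio = coef / se if se > 0 else np.inf
        p_norm = float(2.0 * stats.norm.sf(abs(t_ratio)))
        lo, hi = np.percentile(d, [2.5, 97.5])
        p_perc = float(2.0 * min((d <= 0).mean(), (d >= 0).mean()))
        rows.append((src, dst, coef, se, t_ratio, p_norm, p_perc,
                     float(lo), float(hi), len(d)))
    return pd.DataFrame(rows, columns=["source", "target", "coefficient", "se",
                                       "t_ratio", "p_value", "p_percentile",
                                       "ci_low", "ci_high", "n_resamples"])
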