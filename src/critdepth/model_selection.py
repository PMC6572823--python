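"""OLS core and best-subset search under AICc (AIC for richness responses).

The selection problem: for each (depth column, residualized response) pair,
choose the subset of candidate soil/terrain predictors whose Gaussian linear
model minimises the small-sample-corrected Akaike criterion

    AICc = AIC + 2k(k+1)/(n - k - 1),     AIC = -2 loglik + 2k,

where k counts the intercept, the slopes and the error variance (k = p + 2).
Exhaustive enumeration is the default search (deterministic, globally
optimal); a seeded genetic algorithm covers candidate sets too large to
enumerate.  Subsets are evaluated from precomputed Gram matrices so the full
grid (6 columns x 10 responses) stays fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .soil_columns import DepthColumn

__all__ = [
    "ModelFit",
    "SelectionConfig",
    "SingularDesignError",
    "ols_fit",
    "aicc",
    "aic",
    "SubsetEvaluator",
    "exhaustive_best_subset",
    "genetic_best_subset",
    "best_subset",
    "run_model_grid",
]


class SingularDesignError(np.linalg.LinAlgError):
    pass


@dataclass
class ModelFit:
    response: str
    layer: str
    column: float | None
    selected: tuple[str, ...]
    coefficients: dict[str, float]
    rss: float
    loglik: float
    aic: float
    aicc: float
    r2: float
    adj_r2: float
    n: int
    p: int
    criterion: str = "aicc"

    @property
    def criterion_value(self) -> float:
        return self.aicc if self.criterion == "aicc" else self.aic


@dataclass
class SelectionConfig:
    criterion: str = "aicc"          # aicc | aic; richness responses override to aic
    method: str = "auto"             # exhaustive | genetic | auto (genetic when p > guard)
    max_predictors: int | None = None  # default n - 4 under AICc
    exhaustive_guard: int = 15   # auto-dispatch limit for full enumeration
    seed: int = 0
    population: int = 40
    generations: int = 60
    mutation_rate: float = 0.05
    tournament: int = 3
    elitism: int = 2


def _gaussian_loglik(rss: float, n: int) -> float:
    # ML variance estimate rss/n; rss == 0 gives +inf loglik, handled upstream
    if rss <= 0:
        return np.inf
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def aicc(loglik: float, n: int, k: int) -> float:
    """AICc; inadmissible models (n - k - 1 <= 0) get an infinite penalty."""
    if n - k - 1 <= 0:
        return np.inf
    return aic(loglik, k) + 2.0 * k * (k + 1) / (n - k - 1)


def ols_fit(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    names: Sequence[str] | None = None,
    response: str = "",
    layer: str = "",
    column: float | None = None,
) -> ModelFit:
    """Ordinary least squares with intercept; raises on rank deficiency.

    R^2 and adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) use the
    intercept-only model as baseline.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for p = {p} predictors")
    Z = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        # name the aliased columns for the error message
        _, r = np.linalg.qr(Z)
        bad = [names[j - 1] for j in range(1, Z.shape[1]) if abs(r[j, j]) < 1e-10]
        raise SingularDesignError(f"rank-deficient design; aliased: {bad}")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    ll = _gaussian_loglik(rss, n)
    k = p + 2
    coeffs = {"intercept": float(beta[0])}
    coeffs.update({nm: float(b) for nm, b in zip(names, beta[1:])})
    return ModelFit(
        response=response, layer=layer, column=column, selected=tuple(names),
        coefficients=coeffs, rss=rss, loglik=ll, aic=aic(ll, k),
        aicc=aicc(ll, n, k), r2=r2, adj_r2=float(adj), n=n, p=p,
    )


class SubsetEvaluator:
    """Fast RSS evaluation of predictor subsets via precomputed Gram matrices.

    For the design [1, X_S] the normal equations G_S b = c_S give
    rss = y'y - b'c_S; only a small symmetric solve per subset.
    """

    def __init__(self, X: pd.DataFrame, y: Sequence[float]):
        self.names = list(X.columns)
        Z = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        self.y = np.asarray(y, dtype=float)
        self.n = len(self.y)
        self.G = Z.T @ Z
        self.c = Z.T @ self.y
        self.yy = float(self.y @ self.y)
        self.tss = float(np.sum((self.y - self.y.mean()) ** 2))
        self.Z = Z

    def rss(self, subset: tuple[int, ...]) -> float:
        idx = (0, *[j + 1 for j in subset])
        G = self.G[np.ix_(idx, idx)]
        try:
            b = np.linalg.solve(G, self.c[list(idx)])
        except np.linalg.LinAlgError:
            b, *_ = np.linalg.lstsq(self.Z[:, list(idx)], self.y, rcond=None)
            r = self.y - self.Z[:, list(idx)] @ b
            return float(r @ r)
        return max(float(self.yy - b @ self.c[list(idx)]), 0.0)

    def criterion(self, subset: tuple[int, ...], which: str = "aicc") -> float:
        rss = self.rss(subset)
        ll = _gaussian_loglik(rss, self.n)
        k = len(subset) + 2
        return aicc(ll, self.n, k) if which == "aicc" else aic(ll, k)

    def fit(self, subset: tuple[int, ...], **meta) -> ModelFit:
        names = [self.names[j] for j in subset]
        X = pd.DataFrame(self.Z[:, [j + 1 for j in subset]], columns=names)
        return ols_fit(X, self.y, **meta)


def _search_space(p: int, max_predictors: int | None, n: int, criterion: str) -> int:
    # default cap n - 4 keeps the AICc correction finite with room to spare
    if max_predictors is None:
        max_predictors = n - 4
    return max(0, min(max_predictors, p, n - 2))


def exhaustive_best_subset(
    X: pd.DataFrame,
    y: Sequence[float],
    config: SelectionConfig | None = None,
    **meta,
) -> ModelFit:
    """Enumerate all admissible subsets; return the criterion-minimal fit.

    Ties break toward fewer predictors, then lexicographic subset order (both
    implied by the enumeration order, smallest subsets first).  If no subset is
    admissible the intercept-only fit is returned.
    """
    config = config or SelectionConfig()
    ev = SubsetEvaluator(X, y)
    p = len(ev.names)
    kmax = _search_space(p, config.max_predictors, ev.n, config.criterion)
    best: tuple[float, tuple[int, ...]] = (ev.criterion((), config.criterion), ())
    for size in range(1, kmax + 1):
        for subset in combinations(range(p), size):
            crit = ev.criterion(subset, config.criterion)
            if crit < best[0] - 1e-12:
                best = (crit, subset)
    fit = ev.fit(best[1], **meta)
    fit.criterion = config.criterion
    return fit


def genetic_best_subset(
    X: pd.DataFrame,
    y: Sequence[float],
    config: SelectionConfig | None = None,
    **meta,
) -> ModelFit:
    """Bitstring genetic algorithm over subset indicators.

    Tournament selection, uniform crossover, per-bit mutation and elitism;
    deterministic under ``config.seed``.  Inadmissible bitstrings (too many
    predictors for the criterion) are truncated at random.
    """
    config = config or SelectionConfig()
    rng = np.random.default_rng(config.seed)
    ev = SubsetEvaluator(X, y)
    p = len(ev.names)
    kmax = _search_space(p, config.max_predictors, ev.n, config.criterion)

    def repair(bits: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(bits)
        if len(on) > kmax:
            off = rng.choice(on, size=len(on) - kmax, replace=False)
            bits = bits.copy()
            bits[off] = False
        return bits

    cache: dict[tuple[int, ...], float] = {}

    def score(bits: np.ndarray) -> float:
        subset = tuple(np.flatnonzero(bits))
        if subset not in cache:
            cache[subset] = ev.criterion(subset, config.criterion)
        return cache[subset]

    pop = [repair(rng.random(p) < 0.2) for _ in range(max(config.population, 1))]
    fitness = np.array([score(b) for b in pop])
    for _ in range(config.generations):
        order = np.argsort(fitness, kind="stable")
        elite = [pop[i].copy() for i in order[: config.elitism]]
        children = list(elite)
        while len(children) < len(pop):
            idx = rng.integers(0, len(pop), size=(2, config.tournament))
            pa = pop[idx[0][np.argmin(fitness[idx[0]])]]
            pb = pop[idx[1][np.argmin(fitness[idx[1]])]]
            mask = rng.random(p) < 0.5
            child = np.where(mask, pa, pb)
            child ^= rng.random(p) < config.mutation_rate
            children.append(repair(child))
        pop = children
        fitness = np.array([score(b) for b in pop])
    best = pop[int(np.argmin(fitness))]
    fit = ev.fit(tuple(np.flatnonzero(best)), **meta)
    fit.criterion = config.criterion
    return fit


def best_subset(
    X: pd.DataFrame, y: Sequence[float], config: SelectionConfig | None = None, **meta
) -> ModelFit:
    """Dispatch to exhaustive search, or the GA when p exceeds the guard."""
    config = config or SelectionConfig()
    method = config.method
    if method == "auto":
        method = "exhaustive" if len(X.columns) <= config.exhaustive_guard else "genetic"
    if method == "exhaustive":
        return exhaustive_best_subset(X, y, config, **meta)
    return genetic_best_subset(X, y, config, **meta)


def run_model_grid(
    column_table: pd.DataFrame,
    terrain: pd.DataFrame,
    residuals: pd.DataFrame,
    kept_predictors: Sequence[str],
    config: SelectionConfig | None = None,
    columns: Sequence[DepthColumn] | None = None,
) -> list[ModelFit]:
    """One best-subset fit per (depth column, response, layer).

    ``column_table`` is the long aggregated soil table; ``terrain`` is wide
    (plot_id index or column plus one column per attribute); ``residuals`` is
    the long age-residualized response table.  The criterion is AICc except
    for species-richness responses, which use AIC (AICc collapses them to
    intercept-only models at this sample size).
    """
    config = config or SelectionConfig()
    soil_wide = column_table.pivot_table(
        index="plot_id", columns="property", values="value", sort=False
    )
    terr = terrain.set_index("plot_id") if "plot_id" in terrain.columns else terrain

    lowers = sorted(column_table["column_lower_cm"].unique())
    if columns is not None:
        lowers = [c.lower for c in columns]

    fits: list[ModelFit] = []
    for lower in lowers:
        sub = column_table[column_table["column_lower_cm"] == lower]
        soil = sub.pivot_table(index="plot_id", columns="property", values="value", sort=False)
        design = soil.join(terr, how="inner")
        Xfull = design[[c for c in kept_predictors if c in design.columns]]
        for (layer, response), g in residuals.groupby(["layer", "response"], sort=True):
            y = g.set_index("plot_id")["residual"].reindex(Xfull.index)
            crit = "aic" if response == "richness" else config.criterion
            cfg = SelectionConfig(**{**config.__dict__, "criterion": crit})
            fit = best_subset(
                Xfull, y.to_numpy(), cfg,
                response=response, layer=layer, column=float(lower),
            )
            fits.append(fit)
    return fits


def grid_to_frame(fits: list[ModelFit]) -> pd.DataFrame:
    """Flatten a model grid for CSV export."""
    rows = [
        (
            f.layer, f.response, f.column, f.criterion, f.criterion_value,
            f.r2, f.adj_r2, ";".join(f.selected),
        )
        for f in fits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "layer", "response", "column_lower_cm", "criterion",
            "criterion_value", "r2", "adj_r2", "selected_predictors",
        ],
    )
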