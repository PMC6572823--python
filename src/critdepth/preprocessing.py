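"""Predictor screening and response conditioning ahead of model selection.

Three steps: (1) Spearman rank correlation matrices among soil properties,
computed per depth column; (2) greedy multicollinearity pruning that removes
one member of every predictor pair with |r| above a threshold (default 0.7,
strict); (3) residualization of every response on log(tree age), so that the
soil/terrain models downstream explain variation not attributable to stand age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictorSet",
    "ResidualizedResponse",
    "spearman_matrix",
    "collinearity_filter",
    "age_residualize",
    "residualize_table",
]


@dataclass
class PredictorSet:
    kept: list[str]
    dropped: list[tuple[str, str, str, float]] = field(default_factory=list)
    """(variable, reason, partner, r) for each eliminated predictor."""


@dataclass
class ResidualizedResponse:
    response: str
    layer: str
    residuals: pd.Series
    age_adj_r2: float
    coefficients: tuple[float, float]


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation matrix of a plot x variable table.

    Mid-ranks for ties.  A constant variable yields NaN against its partners
    (scipy emits a warning); the diagonal is forced to 1.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 plots for a rank correlation")
    r = stats.spearmanr(table.to_numpy(), axis=0).statistic
    if np.ndim(r) == 0:  # scipy collapses the two-variable case to a scalar
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=table.columns, columns=table.columns)


def collinearity_filter(
    matrix: pd.DataFrame,
    threshold: float = 0.7,
    keep: list[str] | None = None,
    drop: list[str] | None = None,
) -> PredictorSet:
    """Greedy elimination of collinear predictors.

    While any pair has |r| strictly above the threshold, drop the member with
    the larger mean |r| against the remaining variables (alphabetically later
    name on ties), skipping names on the ``keep`` list.  An explicit ``drop``
    list bypasses the greedy rule entirely (verbatim reproduction of a
    published exclusion set).
    """
    keep = list(keep or [])
    names = list(matrix.columns)
    dropped: list[tuple[str, str, str, float]] = []

    if drop is not None:
        for v in drop:
            if v in names:
                names.remove(v)
                dropped.append((v, "explicit drop-list", "", np.nan))
        return PredictorSet(kept=names, dropped=dropped)

    kept_conflicts = [
        (a, b, matrix.loc[a, b])
        for i, a in enumerate(keep)
        for b in keep[i + 1:]
        if abs(matrix.loc[a, b]) > threshold
    ]
    if kept_conflicts:
        raise ValueError(f"keep-list itself violates the threshold: {kept_conflicts}")

    while True:
        sub = matrix.loc[names, names].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        with np.errstate(invalid="ignore"):
            over = np.argwhere(np.triu(sub, 1) > threshold)
        over = [
            (names[i], names[j]) for i, j in over
            if not (names[i] in keep and names[j] in keep)
        ]
        if not over:
            break
        mean_abs = {n: np.nanmean(sub[k]) for k, n in enumerate(names)}
        # candidates: members of an offending pair that are droppable
        cands = {v for pair in over for v in pair if v not in keep}
        victim = max(cands, key=lambda v: (mean_abs[v], v))
        partner, r = max(
            ((b if a == victim else a, matrix.loc[a, b]) for a, b in over if victim in (a, b)),
            key=lambda t: abs(t[1]),
        )
        names.remove(victim)
        dropped.append((victim, f"|r|>{threshold}", partner, float(r)))
    return PredictorSet(kept=names, dropped=dropped)


def age_residualize(
    y: pd.Series, age: pd.Series, response: str = "", layer: str = ""
) -> ResidualizedResponse:
    """OLS of a response on (1, log age); returns residuals and adjusted R^2.

    Residuals have mean 0 and are orthogonal to log(age); subsequent models
    therefore explain only the age-independent component of the response.
    """
    if (age <= 0).any():
        raise ValueError("tree age must be positive")
    if len(y) < 3:
        raise ValueError("need at least 3 plots")
    la = np.log(age.to_numpy(dtype=float))
    if np.ptp(la) == 0:
        raise ValueError("constant tree age: degenerate design")
    X = np.column_stack([np.ones_like(la), la])
    yv = y.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    n = len(yv)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return ResidualizedResponse(
        response=response,
        layer=layer,
        residuals=pd.Series(resid, index=y.index),
        age_adj_r2=float(adj),
        coefficients=(float(beta[0]), float(beta[1])),
    )


def residualize_table(
    responses: pd.DataFrame, response_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residualize every (response, layer) series on log(tree age).

    ``responses`` follows the response-table schema (plot_id, layer, one column
    per response, tree_age).  Returns a long residual table (plot_id, layer,
    response, residual) and an age-model summary (layer, response, adj_r2).
    """
    from .community_metrics import RESPONSE_NAMES

    response_names = list(response_names or RESPONSE_NAMES)
    resid_rows, model_rows = [], []
    for layer, g in responses.groupby("layer"):
        for name in response_names:
            if name not in g or g[name].isna().all():
                continue
            rr = age_residualize(g[name], g["tree_age"], response=name, layer=layer)
            model_rows.append((layer, name, rr.age_adj_r2))
            for plot, e in zip(g["plot_id"], rr.residuals):
                resid_rows.append((plot, layer, name, e))
    residuals = pd.DataFrame(resid_rows, columns=["plot_id", "layer", "response", "residual"])
    models = pd.DataFrame(model_rows, columns=["layer", "response", "adj_r2"])
    return residuals, models
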