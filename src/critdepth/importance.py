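"""Grouped variable-importance partitioning and depth trends.

Each fitted model's regression sum of squares is decomposed by sequential
(Type I) ANOVA — terms entered in a fixed order, each credited the drop in
residual sum of squares it produces — and the per-predictor SS are pooled
into the three predictor groups (stable soil, dynamic soil, terrain) as
percentages of the summed predictor SS.  Kendall's tau-b against column depth
then tests whether a group gains or loses importance as the soil column
deepens; predictor occurrence counts across the model grid give the
prominence ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_selection import ModelFit

__all__ = [
    "TrendResult",
    "sequential_ss",
    "group_importance",
    "kendall_trend",
    "occurrence_ranking",
    "importance_table",
    "group_trends",
]

GROUPS = ("stable", "dynamic", "terrain")


@dataclass
class TrendResult:
    layer: str
    response: str   # or "pooled"
    group: str
    tau: float
    p_value: float


def sequential_ss(
    X: pd.DataFrame,
    y: Sequence[float],
    order: Sequence[str],
) -> dict[str, float]:
    """Type I sums of squares for predictors entered in the given order.

    Each term's SS is the residual-SS drop when it joins the model after all
    earlier terms (intercept always first).  The identity
    sum(term SS) + residual SS = total SS holds by construction.
    """
    missing = [v for v in order if v not in X.columns]
    if missing:
        raise KeyError(f"predictors not in design: {missing}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    Z = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    out: dict[str, float] = {}
    for name in order:
        Z = np.column_stack([Z, X[name].to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        rss = float(resid @ resid)
        out[name] = rss_prev - rss
        rss_prev = rss
    return out


def default_order(selected: Sequence[str], classes: Mapping[str, str]) -> list[str]:
    """Deterministic entry order: stable, dynamic, terrain; alphabetical within."""
    rank = {g: i for i, g in enumerate(GROUPS)}
    return sorted(selected, key=lambda v: (rank.get(classes[v], len(GROUPS)), v))


def averaged_ss(
    X: pd.DataFrame, y: Sequence[float], selected: Sequence[str], max_exact: int = 8
) -> dict[str, float]:
    """Order-averaged sequential SS over all permutations of the selected terms.

    Exact for up to ``max_exact`` predictors (the decomposition identity holds
    for every permutation, hence for the average).
    """
    selected = list(selected)
    if len(selected) > max_exact:
        raise ValueError(f"too many predictors ({len(selected)}) for exact averaging")
    acc = {v: 0.0 for v in selected}
    count = 0
    for perm in permutations(selected):
        ss = sequential_ss(X, y, perm)
        for v, s in ss.items():
            acc[v] += s
        count += 1
    return {v: s / count for v, s in acc.items()}


def group_importance(
    ss: Mapping[str, float], classes: Mapping[str, str]
) -> dict[str, float]:
    """Percentage of summed predictor SS credited to each group.

    Intercept-only models (zero predictor SS) yield NaN for every group rather
    than zero — importance is undefined, not absent.
    """
    total = sum(ss.values())
    if not ss or total <= 0:
        return {g: float("nan") for g in GROUPS}
    out = {g: 0.0 for g in GROUPS}
    for var, s in ss.items():
        out[classes[var]] += s
    return {g: 100.0 * s / total for g, s in out.items()}


def kendall_trend(
    depths: Sequence[float], values: Sequence[float],
    layer: str = "", response: str = "", group: str = "",
) -> TrendResult:
    """Kendall's tau-b between column depth and an importance series."""
    depths = np.asarray(depths, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.ptp(values[ok]) == 0:
        return TrendResult(layer, response, group, float("nan"), float("nan"))
    res = stats.kendalltau(depths[ok], values[ok])
    return TrendResult(layer, response, group, float(res.statistic), float(res.pvalue))


def occurrence_ranking(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Predictor occurrence counts across all / tree-layer / herb-layer models.

    Dense ranks (ties share a rank, no gaps), descending by count.
    """
    preds = sorted({v for f in fits for v in f.selected})
    rows = []
    for v in preds:
        total = sum(v in f.selected for f in fits)
        tree = sum(v in f.selected for f in fits if f.layer == "tree")
        herb = sum(v in f.selected for f in fits if f.layer == "herb")
        rows.append((v, total, tree, herb))
    tab = pd.DataFrame(rows, columns=["predictor", "total", "tree", "herb"])
    for col in ("total", "tree", "herb"):
        tab[f"{col}_rank"] = tab[col].rank(method="dense", ascending=False).astype(int)
    return tab.sort_values(["total", "predictor"], ascending=[False, True]).reset_index(drop=True)


def importance_table(
    fits: Sequence[ModelFit],
    column_table: pd.DataFrame,
    terrain: pd.DataFrame,
    residuals: pd.DataFrame,
    classes: Mapping[str, str],
    order_mode: str = "sequential",
) -> pd.DataFrame:
    """Group-importance percentages for every model in a grid.

    Re-derives each model's design from the aggregated soil table and terrain
    attributes, decomposes its SS in the canonical order (or order-averaged
    when ``order_mode == "averaged"``), and returns a long table
    (layer, response, column_lower_cm, group, percent).
    """
    terr = terrain.set_index("plot_id") if "plot_id" in terrain.columns else terrain
    rows = []
    for fit in fits:
        sub = column_table[column_table["column_lower_cm"] == fit.column]
        soil = sub.pivot_table(index="plot_id", columns="property", values="value", sort=False)
        design = soil.join(terr, how="inner")
        g = residuals[(residuals["layer"] == fit.layer) & (residuals["response"] == fit.response)]
        y = g.set_index("plot_id")["residual"].reindex(design.index).to_numpy()
        if fit.selected:
            if order_mode == "averaged" and len(fit.selected) <= 8:
                ss = averaged_ss(design, y, fit.selected)
            else:
                ss = sequential_ss(design, y, default_order(fit.selected, classes))
        else:
            ss = {}
        for group, pct in group_importance(ss, classes).items():
            rows.append((fit.layer, fit.response, fit.column, group, pct))
    return pd.DataFrame(
        rows, columns=["layer", "response", "column_lower_cm", "group", "percent"]
    )


def group_trends(importance: pd.DataFrame) -> pd.DataFrame:
    """Kendall depth trends of group importance, per response and pooled.

    Pooled series average the group percentage over a layer's responses at each
    depth.  Returns (layer, response, group, tau, p).
    """
    rows = []
    for (layer, response, group), g in importance.groupby(["layer", "response", "group"]):
        g = g.sort_values("column_lower_cm")
        try:
            tr = kendall_trend(g["column_lower_cm"], g["percent"], layer, response, group)
        except ValueError:
            continue
        rows.append((layer, response, group, tr.tau, tr.p_value))
    pooled = (
        importance.groupby(["layer", "group", "column_lower_cm"])["percent"]
        .mean()
        .reset_index()
    )
    for (layer, group), g in pooled.groupby(["layer", "group"]):
        g = g.sort_values("column_lower_cm")
        try:
            tr = kendall_trend(g["column_lower_cm"], g["percent"], layer, "pooled", group)
        except ValueError:
            continue
        rows.append((layer, "pooled", group, tr.tau, tr.p_value))
    return pd.DataFrame(rows, columns=["layer", "response", "group", "tau", "p"])
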