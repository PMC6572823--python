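"""Smoother fits to explained-variance-vs-depth points and the critical depth.

Each fitted model contributes one point: x = the depth column's lower boundary
(cm), y = the model's explained variance (adjusted R^2 by default).  A local
polynomial smoother — degree-2 local regression with tricube weights, window
spanning a fraction ``span`` of the points (span = 1 uses all of them) — is
fitted per vegetation layer and pooled across layers; a global cubic
polynomial is the alternative smoother.  The *critical soil depth* is the
argmax of the fitted curve over a fine grid of depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_selection import ModelFit

__all__ = [
    "DepthCurve",
    "loess_fit",
    "cubic_fit",
    "find_critical_depth",
    "assemble_curves",
    "curves_to_frame",
]


@dataclass
class DepthCurve:
    curve_id: str
    smoother: str
    x: np.ndarray
    y: np.ndarray
    predict: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    critical_depth: float = float("nan")
    value_at_max: float = float("nan")
    boundary_flag: bool = False


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    degree: int = 2,
    span: float = 1.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Locally weighted polynomial regression (LOWESS), tricube weights.

    At each evaluation point x0 the ``span``-fraction nearest data points form
    the window; with bandwidth h = the largest distance in the window, weights
    are ``(1 - (|x - x0|/h)^3)^3`` and a weighted degree-``degree`` polynomial
    is fitted and evaluated at x0.  ``span = 1`` puts every point in every
    window.  No robustness iterations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(np.unique(x)) < degree + 2:
        raise ValueError(f"need at least {degree + 2} distinct x values")
    q = max(int(np.ceil(span * len(x))), degree + 1)

    def predict(x0: np.ndarray) -> np.ndarray:
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        out = np.empty_like(x0)
        for i, xi in enumerate(x0):
            d = np.abs(x - xi)
            idx = np.argsort(d, kind="stable")[:q]
            h = d[idx].max()
            w = _tricube(d[idx] / h) if h > 0 else np.ones(len(idx))
            if w.sum() <= 0:
                w = np.ones(len(idx))  # degenerate window: unweighted fallback
            B = np.vander(x[idx] - xi, degree + 1, increasing=True)
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(B * sw[:, None], y[idx] * sw, rcond=None)
            out[i] = beta[0]
        return out

    return predict


def cubic_fit(x: Sequence[float], y: Sequence[float]) -> Callable[[np.ndarray], np.ndarray]:
    """Global least-squares cubic polynomial."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct x values for a cubic fit")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 3)

    def predict(x0: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.atleast_1d(np.asarray(x0, float)), coeffs)

    predict.coefficients = coeffs  # type: ignore[attr-defined]
    return predict


def find_critical_depth(
    predict: Callable[[np.ndarray], np.ndarray],
    x_min: float,
    x_max: float,
    grid_step: float = 0.1,
) -> tuple[float, float, bool]:
    """Argmax of the fitted curve on a uniform grid over [x_min, x_max].

    Ties resolve to the smallest depth; the boundary flag marks an argmax at
    either endpoint (the maximum may lie outside the sampled range).
    Returns (critical_depth, value_at_max, boundary_flag).
    """
    grid = np.arange(x_min, x_max + grid_step / 2, grid_step)
    vals = predict(grid)
    i = int(np.argmax(vals))  # first occurrence = smallest depth on ties
    return float(grid[i]), float(vals[i]), i in (0, len(grid) - 1)


def _make_curve(curve_id: str, smoother: str, x, y, grid_step: float) -> DepthCurve | None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 4:
        return None
    predict = loess_fit(x, y) if smoother == "lowess" else cubic_fit(x, y)
    d, v, flag = find_critical_depth(predict, x.min(), x.max(), grid_step)
    return DepthCurve(curve_id, smoother, x, y, predict, d, v, flag)


def assemble_curves(
    fits: Sequence[ModelFit],
    r2_kind: str = "adjusted",
    smoothers: Sequence[str] = ("lowess", "cubic"),
    grid_step: float = 0.1,
) -> list[DepthCurve]:
    """Layer, pooled and per-response depth curves from a model grid.

    Produces, for each smoother: a tree-layer curve, a herb-layer curve, a
    pooled curve over both layers' points, and one curve per (layer, response)
    pair.  Curves with fewer than four distinct depths are skipped.
    """
    val = (lambda f: f.adj_r2) if r2_kind == "adjusted" else (lambda f: f.r2)
    pts = pd.DataFrame(
        [(f.layer, f.response, f.column, val(f)) for f in fits],
        columns=["layer", "response", "depth", "r2"],
    )
    curves: list[DepthCurve] = []
    for smoother in smoothers:
        for layer in ("tree", "herb"):
            g = pts[pts["layer"] == layer]
            c = _make_curve(layer, smoother, g["depth"], g["r2"], grid_step)
            if c:
                curves.append(c)
        c = _make_curve("pooled", smoother, pts["depth"], pts["r2"], grid_step)
        if c:
            curves.append(c)
        for (layer, response), g in pts.groupby(["layer", "response"]):
            c = _make_curve(f"{layer}:{response}", smoother, g["depth"], g["r2"], grid_step)
            if c:
                curves.append(c)
    return curves


def curves_to_frame(curves: Sequence[DepthCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.curve_id, c.smoother, c.critical_depth, c.boundary_flag, c.value_at_max)
            for c in curves
        ],
        columns=["curve_id", "smoother", "critical_depth_cm", "boundary_flag", "r2_at_max"],
    )
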