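"""Depth-profile data model and aggregation of soil properties into cumulative columns.

Soil is sampled in contiguous half-open depth increments ``[top, bottom)`` (cm).
Analyses operate on cumulative *columns* ``[0, d)`` obtained as thickness-weighted
means of the increment values — e.g. for a 0–20 cm column built from 0–5, 5–10
and 10–20 cm increments the weights are 1/4, 1/4 and 1/2.  Soil organic carbon
(SOC) stocks are the exception: they are per-area quantities and are *summed*
over the increments inside a column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthIncrement",
    "DepthColumn",
    "STUDY_INCREMENTS",
    "STUDY_COLUMNS",
    "AlignmentError",
    "MissingDataError",
    "column_weights",
    "aggregate_column",
    "soc_stock_increments",
    "soc_stock_column",
    "build_column_table",
    "validate_increment_table",
    "read_increment_table",
    "write_column_table",
]


class AlignmentError(ValueError):
    """Column boundary does not coincide with an increment boundary."""


class MissingDataError(ValueError):
    """A weighted increment has no value (complete-case policy)."""


@dataclass(frozen=True, order=True)
class DepthIncrement:
    """One sampled soil layer, the half-open interval [top, bottom) in cm."""

    top: float
    bottom: float

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom):
            raise ValueError(f"invalid increment [{self.top}, {self.bottom})")

    @property
    def thickness(self) -> float:
        return self.bottom - self.top

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top + self.bottom)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.top:g}-{self.bottom:g}cm"


@dataclass(frozen=True, order=True)
class DepthColumn:
    """A cumulative soil column spanning [0, lower) cm."""

    lower: float

    def __post_init__(self) -> None:
        if self.lower <= 0:
            raise ValueError("column lower boundary must be positive")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"0-{self.lower:g}cm"


#: The six study increments: 0–5, 5–10, 10–20, 20–30, 30–40, 40–50 cm.
STUDY_INCREMENTS: tuple[DepthIncrement, ...] = tuple(
    DepthIncrement(t, b) for t, b in ((0, 5), (5, 10), (10, 20), (20, 30), (30, 40), (40, 50))
)

#: The matching cumulative columns 0–5 … 0–50 cm.
STUDY_COLUMNS: tuple[DepthColumn, ...] = tuple(DepthColumn(b) for b in (5, 10, 20, 30, 40, 50))


def check_contiguous(increments: Sequence[DepthIncrement]) -> None:
    """Require increments sorted, starting at 0 and gap-free."""
    incs = sorted(increments)
    if not incs:
        raise ValueError("no increments given")
    if incs[0].top != 0:
        raise ValueError("increments must start at depth 0")
    for a, b in zip(incs, incs[1:]):
        if a.bottom != b.top:
            raise ValueError(f"increments not contiguous at {a.bottom} vs {b.top}")


def column_weights(
    increments: Sequence[DepthIncrement], column: DepthColumn
) -> np.ndarray:
    """Thickness fractions each increment contributes to the cumulative column.

    weight_j = thickness_j / column.lower for increments inside [0, column.lower),
    zero for increments below it.  Weights are non-negative and sum to 1.
    """
    check_contiguous(increments)
    bottoms = [inc.bottom for inc in increments]
    if column.lower not in bottoms:
        raise AlignmentError(
            f"column lower boundary {column.lower} cm does not align with "
            f"increment boundaries {bottoms}"
        )
    w = np.array(
        [inc.thickness / column.lower if inc.bottom <= column.lower else 0.0 for inc in increments]
    )
    return w


def aggregate_column(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean of per-increment values; NaN in a weighted slot is an error."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    active = w > 0
    if np.any(np.isnan(v[active])):
        raise MissingDataError("missing value in a weighted increment")
    return float(np.dot(v[active], w[active]))


def soc_stock_increments(
    increments: Sequence[DepthIncrement],
    ct: Sequence[float],
    bd: Sequence[float],
    cm: Sequence[float],
    formula: str = "as_printed",
) -> np.ndarray:
    """Per-increment SOC stock terms.

    ``as_printed`` evaluates, per increment of thickness ``D`` expressed in
    meters, ``D * (Ct/10) * (BD/1000) * (1 - CM/100) / 100`` with Ct the organic
    carbon concentration in mass-%, BD the bulk density in g cm^-3 and CM the
    coarse-material volume fraction in %.  ``conventional`` uses the textbook
    t ha^-1 stock ``D_cm * BD * Ct * (1 - CM/100)`` with thickness in cm.
    """
    ct = np.asarray(ct, dtype=float)
    bd = np.asarray(bd, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if np.any(ct < 0):
        raise ValueError("negative carbon concentration")
    if np.any(bd <= 0):
        raise ValueError("bulk density must be positive")
    if np.any((cm < 0) | (cm > 100)):
        raise ValueError("coarse material fraction outside [0, 100] %")
    thick_cm = np.array([inc.thickness for inc in increments], dtype=float)
    if formula == "as_printed":
        depth_m = thick_cm / 100.0
        return depth_m * (ct / 10.0) * (bd / 1000.0) * (1.0 - cm / 100.0) / 100.0
    if formula == "conventional":
        return thick_cm * bd * ct * (1.0 - cm / 100.0)
    raise ValueError(f"unknown soc formula {formula!r}")


def soc_stock_column(
    increments: Sequence[DepthIncrement],
    ct: Sequence[float],
    bd: Sequence[float],
    cm: Sequence[float],
    column: DepthColumn,
    formula: str = "as_printed",
) -> float:
    """Cumulative SOC stock of the column: sum of increment terms within [0, lower)."""
    check_contiguous(increments)
    if column.lower not in [inc.bottom for inc in increments]:
        raise AlignmentError(f"column {column} not aligned with increments")
    terms = soc_stock_increments(increments, ct, bd, cm, formula=formula)
    inside = np.array([inc.bottom <= column.lower for inc in increments])
    return float(terms[inside].sum())


_INCREMENT_COLUMNS = ["plot_id", "property", "cls", "top_cm", "bottom_cm", "value"]

SOC_STOCK_PROPERTY = "SOCstocks"


def validate_increment_table(table: pd.DataFrame) -> list[DepthIncrement]:
    """Schema and invariant checks on a long increment table.

    Returns the shared increment set.  Raises on duplicated cells, plots with
    increment sets that differ from the rest, or non-contiguous increments.
    """
    missing = [c for c in _INCREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"increment table lacks columns {missing}")
    dup = table.duplicated(["plot_id", "property", "top_cm", "bottom_cm"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicated (plot, property, increment) cells")
    inc_sets = table.groupby("plot_id").apply(
        lambda g: frozenset(zip(g.top_cm, g.bottom_cm)), include_groups=False
    )
    if inc_sets.nunique() != 1:
        raise ValueError("plots do not share an identical increment set")
    increments = sorted(DepthIncrement(t, b) for t, b in inc_sets.iloc[0])
    check_contiguous(increments)
    bd = table.loc[table["property"] == "BD", "value"]
    if (bd <= 0).any():
        raise ValueError("bulk density must be positive")
    cm = table.loc[table["property"] == "CM", "value"]
    if ((cm < 0) | (cm > 100)).any():
        raise ValueError("coarse material outside [0, 100] %")
    return increments


def build_column_table(
    table: pd.DataFrame,
    columns: Iterable[DepthColumn] = STUDY_COLUMNS,
    soc_formula: str = "as_printed",
) -> pd.DataFrame:
    """Aggregate an increment table to cumulative depth columns.

    Every property is a thickness-weighted mean except SOC stocks
    (``property == "SOCstocks"``), which is recomputed from the per-increment
    Ct, BD and CM records and cumulated.  Output is long with columns
    plot_id, property, cls, column_lower_cm, value.
    """
    increments = validate_increment_table(table)
    columns = list(columns)
    weights = {col.lower: column_weights(increments, col) for col in columns}
    order = {(inc.top, inc.bottom): j for j, inc in enumerate(increments)}

    wide = table.pivot_table(
        index=["plot_id", "property", "cls"],
        columns=["top_cm", "bottom_cm"],
        values="value",
        sort=False,
    )
    wide = wide[sorted(wide.columns, key=lambda tb: order[tb])]
    cls_of = dict(zip(table["property"], table["cls"]))

    records: list[tuple] = []
    for (plot, prop, cls), row in wide.iterrows():
        vals = row.to_numpy()
        for col in columns:
            w = weights[col.lower]
            try:
                records.append(
                    (plot, prop, cls, col.lower, aggregate_column(vals, w))
                )
            except MissingDataError as err:
                raise MissingDataError(
                    f"plot {plot}, property {prop}, column {col}: {err}"
                ) from err

    out = pd.DataFrame(
        records, columns=["plot_id", "property", "cls", "column_lower_cm", "value"]
    )

    # SOC stocks are cumulative sums, not means: rebuild them where the raw
    # ingredients (Ct, BD, CM) are present.
    have = set(table["property"])
    if {SOC_STOCK_PROPERTY, "Ct", "BD", "CM"} <= have:
        for plot, g in table.groupby("plot_id"):
            g = g.set_index(["property", "top_cm", "bottom_cm"])["value"]
            ct = [g[("Ct", inc.top, inc.bottom)] for inc in increments]
            bd = [g[("BD", inc.top, inc.bottom)] for inc in increments]
            cm = [g[("CM", inc.top, inc.bottom)] for inc in increments]
            for col in columns:
                stock = soc_stock_column(increments, ct, bd, cm, col, formula=soc_formula)
                sel = (
                    (out["plot_id"] == plot)
                    & (out["property"] == SOC_STOCK_PROPERTY)
                    & (out["column_lower_cm"] == col.lower)
                )
                out.loc[sel, "value"] = stock
    return out


def read_increment_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_increment_table(table)
    return table


def write_column_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
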