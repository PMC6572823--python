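"""Orchestration: aggregate -> metrics -> residualize -> filter -> model grid
-> importance -> critical depth, with file I/O glue and a run report.

Stages are re-entrant: each consumes plain tables that can equally be loaded
from the CSV artifacts of a previous stage.  ``run_synthetic_pipeline`` wires
the synthetic generator straight into the analysis for simulation studies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .critical_depth import DepthCurve, assemble_curves, curves_to_frame
from .importance import group_trends, importance_table, occurrence_ranking
from .model_selection import ModelFit, SelectionConfig, grid_to_frame, run_model_grid
from .preprocessing import collinearity_filter, residualize_table, spearman_matrix
from .soil_columns import (
    STUDY_COLUMNS,
    DepthColumn,
    build_column_table,
    validate_increment_table,
)
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("critdepth")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "run_synthetic_pipeline",
    "validate_inputs",
]


@dataclass
class PipelineConfig:
    soil_increments: str | Path = "soil_increments.csv"
    terrain: str | Path = "terrain.csv"
    responses: str | Path = "responses.csv"
    columns: Sequence[DepthColumn] = STUDY_COLUMNS
    collinearity_threshold: float = 0.7
    reference_column: float = 50.0   # column on which the filter is decided
    drop_list: list[str] | None = None
    soc_formula: str = "as_printed"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    r2_kind: str = "adjusted"
    importance_order: str = "sequential"
    out_dir: str | Path | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    column_table: pd.DataFrame
    residuals: pd.DataFrame
    age_models: pd.DataFrame
    kept_predictors: list[str]
    dropped_predictors: list[tuple]
    fits: list[ModelFit]
    importance: pd.DataFrame
    trends: pd.DataFrame
    occurrence: pd.DataFrame
    curves: list[DepthCurve]
    report: dict

    @property
    def critical_depths(self) -> dict[tuple[str, str], float]:
        """(curve_id, smoother) -> critical depth in cm."""
        return {(c.curve_id, c.smoother): c.critical_depth for c in self.curves}


def _predictor_classes(
    column_table: pd.DataFrame, terrain: pd.DataFrame
) -> dict[str, str]:
    classes = dict(
        column_table[["property", "cls"]].drop_duplicates().itertuples(index=False)
    )
    for attr in terrain.columns:
        if attr != "plot_id":
            classes[attr] = "terrain"
    return classes


def _analyse(
    soil: pd.DataFrame,
    terrain: pd.DataFrame,
    responses: pd.DataFrame,
    config: PipelineConfig,
) -> PipelineResult:
    column_table = build_column_table(soil, config.columns, soc_formula=config.soc_formula)
    logger.info("aggregated %d increment records to %d column records",
                len(soil), len(column_table))

    residuals, age_models = residualize_table(responses)
    logger.info("residualized %d (response, layer) series on log(tree age)",
                len(age_models))

    # collinearity screening on the reference column
    ref = column_table[column_table["column_lower_cm"] == config.reference_column]
    soil_wide = ref.pivot_table(index="plot_id", columns="property", values="value", sort=False)
    terr = terrain.set_index("plot_id")
    design = soil_wide.join(terr, how="inner")
    corr = spearman_matrix(design)
    pset = collinearity_filter(
        corr, threshold=config.collinearity_threshold, drop=config.drop_list
    )
    for var, reason, partner, r in pset.dropped:
        logger.warning("dropped predictor %s (%s, partner=%s, r=%.3f)",
                       var, reason, partner, r if np.isfinite(r) else np.nan)

    fits = run_model_grid(
        column_table, terrain, residuals, pset.kept, config.selection,
        columns=config.columns,
    )
    logger.info("fitted %d models", len(fits))

    classes = _predictor_classes(column_table, terrain)
    imp = importance_table(
        fits, column_table, terrain, residuals, classes,
        order_mode=config.importance_order,
    )
    trends = group_trends(imp)
    occ = occurrence_ranking(fits)
    curves = assemble_curves(fits, r2_kind=config.r2_kind)

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_plots": int(soil["plot_id"].nunique()),
        "n_models": len(fits),
        "kept_predictors": pset.kept,
        "dropped_predictors": [list(d) for d in pset.dropped],
        "age_models": age_models.to_dict(orient="records"),
        "critical_depths": {
            f"{c.curve_id}|{c.smoother}": {
                "critical_depth_cm": c.critical_depth,
                "r2_at_max": c.value_at_max,
                "boundary_flag": bool(c.boundary_flag),
            }
            for c in curves
        },
        "config": {
            "collinearity_threshold": config.collinearity_threshold,
            "reference_column": config.reference_column,
            "soc_formula": config.soc_formula,
            "criterion": config.selection.criterion,
            "method": config.selection.method,
            "r2_kind": config.r2_kind,
        },
    }
    return PipelineResult(
        column_table=column_table,
        residuals=residuals,
        age_models=age_models,
        kept_predictors=pset.kept,
        dropped_predictors=pset.dropped,
        fits=fits,
        importance=imp,
        trends=trends,
        occurrence=occ,
        curves=curves,
        report=report,
    )


def _write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.column_table.to_csv(out / "soil_columns.csv", index=False)
    result.residuals.to_csv(out / "responses_residualized.csv", index=False)
    result.age_models.to_csv(out / "age_models.csv", index=False)
    (out / "predictors_kept.txt").write_text("\n".join(result.kept_predictors) + "\n")
    grid_to_frame(result.fits).to_csv(out / "model_grid.csv", index=False)
    with open(out / "model_grid.json", "w") as fh:
        json.dump(
            [
                {
                    "layer": f.layer, "response": f.response, "column": f.column,
                    "selected": list(f.selected), "coefficients": f.coefficients,
                    "criterion": f.criterion, "criterion_value": f.criterion_value,
                    "r2": f.r2, "adj_r2": f.adj_r2,
                }
                for f in result.fits
            ],
            fh, indent=1,
        )
    result.importance.to_csv(out / "importance.csv", index=False)
    result.trends.to_csv(out / "trends.csv", index=False)
    result.occurrence.to_csv(out / "occurrence.csv", index=False)
    curves_to_frame(result.curves).to_csv(out / "critical_depth.csv", index=False)
    pts = pd.concat(
        [
            pd.DataFrame({
                "curve_id": c.curve_id, "smoother": c.smoother,
                "depth_cm": c.x, "r2": c.y,
            })
            for c in result.curves
        ],
        ignore_index=True,
    )
    pts.to_csv(out / "curve_points.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1)


def validate_inputs(
    soil: pd.DataFrame, terrain: pd.DataFrame, responses: pd.DataFrame
) -> list[str]:
    """Cross-file schema and consistency checks; returns a list of issues."""
    issues: list[str] = []
    try:
        validate_increment_table(soil)
    except ValueError as err:
        issues.append(f"soil_increments: {err}")
    if "plot_id" not in terrain.columns:
        issues.append("terrain: missing plot_id column")
    need = {"plot_id", "layer", "tree_age"}
    missing = need - set(responses.columns)
    if missing:
        issues.append(f"responses: missing columns {sorted(missing)}")
    if not issues:
        plots = set(soil["plot_id"])
        if set(terrain["plot_id"]) != plots:
            issues.append("terrain: plot ids do not match soil table")
        if set(responses["plot_id"]) != plots:
            issues.append("responses: plot ids do not match soil table")
        if (responses["tree_age"] <= 0).any():
            issues.append("responses: non-positive tree age")
    return issues


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven end-to-end run; writes all stage outputs when out_dir set."""
    soil = pd.read_csv(config.soil_increments)
    terrain = pd.read_csv(config.terrain)
    responses = pd.read_csv(config.responses)
    issues = validate_inputs(soil, terrain, responses)
    if issues:
        raise ValueError("input validation failed:\n" + "\n".join(issues))
    result = _analyse(soil, terrain, responses, config)
    if config.out_dir is not None:
        _write_outputs(result, config.out_dir)
    return result


def run_synthetic_pipeline(
    synth_config: SyntheticConfig | None = None,
    seed: int = 0,
    selection_config: SelectionConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> PipelineResult:
    """Generate a synthetic dataset and run the full analysis on it."""
    synth_config = synth_config or SyntheticConfig()
    soil, terrain, responses, truth = generate_dataset(synth_config, seed)
    config = pipeline_config or PipelineConfig()
    config.seed = seed
    if selection_config is not None:
        config.selection = selection_config
    # GA (used when the candidate set is large) must be deterministic per run
    config.selection = SelectionConfig(**{**config.selection.__dict__, "seed": seed})
    result = _analyse(soil, terrain, responses, config)
    result.report["truth"] = {
        "true_column_cm": truth.true_column.lower,
        "active": {f"{l}:{r}": list(v) for (l, r), v in truth.active.items()},
    }
    if config.out_dir is not None:
        _write_outputs(result, config.out_dir)
    return result
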