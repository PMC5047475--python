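"""End-to-end study reproduction: screen the packaged table, derive the
equation family and the composite formula, and predict CI per animal.

This is the library behind the ``cystindex reproduce`` command; everything is
returned as plain DataFrames/strings so it is equally usable from Python.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calculator import (
    DEFAULT_ELIGIBLE_FLUIDS,
    CompositeCalculator,
    equations_from_screen,
    predict_ci,
    render_equation,
    render_formula,
    save_json,
    signal_average,
)
from .errors import IncompletePanelError
from .screening import DEFAULT_GATE, GateConfig, ScreenDecision, screen_all
from .study import StudyTable, count_discrepancies, load_fixture

#: Serum/urine biomarkers expected to survive the gate on the packaged table.
EXPECTED_FLUID_PASSERS = frozenset({"bun", "scr", "il18_urine"})


@dataclass(frozen=True)
class ReportBundle:
    """All artifacts of one reproduction run."""

    correlations: pd.DataFrame
    decisions: list[ScreenDecision]
    calculator: CompositeCalculator
    formula_text: str
    equation_texts: list[str]
    predictions: pd.DataFrame
    counts: pd.DataFrame

    @property
    def passing_fluid_biomarkers(self) -> frozenset[str]:
        return frozenset(
            d.variable_name
            for d in self.decisions
            if d.passed and d.fluid in DEFAULT_ELIGIBLE_FLUIDS
        )


def correlation_table(decisions: list[ScreenDecision]) -> pd.DataFrame:
    """One row per screened variable: n, per-family r, gate outcome."""
    rows = []
    for d in decisions:
        lin = d.linear_fit
        best = d.best_fit
        rows.append(
            {
                "variable": d.variable_name,
                "fluid": d.fluid,
                "n": lin.n,
                "r_linear": lin.r,
                "p_linear": lin.p_value,
                "best_family": best.family,
                "r_best": abs(best.r),
                "p_best": best.p_value,
                "linear_slope": lin.slope,
                "linear_intercept": lin.intercept,
                "passed": d.passed,
            }
        )
    return pd.DataFrame(rows)


def prediction_table(
    calculator: CompositeCalculator, table: StudyTable
) -> pd.DataFrame:
    """Predicted vs observed CI for every animal with a complete panel."""
    rows = []
    for rec in table.records:
        panel = {v: rec.get(v) for v in calculator.variable_names}
        if any(v is None for v in panel.values()):
            continue
        pred = predict_ci(calculator, {k: float(v) for k, v in panel.items()})
        row = {
            "animal_id": rec.animal_id,
            "observed_ci": rec.ci_percent,
            "predicted_ci": pred.ci,
            "residual": pred.ci - rec.ci_percent,
            "out_of_range": pred.out_of_range,
        }
        for name, value in pred.components.items():
            row[f"component_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce(
    table: StudyTable | None = None,
    gate: GateConfig = DEFAULT_GATE,
    eligible_fluids: tuple[str, ...] = DEFAULT_ELIGIBLE_FLUIDS,
) -> ReportBundle:
    """Run the whole derivation on ``table`` (default: the packaged study)."""
    if table is None:
        table = load_fixture()
    decisions = screen_all(table, gate)
    equations = equations_from_screen(decisions, eligible_fluids=eligible_fluids)
    calc = signal_average(equations)
    return ReportBundle(
        correlations=correlation_table(decisions),
        decisions=decisions,
        calculator=calc,
        formula_text=render_formula(calc),
        equation_texts=[render_equation(e) for e in calc.components],
        predictions=prediction_table(calc, table),
        counts=count_discrepancies(table),
    )


def write_bundle(bundle: ReportBundle, outdir: str) -> dict[str, str]:
    """Write the bundle's artifacts under ``outdir``; returns name → path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "correlations": os.path.join(outdir, "correlations.csv"),
        "predictions": os.path.join(outdir, "predictions.csv"),
        "counts": os.path.join(outdir, "pair_counts.csv"),
        "calculator": os.path.join(outdir, "calculator.json"),
        "formula": os.path.join(outdir, "formula.txt"),
    }
    bundle.correlations.to_csv(paths["correlations"], index=False)
    bundle.predictions.to_csv(paths["predictions"], index=False)
    bundle.counts.to_csv(paths["counts"], index=False)
    save_json(bundle.calculator, paths["calculator"])
    with open(paths["formula"], "w", encoding="utf-8") as fh:
        fh.write(bundle.formula_text + "\n")
        for text in bundle.equation_texts:
            fh.write(text + "\n")
    return paths


def predict_panels(
    calculator: CompositeCalculator, panels: pd.DataFrame
) -> pd.DataFrame:
    """Composite CI for each row of a panel DataFrame.

    Raises IncompletePanelError (naming the columns) when a required
    component column is absent from the frame; rows with missing cells in a
    required column are skipped.
    """
    missing_cols = [v for v in calculator.variable_names if v not in panels.columns]
    if missing_cols:
        raise IncompletePanelError(missing_cols)
    rows = []
    for idx, row in panels.iterrows():
        values = {v: row[v] for v in calculator.variable_names}
        if any(pd.isna(v) for v in values.values()):
            continue
        pred = predict_ci(calculator, {k: float(v) for k, v in values.items()})
        out = {"row": idx, "predicted_ci": pred.ci, "out_of_range": pred.out_of_range}
        for name, value in pred.components.items():
            out[f"component_{name}"] = value
        rows.append(out)
    return pd.DataFrame(rows)


def fit_quality(predictions: pd.DataFrame) -> dict[str, float]:
    """Summary agreement between predicted and observed CI."""
    obs = predictions["observed_ci"].to_numpy()
    pred = predictions["predicted_ci"].to_numpy()
    resid = pred - obs
    return {
        "n": float(len(obs)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "pearson_r": float(np.corrcoef(obs, pred)[0, 1]),
    }
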