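"""The cystic-index calculator: univariate CI equations and their
signal-averaged composite.

Each gate-passing biomarker yields one linear equation CI ≈ a·x + b. Because
every equation estimates the *same* quantity, the principle of signal
averaging applies: the equal-weight mean of k such estimates,

    CI ≈ [ (a₁x₁+b₁) + … + (aₖxₖ+bₖ) ] / k
       = Σᵢ (aᵢ/k)·xᵢ + (Σᵢ bᵢ)/k,

is itself an affine formula whose coefficients are each component slope
divided by k and whose intercept is the mean of the component intercepts.
With the three biomarkers retained from the PCK-rat study (BUN, SCr, 24-h
urine IL-18) this yields, at printed rounding,

    %CI = 0.32·BUN (mg/dL) + 17.9·SCr (mg/dL) + 456·urine IL-18 (μg) − 2.18

Coefficients are stored at full precision; rounding happens only at render
time (:func:`render_formula`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .errors import (
    DomainError,
    DuplicateVariableError,
    EmptyCalculatorError,
    IncompletePanelError,
)
from .screening import ScreenDecision

#: Fluids whose biomarkers enter the calculator by default: the point of the
#: formula is to estimate CI from minimally invasive blood/urine samples, so
#: tissue-derived quantities (kidney mass, mass ratio) are excluded even when
#: they pass the gate — knowing them would presuppose nephrectomy.
DEFAULT_ELIGIBLE_FLUIDS: tuple[str, ...] = ("serum", "urine")


@dataclass(frozen=True)
class LinearEquation:
    """CI as an affine function of one biomarker: CI ≈ slope·x + intercept."""

    variable_name: str
    slope: float
    intercept: float
    units: str = ""
    n: int | None = None
    r: float | None = None
    p_value: float | None = None

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class CiPrediction:
    """A composite CI estimate with its per-component univariate estimates."""

    ci: float
    components: Mapping[str, float]
    out_of_range: bool  # CI outside [0, 100]%: reported as computed, flagged

    def __float__(self) -> float:
        return self.ci


@dataclass(frozen=True)
class CompositeCalculator:
    """Signal-averaged combination of k univariate CI equations.

    Exact identity: for any complete panel, the composite prediction equals
    the arithmetic mean of the component predictions.
    """

    components: tuple[LinearEquation, ...]
    combined_coefficients: Mapping[str, float] = field(init=False)
    combined_intercept: float = field(init=False)

    def __post_init__(self) -> None:
        names = [e.variable_name for e in self.components]
        if len(set(names)) != len(names):
            raise DuplicateVariableError(f"duplicate component variables in {names}")
        if not self.components:
            raise EmptyCalculatorError("a calculator needs at least one equation")
        k = len(self.components)
        object.__setattr__(
            self,
            "combined_coefficients",
            {e.variable_name: e.slope / k for e in self.components},
        )
        object.__setattr__(
            self,
            "combined_intercept",
            sum(e.intercept for e in self.components) / k,
        )

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(e.variable_name for e in self.components)


def equations_from_screen(
    decisions: Iterable[ScreenDecision],
    eligible_fluids: tuple[str, ...] | None = DEFAULT_ELIGIBLE_FLUIDS,
) -> list[LinearEquation]:
    """One linear equation per gate-passing, fluid-eligible variable.

    Slopes/intercepts are carried at full precision, with the fit's n, r and
    p as provenance. Raises EmptyCalculatorError when nothing passes.
    """
    equations = []
    for d in decisions:
        if not d.passed:
            continue
        if eligible_fluids is not None and d.fluid not in eligible_fluids:
            continue
        fit = d.chosen
        assert fit is not None and fit.family == "linear"
        equations.append(
            LinearEquation(
                variable_name=d.variable_name,
                slope=fit.slope,
                intercept=fit.intercept,
                units=d.units,
                n=fit.n,
                r=fit.r,
                p_value=fit.p_value,
            )
        )
    if not equations:
        raise EmptyCalculatorError(
            "no biomarker passed the screening gate; cannot build a calculator"
        )
    return equations


def signal_average(equations: Sequence[LinearEquation]) -> CompositeCalculator:
    """Combine univariate equations by equal-weight signal averaging."""
    return CompositeCalculator(tuple(equations))


def predict_ci(
    calculator: CompositeCalculator, panel: Mapping[str, float]
) -> CiPrediction:
    """Evaluate the composite formula on one biomarker panel.

    The panel must supply every component variable (units as declared).
    Out-of-range results (CI < 0 or > 100) are returned as computed with the
    ``out_of_range`` flag set, never clamped.
    """
    missing = [v for v in calculator.variable_names if v not in panel]
    if missing:
        raise IncompletePanelError(missing)
    for name in calculator.variable_names:
        if panel[name] < 0:
            raise DomainError(f"negative value {panel[name]} for {name!r}")
    components = {e.variable_name: e.predict(panel[e.variable_name]) for e in calculator.components}
    ci = (
        sum(c * panel[v] for v, c in calculator.combined_coefficients.items())
        + calculator.combined_intercept
    )
    return CiPrediction(
        ci=float(ci),
        components=components,
        out_of_range=not 0.0 <= ci <= 100.0,
    )


def paper_style_decimals(value: float) -> int:
    """Decimal places used when printing a composite-formula coefficient:
    0 for |v| ≥ 100, 1 for |v| ≥ 10, otherwise 2 (e.g. 455.98 → 456,
    17.87 → 17.9, 0.3170 → 0.32)."""
    a = abs(value)
    if a >= 100:
        return 0
    if a >= 10:
        return 1
    return 2


def table_style_decimals(value: float) -> int:
    """Decimal places used when printing a univariate-equation coefficient:
    0 for |v| ≥ 1000, otherwise 2 (e.g. 1367.95 → 1368, 53.618 → 53.62)."""
    return 0 if abs(value) >= 1000 else 2


def round_coefficient(value: float, style: str = "formula") -> float:
    """Round one coefficient under a named display style.

    ``formula``: the composite-formula convention (paper_style_decimals);
    ``table``: the per-equation convention (table_style_decimals).
    """
    decimals = {"formula": paper_style_decimals, "table": table_style_decimals}[style](value)
    return round(value, decimals)


def _fmt(value: float, style: str) -> str:
    decimals = {"formula": paper_style_decimals, "table": table_style_decimals}[style](value)
    return f"{value:.{decimals}f}"


def render_formula(calculator: CompositeCalculator, style: str = "formula") -> str:
    """Human-readable composite formula with coefficients rounded for display.

    Full-precision coefficients are untouched; only the rendering rounds.
    """
    parts = []
    for eq in calculator.components:
        coeff = calculator.combined_coefficients[eq.variable_name]
        unit = f" ({eq.units})" if eq.units else ""
        parts.append(f"({_fmt(coeff, style)}*{eq.variable_name}{unit})")
    b = calculator.combined_intercept
    sign = "-" if b < 0 else "+"
    return "%CI = " + " + ".join(parts) + f" {sign} {_fmt(abs(b), style)}"


def render_equation(equation: LinearEquation, style: str = "table") -> str:
    """Human-readable univariate equation, e.g. ``CI = 0.95*bun - 8.15``."""
    b = equation.intercept
    sign = "-" if b < 0 else "+"
    unit = f" ({equation.units})" if equation.units else ""
    return (
        f"CI = {_fmt(equation.slope, style)}*{equation.variable_name}{unit} "
        f"{sign} {_fmt(abs(b), style)}"
    )


def to_dict(calculator: CompositeCalculator) -> dict:
    """Plain-JSON document: full-precision coefficients plus fit provenance."""
    return {
        "kind": "cystindex.composite_calculator",
        "components": [
            {
                "variable_name": e.variable_name,
                "slope": e.slope,
                "intercept": e.intercept,
                "units": e.units,
                "n": e.n,
                "r": e.r,
                "p_value": e.p_value,
            }
            for e in calculator.components
        ],
        "combined_coefficients": dict(calculator.combined_coefficients),
        "combined_intercept": calculator.combined_intercept,
    }


def from_dict(doc: Mapping) -> CompositeCalculator:
    eqs = tuple(
        LinearEquation(
            variable_name=c["variable_name"],
            slope=c["slope"],
            intercept=c["intercept"],
            units=c.get("units", ""),
            n=c.get("n"),
            r=c.get("r"),
            p_value=c.get("p_value"),
        )
        for c in doc["components"]
    )
    return CompositeCalculator(eqs)


def save_json(calculator: CompositeCalculator, dest: str | IO[str]) -> None:
    doc = to_dict(calculator)
    if hasattr(dest, "write"):
        json.dump(doc, dest, indent=2)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)


def load_json(source: str | IO[str]) -> CompositeCalculator:
    if hasattr(source, "read"):
        return from_dict(json.load(source))
    with open(source, encoding="utf-8") as fh:
        return from_dict(json.load(fh))
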