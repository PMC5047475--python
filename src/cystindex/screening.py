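"""Association screening: trendline fits of CI on each variable and the
correlation gate that selects biomarkers for the calculator.

Four trendline families are fitted, following ordinary spreadsheet curve-fit
conventions:

``linear``        y = a·x + b, ordinary least squares.
``exponential``   y = A·exp(B·x), fitted as ln(y) on x by least squares
                  (requires all y > 0); r² is reported in the fitting (log)
                  space, as spreadsheet trendlines do.
``logarithmic``   y = a·ln(x) + b (requires all x > 0).
``polynomial2``   y = c₂·x² + c₁·x + c₀ (degree fixed at 2; higher degrees
                  would trivially inflate r² and subvert the gate).

The correlation coefficient r is derived from the trendline's r²: for the
linear family it is the signed Pearson correlation; for the curved families
the sign is undefined and r = √r² is reported non-negative. Significance is
the two-tailed p-value of t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom.

The screening gate retains a variable when the best family's r is at least
``r_min`` (default 0.7) with p below ``p_max`` (default 0.05) *and* the linear
fit's r is within ``linear_margin`` (default 0.10, absolute difference in r)
of that best r — in which case the linear fit is the equation retained for the
calculator, a deliberately simpler model traded for a marginally better curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import (
    ConfigError,
    DegeneratePredictorError,
    FamilyInapplicableError,
    InsufficientDataError,
)
from .study import PairedSeries, StudyTable, paired_series

FAMILIES = ("linear", "logarithmic", "exponential", "polynomial2")


@dataclass(frozen=True)
class FitResult:
    """One trendline family fitted to one (variable, CI) series.

    ``coefficients`` is family-specific: linear (slope, intercept);
    exponential (amplitude A, rate B) for y = A·exp(B·x); logarithmic
    (slope, intercept) for y = slope·ln(x) + intercept; polynomial2
    (c2, c1, c0), descending powers.
    """

    variable_name: str
    family: str
    coefficients: tuple[float, ...]
    r_squared: float
    r: float
    p_value: float
    n: int

    @property
    def slope(self) -> float:
        if self.family != "linear":
            raise AttributeError(f"slope undefined for family {self.family!r}")
        return self.coefficients[0]

    @property
    def intercept(self) -> float:
        if self.family != "linear":
            raise AttributeError(f"intercept undefined for family {self.family!r}")
        return self.coefficients[1]


@dataclass(frozen=True)
class GateConfig:
    """Thresholds of the screening gate (defaults follow the study)."""

    r_min: float = 0.7
    p_max: float = 0.05
    linear_margin: float = 0.10
    families: tuple[str, ...] = FAMILIES

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0:
            raise ConfigError(f"r_min {self.r_min} outside [0, 1]")
        if not 0.0 < self.p_max <= 1.0:
            raise ConfigError(f"p_max {self.p_max} outside (0, 1]")
        if self.linear_margin < 0:
            raise ConfigError("linear_margin must be >= 0")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ConfigError(f"unknown families {sorted(unknown)}")
        if "linear" not in self.families:
            raise ConfigError("the linear family cannot be disabled")


DEFAULT_GATE = GateConfig()


@dataclass(frozen=True)
class ScreenDecision:
    """Outcome of screening one variable."""

    variable_name: str
    fluid: str
    units: str
    fits: tuple[FitResult, ...]
    chosen: FitResult | None
    passed: bool
    linear_preference_applied: bool
    skipped: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def linear_fit(self) -> FitResult:
        return next(f for f in self.fits if f.family == "linear")

    @property
    def best_fit(self) -> FitResult:
        """Highest-|r| fit, ties broken by the fixed family order."""
        return max(self.fits, key=lambda f: (abs(f.r), -FAMILIES.index(f.family)))


def correlation_p_value(r: float, n: int) -> float:
    """Two-tailed significance of a correlation coefficient.

    Uses t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom; |r| = 1 gives 0.
    """
    if n < 3:
        raise InsufficientDataError(f"n = {n} < 3: correlation p-value undefined")
    if not -1.0 <= r <= 1.0:
        raise ConfigError(f"r = {r} outside [-1, 1]")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def fit_linear(series: PairedSeries) -> FitResult:
    """Ordinary least-squares line of CI on the variable.

    r is the signed Pearson correlation (sign of the slope); r² its square.
    """
    if series.n < 3:
        raise InsufficientDataError(f"{series.variable_name!r}: n = {series.n} < 3")
    if np.ptp(series.x) == 0:
        raise DegeneratePredictorError(
            f"{series.variable_name!r} is constant; slope unidentifiable"
        )
    if np.ptp(series.y) == 0:
        # flat response: slope 0, r 0 by convention (r = 0 iff slope = 0)
        return FitResult(
            variable_name=series.variable_name,
            family="linear",
            coefficients=(0.0, float(series.y[0])),
            r_squared=0.0,
            r=0.0,
            p_value=1.0,
            n=series.n,
        )
    res = stats.linregress(series.x, series.y)
    r = float(res.rvalue)
    return FitResult(
        variable_name=series.variable_name,
        family="linear",
        coefficients=(float(res.slope), float(res.intercept)),
        r_squared=r * r,
        r=r,
        p_value=correlation_p_value(r, series.n),
        n=series.n,
    )


def _r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    sst = float(((observed - observed.mean()) ** 2).sum())
    if sst == 0:
        raise DegeneratePredictorError("response is constant; r² undefined")
    ssr = float(((observed - fitted) ** 2).sum())
    return max(0.0, 1.0 - ssr / sst)


def fit_family(series: PairedSeries, family: str) -> FitResult:
    """Fit one trendline family; raises FamilyInapplicableError when its
    preconditions fail (non-positive values for log transforms, n too small).
    """
    if family == "linear":
        return fit_linear(series)
    if family not in FAMILIES:
        raise ConfigError(f"unknown family {family!r}")
    x, y, n = series.x, series.y, series.n
    if n < 3:
        raise InsufficientDataError(f"{series.variable_name!r}: n = {n} < 3")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError(
            f"{series.variable_name!r} is constant; fit unidentifiable"
        )
    if np.ptp(y) == 0:
        raise FamilyInapplicableError("response is constant; trendline r² undefined")

    if family == "exponential":
        if np.any(y <= 0):
            raise FamilyInapplicableError("exponential fit requires all y > 0")
        res = stats.linregress(x, np.log(y))
        coeffs = (float(np.exp(res.intercept)), float(res.slope))
        r_squared = float(res.rvalue**2)
    elif family == "logarithmic":
        if np.any(x <= 0):
            raise FamilyInapplicableError("logarithmic fit requires all x > 0")
        res = stats.linregress(np.log(x), y)
        coeffs = (float(res.slope), float(res.intercept))
        r_squared = float(res.rvalue**2)
    else:  # polynomial2
        if n < 4:
            raise FamilyInapplicableError("polynomial2 fit requires n >= 4")
        c = np.polyfit(x, y, 2)
        coeffs = tuple(float(v) for v in c)
        r_squared = _r2(y, np.polyval(c, x))

    r = float(np.sqrt(r_squared))
    return FitResult(
        variable_name=series.variable_name,
        family=family,
        coefficients=coeffs,
        r_squared=r_squared,
        r=r,
        p_value=correlation_p_value(r, n),
        n=n,
    )


def screen_variable(
    table: StudyTable, variable_name: str, gate: GateConfig = DEFAULT_GATE
) -> ScreenDecision:
    """Fit all applicable families for one variable and apply the gate.

    The gate examines the best family's r and p; the ~10% linear-preference
    rule then requires the linear r to lie within ``linear_margin`` of the
    best r, so that the retained equation is always the linear one.
    """
    series = paired_series(table, variable_name)
    fits: list[FitResult] = []
    skipped: list[tuple[str, str]] = []
    for family in gate.families:
        try:
            fits.append(fit_family(series, family))
        except FamilyInapplicableError as exc:
            skipped.append((family, str(exc)))

    decision_fits = tuple(fits)
    linear = next(f for f in decision_fits if f.family == "linear")
    best = max(decision_fits, key=lambda f: (abs(f.r), -FAMILIES.index(f.family)))

    gate_ok = abs(best.r) >= gate.r_min and best.p_value < gate.p_max
    linear_ok = (abs(best.r) - abs(linear.r)) <= gate.linear_margin
    # A negative linear slope cannot be rescued by an unsigned curved-family r:
    # the gate is for markers that rise with CI the way the retained linear
    # equations do, so require a non-negative linear correlation.
    passed = bool(gate_ok and linear_ok and linear.r >= 0)
    spec = table.spec(variable_name)
    return ScreenDecision(
        variable_name=variable_name,
        fluid=spec.fluid,
        units=spec.units,
        fits=decision_fits,
        chosen=linear if passed else None,
        passed=passed,
        linear_preference_applied=bool(passed and best.family != "linear"),
        skipped=tuple(skipped),
    )


def screen_all(
    table: StudyTable, gate: GateConfig = DEFAULT_GATE
) -> list[ScreenDecision]:
    """Screen every panel variable, in panel order."""
    return [screen_variable(table, name, gate) for name in table.panel_names]


def passing_names(
    decisions: Iterable[ScreenDecision], fluids: tuple[str, ...] | None = None
) -> list[str]:
    """Names of gate-passing variables, optionally restricted by fluid."""
    return [
        d.variable_name
        for d in decisions
        if d.passed and (fluids is None or d.fluid in fluids)
    ]
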