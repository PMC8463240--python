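"""Second-order response-surface modelling for a two-factor CCD.

Fits the full quadratic Y = b0 + b1·X1 + b2·X2 + b12·X1X2 + b11·X1² + b22·X2²
by ordinary least squares in either actual or coded units (the two fits are
the same model expressed in different bases and predict identically), builds
the ANOVA table with partial (Type-III) per-term sums of squares and a
lack-of-fit / pure-error split from replicated runs, predicts and optimizes
the response over a rectangular region, and scores model verification as the
percent deviation of the prediction from the measured replicate mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .doe import DesignMatrix, FactorSpec
from .exceptions import ConfigurationError, FitError

__all__ = [
    "TERMS",
    "QuadraticModel",
    "AnovaRow",
    "VerificationResult",
    "fit_quadratic",
    "anova_table",
    "predict",
    "optimize",
    "verification_deviation",
    "quote_floor",
    "export_surface",
]

TERMS = ("Intercept", "X1", "X2", "X1X2", "X1^2", "X2^2")


def _basis(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x1), x1, x2, x1 * x2, x1**2, x2**2])


def _convert(beta: np.ndarray, factors, direction: str) -> np.ndarray:
    """Exact affine re-expression of the quadratic between coded and actual units."""
    (m1, h1), (m2, h2) = ((f.center, f.half_range) for f in factors)
    b0, b1, b2, b12, b11, b22 = beta
    if direction == "actual_to_coded":
        # substitute X = m + h·x
        return np.array(
            [
                b0 + b1 * m1 + b2 * m2 + b12 * m1 * m2 + b11 * m1**2 + b22 * m2**2,
                b1 * h1 + b12 * h1 * m2 + 2 * b11 * m1 * h1,
                b2 * h2 + b12 * m1 * h2 + 2 * b22 * m2 * h2,
                b12 * h1 * h2,
                b11 * h1**2,
                b22 * h2**2,
            ]
        )
    if direction == "coded_to_actual":
        # substitute x = (X − m)/h
        a12 = b12 / (h1 * h2)
        a11 = b11 / h1**2
        a22 = b22 / h2**2
        a1 = b1 / h1 - a12 * m2 - 2 * a11 * m1
        a2 = b2 / h2 - a12 * m1 - 2 * a22 * m2
        a0 = b0 - b1 * m1 / h1 - b2 * m2 / h2 + a12 * m1 * m2 + a11 * m1**2 + a22 * m2**2
        return np.array([a0, a1, a2, a12, a11, a22])
    raise ValueError(direction)


@dataclass
class QuadraticModel:
    """A fitted six-term quadratic surface plus the design it came from."""

    factors: tuple[FactorSpec, FactorSpec]
    units: str  # "actual" or "coded"
    coefficients: np.ndarray  # ordered as TERMS
    r_squared: float
    df_resid: int
    residual_ms: float
    design_actual: np.ndarray
    response: np.ndarray

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(TERMS, map(float, self.coefficients)))

    def to_units(self, units: str) -> "QuadraticModel":
        if units == self.units:
            return self
        direction = "actual_to_coded" if units == "coded" else "coded_to_actual"
        return QuadraticModel(
            factors=self.factors,
            units=units,
            coefficients=_convert(self.coefficients, self.factors, direction),
            r_squared=self.r_squared,
            df_resid=self.df_resid,
            residual_ms=self.residual_ms,
            design_actual=self.design_actual,
            response=self.response,
        )

    def _evaluate_actual(self, x1, x2) -> np.ndarray:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if self.units == "coded":
            x1 = self.factors[0].code(x1)
            x2 = self.factors[1].code(x2)
        return _basis(np.ravel(x1), np.ravel(x2)) @ self.coefficients


def fit_quadratic(design: DesignMatrix, units: str = "actual") -> QuadraticModel:
    """OLS fit of the full quadratic to a two-factor design with response."""
    if units not in ("actual", "coded"):
        raise ConfigurationError(f"units must be 'actual' or 'coded', got {units!r}")
    if len(design.factors) != 2:
        raise ConfigurationError("quadratic surface fitting expects exactly 2 factors")
    if design.response is None:
        raise ConfigurationError("design carries no response; attach one with with_response()")
    y = design.response
    if len(y) < 6:
        raise FitError(f"need at least 6 runs for the six-term model, got {len(y)}")
    levels = design.actual if units == "actual" else design.coded
    X = _basis(levels[:, 0], levels[:, 1])
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        # name the first term whose column adds no rank
        r_prev = 0
        for j in range(6):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == r_prev:
                raise FitError(f"design cannot estimate term {TERMS[j]}: column is dependent")
            r_prev = r
        raise FitError("design is rank deficient for the quadratic model")
    fit = sm.OLS(y, X).fit()
    return QuadraticModel(
        factors=(design.factors[0], design.factors[1]),
        units=units,
        coefficients=np.asarray(fit.params, dtype=float),
        r_squared=float(fit.rsquared),
        df_resid=int(fit.df_resid),
        residual_ms=float(fit.mse_resid),
        design_actual=design.actual.copy(),
        response=np.asarray(y, dtype=float).copy(),
    )


@dataclass(frozen=True)
class AnovaRow:
    term: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None
    significance: str = ""


def _pure_error(design_actual: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Replicate-only sum of squares: deviations within groups of identical settings."""
    keys = [tuple(np.round(row, 9)) for row in design_actual]
    ss, df = 0.0, 0
    for key in set(keys):
        idx = [i for i, k in enumerate(keys) if k == key]
        if len(idx) > 1:
            grp = y[idx]
            ss += float(((grp - grp.mean()) ** 2).sum())
            df += len(idx) - 1
    return ss, df


def anova_table(model: QuadraticModel, alpha: float = 0.05) -> list[AnovaRow]:
    """Full ANOVA with partial (Type-III) term rows and a lack-of-fit split.

    Per-term SS is the increase in residual SS when that term alone is
    dropped. The lack-of-fit row needs replicated runs; without any, the
    split is omitted with a warning.
    """
    x = np.column_stack(
        [model.factors[0].code(model.design_actual[:, 0]),
         model.factors[1].code(model.design_actual[:, 1])]
    )
    y = model.response
    X = _basis(x[:, 0], x[:, 1])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_resid = float(resid @ resid)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_total - ss_resid
    df_model, df_resid, df_total = 5, len(y) - 6, len(y) - 1
    ms_resid = ss_resid / df_resid

    def f_row(term: str, ss: float, df: int) -> AnovaRow:
        ms = ss / df
        f = ms / ms_resid
        p = float(stats.f.sf(f, df, df_resid))
        label = "significant" if p < alpha else ""
        return AnovaRow(term, ss, df, ms, f, p, label)

    rows = [f_row("Model", ss_model, df_model)]
    for j, term in enumerate(TERMS[1:], start=1):
        Xd = np.delete(X, j, axis=1)
        bd, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rd = y - Xd @ bd
        rows.append(f_row(term, float(rd @ rd) - ss_resid, 1))
    rows.append(AnovaRow("Residual", ss_resid, df_resid, ms_resid, None, None))

    ss_pe, df_pe = _pure_error(model.design_actual, y)
    if df_pe == 0:
        warnings.warn(
            "no replicated runs: lack-of-fit/pure-error split omitted", stacklevel=2
        )
    else:
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        ms_pe = ss_pe / df_pe
        if df_lof > 0:
            ms_lof = ss_lof / df_lof
            f_lof = ms_lof / ms_pe
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
            label = "" if p_lof >= alpha else "significant"
            rows.append(AnovaRow("Lack of fit", ss_lof, df_lof, ms_lof, f_lof, p_lof,
                                 label or "not significant"))
        rows.append(AnovaRow("Pure error", ss_pe, df_pe, ms_pe, None, None))
    rows.append(AnovaRow("Total", ss_total, df_total, None, None, None))
    return rows


def predict(model: QuadraticModel, point, warn_extrapolation: bool = True):
    """Evaluate the surface at actual-unit point(s) (x1, x2).

    Points outside the coded hull of the fitted design (beyond the axial
    distance) are extrapolations and trigger a warning.
    """
    point = np.asarray(point, dtype=float)
    single = point.ndim == 1
    pts = np.atleast_2d(point)
    if warn_extrapolation:
        coded = np.column_stack(
            [model.factors[0].code(pts[:, 0]), model.factors[1].code(pts[:, 1])]
        )
        design_coded = np.column_stack(
            [model.factors[0].code(model.design_actual[:, 0]),
             model.factors[1].code(model.design_actual[:, 1])]
        )
        limit = np.abs(design_coded).max() + 1e-9
        if np.any(np.abs(coded) > limit):
            warnings.warn("prediction point outside the fitted design region", stacklevel=2)
    values = model._evaluate_actual(pts[:, 0], pts[:, 1])
    return float(values[0]) if single else values


def _region_grids(model: QuadraticModel, region, grid_step_coded: float):
    grids = []
    for (lo, hi), spec in zip(region, model.factors):
        if not lo < hi:
            raise ConfigurationError(f"empty region for {spec.name}: [{lo}, {hi}]")
        step = grid_step_coded * spec.half_range
        n = max(2, int(math.ceil((hi - lo) / step)) + 1)
        grids.append(np.linspace(lo, hi, n))
    return grids


def optimize(
    model: QuadraticModel,
    region,
    objective: str = "maximize",
    target: float | None = None,
    grid_step_coded: float = 0.01,
) -> tuple[tuple[float, float], float]:
    """Best point of the surface over a rectangle ``((x1_lo, x1_hi), (x2_lo, x2_hi))``.

    For ``maximize``: if the analytic stationary point (gradient = 0) is a
    maximum inside the region it is returned; otherwise a deterministic dense
    grid (default step 0.01 coded units, boundaries included) is scanned.
    ``target`` mode locates the grid point whose prediction is closest to the
    requested level.
    """
    a = model.to_units("actual").coefficients
    _, a1, a2, a12, a11, a22 = a
    if objective == "maximize":
        H = np.array([[2 * a11, a12], [a12, 2 * a22]])
        det = float(np.linalg.det(H))
        if abs(det) > 1e-12:
            xs = np.linalg.solve(H, -np.array([a1, a2]))
            eigs = np.linalg.eigvalsh(H)
            inside = all(lo <= v <= hi for v, (lo, hi) in zip(xs, region))
            if inside and np.all(eigs < 0):
                return (float(xs[0]), float(xs[1])), predict(
                    model, xs, warn_extrapolation=False
                )
        else:
            warnings.warn("degenerate Hessian; falling back to grid search", stacklevel=2)
    elif objective != "target":
        raise ConfigurationError(f"objective must be 'maximize' or 'target', got {objective!r}")
    if objective == "target" and target is None:
        raise ConfigurationError("objective 'target' needs a target value")

    g1, g2 = _region_grids(model, region, grid_step_coded)
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    values = model._evaluate_actual(G1.ravel(), G2.ravel())
    score = values if objective == "maximize" else -np.abs(values - target)
    best = int(np.argmax(score))  # first occurrence: deterministic tie-break
    return (float(G1.ravel()[best]), float(G2.ravel()[best])), float(values[best])


@dataclass(frozen=True)
class VerificationResult:
    """Prediction vs replicate measurements at the chosen operating point."""

    predicted: float
    measured: tuple[float, ...]
    measured_mean: float
    deviation_percent: float


def verification_deviation(predicted: float, measured) -> VerificationResult:
    """Percent deviation |predicted − mean(measured)| / mean(measured) × 100."""
    measured = tuple(float(v) for v in measured)
    if not measured:
        raise ConfigurationError("verification needs at least one measured replicate")
    mean = sum(measured) / len(measured)
    deviation = abs(predicted - mean) / mean * 100.0
    return VerificationResult(
        predicted=float(predicted),
        measured=measured,
        measured_mean=mean,
        deviation_percent=deviation,
    )


def quote_floor(value: float, decimals: int = 2) -> float:
    """Quote a predicted resolution conservatively: truncate toward zero.

    A separation claim should state a resolution the method can actually
    reach, so the quoted figure never rounds up past the computed value.
    """
    scale = 10**decimals
    return math.floor(value * scale) / scale


def export_surface(model: QuadraticModel, region, shape=(21, 21)):
    """Rectangular grid of predictions for contour/response-surface rendering."""
    import pandas as pd

    (lo1, hi1), (lo2, hi2) = region
    g1 = np.linspace(lo1, hi1, shape[0])
    g2 = np.linspace(lo2, hi2, shape[1])
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    values = model._evaluate_actual(G1.ravel(), G2.ravel())
    return pd.DataFrame(
        {
            model.factors[0].name: G1.ravel(),
            model.factors[1].name: G2.ravel(),
            "predicted": values,
        }
    )
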