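"""Main-effect estimation and significance testing for screening designs.

The screening model is intercept + one coded main effect per factor, fitted by
ordinary least squares; on an orthogonal ±1 design each coefficient reduces to
half the difference of response means between the factor's high and low runs.
Significance uses two-sided t-tests on the residual mean square (runs − factors
− 1 degrees of freedom), and a Pareto ranking orders factors by |t| against the
critical t at the chosen significance level — separating critical method
parameters from noncritical ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .doe import DesignMatrix
from .exceptions import ConfigurationError, FitError

__all__ = ["EffectEstimate", "estimate_effects", "pareto_rank", "classify_factors"]


@dataclass(frozen=True)
class EffectEstimate:
    """One factor's estimated main effect with its t-test.

    ``coefficient`` is the coded-unit regression coefficient (half-effect);
    ``effect`` = 2·coefficient is the predicted response change from the low to
    the high level. ``df_resid`` travels with the estimate so that ranking and
    classification need no further context.
    """

    factor: str
    coefficient: float
    standard_error: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float
    df_resid: int

    @property
    def effect(self) -> float:
        return 2.0 * self.coefficient


def estimate_effects(design: DesignMatrix, alpha: float = 0.05) -> list[EffectEstimate]:
    """OLS main-effects fit of a screening design's response.

    Requires at least two residual degrees of freedom — with zero residual df
    there is no error estimate and a normal/half-normal plot of effects would
    be needed instead (not provided here).
    """
    if design.response is None:
        raise ConfigurationError("design carries no response; attach one with with_response()")
    n, k = design.coded.shape
    df_resid = n - k - 1
    if df_resid < 2:
        raise FitError(
            f"only {df_resid} residual degrees of freedom; need >= 2 for t-tests "
            "(consider a normal plot of effects instead)"
        )
    X = sm.add_constant(design.coded, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("screening design is rank deficient; effects are not estimable")
    fit = sm.OLS(design.response, X).fit()
    # perfect fit (e.g. constant response): no error estimate; a zero
    # coefficient is then trivially non-significant, a nonzero one certain
    scale = max(1.0, float(np.abs(design.response).max()))
    degenerate = fit.mse_resid <= (1e-14 * scale) ** 2
    estimates = []
    for j, name in enumerate(design.factor_names, start=1):
        coef = float(fit.params[j])
        if degenerate:
            zero = abs(coef) <= 1e-12 * scale
            if zero:
                coef = 0.0
            se, t = 0.0, 0.0 if zero else math.inf
            p = 1.0 if zero else 0.0
        else:
            se = float(fit.bse[j])
            t = float(fit.tvalues[j])
            p = float(fit.pvalues[j])
        estimates.append(
            EffectEstimate(
                factor=name,
                coefficient=coef,
                standard_error=se,
                t_statistic=t,
                p_value=p,
                significant=p < alpha,
                alpha=alpha,
                df_resid=int(fit.df_resid),
            )
        )
    return estimates


def pareto_rank(
    effects: list[EffectEstimate], alpha: float = 0.05
) -> tuple[list[EffectEstimate], float]:
    """Sort effects by |t| (descending; ties broken by factor name) with the
    two-sided critical t at the residual degrees of freedom as reference line."""
    if not effects:
        raise ConfigurationError("no effects to rank")
    ranked = sorted(effects, key=lambda e: (-abs(e.t_statistic), e.factor))
    threshold = float(stats.t.ppf(1.0 - alpha / 2.0, effects[0].df_resid))
    return ranked, threshold


def classify_factors(
    effects: list[EffectEstimate], alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Partition factors into critical (p < alpha) and noncritical lists."""
    critical = [e.factor for e in effects if e.p_value < alpha]
    noncritical = [e.factor for e in effects if not e.p_value < alpha]
    return critical, noncritical
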