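"""Analytical method-validation statistics.

Linearity (single-component calibration line over an injected-amount range),
relative standard deviation of replicate measurements (stability,
repeatability, instrument precision), and spike recovery
(measured − endogenous)/spiked × 100. A suite runner aggregates these per
component per scheme and flags exceedances of the acceptance threshold
(default RSD < 2.0 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "LinearityResult",
    "RecoveryInput",
    "linearity",
    "rsd_percent",
    "recovery_percent",
    "run_validation_suite",
]


@dataclass(frozen=True)
class LinearityResult:
    """Calibration line area = slope·amount + intercept over [low, high] µg.

    ``r`` is the Pearson correlation coefficient (not R²); it is None when the
    responses carry no variance and correlation is undefined.
    """

    component_id: str
    slope: float
    intercept: float
    r: float | None
    amount_range: tuple[float, float]

    @property
    def r_computable(self) -> bool:
        return self.r is not None


def linearity(amounts: Sequence[float], areas: Sequence[float], component_id: str = "") -> LinearityResult:
    """Ordinary least-squares calibration line through (amount, area) points."""
    amounts = np.asarray(amounts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if amounts.size < 3:
        raise ConfigurationError(f"linearity needs >= 3 points, got {amounts.size}")
    if not np.all(np.diff(amounts) > 0):
        raise ValidationError("amounts must be strictly increasing")
    if np.ptp(areas) == 0.0:
        # flat response: slope 0, correlation undefined
        return LinearityResult(
            component_id=component_id,
            slope=0.0,
            intercept=float(areas[0]),
            r=None,
            amount_range=(float(amounts[0]), float(amounts[-1])),
        )
    fit = stats.linregress(amounts, areas)
    return LinearityResult(
        component_id=component_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        amount_range=(float(amounts[0]), float(amounts[-1])),
    )


def rsd_percent(values: Iterable[float]) -> float:
    """Relative standard deviation, %: sample (n−1) standard deviation over |mean|."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ConfigurationError(f"RSD needs >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0.0:
        raise ValidationError("RSD undefined for zero mean")
    return float(arr.std(ddof=1) / abs(mean) * 100.0)


@dataclass(frozen=True)
class RecoveryInput:
    """Spike-recovery bookkeeping, all in µg: measured total A, endogenous B, spiked C."""

    measured_total: float
    endogenous: float
    spiked: float

    def __post_init__(self) -> None:
        if self.spiked <= 0 or not math.isfinite(self.spiked):
            raise ValidationError(f"spiked amount must be positive, got {self.spiked}")
        if self.measured_total < 0 or self.endogenous < 0:
            raise ValidationError("measured and endogenous amounts must be non-negative")


def recovery_percent(inp: RecoveryInput) -> float:
    """Spike recovery (A − B)/C × 100."""
    return (inp.measured_total - inp.endogenous) / inp.spiked * 100.0


def _area_rsds(tables, components: Sequence[str]) -> dict[str, float]:
    out = {}
    for cid in components:
        out[cid] = rsd_percent([t.get(cid).area for t in tables])
    return out


def run_validation_suite(
    schemes: Mapping[str, object],
    threshold: float = 2.0,
    components: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate validation statistics per scheme and component.

    ``schemes`` maps a scheme name to either a list of replicate
    :class:`~qamskit.peaktable.PeakTable` (area-RSD schemes) or a
    :class:`~qamskit.chromsim.RecoverySet` (recovery). Returns one row per
    (scheme, component, statistic) with a pass flag: RSD statistics pass when
    below ``threshold`` %.
    """
    from .chromsim import RecoverySet  # local import to avoid a cycle

    if not schemes:
        raise ConfigurationError("no validation schemes supplied")
    rows = []
    for scheme, data in schemes.items():
        if isinstance(data, RecoverySet):
            comps = list(components) if components else list(data.endogenous_amounts)
            for cid in comps:
                ref_area = data.reference.get(cid).area
                ref_amount = data.reference_amounts[cid]
                recoveries = []
                for unspiked, spiked in zip(data.unspiked, data.spiked):
                    b = unspiked.get(cid).area / ref_area * ref_amount
                    a = spiked.get(cid).area / ref_area * ref_amount
                    recoveries.append(
                        recovery_percent(
                            RecoveryInput(
                                measured_total=a,
                                endogenous=b,
                                spiked=data.spiked_amounts[cid],
                            )
                        )
                    )
                mean_rec = float(np.mean(recoveries))
                rsd = rsd_percent(recoveries)
                rows.append((scheme, cid, "recovery_percent", mean_rec, True))
                rows.append((scheme, cid, "rsd_percent", rsd, rsd < threshold))
        else:
            tables = list(data)
            if len(tables) < 2:
                raise ConfigurationError(f"scheme {scheme!r}: needs >= 2 replicate tables")
            comps = list(components) if components else tables[0].component_ids
            for cid, rsd in _area_rsds(tables, comps).items():
                rows.append((scheme, cid, "rsd_percent", rsd, rsd < threshold))
    return pd.DataFrame(rows, columns=["scheme", "component_id", "statistic", "value", "passed"])
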