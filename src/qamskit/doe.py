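"""Screening and response-surface experimental designs.

Factors are described by :class:`FactorSpec` (name, unit, low/high actual
levels); the affine coding map sends the low level to −1, the high level to +1
and the midpoint to 0. :class:`DesignMatrix` carries a design in both coded
and actual units plus an optional measured response.

Two constructors are provided: the 12-run Plackett–Burman screening design
(cyclic generator, four assigned factor columns) and the two-factor rotatable
central composite design (2² factorial + axial points at distance alpha +
replicated center points).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "code_level",
    "uncode_level",
    "make_pbd12",
    "make_ccd",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its actual-unit range."""

    name: str
    unit: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigurationError(
                f"factor {self.name!r}: low must be < high, got [{self.low}, {self.high}]"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, actual):
        return (np.asarray(actual, dtype=float) - self.center) / self.half_range

    def uncode(self, coded):
        return self.center + np.asarray(coded, dtype=float) * self.half_range


def code_level(spec: FactorSpec, actual: float) -> float:
    """Map an actual level to coded units ((actual − center)/half-range)."""
    return float(spec.code(actual))


def uncode_level(spec: FactorSpec, coded: float) -> float:
    """Exact inverse of :func:`code_level`."""
    return float(spec.uncode(coded))


class DesignMatrix:
    """A run list in coded units, with actual units derived through the factor specs."""

    def __init__(
        self,
        factors: Sequence[FactorSpec],
        coded: np.ndarray,
        response: np.ndarray | None = None,
    ) -> None:
        self.factors = tuple(factors)
        self.coded = np.atleast_2d(np.asarray(coded, dtype=float))
        if self.coded.shape[1] != len(self.factors):
            raise ConfigurationError(
                f"coded matrix has {self.coded.shape[1]} columns for {len(self.factors)} factors"
            )
        if response is not None:
            response = np.asarray(response, dtype=float)
            if response.shape != (self.n_runs,):
                raise ConfigurationError(
                    f"response length {response.shape} does not match {self.n_runs} runs"
                )
        self.response = response

    @classmethod
    def from_actual(
        cls,
        factors: Sequence[FactorSpec],
        actual: np.ndarray,
        response: np.ndarray | None = None,
    ) -> "DesignMatrix":
        actual = np.atleast_2d(np.asarray(actual, dtype=float))
        coded = np.column_stack([spec.code(actual[:, j]) for j, spec in enumerate(factors)])
        return cls(factors, coded, response)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(spec.name for spec in self.factors)

    @property
    def actual(self) -> np.ndarray:
        return np.column_stack(
            [spec.uncode(self.coded[:, j]) for j, spec in enumerate(self.factors)]
        )

    def with_response(self, response) -> "DesignMatrix":
        return DesignMatrix(self.factors, self.coded, np.asarray(response, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.actual, columns=list(self.factor_names))
        df.insert(0, "run", np.arange(1, self.n_runs + 1))
        for j, spec in enumerate(self.factors):
            df[f"coded_{spec.name}"] = self.coded[:, j]
        if self.response is not None:
            df["response"] = self.response
        return df

    def to_runsheet(self, path: str | Path) -> Path:
        """Write one row per run: actual levels plus response when present."""
        path = Path(path)
        df = pd.DataFrame(self.actual, columns=list(self.factor_names))
        if self.response is not None:
            df["response"] = self.response
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_runsheet(cls, path: str | Path, factors: Sequence[FactorSpec]) -> "DesignMatrix":
        df = pd.read_csv(path)
        missing = [spec.name for spec in factors if spec.name not in df.columns]
        if missing:
            raise FormatError(f"{path}: run sheet lacks factor column(s) {missing}")
        actual = df[[spec.name for spec in factors]].to_numpy(dtype=float)
        response = df["response"].to_numpy(dtype=float) if "response" in df.columns else None
        return cls.from_actual(factors, actual, response)


# First row of the cyclic PB12 generator (Plackett & Burman's k=11 sequence).
_PB12_GENERATOR = np.array([+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1])


def make_pbd12(factors: Sequence[FactorSpec]) -> DesignMatrix:
    """12-run Plackett–Burman screening design for exactly four factors.

    Built from the standard cyclic generator (11 cyclic shifts plus the
    all-minus run); the four factors occupy the first four columns. Each
    column is balanced (six +1, six −1) and all columns are mutually
    orthogonal.
    """
    if len(factors) != 4:
        raise ConfigurationError(f"PB12 screening expects exactly 4 factors, got {len(factors)}")
    rows = [np.roll(_PB12_GENERATOR, shift) for shift in range(11)]
    rows.append(-np.ones(11, dtype=int))
    full = np.array(rows, dtype=float)
    return DesignMatrix(factors, full[:, : len(factors)])


def make_ccd(
    factors: Sequence[FactorSpec],
    alpha: float = 1.414,
    n_center: int = 5,
) -> DesignMatrix:
    """Two-factor central composite design: 4 factorial + 4 axial + n_center runs.

    ``alpha`` is the axial distance in coded units; 1.414 gives the rotatable
    design (axial levels such as 72.07 / 57.93 % methanol for a 60–70 range).
    Standard run order: factorial, axial, center.
    """
    if len(factors) != 2:
        raise ConfigurationError(f"CCD construction expects exactly 2 factors, got {len(factors)}")
    if alpha <= 0:
        raise ConfigurationError(f"alpha must be positive, got {alpha}")
    if n_center < 1:
        raise ConfigurationError(f"n_center must be >= 1, got {n_center}")
    factorial = [(-1, -1), (+1, -1), (-1, +1), (+1, +1)]
    axial = [(-alpha, 0), (+alpha, 0), (0, -alpha), (0, +alpha)]
    center = [(0, 0)] * n_center
    coded = np.array(factorial + axial + center, dtype=float)
    return DesignMatrix(factors, coded)


def screening_factors() -> tuple[FactorSpec, ...]:
    """The four screened chromatographic factors and their studied ranges."""
    return (
        FactorSpec("methanol_fraction", "% v/v", 60.0, 70.0),
        FactorSpec("flow_rate", "mL/min", 0.8, 1.2),
        FactorSpec("column_temperature", "degC", 20.0, 30.0),
        FactorSpec("injection_volume", "uL", 5.0, 15.0),
    )


def rsm_factors() -> tuple[FactorSpec, ...]:
    """The two critical factors carried into response-surface optimization."""
    return (
        FactorSpec("methanol_fraction", "% v/v", 60.0, 70.0),
        FactorSpec("column_temperature", "degC", 20.0, 30.0),
    )
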