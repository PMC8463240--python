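"""Synthetic HPLC chromatography for the three Euphorbia lathyris diterpenoids.

The generator produces integrated peak tables (never raw signal traces) with
the statistical structure the downstream analyses assume:

* isocratic reversed-phase retention: ``tR = t0·(1 + k)/flow`` with
  ``ln k = c0 − S·φ + c2·(1/T − 1/T_ref)`` — a linear solvent-strength term in
  the methanol fraction φ (% v/v) and a van 't Hoff temperature term
  (T in kelvin). ``S > 0`` so retention falls as the mobile phase gets
  stronger, and ``c2 > 0`` so it falls with rising column temperature;
  together these make the L1/L4 resolution decrease monotonically in both
  critical factors.
* Gaussian peaks on a constant plate count N, baseline width
  ``w = 4·tR/√N``, USP resolution ``Rs = 2·ΔtR/(w1 + w2)``.
* detector areas linear in injected amount with per-component response
  factors, corrupted by multiplicative noise ``area·(1 + ε)``,
  ``ε ~ N(0, noise_cv)`` truncated at −3σ so areas stay positive.

The default calibration anchors the model to the study's observables: at
60 % methanol / 30 °C the relative retentions L3/L1 and L4/L1 are 0.5728 and
1.1271, the L1–L4 resolution is 2.30, and the response factors equal the
calibration-curve slopes (area units per µg). Elution order L3 < L1 < L4
holds across the whole studied factor region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .doe import DesignMatrix
from .exceptions import ComponentLookupError, ConfigurationError, ValidationError
from .peaktable import PeakRecord, PeakTable, ReferenceStandard, RunConditions, write_peak_table

__all__ = [
    "ComponentKinetics",
    "ChromatographyModel",
    "SimulatedCampaign",
    "RecoverySet",
    "default_model",
    "retention_time",
    "peak_width",
    "resolution",
    "pair_resolution",
    "reference_amounts",
    "simulate_peak_table",
    "simulate_doe_campaign",
    "simulate_validation_set",
    "VALIDATION_SCHEMES",
]

T_REF_K = 298.15  # reference temperature for the van 't Hoff term
FLOW_REF = 1.0  # mL/min at which t0 is specified


@dataclass(frozen=True)
class ComponentKinetics:
    """Retention and response parameters of one component.

    ``c0`` is the ln-retention-factor intercept, ``solvent_slope`` the decrease
    of ln k per % methanol (must be positive), ``vant_hoff`` the coefficient of
    (1/T − 1/T_ref) in kelvin, and ``response_factor`` the detector area per µg
    injected.
    """

    c0: float
    solvent_slope: float
    vant_hoff: float
    response_factor: float

    def __post_init__(self) -> None:
        if self.solvent_slope <= 0:
            raise ValidationError("solvent_slope must be positive (retention falls with methanol)")
        if self.response_factor <= 0:
            raise ValidationError("response_factor must be positive")


@dataclass(frozen=True)
class ChromatographyModel:
    """Parametric chromatograph: dead time, plate count, per-component kinetics, noise."""

    t0: float
    plate_count: float
    components: Mapping[str, ComponentKinetics]
    noise_cv: float = 0.01
    rt_jitter_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValidationError(f"t0 must be positive, got {self.t0}")
        if self.plate_count <= 0:
            raise ValidationError(f"plate_count must be positive, got {self.plate_count}")
        if self.noise_cv < 0 or self.rt_jitter_cv < 0:
            raise ValidationError("noise coefficients of variation must be non-negative")

    def kinetics(self, component_id: str) -> ComponentKinetics:
        try:
            return self.components[component_id]
        except KeyError:
            raise ComponentLookupError(component_id) from None

    def rng(self, seed: int | None = None) -> np.random.Generator:
        return np.random.default_rng(self.seed if seed is None else seed)


# Calibration anchors at 60 % methanol, 30 degC, 1.0 mL/min: L1 retained
# 10.0 min with relative retentions 0.5728 (L3) and 1.1271 (L4), and
# Rs(L1, L4) = 2.30. Response factors are the calibration-curve slopes.
_ANCHOR_PHI = 60.0
_ANCHOR_T_C = 30.0
_ANCHOR_TR = {"L3": 0.5728 * 10.0, "L1": 10.0, "L4": 1.1271 * 10.0}
_RESPONSE_FACTORS = {"L1": 1244.6, "L3": 1516.8, "L4": 597.4}
_ANCHOR_RESOLUTION = 2.30
_DEFAULT_T0 = 2.5
_DEFAULT_SOLVENT_SLOPE = 0.09  # per % methanol
_DEFAULT_VANT_HOFF = 2000.0  # kelvin


def _plate_count_for_anchor() -> float:
    t1, t4 = _ANCHOR_TR["L1"], _ANCHOR_TR["L4"]
    sqrt_n = 2.0 * _ANCHOR_RESOLUTION * (t1 + t4) / (t4 - t1)
    return sqrt_n**2


def default_model(noise_cv: float = 0.01, rt_jitter_cv: float = 0.0, seed: int | None = None) -> ChromatographyModel:
    """The default calibrated simulator (see module docstring for the anchors)."""
    anchor_shift = _DEFAULT_VANT_HOFF * (1.0 / (_ANCHOR_T_C + 273.15) - 1.0 / T_REF_K)
    components = {}
    for cid, tr in _ANCHOR_TR.items():
        k_anchor = tr / _DEFAULT_T0 - 1.0
        c0 = math.log(k_anchor) + _DEFAULT_SOLVENT_SLOPE * _ANCHOR_PHI - anchor_shift
        components[cid] = ComponentKinetics(
            c0=c0,
            solvent_slope=_DEFAULT_SOLVENT_SLOPE,
            vant_hoff=_DEFAULT_VANT_HOFF,
            response_factor=_RESPONSE_FACTORS[cid],
        )
    return ChromatographyModel(
        t0=_DEFAULT_T0,
        plate_count=_plate_count_for_anchor(),
        components=components,
        noise_cv=noise_cv,
        rt_jitter_cv=rt_jitter_cv,
        seed=seed,
    )


def retention_time(
    model: ChromatographyModel, component_id: str, conditions: RunConditions
) -> float:
    """Deterministic retention time (min) of one component under given conditions."""
    kin = model.kinetics(component_id)
    t_kelvin = conditions.column_temperature + 273.15
    ln_k = (
        kin.c0
        - kin.solvent_slope * conditions.methanol_fraction
        + kin.vant_hoff * (1.0 / t_kelvin - 1.0 / T_REF_K)
    )
    k = math.exp(ln_k)
    return model.t0 * (1.0 + k) * FLOW_REF / conditions.flow_rate


def peak_width(model: ChromatographyModel, component_id: str, conditions: RunConditions) -> float:
    """Baseline (4σ) peak width in minutes: w = 4·tR/√N."""
    return 4.0 * retention_time(model, component_id, conditions) / math.sqrt(model.plate_count)


def resolution(tr1: float, w1: float, tr2: float, w2: float) -> float:
    """USP resolution 2·(tR2 − tR1)/(w1 + w2) between two peaks (tR2 ≥ tR1)."""
    if w1 <= 0 or w2 <= 0:
        raise ValidationError(f"peak widths must be positive, got {w1}, {w2}")
    if tr2 < tr1:
        raise ValidationError(f"tr2 must be >= tr1, got {tr1} > {tr2}")
    return 2.0 * (tr2 - tr1) / (w1 + w2)


def pair_resolution(
    model: ChromatographyModel,
    conditions: RunConditions,
    pair: tuple[str, str] = ("L1", "L4"),
) -> float:
    """Noise-free resolution between a component pair (ordered by retention internally)."""
    a, b = pair
    tra, trb = retention_time(model, a, conditions), retention_time(model, b, conditions)
    if tra > trb:
        a, b = b, a
        tra, trb = trb, tra
    return resolution(tra, peak_width(model, a, conditions), trb, peak_width(model, b, conditions))


def reference_amounts(
    standards: Mapping[str, ReferenceStandard], injection_volume: float
) -> dict[str, float]:
    """Injected amount (µg) per component: concentration (mg/mL) × volume (µL)."""
    return {cid: std.concentration * injection_volume for cid, std in standards.items()}


def _truncated_relative_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.zeros(size)
    eps = rng.normal(0.0, cv, size=size)
    return np.clip(eps, -3.0 * cv, None)


def simulate_peak_table(
    model: ChromatographyModel,
    conditions: RunConditions,
    amounts: Mapping[str, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PeakTable:
    """One simulated run: areas = RF·amount·(1 + ε), reproducible under a seed.

    Retention times are deterministic unless the model carries retention
    jitter (``rt_jitter_cv``), in which case each tR is scattered
    multiplicatively as well.
    """
    for cid, amount in amounts.items():
        if amount < 0:
            raise ValidationError(f"negative injected amount for {cid!r}: {amount}")
    if rng is None:
        rng = model.rng(seed)
    ids = list(amounts)
    area_eps = _truncated_relative_noise(rng, model.noise_cv, len(ids))
    rt_eps = _truncated_relative_noise(rng, model.rt_jitter_cv, len(ids))
    peaks = []
    for j, cid in enumerate(ids):
        tr = retention_time(model, cid, conditions) * (1.0 + rt_eps[j])
        area = model.kinetics(cid).response_factor * amounts[cid] * (1.0 + area_eps[j])
        peaks.append(PeakRecord(component_id=cid, retention_time=tr, area=area))
    return PeakTable(conditions=conditions, peaks=peaks)


@dataclass
class SimulatedCampaign:
    """A simulated DoE campaign: the design with responses plus one run each."""

    design: DesignMatrix
    peak_tables: list[PeakTable]
    responses: np.ndarray

    def write(self, directory: str | Path) -> Path:
        """Emit a run-sheet CSV plus one peak-table file per run."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.design.to_runsheet(directory / "runsheet.csv")
        for i, table in enumerate(self.peak_tables, start=1):
            write_peak_table(table, directory / f"run_{i:02d}.csv")
        return directory


def _conditions_from_design_row(
    design: DesignMatrix, row: int, defaults: RunConditions
) -> RunConditions:
    values = dict(zip(design.factor_names, design.actual[row]))
    required = {"methanol_fraction", "column_temperature"}
    if not required.issubset(values):
        raise ConfigurationError(
            f"design lacks required factor(s) {sorted(required - set(values))}"
        )
    return replace(
        defaults,
        methanol_fraction=values["methanol_fraction"],
        column_temperature=values["column_temperature"],
        flow_rate=values.get("flow_rate", defaults.flow_rate),
        injection_volume=values.get("injection_volume", defaults.injection_volume),
    )


def simulate_doe_campaign(
    model: ChromatographyModel,
    design: DesignMatrix,
    pair: tuple[str, str] = ("L1", "L4"),
    standards: Mapping[str, ReferenceStandard] | None = None,
    seed: int | None = None,
) -> SimulatedCampaign:
    """Simulate every run of a design and measure the pair resolution response.

    The measured response is the model resolution times multiplicative noise
    ``(1 + ε)`` with the model's ``noise_cv``; with noise off the campaign is a
    deterministic function of the conditions.
    """
    from .fixtures import default_standards

    standards = standards if standards is not None else default_standards()
    rng = model.rng(seed)
    defaults = RunConditions(methanol_fraction=65.0, column_temperature=25.0)
    tables: list[PeakTable] = []
    responses = np.empty(design.n_runs)
    for i in range(design.n_runs):
        conditions = _conditions_from_design_row(design, i, defaults)
        amounts = reference_amounts(standards, conditions.injection_volume)
        tables.append(simulate_peak_table(model, conditions, amounts, rng=rng))
        rs = pair_resolution(model, conditions, pair)
        eps = float(_truncated_relative_noise(rng, model.noise_cv, 1)[0])
        responses[i] = rs * (1.0 + eps)
    return SimulatedCampaign(design.with_response(responses), tables, responses)


VALIDATION_SCHEMES = ("stability", "repeatability", "precision", "recovery")


@dataclass
class RecoverySet:
    """Paired spike-recovery runs with the bookkeeping needed to score them.

    ``reference`` is a run of the mixed standard used for single-point
    quantification; ``unspiked``/``spiked`` are paired sample runs; amounts
    are in µg injected.
    """

    reference: PeakTable
    unspiked: list[PeakTable]
    spiked: list[PeakTable]
    reference_amounts: dict[str, float]
    endogenous_amounts: dict[str, float]
    spiked_amounts: dict[str, float]


def simulate_validation_set(
    model: ChromatographyModel,
    scheme: str,
    n: int,
    conditions: RunConditions | None = None,
    standards: Mapping[str, ReferenceStandard] | None = None,
    seed: int | None = None,
):
    """Replicate runs for one validation scheme.

    ``stability``/``repeatability``/``precision`` return ``n`` peak tables of
    the same solution differing only through the area noise model.
    ``recovery`` returns a :class:`RecoverySet` of paired unspiked/spiked
    sample runs (spike equal to the endogenous level, mimicking a 100 %
    spike) plus a reference run.
    """
    from .fixtures import default_standards

    if scheme not in VALIDATION_SCHEMES:
        raise ConfigurationError(
            f"unknown validation scheme {scheme!r}; expected one of {VALIDATION_SCHEMES}"
        )
    if n < 2:
        raise ConfigurationError(f"validation needs at least 2 replicates, got {n}")
    standards = standards if standards is not None else default_standards()
    if conditions is None:
        conditions = RunConditions(methanol_fraction=60.0, column_temperature=30.0)
    rng = model.rng(seed)
    ref_amounts = reference_amounts(standards, conditions.injection_volume)

    if scheme != "recovery":
        return [
            simulate_peak_table(model, conditions, ref_amounts, rng=rng) for _ in range(n)
        ]

    # endogenous level chosen at the reference level; spike adds the same again
    endogenous = dict(ref_amounts)
    spiked = {cid: endogenous[cid] + ref_amounts[cid] for cid in ref_amounts}
    return RecoverySet(
        reference=simulate_peak_table(model, conditions, ref_amounts, rng=rng),
        unspiked=[
            simulate_peak_table(model, conditions, endogenous, rng=rng) for _ in range(n)
        ],
        spiked=[simulate_peak_table(model, conditions, spiked, rng=rng) for _ in range(n)],
        reference_amounts=ref_amounts,
        endogenous_amounts=endogenous,
        spiked_amounts=ref_amounts,
    )
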