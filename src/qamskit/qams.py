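"""Single-marker quantification (QAMS) calculus.

One component — euphorbia factor L1 by default — serves as the internal
reference ("marker"). A relative correction factor links the marker's detector
response to each analyte's:

    f_si = f_s / f_i = (A_s / C_s) / (A_i / C_i)

so an analyte's concentration in a sample follows from its own peak area, the
marker's single-point reference calibration and the pre-established f̄_si,
without injecting the analyte's reference standard. Analyte peaks are located
by relative retention time (tR_i / tR_marker) within a tolerance window.
External-standard quantification and a method-comparison report are provided
for cross-validation: when f_si is derived from the same reference injection
that supplies the marker calibration, QAMS and external-standard contents are
algebraically identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ComponentLookupError, ConfigurationError, ValidationError
from .peaktable import PeakRecord, PeakTable, ReferenceStandard, SamplePrep
from .validation import rsd_percent

__all__ = [
    "DEFAULT_MARKER",
    "CorrectionFactor",
    "CorrectionFactorSet",
    "RelativeRetentionSummary",
    "ContentResult",
    "PeakAssignment",
    "correction_factor",
    "summarize_factors",
    "relative_retention",
    "summarize_relative_retention",
    "find_marker",
    "locate_peaks",
    "content_external",
    "content_qams",
    "compare_methods",
    "pairs_from_contents_table",
]

DEFAULT_MARKER = "L1"


@dataclass(frozen=True)
class CorrectionFactor:
    """One relative correction factor f_si under a labelled condition."""

    marker_id: str
    analyte_id: str
    value: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value <= 0:
            raise ValidationError(f"correction factor must be positive, got {self.value!r}")


@dataclass(frozen=True)
class CorrectionFactorSet:
    """f_si across conditions with its mean and reproducibility RSD."""

    marker_id: str
    analyte_id: str
    factors: tuple[CorrectionFactor, ...]
    mean: float
    rsd_percent: float


@dataclass(frozen=True)
class RelativeRetentionSummary:
    """Relative retention tR_analyte/tR_marker across conditions."""

    analyte_id: str
    values: tuple[float, ...]
    mean: float
    rsd_percent: float
    tolerance_percent: float = 5.0


@dataclass(frozen=True)
class ContentResult:
    """Percent content (mg per 100 mg dried powder) of one component."""

    component_id: str
    method: str  # "qams" or "external_standard"
    percent_content: float
    replicate_sd: float | None = None
    batch: str = ""

    def __post_init__(self) -> None:
        if self.percent_content < 0:
            raise ValidationError("percent content cannot be negative")


def _response_per_concentration(run: PeakTable, standards: Mapping[str, ReferenceStandard], cid: str) -> float:
    peak = run.get(cid)
    if cid not in standards:
        raise ComponentLookupError(cid)
    conc = standards[cid].concentration
    if peak.area <= 0:
        raise ValidationError(f"zero/negative area for {cid!r} in reference run")
    return peak.area / conc


def correction_factor(
    reference_run: PeakTable,
    standards: Mapping[str, ReferenceStandard],
    marker_id: str = DEFAULT_MARKER,
    analyte_id: str = "",
    condition: str = "",
) -> CorrectionFactor:
    """f_si = (A_s/C_s)/(A_i/C_i) from one mixed-standard injection."""
    if not analyte_id:
        raise ConfigurationError("analyte_id is required")
    fs = _response_per_concentration(reference_run, standards, marker_id)
    fi = _response_per_concentration(reference_run, standards, analyte_id)
    return CorrectionFactor(
        marker_id=marker_id, analyte_id=analyte_id, value=fs / fi, condition=condition
    )


def summarize_factors(factors: Sequence[CorrectionFactor]) -> CorrectionFactorSet:
    """Mean and (n−1) RSD of f_si replicated across conditions."""
    if len(factors) < 2:
        raise ConfigurationError("need >= 2 correction factors to summarize")
    pairs = {(f.marker_id, f.analyte_id) for f in factors}
    if len(pairs) != 1:
        raise ConfigurationError(f"mixed marker/analyte pairs in one summary: {sorted(pairs)}")
    values = [f.value for f in factors]
    return CorrectionFactorSet(
        marker_id=factors[0].marker_id,
        analyte_id=factors[0].analyte_id,
        factors=tuple(factors),
        mean=float(np.mean(values)),
        rsd_percent=rsd_percent(values),
    )


def relative_retention(sample_run: PeakTable, marker_id: str = DEFAULT_MARKER) -> dict[str, float]:
    """tR_i / tR_marker for every non-marker component in the run."""
    marker = sample_run.get(marker_id)
    return {
        p.component_id: p.retention_time / marker.retention_time
        for p in sample_run
        if p.component_id != marker_id
    }


def summarize_relative_retention(
    analyte_id: str, values: Sequence[float], tolerance_percent: float = 5.0
) -> RelativeRetentionSummary:
    if len(values) < 2:
        raise ConfigurationError("need >= 2 relative retentions to summarize")
    return RelativeRetentionSummary(
        analyte_id=analyte_id,
        values=tuple(float(v) for v in values),
        mean=float(np.mean(values)),
        rsd_percent=rsd_percent(values),
        tolerance_percent=tolerance_percent,
    )


def find_marker(
    run: PeakTable, expected_retention: float, tolerance_percent: float = 5.0
) -> PeakRecord:
    """Identify the marker peak: largest area within the tolerance window of its time."""
    window = [
        p
        for p in run
        if abs(p.retention_time / expected_retention - 1.0) * 100.0 <= tolerance_percent
    ]
    if not window:
        raise ComponentLookupError(
            f"no peak within {tolerance_percent}% of {expected_retention} min"
        )
    return max(window, key=lambda p: p.area)


@dataclass(frozen=True)
class PeakAssignment:
    """Result of relative-retention peak localization."""

    marker_retention: float
    assigned: dict[str, PeakRecord]
    unassigned: tuple[str, ...]


def locate_peaks(
    sample_run: PeakTable,
    marker_retention: float,
    expected: Mapping[str, float] | Sequence[RelativeRetentionSummary],
    tolerance_percent: float = 5.0,
) -> PeakAssignment:
    """Assign analyte identities to unlabeled peaks by relative retention.

    ``expected`` maps analyte id to its expected relative retention (or is a
    list of :class:`RelativeRetentionSummary`, whose means are used). Matching
    is global nearest-first greedy: all (analyte, peak) pairs whose observed
    relative retention lies within the tolerance window are ranked by relative
    error and assigned in order, each peak and analyte at most once. Analytes
    left without a candidate are reported unassigned.
    """
    if marker_retention <= 0:
        raise ValidationError("marker retention must be positive")
    if not isinstance(expected, Mapping):
        expected = {s.analyte_id: s.mean for s in expected}
    candidates = []
    for analyte, exp_rrt in expected.items():
        for i, peak in enumerate(sample_run):
            observed = peak.retention_time / marker_retention
            err = abs(observed / exp_rrt - 1.0) * 100.0
            if err <= tolerance_percent:
                candidates.append((err, analyte, i))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    assigned: dict[str, PeakRecord] = {}
    used: set[int] = set()
    for err, analyte, i in candidates:
        if analyte in assigned or i in used:
            continue
        assigned[analyte] = sample_run.peaks[i]
        used.add(i)
    unassigned = tuple(a for a in expected if a not in assigned)
    return PeakAssignment(
        marker_retention=marker_retention, assigned=assigned, unassigned=unassigned
    )


def _percent_content(conc_mg_per_ml: float, prep: SamplePrep) -> float:
    """mg/mL of extract → % w/w of the dried powder (mass in g, volume in mL)."""
    return conc_mg_per_ml * prep.extract_volume / (prep.sample_mass * 1000.0) * 100.0


def _check_injection_match(sample_run: PeakTable, reference_run: PeakTable) -> None:
    vs = sample_run.conditions.injection_volume
    vr = reference_run.conditions.injection_volume
    if not math.isclose(vs, vr, rel_tol=1e-9):
        raise ValidationError(
            f"injection volumes differ (sample {vs} µL vs reference {vr} µL); "
            "single-point calibration requires equal volumes"
        )


def content_external(
    sample_run: PeakTable,
    reference_run: PeakTable,
    standards: Mapping[str, ReferenceStandard],
    prep: SamplePrep,
    component_id: str,
    batch: str = "",
) -> ContentResult:
    """Percent content by single-point external-standard calibration."""
    _check_injection_match(sample_run, reference_run)
    a_sample = sample_run.get(component_id).area
    a_ref = reference_run.get(component_id).area
    if a_ref <= 0:
        raise ValidationError(f"zero reference area for {component_id!r}")
    if component_id not in standards:
        raise ComponentLookupError(component_id)
    conc = a_sample / a_ref * standards[component_id].concentration
    return ContentResult(
        component_id=component_id,
        method="external_standard",
        percent_content=_percent_content(conc, prep),
        batch=batch,
    )


def content_qams(
    sample_run: PeakTable,
    reference_run: PeakTable,
    standards: Mapping[str, ReferenceStandard],
    prep: SamplePrep,
    component_id: str,
    marker_id: str = DEFAULT_MARKER,
    factor: CorrectionFactorSet | CorrectionFactor | float | None = None,
    batch: str = "",
) -> ContentResult:
    """Percent content by the single-marker method.

    ``C_i = A_i,sample · f̄_si · C_marker,ref / A_marker,ref``. Only the
    marker's peak in the reference run is used. When ``factor`` is omitted,
    f_si is computed from the same reference injection — in that case the
    marker calibration cancels and the result equals the external-standard
    content exactly.
    """
    _check_injection_match(sample_run, reference_run)
    if factor is None:
        f_value = correction_factor(
            reference_run, standards, marker_id=marker_id, analyte_id=component_id
        ).value
    elif isinstance(factor, CorrectionFactorSet):
        f_value = factor.mean
    elif isinstance(factor, CorrectionFactor):
        f_value = factor.value
    else:
        f_value = float(factor)
    a_sample = sample_run.get(component_id).area
    a_marker_ref = reference_run.get(marker_id).area
    if a_marker_ref <= 0:
        raise ValidationError(f"zero marker reference area for {marker_id!r}")
    if marker_id not in standards:
        raise ComponentLookupError(marker_id)
    conc = a_sample * f_value * standards[marker_id].concentration / a_marker_ref
    return ContentResult(
        component_id=component_id,
        method="qams",
        percent_content=_percent_content(conc, prep),
        batch=batch,
    )


def compare_methods(
    pairs: Sequence[tuple[ContentResult, ContentResult]],
    flag_threshold_percent: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise QAMS vs external-standard comparison.

    Each pair is (QAMS result, external-standard result) for the same batch
    and component. Returns a per-pair table (with a flag for relative
    differences above the threshold, default 2 %) and a per-component summary
    (mean absolute difference and RSD of the relative differences).
    """
    if not pairs:
        raise ConfigurationError("no paired results to compare")
    rows = []
    for qams_res, ext_res in pairs:
        if qams_res.component_id != ext_res.component_id or qams_res.batch != ext_res.batch:
            raise ConfigurationError(
                f"unpaired results: {qams_res.component_id}/{qams_res.batch} vs "
                f"{ext_res.component_id}/{ext_res.batch}"
            )
        if {qams_res.method, ext_res.method} != {"qams", "external_standard"}:
            raise ConfigurationError("each pair must hold one qams and one external result")
        diff = qams_res.percent_content - ext_res.percent_content
        rel = abs(diff) / ext_res.percent_content * 100.0 if ext_res.percent_content else np.nan
        rows.append(
            {
                "batch": qams_res.batch,
                "component_id": qams_res.component_id,
                "qams_percent": qams_res.percent_content,
                "external_percent": ext_res.percent_content,
                "difference": diff,
                "relative_difference_percent": rel,
                "flagged": bool(rel > flag_threshold_percent),
            }
        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("component_id")
        .agg(
            mean_abs_difference=("difference", lambda d: float(np.mean(np.abs(d)))),
            max_relative_difference_percent=("relative_difference_percent", "max"),
            rsd_of_relative_differences=(
                "relative_difference_percent",
                lambda d: float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
            ),
            n_flagged=("flagged", "sum"),
        )
        .reset_index()
    )
    return table, summary


def pairs_from_contents_table(df: pd.DataFrame) -> list[tuple[ContentResult, ContentResult]]:
    """Build comparison pairs from a batch-contents table (L3/L4, both methods)."""
    pairs = []
    for _, row in df.iterrows():
        for cid in ("L3", "L4"):
            pairs.append(
                (
                    ContentResult(
                        component_id=cid,
                        method="qams",
                        percent_content=float(row[f"l{cid[1]}_qams_mean"]),
                        replicate_sd=float(row[f"l{cid[1]}_qams_sd"]),
                        batch=str(row["batch"]),
                    ),
                    ContentResult(
                        component_id=cid,
                        method="external_standard",
                        percent_content=float(row[f"l{cid[1]}_es_mean"]),
                        replicate_sd=float(row[f"l{cid[1]}_es_sd"]),
                        batch=str(row["batch"]),
                    ),
                )
            )
    return pairs
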