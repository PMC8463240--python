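"""Domain data model and plain-text I/O for integrated chromatographic runs.

A run is carried as a :class:`PeakTable`: the chromatographic conditions it was
acquired under plus one :class:`PeakRecord` per integrated peak, sorted by
retention time. The on-disk format is delimited text with a ``#``-prefixed
``key: value`` header holding the conditions — human-auditable, diff-friendly,
and round-trips to 12 significant digits. Units are fixed package-wide:
minutes, °C, mL/min, µL, mg/mL, % v/v.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .exceptions import ComponentLookupError, FormatError, ValidationError

__all__ = [
    "PeakRecord",
    "RunConditions",
    "PeakTable",
    "ReferenceStandard",
    "SamplePrep",
    "read_peak_table",
    "write_peak_table",
    "load_standards",
    "load_sample_prep",
]


@dataclass(frozen=True)
class PeakRecord:
    """One integrated peak: component label, retention time (min), area (detector units)."""

    component_id: str
    retention_time: float
    area: float

    def __post_init__(self) -> None:
        if not self.component_id:
            raise ValidationError("component_id must be a non-empty string")
        if not math.isfinite(self.retention_time) or self.retention_time <= 0:
            raise ValidationError(
                f"retention_time must be finite and positive, got {self.retention_time!r}"
            )
        if not math.isfinite(self.area) or self.area < 0:
            raise ValidationError(f"area must be finite and non-negative, got {self.area!r}")


@dataclass(frozen=True)
class RunConditions:
    """Chromatographic conditions of a single run.

    ``methanol_fraction`` is the methanol proportion of the mobile phase in
    % v/v, ``column_temperature`` in °C, ``flow_rate`` in mL/min and
    ``injection_volume`` in µL. ``column_id`` / ``instrument_id`` identify the
    hardware for reproducibility studies and may be empty.
    """

    methanol_fraction: float
    column_temperature: float
    flow_rate: float = 1.0
    injection_volume: float = 10.0
    column_id: str = ""
    instrument_id: str = ""

    def __post_init__(self) -> None:
        for name in ("methanol_fraction", "column_temperature", "flow_rate", "injection_volume"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be finite and positive, got {value!r}")
        if self.methanol_fraction > 100:
            raise ValidationError(
                f"methanol_fraction is a percentage, got {self.methanol_fraction!r} > 100"
            )


_NUMERIC_CONDITION_FIELDS = (
    "methanol_fraction",
    "column_temperature",
    "flow_rate",
    "injection_volume",
)
_TEXT_CONDITION_FIELDS = ("column_id", "instrument_id")


@dataclass
class PeakTable:
    """An ordered, validated collection of peaks from one run.

    Peaks are stored sorted by retention time; duplicate component ids and
    tied retention times are rejected (a tie means two co-eluting labels,
    which integration software would not emit).
    """

    conditions: RunConditions
    peaks: list[PeakRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.retention_time)
        seen: set[str] = set()
        for prev, nxt in zip(self.peaks, self.peaks[1:]):
            if nxt.retention_time == prev.retention_time:
                raise ValidationError(
                    f"tied retention times at {prev.retention_time} min "
                    f"({prev.component_id!r} / {nxt.component_id!r})"
                )
        for peak in self.peaks:
            if peak.component_id in seen:
                raise ValidationError(f"duplicate component {peak.component_id!r} in one run")
            seen.add(peak.component_id)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def component_ids(self) -> list[str]:
        return [p.component_id for p in self.peaks]

    def get(self, component_id: str) -> PeakRecord:
        for peak in self.peaks:
            if peak.component_id == component_id:
                return peak
        raise ComponentLookupError(component_id)

    def __contains__(self, component_id: str) -> bool:
        return any(p.component_id == component_id for p in self.peaks)

    def anonymized(self, prefix: str = "peak") -> "PeakTable":
        """Copy with component labels replaced by positional names (for localization tests)."""
        return PeakTable(
            conditions=self.conditions,
            peaks=[replace(p, component_id=f"{prefix}{i + 1}") for i, p in enumerate(self.peaks)],
        )


@dataclass(frozen=True)
class ReferenceStandard:
    """A reference substance at a known concentration (mg/mL) in the mixed standard."""

    component_id: str
    concentration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration <= 0:
            raise ValidationError(
                f"concentration must be positive, got {self.concentration!r}"
            )


@dataclass(frozen=True)
class SamplePrep:
    """Extraction constants: powder mass (g) taken into extract volume (mL)."""

    sample_mass: float
    extract_volume: float

    def __post_init__(self) -> None:
        for name in ("sample_mass", "extract_volume"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be positive, got {value!r}")


# ---------------------------------------------------------------------------
# delimited-text I/O


def _sniff_delimiter(line: str, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in (",", "\t"):
            raise FormatError(f"unsupported delimiter {dialect!r} (use ',' or tab)")
        return dialect
    return "\t" if "\t" in line else ","


def read_peak_table(path: str | Path, dialect: str | None = None) -> PeakTable:
    """Read a peak table from delimited text with a ``#`` key:value header.

    ``dialect`` may force the delimiter (``","`` or ``"\\t"``); by default it is
    sniffed from the column-header line. Comma is the package default, tab is
    accepted.
    """
    path = Path(path)
    header: dict[str, str] = {}
    body: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, sep, value = line.lstrip("#").partition(":")
            if sep:
                header[key.strip()] = value.strip()
        else:
            body.append(line)
    if not body:
        raise FormatError(f"{path}: no column header found")

    delim = _sniff_delimiter(body[0], dialect)
    columns = [c.strip() for c in body[0].split(delim)]
    required = {"component_id", "retention_time", "area"}
    if not required.issubset(columns):
        raise FormatError(
            f"{path}: missing required column(s) {sorted(required - set(columns))}"
        )
    idx = {name: columns.index(name) for name in required}

    kwargs: dict[str, object] = {}
    for name in _NUMERIC_CONDITION_FIELDS:
        if name in header:
            try:
                kwargs[name] = float(header[name])
            except ValueError as exc:
                raise FormatError(f"{path}: bad numeric header {name}: {header[name]!r}") from exc
    for name in _TEXT_CONDITION_FIELDS:
        if name in header:
            kwargs[name] = header[name]
    missing = {"methanol_fraction", "column_temperature"} - set(kwargs)
    if missing:
        raise FormatError(f"{path}: header lacks required condition(s) {sorted(missing)}")
    conditions = RunConditions(**kwargs)  # type: ignore[arg-type]

    peaks = []
    for line in body[1:]:
        cells = [c.strip() for c in line.split(delim)]
        if len(cells) < len(columns):
            raise FormatError(f"{path}: short row {line!r}")
        try:
            peaks.append(
                PeakRecord(
                    component_id=cells[idx["component_id"]],
                    retention_time=float(cells[idx["retention_time"]]),
                    area=float(cells[idx["area"]]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: unparsable row {line!r}") from exc
    return PeakTable(conditions=conditions, peaks=peaks)


def write_peak_table(table: PeakTable, path: str | Path, dialect: str = ",") -> Path:
    """Write ``table`` as delimited text; numeric fields keep 12 significant digits."""
    path = Path(path)
    delim = _sniff_delimiter("", dialect) if dialect != "," else ","
    lines = []
    for name in _NUMERIC_CONDITION_FIELDS:
        lines.append(f"# {name}: {getattr(table.conditions, name):.12g}")
    for name in _TEXT_CONDITION_FIELDS:
        value = getattr(table.conditions, name)
        if value:
            lines.append(f"# {name}: {value}")
    lines.append(delim.join(["component_id", "retention_time", "area"]))
    for peak in table.peaks:
        lines.append(
            delim.join([peak.component_id, f"{peak.retention_time:.12g}", f"{peak.area:.12g}"])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# YAML / JSON configuration for standards and sample prep


def _load_mapping(path: str | Path) -> Mapping:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise FormatError(f"{path}: expected a mapping at top level")
    return data


def load_standards(path: str | Path) -> dict[str, ReferenceStandard]:
    """Load reference-standard concentrations (mg/mL) keyed by component id.

    Accepts YAML or JSON of the form ``{standards: {L1: 0.1008, ...}}`` or the
    bare inner mapping.
    """
    data = _load_mapping(path)
    inner = data.get("standards", data)
    if not isinstance(inner, Mapping) or not inner:
        raise FormatError(f"{path}: no standards mapping found")
    return {
        str(cid): ReferenceStandard(component_id=str(cid), concentration=float(conc))
        for cid, conc in inner.items()
    }


def load_sample_prep(path: str | Path) -> SamplePrep:
    """Load sample-prep constants from YAML/JSON with keys sample_mass, extract_volume."""
    data = _load_mapping(path)
    inner = data.get("sample_prep", data)
    try:
        return SamplePrep(
            sample_mass=float(inner["sample_mass"]),
            extract_volume=float(inner["extract_volume"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing sample-prep key {exc}") from exc


def standards_table(standards: Iterable[ReferenceStandard] | Mapping[str, ReferenceStandard]) -> dict[str, float]:
    """Concentrations (mg/mL) keyed by component id, from either container shape."""
    if isinstance(standards, Mapping):
        return {cid: std.concentration for cid, std in standards.items()}
    return {std.component_id: std.concentration for std in standards}
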