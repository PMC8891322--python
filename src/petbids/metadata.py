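"""The _pet.json sidecar: typed model, reader/writer and field-level checks.

The sidecar describes one PET acquisition: tracer identity, injected dose,
the clock time serving as "time zero", scan/injection offsets, frame timing
and the decay-correction state of the image.  All times are numeric seconds
relative to TimeZero; TimeZero itself is an HH:MM:SS wall-clock string.

The required-field set is fixed by the schema table below.  The literal
lowercase string ``"n/a"`` marks a value that could not be measured and is
permitted only for InjectedMass and SpecificRadioactivity (e.g. [18F]FDG,
whose injected mass is too low to measure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from typing import Any

from .findings import Finding, error, sort_findings, warning

__all__ = [
    "NA",
    "PetMetadata",
    "AnatMetadata",
    "REQUIRED_FIELDS",
    "UNIT_EXPECTATIONS",
    "SidecarFormatError",
    "read_pet_sidecar",
    "write_pet_sidecar",
    "check_required_fields",
    "check_units",
    "check_frame_timing",
    "check_time_anchor",
]

#: The missing-value sentinel, bit-exact lowercase.
NA = "n/a"

#: Fields where the "n/a" sentinel may stand in for a measurement.
NA_PERMITTED_KEYS = frozenset({"InjectedMass", "SpecificRadioactivity"})


class SidecarFormatError(ValueError):
    """Raised when sidecar input is not well-formed JSON (or not an object)."""


@dataclass(frozen=True)
class PetMetadata:
    """Typed view of a _pet.json sidecar.

    Unknown keys are preserved verbatim in ``extra`` so write-after-read
    loses nothing.  ``None`` marks an absent field (reported by
    :func:`check_required_fields`, never an exception).
    """

    tracer_name: str | None = None
    tracer_radionuclide: str | None = None
    injected_radioactivity: float | None = None
    injected_radioactivity_units: str | None = None
    injected_mass: float | str | None = None
    injected_mass_units: str | None = None
    specific_radioactivity: float | str | None = None
    specific_radioactivity_units: str | None = None
    units: str | None = None
    time_zero: str | None = None
    scan_start: float | None = None
    injection_start: float | None = None
    frame_times_start: list[float] = field(default_factory=list)
    frame_duration: list[float] = field(default_factory=list)
    image_decay_corrected: bool | None = None
    image_decay_correction_time: float | None = None
    reconstruction_description: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times_start)


@dataclass(frozen=True)
class AnatMetadata:
    """Anatomical MRI sidecar subset relevant when PET data are present."""

    nonlinear_gradient_correction: bool | None = None
    extra: dict[str, Any] = field(default_factory=dict)


# JSON key <-> attribute mapping and expected JSON types.
_NUMBER = (int, float)
_SCHEMA: dict[str, tuple[str, tuple | type]] = {
    "TracerName": ("tracer_name", str),
    "TracerRadionuclide": ("tracer_radionuclide", str),
    "InjectedRadioactivity": ("injected_radioactivity", _NUMBER),
    "InjectedRadioactivityUnits": ("injected_radioactivity_units", str),
    "InjectedMass": ("injected_mass", _NUMBER),
    "InjectedMassUnits": ("injected_mass_units", str),
    "SpecificRadioactivity": ("specific_radioactivity", _NUMBER),
    "SpecificRadioactivityUnits": ("specific_radioactivity_units", str),
    "Units": ("units", str),
    "TimeZero": ("time_zero", str),
    "ScanStart": ("scan_start", _NUMBER),
    "InjectionStart": ("injection_start", _NUMBER),
    "FrameTimesStart": ("frame_times_start", list),
    "FrameDuration": ("frame_duration", list),
    "ImageDecayCorrected": ("image_decay_corrected", bool),
    "ImageDecayCorrectionTime": ("image_decay_correction_time", _NUMBER),
    "ReconstructionDescription": ("reconstruction_description", str),
}

#: Required keys (ReconstructionDescription is optional;
#: ImageDecayCorrectionTime is required iff ImageDecayCorrected is true).
REQUIRED_FIELDS: tuple[str, ...] = (
    "TracerName",
    "TracerRadionuclide",
    "InjectedRadioactivity",
    "InjectedRadioactivityUnits",
    "InjectedMass",
    "InjectedMassUnits",
    "SpecificRadioactivity",
    "SpecificRadioactivityUnits",
    "Units",
    "TimeZero",
    "ScanStart",
    "InjectionStart",
    "FrameTimesStart",
    "FrameDuration",
    "ImageDecayCorrected",
)

#: Canonical unit strings.  The image and time units are prescribed by the
#: standard ("Bq/mL", seconds); the dose units are this package's schema
#: choice, fixed here so validation is self-contained.
UNIT_EXPECTATIONS: dict[str, str] = {
    "Units": "Bq/mL",
    "InjectedRadioactivityUnits": "Bq",
    "InjectedMassUnits": "ug",
    "SpecificRadioactivityUnits": "Bq/g",
    # Optional explicit time-unit keys, validated when present:
    "ScanStartUnits": "s",
    "InjectionStartUnits": "s",
    "FrameTimesStartUnits": "s",
    "FrameDurationUnits": "s",
    "ImageDecayCorrectionTimeUnits": "s",
}

_NA_VARIANTS = frozenset({"n/a", "N/A", "N/a", "n/A", "NA", "na", "Na", "nA"})


def _is_na_variant(value: Any) -> bool:
    return isinstance(value, str) and value in _NA_VARIANTS


def read_pet_sidecar(doc: str | bytes | dict, path: str = "") -> tuple[PetMetadata, list[Finding]]:
    """Parse a _pet.json document into :class:`PetMetadata` plus findings.

    ``doc`` may be JSON text/bytes or an already-decoded object.  Malformed
    JSON raises :class:`SidecarFormatError`; every schema violation (wrong
    type, misplaced or miscased "n/a") becomes an error finding instead of
    an exception, leaving the offending attribute unset.
    """
    if isinstance(doc, (str, bytes)):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise SidecarFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SidecarFormatError("sidecar must be a JSON object")

    findings: list[Finding] = []
    values: dict[str, Any] = {}
    extra: dict[str, Any] = {}

    for key, value in doc.items():
        if key not in _SCHEMA:
            extra[key] = value  # unknown keys preserved, warning-free
            continue
        attr, expected = _SCHEMA[key]

        if _is_na_variant(value):
            if value != NA:
                findings.append(error(
                    "PET203", path,
                    f"{key}: missing-value sentinel must be the literal lowercase "
                    f"'n/a', got {value!r}",
                ))
                continue
            if key not in NA_PERMITTED_KEYS:
                findings.append(error(
                    "PET202", path,
                    f"{key}: 'n/a' is only permitted for InjectedMass and "
                    "SpecificRadioactivity",
                ))
                continue
            values[attr] = NA
            continue

        if expected is bool:
            ok = isinstance(value, bool)
        elif expected is list:
            ok = isinstance(value, list) and all(
                isinstance(v, _NUMBER) and not isinstance(v, bool) for v in value
            )
        else:
            ok = isinstance(value, expected) and not isinstance(value, bool)
        if not ok:
            findings.append(error(
                "PET208", path, f"{key}: expected {_type_name(expected)}, got "
                f"{type(value).__name__}",
            ))
            continue
        values[attr] = [float(v) for v in value] if expected is list else value

    meta = PetMetadata(**values, extra=extra)
    return meta, sort_findings(findings)


def _type_name(expected) -> str:
    if expected is _NUMBER:
        return "number"
    if isinstance(expected, tuple):
        return "number"
    return {bool: "boolean", list: "list of numbers", str: "string"}.get(expected, str(expected))


def write_pet_sidecar(m: PetMetadata) -> str:
    """Serialize metadata to canonical JSON: UTF-8, 4-space indent, sorted keys.

    Inverse of :func:`read_pet_sidecar` for valid documents; unknown keys in
    ``extra`` are written back verbatim.
    """
    doc: dict[str, Any] = dict(m.extra)
    by_attr = {attr: key for key, (attr, _) in _SCHEMA.items()}
    for f in fields(m):
        if f.name in ("extra",):
            continue
        value = getattr(m, f.name)
        if value is None or value == []:
            continue  # absent fields are simply not written
        doc[by_attr[f.name]] = value
    return json.dumps(doc, indent=4, sort_keys=True, ensure_ascii=False) + "\n"


def check_required_fields(m: PetMetadata, path: str = "") -> list[Finding]:
    """One error finding per missing required field.

    "n/a" counts as present only where the sentinel is permitted.
    ImageDecayCorrectionTime joins the required set when the image is
    declared decay-corrected.
    """
    findings = []
    for key in REQUIRED_FIELDS:
        attr, _ = _SCHEMA[key]
        value = getattr(m, attr)
        if value is None or (isinstance(value, list) and not value):
            findings.append(error("PET201", path, f"required field {key} is missing"))
    if m.image_decay_corrected is True and m.image_decay_correction_time is None:
        findings.append(error(
            "PET201", path,
            "ImageDecayCorrectionTime is required when ImageDecayCorrected is true",
        ))
    return sort_findings(findings)


def check_units(m: PetMetadata, path: str = "") -> list[Finding]:
    """Enforce the canonical unit strings (SI: Bq/mL for concentration, s for time)."""
    findings = []
    present = {
        "Units": m.units,
        "InjectedRadioactivityUnits": m.injected_radioactivity_units,
        "InjectedMassUnits": m.injected_mass_units,
        "SpecificRadioactivityUnits": m.specific_radioactivity_units,
    }
    for key, value in m.extra.items():
        if key in UNIT_EXPECTATIONS:
            present[key] = value
    for key, value in present.items():
        expected = UNIT_EXPECTATIONS[key]
        if value is not None and value != expected:
            findings.append(error(
                "PET204", path,
                f"{key}: expected SI unit {expected!r}, got {value!r}",
            ))
    return sort_findings(findings)


def check_frame_timing(m: PetMetadata, n_volumes: int | None = None, path: str = "") -> list[Finding]:
    """Frame lists consistent, chronological and non-overlapping.

    ``n_volumes`` is the volume count from the image header (4th dimension);
    pass ``None`` to skip the length-vs-image comparison (e.g. zero-byte
    placeholder images).  Gaps between frames are legal — an interrupted
    acquisition is missing data within a run, not an error.
    """
    findings = []
    starts, durations = m.frame_times_start, m.frame_duration
    if len(starts) != len(durations):
        findings.append(error(
            "PET205", path,
            f"FrameTimesStart has {len(starts)} entries but FrameDuration has "
            f"{len(durations)}",
        ))
    if n_volumes is not None:
        for name, lst in (("FrameTimesStart", starts), ("FrameDuration", durations)):
            if lst and len(lst) != n_volumes:
                findings.append(error(
                    "PET205", path,
                    f"{name} has {len(lst)} entries but the image stores "
                    f"{n_volumes} volumes",
                ))
    if any(b <= a for a, b in zip(starts, starts[1:])):
        findings.append(error(
            "PET206", path, "FrameTimesStart must be strictly increasing "
            "(frames are stored in chronological order)",
        ))
    elif len(starts) == len(durations):
        for i, (s, d, nxt) in enumerate(zip(starts, durations, starts[1:])):
            if s + d > nxt:
                findings.append(error(
                    "PET207", path,
                    f"frame {i} (start {s}, duration {d}) overlaps frame {i + 1} "
                    f"(start {nxt})",
                ))
    if any(d <= 0 for d in durations):
        findings.append(error("PET208", path, "FrameDuration entries must be positive"))
    return sort_findings(findings)


def check_time_anchor(m: PetMetadata, path: str = "") -> list[Finding]:
    """Warnings about the time-zero convention.

    Time zero should be one of the two anchors (ScanStart or InjectionStart
    equal to 0), and decay correction is expected to reference time zero.
    """
    findings = []
    if (
        m.scan_start is not None
        and m.injection_start is not None
        and 0.0 not in (float(m.scan_start), float(m.injection_start))
    ):
        findings.append(warning(
            "PET209", path,
            "neither ScanStart nor InjectionStart equals 0; time zero should be "
            "injection or scan start",
        ))
    if (
        m.image_decay_correction_time is not None
        and float(m.image_decay_correction_time) != 0.0
    ):
        findings.append(warning(
            "PET210", path,
            f"ImageDecayCorrectionTime is {m.image_decay_correction_time}, not "
            "time zero",
        ))
    return sort_findings(findings)
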