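"""PET-BIDS filename grammar: entity key-value parsing and composition.

PET-BIDS filenames are a sequence of ``key-label`` entities joined by
underscores, followed by a suffix and an extension, e.g.::

    sub-01_ses-baseline_trc-cimbi36_rec-acdyn_run-1_pet.nii.gz
    sub-01_recording-manual_blood.tsv

Entities appear in a fixed canonical order (sub, ses, task, trc, rec, run,
recording), labels are alphanumeric, ``run`` is a positive integer index,
and the suffix constrains the allowed extensions (``blood`` pairs with
``.json``/``.tsv`` only; ``pet`` with ``.nii``/``.nii.gz``/``.json``).

The reconstruction entity ``rec`` has four reserved labels describing
attenuation correction and dynamic/static data (``acdyn``, ``acstat``,
``nacdyn``, ``nacstat``); the blood ``recording`` entity has two reserved
labels (``manual``, ``autosampler``).  Non-reserved labels parse fine —
they are a validator warning, not a grammar error.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "ENTITY_ORDER",
    "ArtifactName",
    "RecKind",
    "RecordingKind",
    "RESERVED_REC_LABELS",
    "RESERVED_RECORDING_LABELS",
    "NameError_",
    "ParseError",
    "MalformedTokenError",
    "UnknownEntityError",
    "DuplicateEntityError",
    "IllegalLabelError",
    "MissingSuffixError",
    "UnknownExtensionError",
    "CompositionError",
    "InvariantError",
    "parse_artifact_name",
    "compose_artifact_name",
    "classify_rec_label",
    "classify_recording_label",
]

#: Canonical entity order, following the order entities are introduced when
#: describing the standard: subject, session, task, tracer, reconstruction,
#: run index, blood recording.
ENTITY_ORDER: tuple[str, ...] = ("sub", "ses", "task", "trc", "rec", "run", "recording")

#: Extensions recognised for PET-BIDS artifacts; matched longest-first so
#: ``.nii.gz`` is a single two-part extension.
KNOWN_EXTENSIONS: tuple[str, ...] = (".nii.gz", ".nii", ".json", ".tsv")

_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")


class NameError_(ValueError):
    """Base class for filename grammar errors."""


class ParseError(NameError_):
    """A filename could not be parsed; subclasses identify the fault."""


class MalformedTokenError(ParseError):
    """An entity token contains no hyphen separating key from label."""


class UnknownEntityError(ParseError):
    """An entity key outside the PET-BIDS entity set."""


class DuplicateEntityError(ParseError):
    """The same entity key appears more than once."""


class IllegalLabelError(ParseError):
    """A label contains characters outside [A-Za-z0-9] (or a bad run index)."""


class MissingSuffixError(ParseError):
    """No suffix token (the final underscore-separated token) was found."""


class UnknownExtensionError(ParseError):
    """The extension is not one of .nii, .nii.gz, .json, .tsv."""


class CompositionError(NameError_):
    """An ArtifactName violating its invariants cannot be composed."""


class InvariantError(CompositionError, ParseError):
    """Suffix/extension/entity combination violates an ArtifactName invariant."""


class RecKind(enum.Enum):
    """Reconstruction label classes: the four reserved labels plus custom."""

    ACDYN = "acdyn"  # attenuation-corrected, dynamic
    ACSTAT = "acstat"  # attenuation-corrected, static
    NACDYN = "nacdyn"  # no attenuation correction, dynamic
    NACSTAT = "nacstat"  # no attenuation correction, static
    CUSTOM = "custom"


class RecordingKind(enum.Enum):
    """Blood recording modes: continuous autosampler vs discrete manual draws."""

    MANUAL = "manual"
    AUTOSAMPLER = "autosampler"


RESERVED_REC_LABELS: frozenset[str] = frozenset(
    k.value for k in RecKind if k is not RecKind.CUSTOM
)
RESERVED_RECORDING_LABELS: frozenset[str] = frozenset(k.value for k in RecordingKind)

#: Suffix → allowed extensions.  Suffixes not listed accept any known extension.
_SUFFIX_EXTENSIONS: dict[str, frozenset[str]] = {
    "pet": frozenset({".nii", ".nii.gz", ".json"}),
    "blood": frozenset({".json", ".tsv"}),
}


@dataclass(frozen=True)
class ArtifactName:
    """A parsed PET-BIDS filename: ordered entities + suffix + extension.

    ``entities`` maps entity key to label, in canonical order.  Equality is
    order-insensitive on construction because :func:`parse_artifact_name` and
    the constructor-normalising :func:`compose_artifact_name` both emit
    canonical order.
    """

    entities: dict[str, str] = field(default_factory=dict)
    suffix: str = "pet"
    extension: str = ".nii.gz"

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", _canonical_entities(self.entities))

    def __hash__(self) -> int:
        return hash((tuple(self.entities.items()), self.suffix, self.extension))


def _canonical_entities(entities: dict[str, str]) -> dict[str, str]:
    """Validate keys/labels and return the mapping in canonical entity order."""
    for key, label in entities.items():
        if key not in ENTITY_ORDER:
            raise UnknownEntityError(f"unknown entity key {key!r}")
        if not isinstance(label, str) or not _LABEL_RE.match(label):
            raise IllegalLabelError(
                f"label {label!r} for entity {key!r} must be non-empty [A-Za-z0-9]"
            )
    if "run" in entities:
        entities = dict(entities)
        entities["run"] = _canonical_run(entities["run"])
    return {k: entities[k] for k in ENTITY_ORDER if k in entities}


def _canonical_run(label: str) -> str:
    if not label.isdigit() or int(label) < 1:
        raise IllegalLabelError(f"run index {label!r} must be a positive integer")
    return str(int(label))  # strip leading zeros: run-02 -> run-2


def _check_invariants(entities: dict[str, str], suffix: str, extension: str) -> None:
    if "sub" not in entities:
        raise InvariantError("the sub entity is required in every filename")
    allowed = _SUFFIX_EXTENSIONS.get(suffix)
    if allowed is not None and extension not in allowed:
        raise InvariantError(
            f"suffix {suffix!r} does not pair with extension {extension!r}"
        )
    if "recording" in entities and suffix != "blood":
        raise InvariantError(
            "the recording entity is only valid with the blood suffix"
        )


def parse_artifact_name(name: str) -> ArtifactName:
    """Parse a bare PET-BIDS filename into entities, suffix and extension.

    Raises a :class:`ParseError` subclass identifying the offending token:
    missing hyphen, unknown key, duplicate key, illegal label characters,
    missing suffix or unknown extension.
    """
    if "/" in name or "\\" in name:
        raise ParseError(f"{name!r} is not a bare filename")

    extension = None
    for ext in KNOWN_EXTENSIONS:  # longest-first
        if name.endswith(ext):
            extension = ext
            stem = name[: -len(ext)]
            break
    if extension is None:
        raise UnknownExtensionError(
            f"{name!r} does not end in one of {', '.join(KNOWN_EXTENSIONS)}"
        )
    if not stem:
        raise MissingSuffixError(f"{name!r} has no suffix before the extension")

    tokens = stem.split("_")
    suffix = tokens[-1]
    if "-" in suffix or not suffix:
        raise MissingSuffixError(
            f"final token {suffix!r} is an entity, not a suffix; "
            "filenames end with a plain suffix such as pet or blood"
        )
    if not _LABEL_RE.match(suffix):
        raise IllegalLabelError(f"suffix {suffix!r} must be alphanumeric")

    entities: dict[str, str] = {}
    for token in tokens[:-1]:
        if "-" not in token:
            raise MalformedTokenError(f"token {token!r} has no key-label hyphen")
        key, _, label = token.partition("-")
        if key not in ENTITY_ORDER:
            raise UnknownEntityError(f"unknown entity key {key!r} in token {token!r}")
        if key in entities:
            raise DuplicateEntityError(f"entity {key!r} appears more than once")
        if not _LABEL_RE.match(label):
            raise IllegalLabelError(
                f"label {label!r} in token {token!r} must be non-empty [A-Za-z0-9]"
            )
        entities[key] = label

    if "run" in entities:
        entities["run"] = _canonical_run(entities["run"])
    _check_invariants(entities, suffix, extension)
    return ArtifactName(entities=entities, suffix=suffix, extension=extension)


def compose_artifact_name(a: ArtifactName) -> str:
    """Compose the canonical filename for an :class:`ArtifactName`.

    The inverse of :func:`parse_artifact_name`:
    ``parse_artifact_name(compose_artifact_name(a)) == a``.
    """
    try:
        entities = _canonical_entities(a.entities)
        _check_invariants(entities, a.suffix, a.extension)
        if a.extension not in KNOWN_EXTENSIONS:
            raise InvariantError(f"unknown extension {a.extension!r}")
        if not _LABEL_RE.match(a.suffix):
            raise InvariantError(f"suffix {a.suffix!r} must be alphanumeric")
    except ParseError as exc:
        raise CompositionError(str(exc)) from None
    parts = [f"{k}-{v}" for k, v in entities.items()] + [a.suffix]
    return "_".join(parts) + a.extension


def classify_rec_label(label: str) -> RecKind:
    """Classify a rec-<label> as one of the four reserved reconstructions.

    Non-reserved labels classify as :attr:`RecKind.CUSTOM`; the validator
    reports those as a warning, never an error.
    """
    try:
        return RecKind(label)
    except ValueError:
        return RecKind.CUSTOM


def classify_recording_label(label: str) -> RecordingKind | str:
    """Classify a recording-<label> as manual/autosampler, else ``"custom"``."""
    try:
        return RecordingKind(label)
    except ValueError:
        return "custom"
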