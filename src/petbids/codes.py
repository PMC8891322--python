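"""Registry of validation rule codes.

Each rule has a stable ``PETnnn`` code, a default severity, a short name and
an explanation of the rationale.  1xx codes are dataset-structure rules,
2xx are PET sidecar metadata rules, 3xx are blood recording rules.
"""

from __future__ import annotations

from .findings import Severity

__all__ = ["CODES", "RuleInfo"]


class RuleInfo:
    __slots__ = ("code", "severity", "name", "explanation")

    def __init__(self, code: str, severity: Severity, name: str, explanation: str):
        self.code = code
        self.severity = severity
        self.name = name
        self.explanation = explanation


def _rule(code: str, severity: Severity, name: str, explanation: str) -> RuleInfo:
    return RuleInfo(code, severity, name, explanation)


CODES: dict[str, RuleInfo] = {
    r.code: r
    for r in [
        _rule(
            "PET101", Severity.ERROR, "MISSING_DATASET_DESCRIPTION",
            "dataset_description.json must exist at the dataset root and parse as "
            "JSON; it carries the generic dataset information crediting the authors "
            "sharing the data.",
        ),
        _rule(
            "PET102", Severity.WARNING, "MISSING_README",
            "A free-form README describing the dataset (known issues such as head "
            "movement or lesions) should accompany the dataset root.",
        ),
        _rule(
            "PET103", Severity.ERROR, "INVALID_DIRECTORY_NAME",
            "Subject directories must be named sub-<label> and session "
            "subdirectories ses-<label>, with alphanumeric labels.",
        ),
        _rule(
            "PET104", Severity.ERROR, "MISSING_PET_SIDECAR",
            "Every _pet NIfTI image requires a _pet.json sidecar in the same "
            "directory detailing the acquisition metadata.",
        ),
        _rule(
            "PET105", Severity.ERROR, "INVALID_FILENAME",
            "Filenames must follow the entity grammar: key-label pairs joined by "
            "hyphens, separated by underscores, then a suffix and extension.",
        ),
        _rule(
            "PET106", Severity.WARNING, "MISSING_PARTICIPANTS",
            "A participants.tsv with participant-level information is customary at "
            "the dataset root.",
        ),
        _rule(
            "PET107", Severity.ERROR, "MISSING_GRADIENT_CORRECTION",
            "When PET data are present, accompanying MR images must state whether "
            "gradient non-linearities were corrected (NonLinearGradientCorrection): "
            "the MRI needs to be corrected for nonlinear gradients causing spatial "
            "distortions to have the same shape as the PET scans for "
            "co-registration.",
        ),
        _rule(
            "PET108", Severity.WARNING, "ZERO_BYTE_IMAGE",
            "Zero-byte NIfTI placeholder images (as in published example trees) are "
            "tolerated; volume-count checks are skipped for them.",
        ),
        _rule(
            "PET109", Severity.ERROR, "SUBJECT_MISMATCH",
            "Entities in a filename must match the enclosing subject/session "
            "directories.",
        ),
        _rule(
            "PET110", Severity.WARNING, "NONRESERVED_REC_LABEL",
            "rec-<label> has four reserved values (acdyn, acstat, nacdyn, nacstat) "
            "describing attenuation correction of dynamic/static data; other labels "
            "are allowed but flagged.",
        ),
        _rule(
            "PET201", Severity.ERROR, "MISSING_REQUIRED_FIELD",
            "A required PET sidecar metadata field is absent; 'n/a' satisfies "
            "presence only for InjectedMass and SpecificRadioactivity.",
        ),
        _rule(
            "PET202", Severity.ERROR, "NA_NOT_PERMITTED",
            "'n/a' is only valid for InjectedMass and SpecificRadioactivity (for "
            "tracers whose mass is too low to measure); all other required fields "
            "need real values.",
        ),
        _rule(
            "PET203", Severity.ERROR, "NA_CASE_VARIANT",
            "The missing-value sentinel is the literal lowercase 'n/a'; case "
            "variants break bit-exact interoperability and are rejected.",
        ),
        _rule(
            "PET204", Severity.ERROR, "NON_SI_UNITS",
            "SI units are mandatory: 'Bq/mL' for radioactivity concentration and "
            "seconds ('s') for time.",
        ),
        _rule(
            "PET205", Severity.ERROR, "FRAME_LENGTH_MISMATCH",
            "FrameTimesStart and FrameDuration must both have one entry per image "
            "volume.",
        ),
        _rule(
            "PET206", Severity.ERROR, "FRAME_TIMES_NOT_INCREASING",
            "Frames are stored in chronological order, so FrameTimesStart must be "
            "strictly increasing.",
        ),
        _rule(
            "PET207", Severity.ERROR, "FRAME_OVERLAP",
            "Consecutive frames may not overlap in time; gaps (interrupted "
            "acquisitions treated as missing data within a run) are permitted.",
        ),
        _rule(
            "PET208", Severity.ERROR, "TYPE_MISMATCH",
            "A sidecar field has the wrong JSON type for its schema entry.",
        ),
        _rule(
            "PET209", Severity.WARNING, "NO_TIME_ZERO_ANCHOR",
            "Time zero should coincide with injection or scan start: at least one "
            "of ScanStart and InjectionStart is expected to equal 0.",
        ),
        _rule(
            "PET210", Severity.WARNING, "DECAY_CORRECTION_TIME_NONZERO",
            "ImageDecayCorrectionTime differs from time zero; data are decay-"
            "corrected to a different reference than the dataset anchor.",
        ),
        _rule(
            "PET211", Severity.WARNING, "MIXED_DECAY_REFERENCE",
            "PET images within one dataset are decay-corrected to different "
            "reference times; optimally all PET and blood data share one "
            "decay-correction time point.",
        ),
        _rule(
            "PET301", Severity.ERROR, "MISSING_TIME_COLUMN",
            "Every blood TSV needs a 'time' column on the single reference time "
            "scale relative to time zero.",
        ),
        _rule(
            "PET302", Severity.ERROR, "NON_MONOTONIC_TIME",
            "Blood sample times must be strictly increasing.",
        ),
        _rule(
            "PET303", Severity.ERROR, "NON_NUMERIC_CELL",
            "Blood TSV cells are numbers or the literal 'n/a'.",
        ),
        _rule(
            "PET304", Severity.ERROR, "DECLARED_NOT_PRESENT",
            "Blood metadata declares an available quantity whose column is missing "
            "from the TSV table.",
        ),
        _rule(
            "PET305", Severity.ERROR, "PRESENT_NOT_DECLARED",
            "A blood TSV column has no descriptor in the JSON sidecar.",
        ),
        _rule(
            "PET306", Severity.ERROR, "FRACTION_OUT_OF_RANGE",
            "Metabolite fractions are dimensionless and must lie in [0, 1].",
        ),
        _rule(
            "PET307", Severity.ERROR, "MISSING_BLOOD_TSV",
            "A _blood.json sidecar must be accompanied by a _blood.tsv table with "
            "the recorded values.",
        ),
        _rule(
            "PET308", Severity.ERROR, "MISSING_BLOOD_JSON",
            "A _blood.tsv table must be accompanied by a _blood.json sidecar "
            "describing what blood data are available.",
        ),
        _rule(
            "PET309", Severity.WARNING, "NONRESERVED_RECORDING_LABEL",
            "recording-<label> has two reserved values for blood data: autosampler "
            "(continuous whole-blood monitoring) and manual (discrete draws); "
            "other labels are allowed but flagged.",
        ),
    ]
}
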