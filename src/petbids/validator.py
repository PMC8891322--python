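"""Whole-dataset validation: walk a tree, apply every rule, emit a report.

The validator applies the structural rules (dataset description, README,
subject/session directory grammar), the filename grammar, the PET sidecar
schema (required fields, SI units, the "n/a" policy, frame timing against
the NIfTI volume count), blood JSON/TSV pairing and cross-checks, the
MR gradient-correction requirement, and the time-zero/decay-reference
advisories.  Findings carry stable PETnnn codes and the report is
deterministic: sorted by (path, code) and identical across runs.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib

from . import blood as blood_mod
from . import metadata as meta_mod
from .codes import CODES
from .findings import Finding, Severity, error, sort_findings, warning
from .naming import (
    ParseError,
    RecKind,
    classify_rec_label,
    classify_recording_label,
    parse_artifact_name,
)

__all__ = ["ValidationReport", "validate_dataset", "explain_code"]

_SUB_DIR_RE = re.compile(r"^sub-[A-Za-z0-9]+$")
_SES_DIR_RE = re.compile(r"^ses-[A-Za-z0-9]+$")
_MODALITY_DIRS = {"pet", "anat"}
_ROOT_FILES = {
    "dataset_description.json", "README", "README.md", "README.txt",
    "participants.tsv", "participants.json", "CHANGES", "LICENSE",
}


@dataclass(frozen=True)
class ValidationReport:
    """Ordered findings for one dataset tree; ok iff no error-severity finding."""

    findings: tuple[Finding, ...] = ()

    @property
    def ok(self) -> bool:
        return not any(f.severity is Severity.ERROR for f in self.findings)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity is Severity.ERROR]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity is Severity.WARNING]

    def codes(self) -> list[str]:
        return [f.code for f in self.findings]

    def render(self) -> str:
        lines = [f.render() for f in self.findings]
        lines.append(f"{'OK' if self.ok else 'FAIL'}: "
                     f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "report_version": 1,
            "ok": self.ok,
            "findings": [f.as_dict() for f in self.findings],
        }


def explain_code(code: str) -> str:
    """Rule description and rationale for a registered PETnnn code."""
    try:
        rule = CODES[code]
    except KeyError:
        raise KeyError(f"unknown validation code {code!r}") from None
    return f"{rule.code} ({rule.name}, {rule.severity.value}): {rule.explanation}"


def validate_dataset(root: str | Path, strict: bool = False) -> ValidationReport:
    """Validate a candidate PET-BIDS tree, returning a deterministic report.

    ``strict`` promotes warnings to errors.  An unreadable/absent root
    raises; every dataset problem is a finding, never an exception.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a readable directory")

    findings: list[Finding] = []
    findings += _check_root(root)

    dataset_has_pet = any(root.glob("sub-*/**/pet/*_pet.nii*")) or any(
        root.glob("sub-*/pet/*_pet.nii*")
    )
    decay_refs: set[float] = set()

    for sub_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        if not _SUB_DIR_RE.match(sub_dir.name):
            if sub_dir.name not in ("derivatives", "code", "sourcedata", "scratch"):
                findings.append(error(
                    "PET103", sub_dir.name,
                    f"directory {sub_dir.name!r} does not match sub-<label>",
                ))
            continue
        session_dirs = [p for p in sorted(sub_dir.iterdir()) if p.is_dir()
                        and p.name not in _MODALITY_DIRS]
        for ses_dir in session_dirs:
            if not _SES_DIR_RE.match(ses_dir.name):
                findings.append(error(
                    "PET103", str(ses_dir.relative_to(root)),
                    f"directory {ses_dir.name!r} does not match ses-<label>",
                ))
                continue
            findings += _check_subject_tree(
                root, ses_dir, sub_dir.name, ses_dir.name, dataset_has_pet, decay_refs
            )
        if any((sub_dir / m).is_dir() for m in _MODALITY_DIRS):
            findings += _check_subject_tree(
                root, sub_dir, sub_dir.name, None, dataset_has_pet, decay_refs
            )

    if len(decay_refs) > 1:
        findings.append(warning(
            "PET211", ".",
            f"PET images are decay-corrected to {len(decay_refs)} different "
            "reference times; one shared reference is expected",
        ))

    if strict:
        findings = [
            Finding(path=f.path, code=f.code, severity=Severity.ERROR, message=f.message)
            for f in findings
        ]
    return ValidationReport(findings=tuple(sort_findings(findings)))


def _check_root(root: Path) -> list[Finding]:
    findings = []
    dd = root / "dataset_description.json"
    if not dd.is_file():
        findings.append(error(
            "PET101", "dataset_description.json",
            "dataset_description.json is missing from the dataset root",
        ))
    else:
        try:
            doc = json.loads(dd.read_text(encoding="utf-8"))
            if not isinstance(doc, dict):
                raise ValueError("not a JSON object")
        except (ValueError, UnicodeDecodeError) as exc:
            findings.append(error(
                "PET101", "dataset_description.json",
                f"dataset_description.json does not parse: {exc}",
            ))
    if not any((root / n).is_file() for n in ("README", "README.md", "README.txt")):
        findings.append(warning(
            "PET102", "README", "a README describing the dataset should be provided",
        ))
    if not (root / "participants.tsv").is_file():
        findings.append(warning(
            "PET106", "participants.tsv", "participants.tsv is customary at the root",
        ))
    return findings


def _check_subject_tree(
    root: Path,
    base: Path,
    sub_name: str,
    ses_name: str | None,
    dataset_has_pet: bool,
    decay_refs: set[float],
) -> list[Finding]:
    """Validate the modality directories under one subject/session level."""
    findings: list[Finding] = []
    for modality in sorted(_MODALITY_DIRS):
        mod_dir = base / modality
        if not mod_dir.is_dir():
            continue
        for f in sorted(mod_dir.iterdir()):
            if not f.is_file():
                continue
            rel = str(f.relative_to(root))
            try:
                art = parse_artifact_name(f.name)
            except ParseError as exc:
                findings.append(error("PET105", rel, f"invalid filename: {exc}"))
                continue

            if f"sub-{art.entities.get('sub')}" != sub_name or (
                ses_name is not None and f"ses-{art.entities.get('ses')}" != ses_name
            ) or (ses_name is None and "ses" in art.entities):
                findings.append(error(
                    "PET109", rel,
                    "filename entities do not match the enclosing "
                    "subject/session directories",
                ))

            if "rec" in art.entities and classify_rec_label(
                art.entities["rec"]
            ) is RecKind.CUSTOM:
                findings.append(warning(
                    "PET110", rel,
                    f"rec-{art.entities['rec']} is not one of the four reserved "
                    "reconstruction labels",
                ))
            if "recording" in art.entities and classify_recording_label(
                art.entities["recording"]
            ) == "custom":
                findings.append(warning(
                    "PET309", rel,
                    f"recording-{art.entities['recording']} is not a reserved "
                    "recording label (autosampler, manual)",
                ))

            if art.suffix == "pet" and art.extension in (".nii", ".nii.gz"):
                findings += _check_pet_image(root, f, decay_refs)
            elif art.suffix == "blood" and art.extension == ".json":
                findings += _check_blood_pair(root, f)
            elif art.suffix == "blood" and art.extension == ".tsv":
                if not f.with_suffix("").with_suffix(".json").exists():
                    findings.append(error(
                        "PET308", rel, "blood TSV without a _blood.json sidecar",
                    ))
            elif modality == "anat" and art.extension in (".nii", ".nii.gz"):
                if dataset_has_pet:
                    findings += _check_anat_sidecar(root, f)
    return findings


def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return image_path.with_name(name[: -len(ext)] + ".json")
    raise ValueError(f"{image_path} is not a NIfTI path")


def _n_volumes(image_path: Path) -> int | None:
    """Volume count from the NIfTI header; None for zero-byte placeholders."""
    if image_path.stat().st_size == 0:
        return None
    img = nib.load(str(image_path))
    shape = img.shape
    return shape[3] if len(shape) == 4 else 1


def _check_pet_image(root: Path, image: Path, decay_refs: set[float]) -> list[Finding]:
    findings: list[Finding] = []
    rel = str(image.relative_to(root))
    sidecar = _sidecar_path(image)
    if not sidecar.is_file():
        findings.append(error(
            "PET104", rel, "every _pet image requires a _pet.json sidecar",
        ))
        return findings

    rel_sc = str(sidecar.relative_to(root))
    try:
        meta, meta_findings = meta_mod.read_pet_sidecar(
            sidecar.read_text(encoding="utf-8"), path=rel_sc
        )
    except meta_mod.SidecarFormatError as exc:
        findings.append(error("PET208", rel_sc, f"sidecar does not parse: {exc}"))
        return findings
    findings += meta_findings
    findings += meta_mod.check_required_fields(meta, path=rel_sc)
    findings += meta_mod.check_units(meta, path=rel_sc)
    findings += meta_mod.check_time_anchor(meta, path=rel_sc)

    n_vol: int | None
    if image.stat().st_size == 0:
        findings.append(warning(
            "PET108", rel, "zero-byte placeholder image; volume checks skipped",
        ))
        n_vol = None
    else:
        try:
            n_vol = _n_volumes(image)
        except (nib.filebasedimages.ImageFileError, OSError, gzip.BadGzipFile) as exc:
            findings.append(error("PET105", rel, f"unreadable NIfTI image: {exc}"))
            n_vol = None
    findings += meta_mod.check_frame_timing(meta, n_volumes=n_vol, path=rel_sc)

    if meta.image_decay_corrected is True and meta.image_decay_correction_time is not None:
        decay_refs.add(float(meta.image_decay_correction_time))
    return findings


def _check_blood_pair(root: Path, json_path: Path) -> list[Finding]:
    findings: list[Finding] = []
    rel = str(json_path.relative_to(root))
    tsv_path = json_path.with_suffix(".tsv")
    if not tsv_path.is_file():
        findings.append(error(
            "PET307", rel, "blood sidecar without a _blood.tsv table",
        ))
        return findings
    try:
        _, _, pair_findings = blood_mod.read_blood_record(
            json_path.read_text(encoding="utf-8"),
            tsv_path.read_text(encoding="utf-8"),
            path=str(tsv_path.relative_to(root)),
        )
    except meta_mod.SidecarFormatError as exc:
        findings.append(error("PET208", rel, f"blood sidecar does not parse: {exc}"))
        return findings
    return findings + pair_findings


def _check_anat_sidecar(root: Path, image: Path) -> list[Finding]:
    sidecar = _sidecar_path(image)
    rel = str(sidecar.relative_to(root))
    if not sidecar.is_file():
        return [error(
            "PET107", rel,
            "anatomical image in a PET dataset needs a sidecar stating "
            "NonLinearGradientCorrection",
        )]
    try:
        doc = json.loads(sidecar.read_text(encoding="utf-8"))
    except ValueError as exc:
        return [error("PET208", rel, f"anat sidecar does not parse: {exc}")]
    if not isinstance(doc, dict) or not isinstance(
        doc.get("NonLinearGradientCorrection"), bool
    ):
        return [error(
            "PET107", rel,
            "NonLinearGradientCorrection must be explicitly true or false when "
            "PET data are present",
        )]
    return []
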