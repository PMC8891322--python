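"""Whole-dataset validation: compliant fixture, single-fault mutations, determinism."""

import json
from pathlib import Path

import pytest

from petbids.synthgen import StudySpec, generate_dataset
from petbids.validator import explain_code, validate_dataset

from conftest import write_json


def first_pet_sidecar(root: Path) -> Path:
    return sorted(root.glob("sub-*/**/*_pet.json"))[0]


def edit_sidecar(root: Path, **changes) -> Path:
    path = first_pet_sidecar(root)
    doc = json.loads(path.read_text())
    for key, value in changes.items():
        if value is None:
            doc.pop(key, None)
        else:
            doc[key] = value
    write_json(path, doc)
    return path


def test_compliant_dataset_has_zero_errors(compliant_dataset):
    report = validate_dataset(compliant_dataset)
    assert report.ok
    assert report.errors == []


def test_unreadable_root_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        validate_dataset(tmp_path / "nowhere")


def test_reports_are_deterministic(compliant_dataset):
    r1 = validate_dataset(compliant_dataset)
    r2 = validate_dataset(compliant_dataset)
    assert r1.render() == r2.render()
    assert [f.as_dict() for f in r1.findings] == [f.as_dict() for f in r2.findings]


# --- single-fault mutation suite -------------------------------------------
# Each mutation injects exactly one fault into a fresh copy of the compliant
# dataset and must trigger its own rule code with no unrelated *new* errors.

def mut_delete_dataset_description(root: Path):
    (root / "dataset_description.json").unlink()
    return "PET101", "error"


def mut_corrupt_dataset_description(root: Path):
    (root / "dataset_description.json").write_text("{broken")
    return "PET101", "error"


def mut_delete_readme(root: Path):
    (root / "README").unlink()
    return "PET102", "warning"


def mut_bad_subject_dir(root: Path):
    (root / "sub-01").rename(root / "subject01")
    return "PET103", "error"


def mut_bad_session_dir(root: Path):
    (root / "sub-01" / "ses-baseline").rename(root / "sub-01" / "visit1")
    return "PET103", "error"


def mut_delete_pet_sidecar(root: Path):
    first_pet_sidecar(root).unlink()
    return "PET104", "error"


def mut_invalid_filename(root: Path):
    img = sorted(root.glob("sub-*/**/*_pet.nii.gz"))[0]
    img.rename(img.with_name("sub-01_acq-x_pet.nii.gz"))
    return "PET105", "error"


def mut_delete_participants(root: Path):
    (root / "participants.tsv").unlink()
    return "PET106", "warning"


def mut_remove_gradient_correction(root: Path):
    sidecar = sorted(root.glob("sub-*/**/anat/*_T1w.json"))[0]
    write_json(sidecar, {"Comment": "flag removed"})
    return "PET107", "error"


def mut_zero_byte_image(root: Path):
    img = sorted(root.glob("sub-*/**/*_pet.nii.gz"))[0]
    img.write_bytes(b"")
    return "PET108", "warning"


def mut_subject_mismatch(root: Path):
    img = sorted(root.glob("sub-01/ses-baseline/pet/*_pet.nii.gz"))[0]
    edited = img.name.replace("sub-01", "sub-99")
    img.rename(img.with_name(edited))
    return "PET109", "error"


def mut_nonreserved_rec_label(root: Path):
    img = sorted(root.glob("sub-01/ses-baseline/pet/*_pet.nii.gz"))[0]
    sidecar = Path(str(img)[: -len(".nii.gz")] + ".json")
    new_img = img.with_name(img.name.replace("_pet.nii.gz", "_rec-osem3d_pet.nii.gz"))
    img.rename(new_img)
    sidecar.rename(sidecar.with_name(sidecar.name.replace("_pet.json", "_rec-osem3d_pet.json")))
    return "PET110", "warning"


def mut_missing_required_field(root: Path):
    edit_sidecar(root, TracerRadionuclide=None)
    return "PET201", "error"


def mut_na_not_permitted(root: Path):
    edit_sidecar(root, InjectedRadioactivity="n/a")
    return "PET202", "error"


def mut_na_case_variant(root: Path):
    edit_sidecar(root, InjectedMass="N/A")
    return "PET203", "error"


def mut_non_si_units(root: Path):
    edit_sidecar(root, Units="kBq/ml")
    return "PET204", "error"


def mut_frame_length_mismatch(root: Path):
    path = first_pet_sidecar(root)
    doc = json.loads(path.read_text())
    doc["FrameTimesStart"] = doc["FrameTimesStart"][:-1]
    doc["FrameDuration"] = doc["FrameDuration"][:-1]
    write_json(path, doc)
    return "PET205", "error"


def mut_non_increasing_frames(root: Path):
    path = first_pet_sidecar(root)
    doc = json.loads(path.read_text())
    doc["FrameTimesStart"] = list(reversed(doc["FrameTimesStart"]))
    write_json(path, doc)
    return "PET206", "error"


def mut_overlapping_frames(root: Path):
    path = first_pet_sidecar(root)
    doc = json.loads(path.read_text())
    doc["FrameDuration"] = [d * 3 for d in doc["FrameDuration"]]
    write_json(path, doc)
    return "PET207", "error"


def mut_type_mismatch(root: Path):
    edit_sidecar(root, ImageDecayCorrected="yes")
    return "PET208", "error"


def mut_no_time_zero_anchor(root: Path):
    edit_sidecar(root, ScanStart=30, InjectionStart=90)
    return "PET209", "warning"


def mut_nonzero_decay_time(root: Path):
    edit_sidecar(root, ImageDecayCorrectionTime=45)
    return "PET210", "warning"


def mut_mixed_decay_reference(root: Path):
    edit_sidecar(root, ImageDecayCorrectionTime=60, ScanStart=60)
    return "PET211", "warning"


def mut_missing_time_column(root: Path):
    tsv = sorted(root.glob("sub-*/**/*recording-manual_blood.tsv"))[0]
    lines = tsv.read_text().splitlines()
    cols = lines[0].split("\t")
    keep = [i for i, c in enumerate(cols) if c != "time"]
    out = ["\t".join(line.split("\t")[i] for i in keep) for line in lines]
    tsv.write_text("\n".join(out) + "\n")
    return "PET301", "error"


def mut_non_monotonic_blood_time(root: Path):
    tsv = sorted(root.glob("sub-*/**/*recording-manual_blood.tsv"))[0]
    lines = tsv.read_text().splitlines()
    lines[1], lines[2] = lines[2], lines[1]
    tsv.write_text("\n".join(lines) + "\n")
    return "PET302", "error"


def mut_non_numeric_cell(root: Path):
    tsv = sorted(root.glob("sub-*/**/*recording-manual_blood.tsv"))[0]
    lines = tsv.read_text().splitlines()
    cells = lines[1].split("\t")
    cells[1] = "oops"
    lines[1] = "\t".join(cells)
    tsv.write_text("\n".join(lines) + "\n")
    return "PET303", "error"


def mut_declared_not_present(root: Path):
    tsv = sorted(root.glob("sub-*/**/*recording-manual_blood.tsv"))[0]
    lines = tsv.read_text().splitlines()
    cols = lines[0].split("\t")
    keep = [i for i, c in enumerate(cols) if c != "plasma_radioactivity"]
    out = ["\t".join(line.split("\t")[i] for i in keep) for line in lines]
    tsv.write_text("\n".join(out) + "\n")
    return "PET304", "error"


def mut_present_not_declared(root: Path):
    sidecar = sorted(root.glob("sub-*/**/*recording-manual_blood.json"))[0]
    doc = json.loads(sidecar.read_text())
    doc.pop("plasma_radioactivity")
    write_json(sidecar, doc)
    return "PET305", "error"


def mut_fraction_out_of_range(root: Path):
    tsv = sorted(root.glob("sub-*/**/*recording-manual_blood.tsv"))[0]
    lines = tsv.read_text().splitlines()
    idx = lines[0].split("\t").index("metabolite_parent_fraction")
    cells = lines[1].split("\t")
    cells[idx] = "1.7"
    lines[1] = "\t".join(cells)
    tsv.write_text("\n".join(lines) + "\n")
    return "PET306", "error"


def mut_blood_json_without_tsv(root: Path):
    sorted(root.glob("sub-*/**/*recording-manual_blood.tsv"))[0].unlink()
    return "PET307", "error"


def mut_blood_tsv_without_json(root: Path):
    sorted(root.glob("sub-*/**/*recording-manual_blood.json"))[0].unlink()
    return "PET308", "error"


def mut_nonreserved_recording_label(root: Path):
    for f in sorted(root.glob("sub-01/ses-baseline/pet/*recording-manual_blood.*")):
        f.rename(f.with_name(f.name.replace("recording-manual", "recording-venous")))
    return "PET309", "warning"


MUTATIONS = [
    mut_delete_dataset_description,
    mut_corrupt_dataset_description,
    mut_delete_readme,
    mut_bad_subject_dir,
    mut_bad_session_dir,
    mut_delete_pet_sidecar,
    mut_invalid_filename,
    mut_delete_participants,
    mut_remove_gradient_correction,
    mut_zero_byte_image,
    mut_subject_mismatch,
    mut_nonreserved_rec_label,
    mut_missing_required_field,
    mut_na_not_permitted,
    mut_na_case_variant,
    mut_non_si_units,
    mut_frame_length_mismatch,
    mut_non_increasing_frames,
    mut_overlapping_frames,
    mut_type_mismatch,
    mut_no_time_zero_anchor,
    mut_nonzero_decay_time,
    mut_mixed_decay_reference,
    mut_missing_time_column,
    mut_non_monotonic_blood_time,
    mut_non_numeric_cell,
    mut_declared_not_present,
    mut_present_not_declared,
    mut_fraction_out_of_range,
    mut_blood_json_without_tsv,
    mut_blood_tsv_without_json,
    mut_nonreserved_recording_label,
]


@pytest.mark.parametrize("mutate", MUTATIONS, ids=lambda m: m.__name__)
def test_single_fault_mutation_triggers_its_code(mutable_dataset, mutate):
    expected_code, expected_severity = mutate(mutable_dataset)
    report = validate_dataset(mutable_dataset)
    triggered = [f for f in report.findings if f.code == expected_code]
    assert triggered, f"{expected_code} not raised; got {report.codes()}"
    assert all(f.severity.value == expected_severity for f in triggered)
    if expected_severity == "warning":
        # a warning-level fault must not produce spurious errors
        unrelated = [f.code for f in report.errors]
        assert unrelated == [], unrelated


def test_mutation_suite_covers_at_least_12_distinct_rules():
    assert len(MUTATIONS) >= 12


def test_adding_a_valid_file_never_breaks_existing_files(tmp_path):
    """Monotonicity: growing a valid dataset keeps pre-existing files clean."""
    root = tmp_path / "grow"
    generate_dataset(StudySpec(n_subjects=1, blood="manual", seed=2), root)
    before = validate_dataset(root)
    assert before.ok
    generate_dataset(
        StudySpec(n_subjects=2, blood="manual", seed=2), root, overwrite=True
    )
    after = validate_dataset(root)
    assert after.ok
    assert {f.code for f in after.findings} <= {f.code for f in before.findings} | set()


def test_strict_mode_promotes_warnings(mutable_dataset):
    (mutable_dataset / "README").unlink()
    assert validate_dataset(mutable_dataset).ok
    assert not validate_dataset(mutable_dataset, strict=True).ok


class TestExplainCode:
    def test_known_codes(self):
        assert "dataset_description" in explain_code("PET101")
        text = explain_code("PET107")
        assert "NonLinearGradientCorrection" in text
        assert "co-registration" in text

    def test_unknown_code_raises(self):
        with pytest.raises(KeyError):
            explain_code("XYZ")
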