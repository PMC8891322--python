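import json
from pathlib import Path

import pytest

from petbids.synthgen import StudySpec, generate_dataset


MINIMAL_SIDECAR = {
    "TracerName": "cimbi36",
    "TracerRadionuclide": "C11",
    "InjectedRadioactivity": 6.0e8,
    "InjectedRadioactivityUnits": "Bq",
    "InjectedMass": 0.5,
    "InjectedMassUnits": "ug",
    "SpecificRadioactivity": 1.2e12,
    "SpecificRadioactivityUnits": "Bq/g",
    "Units": "Bq/mL",
    "TimeZero": "10:00:00",
    "ScanStart": 0,
    "InjectionStart": 0,
    "FrameTimesStart": [0, 60, 120],
    "FrameDuration": [60, 60, 120],
    "ImageDecayCorrected": True,
    "ImageDecayCorrectionTime": 0,
}


@pytest.fixture
def minimal_sidecar() -> dict:
    """A fully specified, schema-valid _pet.json document."""
    return dict(MINIMAL_SIDECAR)


@pytest.fixture(scope="session")
def compliant_dataset(tmp_path_factory) -> Path:
    """A generated dataset that must validate with zero errors."""
    root = tmp_path_factory.mktemp("ds") / "study"
    spec = StudySpec(
        n_subjects=2,
        sessions=("baseline", "rescan"),
        blood="manual+autosampler",
        with_anat=True,
        seed=11,
    )
    generate_dataset(spec, root)
    return root


def copy_dataset(src: Path, dst: Path) -> Path:
    """Copy a dataset tree so mutation tests never touch the shared fixture."""
    import shutil

    shutil.copytree(src, dst)
    return dst


@pytest.fixture
def mutable_dataset(compliant_dataset, tmp_path) -> Path:
    return copy_dataset(compliant_dataset, tmp_path / "mut")


def write_json(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(doc, indent=4, sort_keys=True) + "\n", encoding="utf-8")
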