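"""Deterministic generation of compliant synthetic PET-BIDS datasets.

Produces a full dataset tree — dataset_description.json, README,
participants.tsv, per-subject/session 4D PET NIfTI images with _pet.json
sidecars, optional manual/autosampler blood recordings and an anatomical
T1w with the gradient-correction flag — entirely from a seeded
:class:`StudySpec`.  Identical specs yield byte-identical trees (NIfTI
headers are fixed, gzip streams carry no timestamp), so generated datasets
double as reproducible test fixtures.

The kinetics are a fixed two-exponential family (fast uptake, slower
clearance) with seeded per-subject parameters; the parent fraction decays
monotonically from 1.  This emulates the shape of real tracer curves, not
their biology.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .blood import BloodMetadata, BloodTable, default_column_descriptors, write_blood_record
from .metadata import PetMetadata, write_pet_sidecar
from .naming import ArtifactName, compose_artifact_name

__all__ = ["StudySpec", "simulate_tac", "simulate_parent_fraction", "generate_dataset"]

#: Default frame scheme: 6 frames over 10 minutes, (start, duration) seconds.
DEFAULT_FRAMES: tuple[tuple[float, float], ...] = (
    (0, 60), (60, 60), (120, 120), (240, 120), (360, 120), (480, 120),
)


@dataclass(frozen=True)
class StudySpec:
    """Configuration for one synthetic study.

    ``blood`` is one of ``"none"``, ``"manual"``, ``"manual+autosampler"``.
    The seed fixes every random draw; the image grid stays tiny so full
    datasets generate in milliseconds.
    """

    n_subjects: int = 1
    sessions: tuple[str, ...] = ()
    tracer: str = "cimbi36"
    radionuclide: str = "C11"
    half_life_s: float = 1221.84
    frames: tuple[tuple[float, float], ...] = DEFAULT_FRAMES
    blood: str = "manual"
    with_anat: bool = True
    seed: int = 0
    grid: tuple[int, int, int] = (8, 8, 8)
    injected_radioactivity_bq: float = 6.0e8
    time_zero: str = "10:00:00"

    def __post_init__(self) -> None:
        if self.blood not in ("none", "manual", "manual+autosampler"):
            raise ValueError(f"unknown blood option {self.blood!r}")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        starts = [s for s, _ in self.frames]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("frame scheme must be chronological")
        for (s, d), nxt in zip(self.frames, starts[1:]):
            if s + d > nxt:
                raise ValueError("frame scheme must be non-overlapping")
        object.__setattr__(self, "sessions", tuple(self.sessions))
        object.__setattr__(
            self, "frames", tuple((float(s), float(d)) for s, d in self.frames)
        )


def _kinetic_params(spec: StudySpec, subject_index: int) -> tuple[float, float, float]:
    """Seeded (amplitude, uptake rate, clearance rate) for one subject."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index]))
    amplitude = rng.uniform(2e4, 5e4)  # peak scale, Bq/mL
    k_in = rng.uniform(1 / 120.0, 1 / 60.0)  # fast uptake, 1/s
    k_out = rng.uniform(1 / 3000.0, 1 / 1200.0)  # slow clearance, 1/s
    return amplitude, k_in, k_out


def _tac_curve(t: np.ndarray, amplitude: float, k_in: float, k_out: float) -> np.ndarray:
    """Two-exponential tracer curve: rises with k_in, clears with k_out."""
    return amplitude * np.maximum(np.exp(-k_out * t) - np.exp(-k_in * t), 0.0)


def simulate_tac(
    spec: StudySpec, region_scale: float, subject_index: int = 0
) -> np.ndarray:
    """Frame-wise tissue activities (Bq/mL) for one region.

    Evaluates the subject's two-exponential curve at each frame midpoint and
    scales linearly by ``region_scale`` (so doubling the scale doubles every
    frame, and scale 0 gives an all-zero curve).  Deterministic given the
    spec seed.
    """
    amplitude, k_in, k_out = _kinetic_params(spec, subject_index)
    mids = np.array([s + d / 2.0 for s, d in spec.frames])
    return region_scale * _tac_curve(mids, amplitude, k_in, k_out)


def simulate_parent_fraction(spec: StudySpec, times: np.ndarray, subject_index: int = 0) -> np.ndarray:
    """Monotonically non-increasing parent fraction, 1.0 at time zero."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index, 7]))
    rate = rng.uniform(1 / 2400.0, 1 / 900.0)
    return np.exp(-rate * np.maximum(np.asarray(times, dtype=float), 0.0))


def _blood_tables(spec: StudySpec, subject_index: int) -> dict[str, BloodTable]:
    """Manual (and optionally autosampler) tables for one subject."""
    amplitude, k_in, k_out = _kinetic_params(spec, subject_index)
    scan_end = spec.frames[-1][0] + spec.frames[-1][1]
    out: dict[str, BloodTable] = {}

    if spec.blood in ("manual", "manual+autosampler"):
        t = np.linspace(60.0, scan_end, 8)
        plasma = _tac_curve(t, 1.4 * amplitude, k_in, k_out)
        pf = simulate_parent_fraction(spec, t, subject_index)
        polar = (1.0 - pf) * 0.6
        whole = plasma * (0.5 + 0.5 * pf)  # >= plasma * pf at every point
        out["manual"] = BloodTable(pd.DataFrame({
            "time": t,
            "plasma_radioactivity": plasma,
            "whole_blood_radioactivity": whole,
            "metabolite_parent_fraction": pf,
            "metabolite_polar_fraction": polar,
        }, dtype=float))

    if spec.blood == "manual+autosampler":
        t = np.arange(0.0, min(scan_end, 600.0) + 1, 5.0)
        plasma = _tac_curve(t, 1.4 * amplitude, k_in, k_out)
        pf = simulate_parent_fraction(spec, t, subject_index)
        whole = plasma * (0.5 + 0.5 * pf)
        out["autosampler"] = BloodTable(pd.DataFrame({
            "time": t,
            "whole_blood_radioactivity": whole,
        }, dtype=float))
    return out


def _pet_sidecar(spec: StudySpec) -> PetMetadata:
    starts = [s for s, _ in spec.frames]
    durations = [d for _, d in spec.frames]
    return PetMetadata(
        tracer_name=spec.tracer,
        tracer_radionuclide=spec.radionuclide,
        injected_radioactivity=spec.injected_radioactivity_bq,
        injected_radioactivity_units="Bq",
        injected_mass=0.5,
        injected_mass_units="ug",
        specific_radioactivity=1.2e12,
        specific_radioactivity_units="Bq/g",
        units="Bq/mL",
        time_zero=spec.time_zero,
        scan_start=0.0,
        injection_start=0.0,
        frame_times_start=starts,
        frame_duration=durations,
        image_decay_corrected=True,
        image_decay_correction_time=0.0,
        reconstruction_description="synthetic OSEM-like reconstruction",
    )


def _write_nifti_gz(path: Path, data: np.ndarray) -> None:
    """Write a .nii.gz with fixed header and zeroed gzip mtime (byte-stable)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine=np.eye(4))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    raw = img.to_bytes()
    path.write_bytes(gzip.compress(raw, compresslevel=6, mtime=0))


def _pet_image(spec: StudySpec, subject_index: int) -> np.ndarray:
    """4D volume: voxelwise scaled copies of the subject TAC."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index, 13]))
    scales = rng.uniform(0.2, 1.0, size=spec.grid)
    tac = simulate_tac(spec, 1.0, subject_index)
    return scales[..., None] * tac[None, None, None, :]


def generate_dataset(spec: StudySpec, out_root: str | Path, overwrite: bool = False):
    """Write a compliant synthetic PET-BIDS dataset under ``out_root``.

    Returns a summary dict (subjects, sessions, files written).  Refuses a
    non-empty target unless ``overwrite`` is set.  The output passes
    :func:`petbids.validator.validate_dataset` with zero errors and is
    byte-identical across runs of the same spec.
    """
    root = Path(out_root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"{root} is not empty (pass overwrite=True)")
    root.mkdir(parents=True, exist_ok=True)

    files: list[str] = []

    def write_text(rel: str, text: str) -> None:
        p = root / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text, encoding="utf-8", newline="\n")
        files.append(rel)

    write_text("dataset_description.json", json.dumps({
        "Name": f"Synthetic {spec.tracer} PET dataset",
        "BIDSVersion": "1.6.0",
        "DatasetType": "raw",
        "Authors": ["petbids synthetic generator"],
    }, indent=4, sort_keys=True) + "\n")
    write_text("README", (
        "Synthetic dynamic PET dataset produced by the petbids generator.\n"
        f"Tracer {spec.tracer} ({spec.radionuclide}), "
        f"{spec.n_subjects} subject(s), seed {spec.seed}.\n"
        "All image and blood values come from a seeded two-exponential "
        "kinetic model; no claim of biological fidelity.\n"
    ))

    subjects = [f"{i + 1:02d}" for i in range(spec.n_subjects)]
    write_text("participants.tsv", "\n".join(
        ["participant_id"] + [f"sub-{s}" for s in subjects]
    ) + "\n")

    sessions: tuple[str, ...] = spec.sessions or ("",)
    for idx, sub in enumerate(subjects):
        for ses in sessions:
            entities = {"sub": sub}
            rel_dir = Path(f"sub-{sub}")
            if ses:
                entities["ses"] = ses
                rel_dir = rel_dir / f"ses-{ses}"

            pet_dir = rel_dir / "pet"
            pet_entities = dict(entities, trc=spec.tracer)
            base = ArtifactName(entities=pet_entities, suffix="pet", extension=".nii.gz")
            nii_name = compose_artifact_name(base)
            (root / pet_dir).mkdir(parents=True, exist_ok=True)
            _write_nifti_gz(root / pet_dir / nii_name, _pet_image(spec, idx))
            files.append(str(pet_dir / nii_name))

            sidecar_name = compose_artifact_name(
                ArtifactName(entities=pet_entities, suffix="pet", extension=".json")
            )
            write_text(str(pet_dir / sidecar_name), write_pet_sidecar(_pet_sidecar(spec)))

            for recording, table in _blood_tables(spec, idx).items():
                cols = list(table.frame.columns)
                meta = BloodMetadata(
                    recording=recording,
                    plasma_avail="plasma_radioactivity" in cols,
                    whole_blood_avail="whole_blood_radioactivity" in cols,
                    metabolite_avail="metabolite_parent_fraction" in cols,
                    columns=default_column_descriptors(cols),
                )
                json_doc, tsv_doc = write_blood_record(meta, table)
                blood_entities = dict(entities, recording=recording)
                jname = compose_artifact_name(ArtifactName(
                    entities=blood_entities, suffix="blood", extension=".json"
                ))
                tname = compose_artifact_name(ArtifactName(
                    entities=blood_entities, suffix="blood", extension=".tsv"
                ))
                write_text(str(pet_dir / jname), json_doc)
                write_text(str(pet_dir / tname), tsv_doc)

            if spec.with_anat:
                anat_dir = rel_dir / "anat"
                (root / anat_dir).mkdir(parents=True, exist_ok=True)
                t1_name = compose_artifact_name(
                    ArtifactName(entities=entities, suffix="T1w", extension=".nii.gz")
                )
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, idx, 29])
                )
                _write_nifti_gz(
                    root / anat_dir / t1_name,
                    rng.uniform(0, 1000, size=spec.grid).astype(np.float32),
                )
                files.append(str(anat_dir / t1_name))
                t1_json = compose_artifact_name(
                    ArtifactName(entities=entities, suffix="T1w", extension=".json")
                )
                write_text(str(anat_dir / t1_json), json.dumps(
                    {"NonLinearGradientCorrection": True},
                    indent=4, sort_keys=True,
                ) + "\n")

    return {
        "root": str(root),
        "subjects": [f"sub-{s}" for s in subjects],
        "sessions": list(spec.sessions),
        "n_files": len(files),
        "files": sorted(files),
    }
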