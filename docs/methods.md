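# Methods

This note documents the conventions, models and numerical choices behind
`petbids`, and what the synthetic-data tests do and do not establish.

## Filename grammar

A PET-BIDS filename is `key-label` entities joined by underscores, a suffix,
and an extension. The entity vocabulary is `sub`, `ses`, `task`, `trc`,
`rec`, `run`, `recording`; labels are `[A-Za-z0-9]+` and `run` must parse as
a positive integer (leading zeros are normalized away: `run-02` → `run-2`).
The canonical entity order follows the order in which the entities enter a
study description — subject, session, task, tracer, reconstruction, run,
blood recording — since no total order is otherwise mandated. Parsing accepts
entities in any order and canonicalizes; composition always emits canonical
order, so `parse ∘ compose` is the identity and serialization is idempotent.

`.nii.gz` is treated as a single two-part extension (longest match). Unknown
entity keys are a parse error rather than preserved: silently carrying keys
from other imaging modalities would let misspelled PET entities pass
validation. Non-reserved `rec`/`recording` labels parse successfully — the
reserved sets are reserved, not exhaustive — and surface as validator
warnings (PET110, PET309), not errors.

## Sidecar schema

The required `_pet.json` fields are fixed in one table
(`petbids.metadata.REQUIRED_FIELDS`): tracer identity, the three dose
quantities with their unit strings, the image value unit, `TimeZero`,
`ScanStart`, `InjectionStart`, the two frame-timing lists, and
`ImageDecayCorrected` (with `ImageDecayCorrectionTime` required exactly when
it is true). `ReconstructionDescription` is optional. Unknown keys are
preserved verbatim and never flagged, for forward compatibility.

Encoding choice: `TimeZero` is an `HH:MM:SS` wall-clock string; every other
time is a number in seconds relative to it, so all arithmetic happens in one
unit. Canonical unit strings are pinned for bit-exact interoperability:

| key | unit |
|---|---|
| `Units` (image values) | `Bq/mL` |
| `InjectedRadioactivityUnits` | `Bq` |
| `InjectedMassUnits` | `ug` |
| `SpecificRadioactivityUnits` | `Bq/g` |
| optional `*Units` for time fields | `s` |

`Bq/mL` and seconds are the standard's own SI requirement; the dose units
are this package's canonical choice, fixed here so validation is
self-contained. Any other string (including case variants like `Bq/ml`) is a
PET204 error.

The missing-value sentinel is the literal lowercase `n/a`, valid only for
`InjectedMass` and `SpecificRadioactivity` (tracers such as [18F]FDG have
too little mass to measure). Case variants are rejected with a dedicated
code (PET203) rather than normalized, again for bit-exact round trips.

Frame timing: `FrameTimesStart` strictly increasing, one entry per image
volume, no overlap between consecutive frames. Gaps are legal — a subject
leaving the scanner mid-acquisition is missing data within a run, not a
protocol violation.

## Blood recordings

Machine-readable column names are lower snake case (`time`,
`plasma_radioactivity`, `whole_blood_radioactivity`,
`metabolite_parent_fraction`, `metabolite_polar_fraction`); the quantities
are standard but no machine names are mandated, so one spelling is fixed
here. TSVs are tab-separated, UTF-8, LF, header row mandatory, `n/a` for
missing cells. Floats are rendered via Python's shortest-repr, so every
written value re-parses to the identical double (0 ulp); integers render
without a decimal point. In memory a table is a float DataFrame with NaN for
`n/a`.

Merging manual + autosampler recordings takes the union of time points,
sorted. At a shared time the continuous device wins for whole-blood
radioactivity (it is the instrument actually measuring that quantity
continuously); plasma and metabolite columns always come from manual draws,
and a conflict on those raises. No interpolation or resampling is performed:
the format stores measurements, and derived curves belong to analysis
pipelines outside this package's scope.

## Decay correction and time zero

All corrections use the exponential decay law in base-2 form,
`factor(Δt) = 2^(Δt/T½)`, with the half-life always supplied explicitly via
`DecayContext`. A small registry of common radionuclide half-lives
(`HALF_LIVES_S`) ships as reference data from standard nuclear-data tables;
nothing looks it up implicitly. Negative elapsed times (pre-injection
samples) are legal and yield factors below 1. The group property
`factor(a+b) = factor(a)·factor(b)` makes re-referencing between time zeros
a single constant multiplication, which `shift_time_zero` applies to every
radioactivity column while shifting every time field by the same constant —
inter-event intervals are preserved exactly, and the operation is an
involution up to floating point. Fraction columns are dimensionless and are
never rescaled.

Mixed decay-correction references within one dataset are a warning (PET211),
not an error: a single shared reference is optimal but the standard
tolerates deviations, and the condition is mechanically repairable with
`rereference_correction`.

## Validator severity policy

Rules phrased as hard requirements (sidecar presence, SI units, the `n/a`
policy, `NonLinearGradientCorrection` whenever PET data accompany MR images)
are errors; advisory conventions (README, participants.tsv, time zero
anchored at an event, reserved labels, shared decay reference) are warnings.
`--strict` promotes warnings to errors. Zero-byte NIfTI files — the
convention used by published example trees — get a warning and skip
volume-count checks, so those trees validate. Sidecars are required in the
same directory as their image; BIDS inheritance from upper levels is not
implemented. Reports are sorted by (path, code) and are byte-identical
across runs.

## Synthetic data generator

`StudySpec` defaults describe a small dynamic [11C] brain study: one
subject, a 6-frame / 10-minute acquisition, manual blood sampling (8 draws),
an anatomical T1w, an 8×8×8 voxel grid, 600 MBq injected. Tissue and plasma
curves are a fixed two-exponential family
`A(t) = amplitude · (e^(−k_out·t) − e^(−k_in·t))` with per-subject
parameters drawn from seeded uniform ranges (uptake 1/120–1/60 s⁻¹,
clearance 1/3000–1/1200 s⁻¹, peak 20–50 kBq/mL); the parent fraction decays
exponentially from 1, and whole blood is `plasma · (0.5 + 0.5·pf)`, which
keeps whole-blood activity ≥ plasma parent activity at every sample. Voxels
are scaled copies of one subject curve.

What this emulates: the structural and metadata shape of a real dataset,
plausible curve shapes, and the single-time-scale bookkeeping. What it does
not: scanner noise, attenuation/scatter, reconstruction artifacts, real
pharmacokinetics, or inter-site metadata heterogeneity. Passing the
generator→validator sweep therefore demonstrates the rule set's internal
consistency on well-formed data, not robustness to every malformation found
in the wild — the mutation suite covers the fault classes the rules define,
one fault at a time.

Determinism: all randomness flows through `numpy` seed sequences derived
from `StudySpec.seed`; NIfTI headers are fixed, data are float32, and gzip
streams are written with a zeroed timestamp, so identical specs produce
byte-identical trees. Grids ≤16³ and ≤10 frames keep the full suite fast.

## Numerical choices and degenerate inputs

- All tolerances in tests are relative 1e-12 for decay arithmetic (pure
  floating-point identities) and exact equality for I/O round trips.
- An empty blood table (header only) is valid; merge with an empty table is
  the identity.
- `ImageDecayCorrectionTime ≠ 0` is only a warning: the standard does not
  state that correction must reference time zero, so presence and type are
  validated and the mismatch surfaced without failing the dataset.
- Findings within one file are deduplicated by construction (each rule
  emits at most once per offending field) and sorted deterministically.

## Known limitations

- No DICOM/ECAT conversion; inputs are assumed already NIfTI + JSON/TSV.
- No pharmacokinetic modeling, dispersion/delay correction, or derivative
  outputs.
- Only the PET-relevant entity subset is parsed; datasets mixing in other
  modalities' entities will flag those filenames.
- BIDS inheritance of sidecars from parent directories is unimplemented.
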