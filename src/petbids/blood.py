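"""Blood recordings: _blood.json metadata paired with a _blood.tsv table.

A blood recording documents the radiotracer concentration measured in blood
during the PET scan — continuously by an autosampler (whole blood only) or
as discrete manual draws (plasma, whole blood and metabolite fractions).
The canonical table columns are::

    time                          seconds relative to time zero
    plasma_radioactivity          Bq/mL
    whole_blood_radioactivity     Bq/mL
    metabolite_parent_fraction    dimensionless, in [0, 1]
    metabolite_polar_fraction     dimensionless, in [0, 1]

Missing cells hold the literal lowercase sentinel ``n/a``.  The JSON sidecar
declares which quantities are available and describes each column (free-text
description plus units).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .findings import Finding, error, sort_findings
from .metadata import NA, SidecarFormatError

__all__ = [
    "CANONICAL_COLUMNS",
    "RADIOACTIVITY_COLUMNS",
    "FRACTION_COLUMNS",
    "BloodMetadata",
    "BloodTable",
    "read_blood_record",
    "write_blood_record",
    "merge_recordings",
]

#: Canonical column order for blood TSV tables.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "time",
    "plasma_radioactivity",
    "whole_blood_radioactivity",
    "metabolite_parent_fraction",
    "metabolite_polar_fraction",
)

RADIOACTIVITY_COLUMNS = frozenset(
    {"plasma_radioactivity", "whole_blood_radioactivity"}
)
FRACTION_COLUMNS = frozenset(
    {"metabolite_parent_fraction", "metabolite_polar_fraction"}
)

#: Availability flag in the JSON sidecar -> the column it promises.
_AVAILABILITY_TO_COLUMN = {
    "PlasmaAvail": "plasma_radioactivity",
    "WholeBloodAvail": "whole_blood_radioactivity",
    "MetaboliteAvail": "metabolite_parent_fraction",
}

_EXPECTED_COLUMN_UNITS = {
    "time": "s",
    "plasma_radioactivity": "Bq/mL",
    "whole_blood_radioactivity": "Bq/mL",
    "metabolite_parent_fraction": "arbitrary",
    "metabolite_polar_fraction": "arbitrary",
}


@dataclass(frozen=True)
class BloodMetadata:
    """_blood.json content: recording mode, availability flags, column docs."""

    recording: str = "manual"
    plasma_avail: bool = False
    whole_blood_avail: bool = False
    metabolite_avail: bool = False
    columns: dict[str, dict[str, str]] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)

    def declared_columns(self) -> list[str]:
        out = ["time"]
        if self.plasma_avail:
            out.append("plasma_radioactivity")
        if self.whole_blood_avail:
            out.append("whole_blood_radioactivity")
        if self.metabolite_avail:
            out.extend(
                c for c in ("metabolite_parent_fraction", "metabolite_polar_fraction")
                if c in self.columns
            )
        return out


@dataclass(frozen=True)
class BloodTable:
    """Timed blood samples as a float DataFrame; missing cells are NaN.

    NaN is the in-memory image of the ``n/a`` sentinel; the TSV writer maps
    it back.  The ``time`` column is always first and strictly increasing
    for a valid table.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame({"time": []}))

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    def __eq__(self, other) -> bool:  # value equality incl. NaN cells
        if not isinstance(other, BloodTable):
            return NotImplemented
        if list(self.frame.columns) != list(other.frame.columns):
            return False
        if len(self.frame) != len(other.frame):
            return False
        a = self.frame.to_numpy(dtype=float)
        b = other.frame.to_numpy(dtype=float)
        return bool(np.array_equal(a, b, equal_nan=True))


def _parse_blood_json(doc: str | bytes | dict) -> tuple[BloodMetadata, list]:
    if isinstance(doc, (str, bytes)):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise SidecarFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SidecarFormatError("blood sidecar must be a JSON object")

    known_bools = {
        "PlasmaAvail": "plasma_avail",
        "WholeBloodAvail": "whole_blood_avail",
        "MetaboliteAvail": "metabolite_avail",
    }
    values: dict[str, Any] = {}
    columns: dict[str, dict[str, str]] = {}
    extra: dict[str, Any] = {}
    for key, value in doc.items():
        if key == "Recording" and isinstance(value, str):
            values["recording"] = value
        elif key in known_bools and isinstance(value, bool):
            values[known_bools[key]] = value
        elif key in CANONICAL_COLUMNS and isinstance(value, dict):
            columns[key] = {str(k): str(v) for k, v in value.items()}
        else:
            extra[key] = value
    return BloodMetadata(**values, columns=columns, extra=extra), []


def _parse_blood_tsv(
    tsv_doc: str, path: str
) -> tuple[BloodTable, list[Finding], set[str]]:
    """Parse TSV text; also report which columns hold literal 'n/a' cells."""
    findings: list[Finding] = []
    na_columns: set[str] = set()
    raw = pd.read_csv(
        io.StringIO(tsv_doc), sep="\t", dtype=str, keep_default_na=False
    )
    data: dict[str, list[float]] = {}
    for col in raw.columns:
        out = []
        for i, cell in enumerate(raw[col]):
            if cell == NA:
                out.append(math.nan)
                na_columns.add(col)
                continue
            try:
                out.append(float(cell))
            except ValueError:
                findings.append(error(
                    "PET303", path,
                    f"row {i}, column {col}: {cell!r} is neither a number nor 'n/a'",
                ))
                out.append(math.nan)
        data[col] = out
    table = BloodTable(pd.DataFrame(data, columns=list(raw.columns), dtype=float))
    return table, findings, na_columns


def read_blood_record(
    json_doc: str | bytes | dict, tsv_doc: str, path: str = ""
) -> tuple[BloodMetadata, BloodTable, list[Finding]]:
    """Parse and cross-validate a blood JSON/TSV pair.

    Findings cover: a missing or non-monotonic ``time`` column, non-numeric
    cells, fractions outside [0, 1], quantities declared available but
    absent from the table (DECLARED_NOT_PRESENT) and columns present with
    no sidecar descriptor (PRESENT_NOT_DECLARED).
    """
    meta, findings = _parse_blood_json(json_doc)
    table, tsv_findings, na_columns = _parse_blood_tsv(tsv_doc, path)
    findings = list(findings) + tsv_findings

    cols = list(table.frame.columns)
    if "time" not in cols:
        findings.append(error("PET301", path, "blood TSV has no 'time' column"))
    else:
        t = table.frame["time"].to_numpy(dtype=float)
        if "time" in na_columns:
            findings.append(error("PET303", path, "time column contains 'n/a' cells"))
        elif not np.isnan(t).any() and len(t) > 1 and not (np.diff(t) > 0).all():
            findings.append(error(
                "PET302", path, "time column must be strictly increasing",
            ))

    for col in cols:
        if col in FRACTION_COLUMNS:
            v = table.frame[col].to_numpy(dtype=float)
            bad = v[~np.isnan(v)]
            if ((bad < 0) | (bad > 1)).any():
                findings.append(error(
                    "PET306", path, f"{col} values must lie in [0, 1]",
                ))

    for col in meta.declared_columns():
        if col != "time" and col not in cols:
            findings.append(error(
                "PET304", path,
                f"metadata declares {col} available but the TSV has no such column",
            ))
    for col in cols:
        if col != "time" and col not in meta.columns:
            findings.append(error(
                "PET305", path,
                f"TSV column {col} has no descriptor in the blood sidecar",
            ))
    return meta, table, sort_findings(findings)


def _validate_for_write(meta: BloodMetadata, table: BloodTable) -> None:
    cols = list(table.frame.columns)
    if not cols or cols[0] != "time":
        raise ValueError("blood table must start with a 'time' column")
    t = table.times
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValueError("blood table time must be strictly increasing")
    for col in cols:
        if col in FRACTION_COLUMNS:
            v = table.frame[col].to_numpy(dtype=float)
            ok = v[~np.isnan(v)]
            if ((ok < 0) | (ok > 1)).any():
                raise ValueError(f"{col} values must lie in [0, 1]")
        if col != "time" and col not in meta.columns:
            raise ValueError(f"column {col} lacks a sidecar descriptor")


def write_blood_record(meta: BloodMetadata, table: BloodTable) -> tuple[str, str]:
    """Serialize a blood record to (json_doc, tsv_doc).

    Inverse of :func:`read_blood_record`: values round-trip exactly thanks
    to ``repr``-precision float rendering, NaN cells become literal ``n/a``,
    and the TSV uses tab separators, LF line endings and a header row.
    """
    _validate_for_write(meta, table)

    doc: dict[str, Any] = dict(meta.extra)
    doc["Recording"] = meta.recording
    doc["PlasmaAvail"] = meta.plasma_avail
    doc["WholeBloodAvail"] = meta.whole_blood_avail
    doc["MetaboliteAvail"] = meta.metabolite_avail
    for col, descriptor in meta.columns.items():
        doc[col] = descriptor
    json_doc = json.dumps(doc, indent=4, sort_keys=True, ensure_ascii=False) + "\n"

    lines = ["\t".join(table.frame.columns)]
    for _, row in table.frame.iterrows():
        lines.append("\t".join(
            NA if math.isnan(v) else _render_float(v) for v in row.to_numpy(float)
        ))
    return json_doc, "\n".join(lines) + "\n"


def _render_float(v: float) -> str:
    """Shortest decimal that parses back to the same double (0 ulp loss)."""
    v = float(v)
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(v)


def default_column_descriptors(columns) -> dict[str, dict[str, str]]:
    """Sidecar descriptors (description + SI units) for canonical columns."""
    descriptions = {
        "time": "Sample time relative to time zero",
        "plasma_radioactivity": "Radioactivity concentration in plasma",
        "whole_blood_radioactivity": "Radioactivity concentration in whole blood",
        "metabolite_parent_fraction": "Fraction of plasma radioactivity from the unmetabolized parent compound",
        "metabolite_polar_fraction": "Fraction of plasma radioactivity from polar metabolites",
    }
    return {
        c: {"Description": descriptions[c], "Units": _EXPECTED_COLUMN_UNITS[c]}
        for c in columns
    }


def merge_recordings(manual: BloodTable, autosampler: BloodTable) -> BloodTable:
    """Combine a manual-draw table with an autosampler stream.

    The result is the union of time points, sorted.  At a shared time the
    continuous device wins for whole-blood radioactivity; plasma and
    metabolite columns always come from the manual draws.  No interpolation
    is performed — the standard stores measurements, not derived curves.
    Duplicate times with disagreeing manual values raise.
    """
    for t in (manual, autosampler):
        times = t.times
        if len(times) > 1 and not (np.diff(times) > 0).all():
            raise ValueError("input tables must have strictly increasing time")

    man = manual.frame.set_index("time") if "time" in manual.frame else pd.DataFrame()
    auto = (
        autosampler.frame.set_index("time")
        if "time" in autosampler.frame
        else pd.DataFrame()
    )

    all_times = sorted(set(man.index) | set(auto.index))
    columns = ["time"] + [
        c for c in CANONICAL_COLUMNS[1:]
        if c in man.columns or c in auto.columns
    ]
    rows = []
    for t in all_times:
        row = {"time": t}
        for col in columns[1:]:
            man_v = man.at[t, col] if t in man.index and col in man.columns else math.nan
            auto_v = (
                auto.at[t, col] if t in auto.index and col in auto.columns else math.nan
            )
            if col == "whole_blood_radioactivity" and not math.isnan(auto_v):
                # continuous device wins at shared time points
                row[col] = auto_v
            elif not math.isnan(man_v):
                if not math.isnan(auto_v) and auto_v != man_v:
                    raise ValueError(
                        f"disagreeing values for {col} at shared time {t}: "
                        f"manual {man_v} vs autosampler {auto_v}"
                    )
                row[col] = man_v
            else:
                row[col] = auto_v
        rows.append(row)

    merged = pd.DataFrame(rows, columns=columns, dtype=float) if rows else pd.DataFrame(
        {c: pd.Series(dtype=float) for c in columns}
    )
    return BloodTable(merged)
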