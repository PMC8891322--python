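"""Single-time-scale conventions: decay correction and time-zero anchoring.

Every time in a PET-BIDS dataset — frame starts, blood sample times, the
decay-correction reference — is expressed in seconds relative to one
"time zero", defined as either injection start or scan start.  Radioactive
decay is compensated with the standard exponential law: an activity measured
``t`` seconds after the reference is multiplied by

    factor(t) = 2 ** (t / T_half)

to obtain the activity decay-corrected to the reference.  Negative elapsed
times (samples drawn before time zero) are legal and give factors below 1.

The injected dose is conventionally decay-corrected to the moment of
injection, regardless of which anchor the dataset uses as time zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .blood import BloodTable
    from .metadata import PetMetadata

__all__ = [
    "TimeZeroConvention",
    "DecayContext",
    "HALF_LIVES_S",
    "decay_correction_factor",
    "rereference_correction",
    "dose_at_injection",
    "shift_time_zero",
]


class TimeZeroConvention(enum.Enum):
    INJECTION_START = "injection_start"
    SCAN_START = "scan_start"


#: Reference half-lives (seconds) of radionuclides common in brain PET.
#: Convenience values from standard nuclear-data tables; half-lives are
#: always supplied explicitly through DecayContext, never looked up silently.
HALF_LIVES_S: dict[str, float] = {
    "C11": 1221.84,
    "N13": 597.9,
    "O15": 122.24,
    "F18": 6586.2,
    "Ga68": 4062.6,
    "Zr89": 282276.0,
}


@dataclass(frozen=True)
class DecayContext:
    """Radionuclide half-life plus the chosen time-zero convention."""

    half_life_s: float
    time_zero_convention: TimeZeroConvention = TimeZeroConvention.INJECTION_START

    def __post_init__(self) -> None:
        if not self.half_life_s > 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_s}")


def decay_correction_factor(elapsed_s, ctx: DecayContext):
    """Multiplicative factor correcting an activity back to time zero.

    ``measured * factor`` is the activity decay-corrected to the reference
    time; ``factor(0) == 1`` and ``factor(T_half) == 2``.  Accepts scalars
    or arrays of elapsed seconds.
    """
    factor = 2.0 ** (np.asarray(elapsed_s, dtype=float) / ctx.half_life_s)
    return float(factor) if np.ndim(factor) == 0 else factor


def rereference_correction(
    values: Sequence[float],
    old_zero_offset_s: float,
    new_zero_offset_s: float,
    ctx: DecayContext,
) -> np.ndarray:
    """Re-reference decay-corrected values from one time zero to another.

    ``values`` are decay-corrected to a reference sitting at
    ``old_zero_offset_s`` on some common clock; the result is corrected to
    the reference at ``new_zero_offset_s``.  Because the decay law is
    exponential this is one constant factor,
    ``2 ** ((old - new) / T_half)``, applied to every value: moving the
    reference one half-life earlier doubles every corrected value.
    """
    factor = 2.0 ** ((old_zero_offset_s - new_zero_offset_s) / ctx.half_life_s)
    return np.asarray(values, dtype=float) * factor


def dose_at_injection(
    measured_activity: float, measurement_offset_s: float, ctx: DecayContext
) -> float:
    """Decay-correct a dose assay to the moment of injection.

    ``measurement_offset_s`` is signed: positive when the dose was assayed
    after the injection (the decayed reading is scaled up), negative when
    assayed before (scaled down).
    """
    return measured_activity * 2.0 ** (measurement_offset_s / ctx.half_life_s)


def shift_time_zero(
    m: "PetMetadata",
    tables: Sequence["BloodTable"],
    new_convention: TimeZeroConvention,
    ctx: DecayContext,
) -> tuple["PetMetadata", list["BloodTable"]]:
    """Move the dataset's time zero to the other anchor (injection/scan start).

    Every time field — ScanStart, InjectionStart, FrameTimesStart,
    ImageDecayCorrectionTime, blood ``time`` columns — is shifted by the same
    constant so the new anchor reads 0, preserving all inter-event intervals
    exactly.  Decay-corrected radioactivity columns are re-referenced to the
    new zero via :func:`rereference_correction`.  Shifting back restores the
    original up to floating point (the operation is an involution).
    """
    from .blood import RADIOACTIVITY_COLUMNS

    if m.scan_start is None or m.injection_start is None:
        raise ValueError("shift_time_zero requires both ScanStart and InjectionStart")

    delta = (
        m.injection_start
        if new_convention is TimeZeroConvention.INJECTION_START
        else m.scan_start
    )

    new_meta = replace(
        m,
        scan_start=m.scan_start - delta,
        injection_start=m.injection_start - delta,
        frame_times_start=[t - delta for t in m.frame_times_start],
        image_decay_correction_time=(
            None
            if m.image_decay_correction_time is None
            else m.image_decay_correction_time - delta
        ),
        time_zero=_shift_clock(m.time_zero, delta),
    )

    new_tables = []
    for table in tables:
        df = table.frame.copy()
        df["time"] = df["time"] - delta
        for col in df.columns:
            if col in RADIOACTIVITY_COLUMNS:
                df[col] = rereference_correction(df[col].to_numpy(float), 0.0, delta, ctx)
        new_tables.append(replace(table, frame=df))
    return new_meta, new_tables


def _shift_clock(hhmmss: str | None, delta_s: float) -> str | None:
    """Advance an HH:MM:SS clock string by delta seconds (wraps at midnight)."""
    if hhmmss is None:
        return None
    h, mi, s = (int(x) for x in hhmmss.split(":"))
    total = (h * 3600 + mi * 60 + s + int(round(delta_s))) % 86400
    return f"{total // 3600:02d}:{total % 3600 // 60:02d}:{total % 60:02d}"
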