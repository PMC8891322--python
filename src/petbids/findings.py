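"""Finding and report types shared by the metadata, blood and validator layers.

A *finding* is one rule violation (or advisory) attached to a dataset-relative
path.  Findings carry a stable code so that downstream tooling can filter and
so that the test suite can assert on exact rules rather than message text.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, order=True)
class Finding:
    """One validation finding: stable code, severity, path and message."""

    path: str
    code: str
    severity: Severity = field(compare=False)
    message: str = field(compare=False)

    def as_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity.value,
            "path": self.path,
            "message": self.message,
        }

    def render(self) -> str:
        return f"{self.severity.value} {self.code} {self.path}: {self.message}"


def error(code: str, path: str, message: str) -> Finding:
    return Finding(path=path, code=code, severity=Severity.ERROR, message=message)


def warning(code: str, path: str, message: str) -> Finding:
    return Finding(path=path, code=code, severity=Severity.WARNING, message=message)


def sort_findings(findings: list[Finding]) -> list[Finding]:
    """Deterministic report order: by (path, code), then message for stability."""
    return sorted(findings, key=lambda f: (f.path, f.code, f.message))
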