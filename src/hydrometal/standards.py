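"""Regulatory constants: permissible limits, oral reference doses, slope factors.

The permissible limits default to WHO drinking-water guideline values
(Cd 0.003, Cu 2, Fe 0.3, Pb 0.01, Zn 3 mg/L); reference doses default to
the standard oral RfDs used in ingestion risk assessment.  Cancer slope
factors are never defaulted silently: an example table (Cd, Pb only) is
loaded only on explicit request, since the choice of slope factor
dominates any carcinogenic-risk figure.  All three tables are
overridable via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .records import METALS

#: WHO drinking-water guideline limits, mg/L.
WHO_LIMITS: dict[str, float] = {
    "cd": 0.003,
    "cu": 2.0,
    "fe": 0.3,
    "pb": 0.01,
    "zn": 3.0,
}

#: Standard oral reference doses, mg/(kg day).
DEFAULT_RFD: dict[str, float] = {
    "cd": 5e-4,
    "cu": 0.04,
    "fe": 0.7,
    "pb": 3.5e-3,
    "zn": 0.3,
}

#: Example oral cancer slope factors, (mg/(kg day))^-1.  Only Cd and Pb
#: have commonly tabulated oral values; the others are left absent.
EXAMPLE_CSF: dict[str, float] = {"cd": 6.1, "pb": 0.0085}


@dataclass
class StandardsTable:
    """Per-metal permissible limit, reference dose and optional slope factor."""

    limits: dict[str, float]
    rfd: dict[str, float] = field(default_factory=dict)
    csf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, v in self.limits.items():
            if v <= 0:
                raise ValueError(f"permissible limit for {m!r} must be > 0, got {v}")
        for m, v in self.rfd.items():
            if v <= 0:
                raise ValueError(f"RfD for {m!r} must be > 0, got {v}")
        for m, v in self.csf.items():
            if v < 0:
                raise ValueError(f"CSF for {m!r} must be >= 0, got {v}")

    @classmethod
    def default(cls, with_example_csf: bool = False) -> "StandardsTable":
        """WHO limits and standard RfDs; slope factors only if asked for."""
        return cls(
            limits=dict(WHO_LIMITS),
            rfd=dict(DEFAULT_RFD),
            csf=dict(EXAMPLE_CSF) if with_example_csf else {},
        )

    @classmethod
    def from_yaml(cls, path) -> "StandardsTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            limits={k: float(v) for k, v in raw.get("limits", {}).items()},
            rfd={k: float(v) for k, v in raw.get("rfd", {}).items()},
            csf={k: float(v) for k, v in raw.get("csf", {}).items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"limits": self.limits, "rfd": self.rfd, "csf": self.csf}, fh
            )

    def require_limits(self, metals=METALS) -> None:
        missing = [m for m in metals if m not in self.limits]
        if missing:
            raise KeyError(f"no permissible limit for metals: {missing}")

    def require_rfd(self, metals=METALS) -> None:
        missing = [m for m in metals if m not in self.rfd]
        if missing:
            raise KeyError(f"no reference dose for metals: {missing}")
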