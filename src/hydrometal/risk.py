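"""Deterministic ingestion health-risk chain.

Average daily intake (ADI, mg per kg body weight per day) of each metal
follows the standard US-EPA exposure model

    ADI = C * IR * EF * ED / (BW * AT)

with C the water concentration (mg/L), IR the daily water intake (L/day),
EF the exposure frequency (days/yr), ED the exposure duration (yr), BW
the body weight (kg) and AT the averaging time (days).  Under the
lifetime scenario used here AT = ED * EF, so ED and EF cancel and
ADI = C * IR / BW.

Non-carcinogenic risk: hazard quotient HQ = ADI / RfD per metal, hazard
index HI = sum of HQs; HI <= 1 means no adverse effect is expected.
Carcinogenic risk: CR = ADI * CSF per metal with a slope factor,
carcinogenic index CI = sum of CRs; the conventional acceptable band is
1e-6 to 1e-4 excess lifetime cancer probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import METALS, SampleRecord, replicate_means
from .standards import StandardsTable

#: Acceptable excess lifetime cancer probability band (1 in 1,000,000
#: to 1 in 10,000).
CR_ACCEPTABLE = (1e-6, 1e-4)


@dataclass(frozen=True)
class ExposureProfile:
    """Ingestion exposure scenario.

    Defaults: adult lifetime drinking-water scenario — 70 kg body
    weight, 2 L/day intake, 365 days/yr over 70 years, averaging time
    ED * EF days.
    """

    body_weight: float = 70.0  # kg
    intake_rate: float = 2.0  # L/day
    exposure_frequency: float = 365.0  # days/yr
    exposure_duration: float = 70.0  # yr
    averaging_time: float | None = None  # days; None -> ED * EF

    def __post_init__(self) -> None:
        for name in (
            "body_weight",
            "intake_rate",
            "exposure_frequency",
            "exposure_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.averaging_time is None:
            object.__setattr__(
                self,
                "averaging_time",
                self.exposure_duration * self.exposure_frequency,
            )
        if self.averaging_time <= 0:
            raise ValueError("averaging_time must be > 0")


#: Named scenario presets: shorter residency durations and a lower
#: drinking-water intake sometimes used for local conditions.
PRESETS: dict[str, ExposureProfile] = {
    "default": ExposureProfile(),
    "ed30": ExposureProfile(exposure_duration=30.0),
    "ed65": ExposureProfile(exposure_duration=65.0),
    "ir1.5": ExposureProfile(intake_rate=1.5),
}


def average_daily_intake(conc: float, profile: ExposureProfile) -> float:
    """ADI in mg/(kg day) for a concentration in mg/L."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return (
        conc
        * profile.intake_rate
        * profile.exposure_frequency
        * profile.exposure_duration
    ) / (profile.body_weight * profile.averaging_time)


def hazard_quotient(adi: float, rfd: float) -> float:
    if rfd <= 0:
        raise ValueError(f"reference dose must be > 0, got {rfd}")
    return adi / rfd


def carcinogenic_risk(adi: float, csf: float | None) -> float | None:
    """CR = ADI * CSF; ``None`` slope factor yields ``None`` (excluded from CI)."""
    if csf is None:
        return None
    if csf < 0:
        raise ValueError(f"slope factor must be >= 0, got {csf}")
    return adi * csf


@dataclass
class RiskResult:
    """Per-metal ADI/HQ/CR and the HI / CI aggregates for one sample."""

    sample_id: str
    season: str
    adi: dict[str, float]
    hq: dict[str, float] = field(default_factory=dict)
    cr: dict[str, float] = field(default_factory=dict)
    hi: float | None = None
    ci: float | None = None
    exceeds_unity: bool = False
    ci_class: str | None = None
    no_csf: list[str] = field(default_factory=list)


def hazard_index(
    record: SampleRecord, standards: StandardsTable, profile: ExposureProfile
) -> RiskResult:
    """Sum of hazard quotients over all metals; flags HI > 1."""
    metals = [m for m in METALS if m in record.conc]
    standards.require_rfd(metals)
    adi = {m: average_daily_intake(record.conc[m], profile) for m in metals}
    hq = {m: hazard_quotient(adi[m], standards.rfd[m]) for m in metals}
    hi = float(sum(hq.values()))
    return RiskResult(
        sample_id=record.sample_id,
        season=record.season,
        adi=adi,
        hq=hq,
        hi=hi,
        exceeds_unity=hi > 1.0,
    )


def _classify_ci(ci: float) -> str:
    lo, hi = CR_ACCEPTABLE
    if ci < lo:
        return "below_acceptable_band"
    if ci <= hi:
        return "acceptable"
    return "above_acceptable_band"


def carcinogenic_index(
    record: SampleRecord, standards: StandardsTable, profile: ExposureProfile
) -> RiskResult:
    """Sum of carcinogenic risks over metals that have a slope factor."""
    metals = [m for m in METALS if m in record.conc]
    with_csf = [m for m in metals if m in standards.csf]
    if not with_csf:
        raise ValueError("no metal in the standards table has a cancer slope factor")
    adi = {m: average_daily_intake(record.conc[m], profile) for m in metals}
    cr = {m: adi[m] * standards.csf[m] for m in with_csf}
    ci = float(sum(cr.values()))
    return RiskResult(
        sample_id=record.sample_id,
        season=record.season,
        adi=adi,
        cr=cr,
        ci=ci,
        ci_class=_classify_ci(ci),
        no_csf=[m for m in metals if m not in standards.csf],
    )


def risk_table(
    records: list[SampleRecord],
    standards: StandardsTable,
    profile: ExposureProfile | None = None,
    replicate_mode: str = "mean",
) -> pd.DataFrame:
    """Tidy per-sample risk table: adi_*, hq_*, hi, cr_*, ci and flags.

    CI columns appear only when the standards table carries slope
    factors.  Replicates are averaged per station x season by default.
    """
    if replicate_mode not in ("mean", "each"):
        raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    profile = profile or ExposureProfile()
    if replicate_mode == "mean":
        records = replicate_means(records)
    has_csf = bool(standards.csf)
    rows = []
    for rec in records:
        res = hazard_index(rec, standards, profile)
        row: dict[str, object] = {
            "sample_id": rec.sample_id,
            "river": rec.river,
            "season": rec.season,
        }
        for m in METALS:
            row[f"adi_{m}"] = res.adi.get(m, float("nan"))
        for m in METALS:
            row[f"hq_{m}"] = res.hq.get(m, float("nan"))
        row["hi"] = res.hi
        row["exceeds_unity"] = res.exceeds_unity
        if has_csf:
            cres = carcinogenic_index(rec, standards, profile)
            for m in METALS:
                row[f"cr_{m}"] = cres.cr.get(m, float("nan"))
            row["ci"] = cres.ci
            row["ci_class"] = cres.ci_class
        rows.append(row)
    return pd.DataFrame(rows)
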