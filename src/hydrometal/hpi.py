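"""Weighted heavy-metal pollution index (HPI).

Each metal contributes a sub-index Wp * Sc, where the parameter weight
Wp is the metal's limit-reciprocal Rw = 1/limit normalised over all
metals (so sum Wp = 1), and the contamination status Sc is the measured
concentration divided by the permissible limit.  The total index is the
sum of sub-indices, so water exactly at every limit scores 1.

Classification uses a five-band scale: 0-0.25 negligible pollution
(excellent water), 0.25-0.5 very low (good), 0.5-0.75 low (poor),
0.75-1 moderate (very poor), above 1 high pollution (not fit for
drinking).  Band edges belong to the lower band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import METALS, SampleRecord, replicate_means, to_frame
from .standards import StandardsTable

#: (upper edge, band label); the final band is open above 1.
BANDS: tuple[tuple[float, str], ...] = (
    (0.25, "negligible/excellent"),
    (0.5, "very_low/good"),
    (0.75, "low/poor"),
    (1.0, "moderate/very_poor"),
    (float("inf"), "high/unfit"),
)


def relative_weight(limit: float) -> float:
    """Rw = 1 / permissible limit (L/mg)."""
    if limit <= 0:
        raise ValueError(f"permissible limit must be > 0, got {limit}")
    return 1.0 / limit


def parameter_weights(standards: StandardsTable) -> dict[str, float]:
    """Normalised weights Wp = Rw / sum(Rw); they sum to 1."""
    if not standards.limits:
        raise ValueError("standards table has no permissible limits")
    rw = {m: relative_weight(v) for m, v in standards.limits.items()}
    total = sum(rw.values())
    return {m: w / total for m, w in rw.items()}


def contamination_status(conc: float, limit: float) -> float:
    """Sc = measured concentration / permissible limit."""
    if limit <= 0:
        raise ValueError(f"permissible limit must be > 0, got {limit}")
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    return conc / limit


def classify_hpi(value: float) -> str:
    """Map an index value onto the five-band quality scale."""
    if value < 0:
        raise ValueError(f"HPI must be >= 0, got {value}")
    for upper, label in BANDS:
        if value <= upper:
            return label
    raise AssertionError("unreachable")


@dataclass
class HPIResult:
    """Per-metal decomposition and total of the pollution index."""

    sample_id: str
    season: str
    rw: dict[str, float]
    wp: dict[str, float]
    sc: dict[str, float]
    subindex: dict[str, float]
    hpi_total: float
    band: str
    excluded: frozenset[str] = frozenset()
    warnings: list[str] = field(default_factory=list)


def hpi_total(
    record: SampleRecord,
    standards: StandardsTable,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> HPIResult:
    """Compute the full index chain for one sample.

    ``exclude`` drops metals from the sum *without* renormalising the
    weights: the question "what if cadmium were absent" is answered by
    removing its sub-index, not by re-weighting the rest.
    """
    exclude = frozenset(exclude)
    metals = [m for m in METALS if m in record.conc]
    standards.require_limits([m for m in metals if m not in exclude])
    wp = parameter_weights(standards)
    rw = {m: relative_weight(standards.limits[m]) for m in standards.limits}
    sc = {
        m: contamination_status(record.conc[m], standards.limits[m])
        for m in metals
        if m not in exclude
    }
    sub = {m: wp[m] * sc[m] for m in sc}
    total = float(sum(sub.values()))
    warnings = [
        f"{m}: censored value entered at its substitution level"
        for m in sc
        if record.below_detection.get(m, False)
    ]
    return HPIResult(
        sample_id=record.sample_id,
        season=record.season,
        rw=rw,
        wp=wp,
        sc=sc,
        subindex=sub,
        hpi_total=total,
        band=classify_hpi(total),
        excluded=exclude,
        warnings=warnings,
    )


def hpi_table(
    records: list[SampleRecord],
    standards: StandardsTable,
    exclude: frozenset[str] | set[str] = frozenset(),
    replicate_mode: str = "mean",
) -> pd.DataFrame:
    """Tidy per-sample table of sub-indices, total and band.

    ``replicate_mode="mean"`` averages replicates per station x season
    first (the default); ``"each"`` scores every replicate.
    """
    if replicate_mode not in ("mean", "each"):
        raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    if replicate_mode == "mean":
        records = replicate_means(records)
    rows = []
    for rec in records:
        res = hpi_total(rec, standards, exclude)
        row: dict[str, object] = {
            "sample_id": res.sample_id,
            "river": rec.river,
            "season": res.season,
        }
        for m in METALS:
            row[f"hpi_{m}"] = res.subindex.get(m, float("nan"))
        row["hpi_total"] = res.hpi_total
        row["band"] = res.band
        row["n_censored"] = len(res.warnings)
        rows.append(row)
    return pd.DataFrame(rows)
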