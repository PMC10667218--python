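"""Canonical sample records and their CSV schema.

A record is one station x season x replicate observation of the five
heavy metals (Cd, Cu, Fe, Pb, Zn) in surface water, in mg/L, with a
below-detection flag per metal.  All modules exchange tables through
this schema, so pipeline stages compose via files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Metals handled throughout, in canonical column order.
METALS: tuple[str, ...] = ("cd", "cu", "fe", "pb", "zn")

#: Canonical CSV column order.
CSV_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "river",
    "season",
    "lon",
    "lat",
    "replicate",
    *(f"{m}_mg_l" for m in METALS),
    *(f"bdl_{m}" for m in METALS),
)


@dataclass
class SampleRecord:
    """One station x season x replicate water sample.

    ``conc`` holds concentrations in mg/L; ``below_detection`` marks
    metals whose raw measurement fell under the detection limit, in
    which case ``conc`` stores the substitution value (never negative).
    ``note`` carries free-text provenance and is not part of the CSV
    schema.
    """

    sample_id: str
    river: str
    season: str
    lon: float
    lat: float
    replicate: int
    conc: dict[str, float]
    below_detection: dict[str, bool] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        for m in METALS:
            if m not in self.conc:
                raise ValueError(f"record {self.sample_id}: missing metal {m!r}")
            if self.conc[m] < 0:
                raise ValueError(
                    f"record {self.sample_id}: negative concentration for {m!r}"
                )
            self.below_detection.setdefault(m, False)


def to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Convert records to a tidy DataFrame in the canonical schema."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "river": r.river,
            "season": r.season,
            "lon": r.lon,
            "lat": r.lat,
            "replicate": r.replicate,
        }
        for m in METALS:
            row[f"{m}_mg_l"] = r.conc[m]
            row[f"bdl_{m}"] = bool(r.below_detection.get(m, False))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def from_frame(df: pd.DataFrame) -> list[SampleRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                river=str(row["river"]),
                season=str(row["season"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                replicate=int(row["replicate"]),
                conc={m: float(row[f"{m}_mg_l"]) for m in METALS},
                below_detection={m: bool(row[f"bdl_{m}"]) for m in METALS},
            )
        )
    return records


def write_csv(records: list[SampleRecord], path) -> None:
    to_frame(records).to_csv(path, index=False)


def read_csv(path) -> list[SampleRecord]:
    return from_frame(pd.read_csv(path))


def replicate_means(records: list[SampleRecord]) -> list[SampleRecord]:
    """Average replicates per station x season.

    The mean concentration per metal is taken over replicates; the
    below-detection flag is propagated if any replicate was censored
    (its substitution value already entered the mean).
    """
    df = to_frame(records)
    out: list[SampleRecord] = []
    for (sid, river, season), grp in df.groupby(
        ["sample_id", "river", "season"], sort=False
    ):
        out.append(
            SampleRecord(
                sample_id=str(sid),
                river=str(river),
                season=str(season),
                lon=float(grp["lon"].mean()),
                lat=float(grp["lat"].mean()),
                replicate=0,
                conc={m: float(grp[f"{m}_mg_l"].mean()) for m in METALS},
                below_detection={m: bool(grp[f"bdl_{m}"].any()) for m in METALS},
            )
        )
    return out
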