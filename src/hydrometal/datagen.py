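"""Synthetic surface-water sampling campaigns.

Emulates a seasonal river monitoring design: a fixed set of stations on
a few rivers (plus a coastal lagoon), sampled in replicate in two
seasons, with the five metals drawn from a Gaussian copula so that both
the per-metal concentration ranges and the season-specific inter-metal
correlation structure can be dialled in.  Detection-limit censoring is
applied per station x season with a selectable substitution policy.

Only ranges and correlations define the marginals (no distribution
family is implied by range data), so each metal is mapped from its
copula normal score to a uniform on [low, high].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import ndtr

from .records import METALS, SampleRecord

#: Substitution policies for values below the detection limit.
CENSOR_POLICIES = ("zero", "half_lod", "drop")

# Study-shaped defaults: 10 stations on three rivers plus one lagoon,
# two seasons, 3 replicates.  Station S10 is the river confluence.
DEFAULT_STATIONS: dict[str, str] = {
    "S1": "nfifikh",
    "S2": "nfifikh",
    "S3": "lagoon",
    "S4": "el_maleh",
    "S5": "el_maleh",
    "S6": "hassar",
    "S7": "hassar",
    "S8": "el_maleh",
    "S9": "el_maleh",
    "S10": "el_maleh",
}

#: Observed per-metal concentration ranges, mg/L.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "cd": (0.005, 0.01),
    "cu": (0.005, 0.01),
    "fe": (0.007, 0.34),
    "pb": (0.007, 0.22),
    "zn": (0.009, 0.3),
}

#: Typical flame-AAS quantification limit used for all five metals, mg/L.
DEFAULT_DETECTION_LIMIT: dict[str, float] = {m: 0.004 for m in METALS}


def _corr(pairs: dict[tuple[str, str], float], fill: float = 0.2) -> np.ndarray:
    """Build a 5x5 correlation matrix from named pairs, default elsewhere."""
    k = len(METALS)
    c = np.full((k, k), fill)
    np.fill_diagonal(c, 1.0)
    idx = {m: i for i, m in enumerate(METALS)}
    for (a, b), r in pairs.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    return c

# Winter: moderate common-origin signal among Cd/Cu/Zn; spring: a
# near-singular structure with Cd/Fe/Zn moving together and Cd-Pb 0.998.
DEFAULT_CORRELATIONS: dict[str, np.ndarray] = {
    "winter": _corr(
        {("cd", "cu"): 0.727, ("cu", "zn"): 0.607, ("cd", "zn"): 0.607}, fill=0.3
    ),
    "spring": _corr(
        {
            ("cd", "fe"): 0.999,
            ("cd", "zn"): 0.999,
            ("fe", "zn"): 0.999,
            ("cd", "pb"): 0.998,
            ("fe", "pb"): 0.998,
            ("zn", "pb"): 0.998,
            ("cd", "cu"): 0.85,
            ("fe", "cu"): 0.85,
            ("zn", "cu"): 0.85,
            ("pb", "cu"): 0.85,
        },
        fill=0.85,
    ),
}

#: Stations whose spring samples fall below detection (downstream
#: border-river points and the confluence).
DEFAULT_CENSOR_STATIONS: dict[str, tuple[str, ...]] = {
    "spring": ("S1", "S2", "S10")
}

#: Study-extent bounding box, degrees (lon_min, lat_min, lon_max, lat_max).
DEFAULT_BBOX = (-7.45, 33.55, -7.15, 33.85)


def nearest_psd(corr: np.ndarray, tol: float = 0.1) -> np.ndarray:
    """Repair a symmetric correlation matrix to positive semi-definite.

    Negative eigenvalues are clipped to 1e-10 and the diagonal is
    renormalised back to 1.  If the repair moves the matrix by more
    than ``tol`` in Frobenius norm, the input is considered invalid.
    """
    c = np.asarray(corr, dtype=float)
    if c.shape != (len(METALS), len(METALS)):
        raise ValueError(f"correlation matrix must be {len(METALS)}x{len(METALS)}")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    w, v = np.linalg.eigh(c)
    if w.min() >= 0:
        return c
    w = np.clip(w, 1e-10, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.linalg.norm(fixed - c, "fro") > tol:
        raise ValueError(
            "correlation matrix is too far from positive semi-definite "
            f"(Frobenius repair distance > {tol})"
        )
    return fixed


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic sampling campaign."""

    stations: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STATIONS)
    )  # station id -> river label
    seasons: tuple[str, ...] = ("winter", "spring")
    replicates: int = 3
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    correlations: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_CORRELATIONS.items()}
    )
    detection_limits: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_LIMIT)
    )
    censor_stations: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CENSOR_STATIONS)
    )
    censor_policy: str = "half_lod"
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    replicate_cv: float = 0.02  # relative measurement noise across replicates
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stations:
            raise ValueError("at least one station is required")
        if not self.seasons:
            raise ValueError("at least one season is required")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.censor_policy not in CENSOR_POLICIES:
            raise ValueError(f"unknown censor policy {self.censor_policy!r}")
        for m, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"range for {m!r} must satisfy 0 < low < high")
        self.correlations = {
            s: nearest_psd(c) for s, c in self.correlations.items()
        }

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "correlations" in raw:
            raw["correlations"] = {
                s: np.asarray(c, dtype=float) for s, c in raw["correlations"].items()
            }
        for key in ("seasons",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "ranges" in raw:
            raw["ranges"] = {m: tuple(v) for m, v in raw["ranges"].items()}
        if "censor_stations" in raw:
            raw["censor_stations"] = {
                s: tuple(v) for s, v in raw["censor_stations"].items()
            }
        if "bbox" in raw:
            raw["bbox"] = tuple(raw["bbox"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "stations": self.stations,
            "seasons": list(self.seasons),
            "replicates": self.replicates,
            "ranges": {m: list(v) for m, v in self.ranges.items()},
            "correlations": {
                s: np.asarray(c).tolist() for s, c in self.correlations.items()
            },
            "detection_limits": self.detection_limits,
            "censor_stations": {
                s: list(v) for s, v in self.censor_stations.items()
            },
            "censor_policy": self.censor_policy,
            "bbox": list(self.bbox),
            "replicate_cv": self.replicate_cv,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _station_coordinates(
    config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, tuple[float, float]]:
    """Uniform coordinates in the bounding box, rivers in longitude bands."""
    lon_min, lat_min, lon_max, lat_max = config.bbox
    rivers = sorted(set(config.stations.values()))
    width = (lon_max - lon_min) / len(rivers)
    band = {r: i for i, r in enumerate(rivers)}
    coords = {}
    for sid, river in config.stations.items():
        b = band[river]
        lon = rng.uniform(lon_min + b * width, lon_min + (b + 1) * width)
        lat = rng.uniform(lat_min, lat_max)
        coords[sid] = (float(lon), float(lat))
    return coords


def generate_samples(config: GeneratorConfig) -> list[SampleRecord]:
    """Draw one full campaign: stations x seasons x replicates records.

    Station-level metal vectors come from a Gaussian copula with the
    season's correlation matrix, mapped to uniform marginals on each
    metal's range; replicates add a small multiplicative measurement
    noise (clipped back into the range).  A dedicated child stream per
    season keeps seasons independently reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    coord_seq, *season_seqs = root.spawn(1 + len(config.seasons))
    coords = _station_coordinates(config, np.random.default_rng(coord_seq))
    station_ids = list(config.stations)
    records: list[SampleRecord] = []
    for season, seq in zip(config.seasons, season_seqs):
        if season not in config.correlations:
            raise KeyError(f"no correlation matrix configured for season {season!r}")
        rng = np.random.default_rng(seq)
        # Invert the Gaussian-copula attenuation for uniform marginals:
        # a normal-score correlation of 2*sin(pi*r/6) yields Pearson r
        # between the uniforms.
        corr = 2.0 * np.sin(np.pi * config.correlations[season] / 6.0)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(METALS)))
        z = rng.standard_normal((len(station_ids), len(METALS))) @ chol.T
        u = ndtr(z)  # normal scores -> uniforms, correlation preserved in rank
        for i, sid in enumerate(station_ids):
            base = {
                m: config.ranges[m][0]
                + u[i, j] * (config.ranges[m][1] - config.ranges[m][0])
                for j, m in enumerate(METALS)
            }
            for rep in range(1, config.replicates + 1):
                noise = rng.normal(1.0, config.replicate_cv, size=len(METALS))
                conc = {
                    m: float(
                        np.clip(
                            base[m] * noise[j],
                            config.ranges[m][0],
                            config.ranges[m][1],
                        )
                    )
                    for j, m in enumerate(METALS)
                }
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        river=config.stations[sid],
                        season=season,
                        lon=coords[sid][0],
                        lat=coords[sid][1],
                        replicate=rep,
                        conc=conc,
                    )
                )
    # Forced below-detection cells (e.g. spring at the border-river
    # stations): push the raw value under the limit, then substitute.
    forced = {
        (season, sid)
        for season, sids in config.censor_stations.items()
        for sid in sids
    }
    if forced:
        for rec in records:
            if (rec.season, rec.sample_id) in forced:
                for m in METALS:
                    rec.conc[m] = config.detection_limits[m] * 0.9
    return apply_censoring(records, config.detection_limits, config.censor_policy)


def apply_censoring(
    records: list[SampleRecord],
    detection_limits: dict[str, float],
    policy: str = "half_lod",
) -> list[SampleRecord]:
    """Flag and substitute concentrations below the detection limit.

    Policies: ``half_lod`` stores LOD/2 (the common environmental-
    statistics convention), ``zero`` stores 0, ``drop`` removes any
    record with a censored metal.
    """
    if policy not in CENSOR_POLICIES:
        raise ValueError(
            f"unknown censor policy {policy!r}; expected one of {CENSOR_POLICIES}"
        )
    out: list[SampleRecord] = []
    for rec in records:
        censored = [
            m
            for m in METALS
            if m in detection_limits and rec.conc[m] < detection_limits[m]
        ]
        if censored and policy == "drop":
            continue
        for m in censored:
            rec.below_detection[m] = True
            rec.conc[m] = 0.0 if policy == "zero" else detection_limits[m] / 2.0
        out.append(rec)
    return out


# --- printed station vectors -------------------------------------------------

# Synthetic placeholder coordinates (the survey's true station
# coordinates are not published): one per station label, inside the
# study-extent bounding box, west-to-east by river.
_FIXTURE_COORDS: dict[tuple[str, str], tuple[float, float]] = {
    ("S1", "nfifikh"): (-7.42, 33.58),
    ("S2", "nfifikh"): (-7.40, 33.70),
    ("S3", "lagoon"): (-7.36, 33.72),
    ("S4", "el_maleh"): (-7.33, 33.69),
    ("S5", "el_maleh"): (-7.32, 33.71),
    ("S8", "el_maleh"): (-7.30, 33.60),
    ("S9", "el_maleh"): (-7.29, 33.62),
    ("S4", "hassar"): (-7.25, 33.66),
    ("S5", "hassar"): (-7.24, 33.68),
    ("S10", "hassar"): (-7.31, 33.73),
}


def _rec(
    sid: str,
    river: str,
    season: str,
    cd: float,
    cu: float,
    fe: float,
    pb: float,
    zn: float,
    note: str = "",
    bdl: bool = False,
) -> SampleRecord:
    lon, lat = _FIXTURE_COORDS[(sid, river)]
    return SampleRecord(
        sample_id=sid,
        river=river,
        season=season,
        lon=lon,
        lat=lat,
        replicate=1,
        conc={"cd": cd, "cu": cu, "fe": fe, "pb": pb, "zn": zn},
        below_detection={m: bdl for m in METALS},
        note=note,
    )


def reference_survey(nfifikh_winter_variant: str = "both") -> list[SampleRecord]:
    """Station-level concentration vectors reported for the Mohammedia
    prefecture survey (rivers Nfifikh, Hassar, El Maleh and the Douar El
    Marja lagoon; winter and spring).

    Values are transcribed from the survey's running text and kept under
    the station labels as reported, even where those labels conflict:
    the text assigns S4/S5 to both El Maleh and Hassar, and indexes up
    to S10 while describing nine sampling points.  Coordinates are
    synthetic placeholders (the true ones are unpublished).

    The Nfifikh winter sentence is ambiguous: read positionally it puts
    Cu at 0.34 mg/L, but the per-metal summary ranges cap Cu at 0.01 and
    let Fe reach 0.34.  ``nfifikh_winter_variant`` selects ``"literal"``
    (positional reading), ``"range_consistent"`` (Fe/Cu swapped to match
    the summary ranges) or ``"both"`` (default; both variants included,
    tagged in ``note``).

    Spring samples below detection (Nfifikh S1/S2, confluence S10) carry
    the LOD/2 substitution value (LOD 0.004 mg/L) and set flags.
    """
    if nfifikh_winter_variant not in ("literal", "range_consistent", "both"):
        raise ValueError(f"unknown variant {nfifikh_winter_variant!r}")
    half_lod = DEFAULT_DETECTION_LIMIT["cd"] / 2.0

    literal = [
        _rec("S1", "nfifikh", "winter", 0.009, 0.018, 0.007, 0.019, 0.018,
             note="nfifikh winter, literal positional reading"),
        _rec("S2", "nfifikh", "winter", 0.008, 0.34, 0.009, 0.02, 0.06,
             note="nfifikh winter, literal positional reading"),
    ]
    range_consistent = [
        _rec("S1", "nfifikh", "winter", 0.009, 0.007, 0.018, 0.019, 0.018,
             note="nfifikh winter, Fe/Cu swapped to match summary ranges"),
        _rec("S2", "nfifikh", "winter", 0.008, 0.009, 0.34, 0.02, 0.06,
             note="nfifikh winter, Fe/Cu swapped to match summary ranges"),
    ]
    if nfifikh_winter_variant == "literal":
        nfifikh_winter = literal
    elif nfifikh_winter_variant == "range_consistent":
        nfifikh_winter = range_consistent
    else:
        nfifikh_winter = literal + range_consistent

    records = [
        # El Maleh winter: upstream points S8/S9 (range endpoints) and
        # the urban points S4/S5 downstream of the city.
        _rec("S8", "el_maleh", "winter", 0.006, 0.006, 0.006, 0.008, 0.009),
        _rec("S9", "el_maleh", "winter", 0.009, 0.007, 0.009, 0.009, 0.009),
        _rec("S4", "el_maleh", "winter", 0.01, 0.01, 0.009, 0.01, 0.009),
        _rec("S5", "el_maleh", "winter", 0.01, 0.01, 0.009, 0.01, 0.3),
        # Hassar winter, labels S4/S5 as reported despite the clash.
        _rec("S4", "hassar", "winter", 0.007, 0.01, 0.007, 0.009, 0.009),
        _rec("S5", "hassar", "winter", 0.009, 0.009, 0.007, 0.009, 0.009),
        # Hassar spring: all five metals at 0.009 mg/L.
        _rec("S4", "hassar", "spring", 0.009, 0.009, 0.009, 0.009, 0.009),
        _rec("S5", "hassar", "spring", 0.009, 0.009, 0.009, 0.009, 0.009),
        # Confluence S10: winter dilution; spring below detection.
        _rec("S10", "hassar", "winter", 0.005, 0.005, 0.006, 0.006, 0.009),
        _rec("S10", "hassar", "spring", half_lod, half_lod, half_lod,
             half_lod, half_lod, note="all metals below detection", bdl=True),
        *nfifikh_winter,
        _rec("S1", "nfifikh", "spring", half_lod, half_lod, half_lod,
             half_lod, half_lod, note="all metals below detection", bdl=True),
        _rec("S2", "nfifikh", "spring", half_lod, half_lod, half_lod,
             half_lod, half_lod, note="all metals below detection", bdl=True),
        # Coastal lagoon S3, both seasons.
        _rec("S3", "lagoon", "winter", 0.01, 0.01, 0.02, 0.22, 0.17),
        _rec("S3", "lagoon", "spring", 0.009, 0.01, 0.009, 0.009, 0.009),
    ]
    return records


def river_records(records: list[SampleRecord]) -> list[SampleRecord]:
    """Drop non-river (lagoon) samples."""
    return [r for r in records if r.river != "lagoon"]
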