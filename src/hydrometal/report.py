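"""Correlation summaries and end-to-end pipeline orchestration.

``run_pipeline`` chains every stage — sample generation or loading,
pollution index, health risk, model comparison, correlation matrices,
IDW surfaces — into one seeded, reproducible run that leaves a tidy CSV
per stage, plain-text map exports, a YAML manifest (config hash, seed)
and a human-readable summary of the headline checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import geo
from .datagen import GeneratorConfig, generate_samples
from .hpi import hpi_table
from .ml import compare_models
from .records import METALS, SampleRecord, read_csv, replicate_means, to_frame, write_csv
from .risk import ExposureProfile, risk_table
from .standards import StandardsTable

log = logging.getLogger("hydrometal")


@dataclass
class CorrelationReport:
    """Per-season Pearson matrix with two-sided p-values.

    p-values come from the standard t-transform of r; no
    multiple-testing correction is applied (stated in the output
    header).  Zero-variance metals yield undefined correlations,
    reported as NaN with a warning.
    """

    season: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# season={self.season} n={self.n} "
                "pearson r (upper block) and two-sided p (lower block); "
                "no multiple-testing correction applied\n"
            )
            self.r.to_csv(fh)
            self.p.to_csv(fh)


def correlation_matrix(
    records: list[SampleRecord], season: str
) -> CorrelationReport:
    """Pearson correlations between metals on station-level means."""
    means = [r for r in replicate_means(records) if r.season == season]
    if len(means) < 3:
        raise ValueError(
            f"need >= 3 stations with complete values for season {season!r}"
        )
    df = to_frame(means)
    data = {m: df[f"{m}_mg_l"].to_numpy() for m in METALS}
    k = len(METALS)
    r = np.eye(k)
    p = np.zeros((k, k))
    warns: list[str] = []
    for i, a in enumerate(METALS):
        for j in range(i + 1, k):
            b = METALS[j]
            if np.std(data[a]) == 0 or np.std(data[b]) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                warns.append(f"zero variance: correlation {a}-{b} undefined")
                continue
            res = stats.pearsonr(data[a], data[b])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    if warns:
        for w in warns:
            warnings.warn(w, RuntimeWarning, stacklevel=2)
    idx = list(METALS)
    return CorrelationReport(
        season=season,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=len(means),
        warnings=warns,
    )


@dataclass
class RunConfig:
    """One end-to-end pipeline run."""

    outdir: Path
    input_csv: Path | None = None  # exclusive with generator
    generator: GeneratorConfig | None = None
    standards: StandardsTable | None = None
    profile: ExposureProfile | None = None
    seed: int = 0
    censor_policy: str = "half_lod"
    with_csf: bool = False
    replicate_mode: str = "mean"
    k_folds: int = 5
    algorithms: tuple[str, ...] = ("random_forest", "svr", "ann")
    run_models: bool = True
    run_surfaces: bool = True
    cell_size: float = 0.01

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.input_csv is None and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)

    def digest(self) -> str:
        payload = {
            "input_csv": str(self.input_csv),
            "generator_seed": self.generator.seed if self.generator else None,
            "seed": self.seed,
            "censor_policy": self.censor_policy,
            "with_csf": self.with_csf,
            "replicate_mode": self.replicate_mode,
            "k_folds": self.k_folds,
            "algorithms": list(self.algorithms),
            "cell_size": self.cell_size,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _grid_spec(records: list[SampleRecord], cell_size: float):
    df = to_frame(records)
    pad = 2 * cell_size
    return dict(
        west=float(df["lon"].min()) - pad,
        south=float(df["lat"].min()) - pad,
        east=float(df["lon"].max()) + pad,
        north=float(df["lat"].max()) + pad,
        cell_size=cell_size,
    )


def _surfaces(records, hpi_df, risk_df, outdir: Path, cell_size: float) -> list[str]:
    means = replicate_means(records)
    spec = _grid_spec(means, cell_size)
    written = []
    seasons = sorted({r.season for r in means})
    for season in seasons:
        sub = [r for r in means if r.season == season]
        # per-metal concentration surfaces
        for metal in METALS:
            stations = [(r.lon, r.lat, r.conc[metal]) for r in sub]
            surf = geo.idw_interpolate(
                stations,
                geo.empty_grid(**spec, name=metal, season=season),
            )
            path = outdir / f"surface_{metal}_{season}.asc"
            geo.write_ascii_grid(surf, path)
            written.append(path.name)
        # pollution-index surface + banded map
        hsub = hpi_df[hpi_df["season"] == season]
        merged = {
            (r.sample_id, r.river): (r.lon, r.lat) for r in sub
        }
        stations = [
            (*merged[(row.sample_id, row.river)], row.hpi_total)
            for row in hsub.itertuples()
        ]
        surf = geo.idw_interpolate(
            stations, geo.empty_grid(**spec, name="hpi", season=season)
        )
        geo.write_ascii_grid(surf, outdir / f"surface_hpi_{season}.asc")
        banded = geo.band_surface(surf, geo.hpi_bands())
        geo.write_geojson_bands(banded, outdir / f"hpi_bands_{season}.geojson")
        geo.quicklook_png(banded, outdir / f"hpi_bands_{season}.png")
        written += [
            f"surface_hpi_{season}.asc",
            f"hpi_bands_{season}.geojson",
            f"hpi_bands_{season}.png",
        ]
        # hazard-index surface
        rsub = risk_df[risk_df["season"] == season]
        stations = [
            (*merged[(row.sample_id, row.river)], row.hi)
            for row in rsub.itertuples()
        ]
        surf = geo.idw_interpolate(
            stations, geo.empty_grid(**spec, name="hi", season=season)
        )
        geo.write_ascii_grid(surf, outdir / f"surface_hi_{season}.asc")
        written.append(f"surface_hi_{season}.asc")
    return written


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute every stage and write the report bundle to ``outdir``.

    Returns a dict with the in-memory tables and the list of files
    written.  Any stage failure propagates with the stage name; files
    already written are retained.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    standards = config.standards or StandardsTable.default(
        with_example_csf=config.with_csf
    )
    profile = config.profile or ExposureProfile()
    bundle: dict[str, object] = {"files": []}
    files: list[str] = bundle["files"]

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("stage %s", name)

    try:
        stage("samples")
        if config.input_csv is not None:
            records = read_csv(config.input_csv)
        else:
            records = generate_samples(config.generator)
        write_csv(records, outdir / "samples.csv")
        files.append("samples.csv")
        bundle["records"] = records

        stage("hpi")
        hpi_df = hpi_table(records, standards,
                           replicate_mode=config.replicate_mode)
        hpi_df.to_csv(outdir / "hpi.csv", index=False)
        files.append("hpi.csv")
        bundle["hpi"] = hpi_df

        stage("risk")
        risk_df = risk_table(records, standards, profile,
                             replicate_mode=config.replicate_mode)
        risk_df.to_csv(outdir / "risk.csv", index=False)
        files.append("risk.csv")
        bundle["risk"] = risk_df

        stage("correlations")
        seasons = sorted({r.season for r in records})
        corr_reports = []
        for season in seasons:
            try:
                rep = correlation_matrix(records, season)
            except ValueError:
                continue
            rep.to_csv(outdir / f"correlations_{season}.csv")
            files.append(f"correlations_{season}.csv")
            corr_reports.append(rep)
        bundle["correlations"] = corr_reports

        if config.run_models:
            stage("models")
            report = compare_models(
                records,
                algorithms=config.algorithms,
                k=config.k_folds,
                seed=config.seed,
            )
            report.to_csv(outdir / "metrics.csv")
            files.append("metrics.csv")
            if report.predictions is not None:
                report.predictions.to_csv(outdir / "predictions.csv",
                                          index=False)
                files.append("predictions.csv")
            bundle["metrics"] = report

        if config.run_surfaces:
            stage("surfaces")
            files.extend(
                _surfaces(records, hpi_df, risk_df, outdir, config.cell_size)
            )

        stage("summary")
        max_hi = float(risk_df["hi"].max())
        band_shares = (
            hpi_df["band"].value_counts(normalize=True).sort_index()
        )
        lines = [
            "hydrometal pipeline summary",
            f"config digest: {config.digest()}  seed: {config.seed}",
            f"samples: {len(records)}  stations x seasons scored: "
            f"{len(hpi_df)}",
            f"max hazard index: {max_hi:.4f} "
            f"({'<= 1: no adverse effect expected' if max_hi <= 1 else '> 1: potential risk'})",
            "pollution-index band shares:",
        ]
        lines += [f"  {band}: {share:.2%}" for band, share in band_shares.items()]
        if config.with_csf and "ci" in risk_df.columns:
            lines.append(f"max carcinogenic index: {risk_df['ci'].max():.4g}")
        summary = "\n".join(lines) + "\n"
        (outdir / "summary.txt").write_text(summary)
        files.append("summary.txt")
        bundle["summary"] = summary

        manifest = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "censor_policy": config.censor_policy,
            "with_csf": config.with_csf,
            "k_folds": config.k_folds,
            "algorithms": list(config.algorithms),
            "files": files,
        }
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        files.append("manifest.yaml")
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(
            f"pipeline stage {current['stage']!r} failed (partial outputs "
            f"retained in {outdir}): {exc}"
        ) from exc
    return bundle
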