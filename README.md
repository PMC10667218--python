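# hydrometal

Assessment toolkit for heavy-metal contamination of surface water
(rivers, lagoons), built around the seasonal monitoring campaign design
used for the rivers of Mohammedia prefecture, Morocco: ten stations on
three rivers plus a coastal lagoon, two seasons (winter/spring), three
replicates per station, five metals — Cd, Cu, Fe, Pb, Zn — in mg/L.

It is aimed at environmental scientists and water-quality engineers who
want, from one tabular set of station concentrations:

1. **A weighted heavy-metal pollution index (HPI).** Each metal's
   sub-index is the product of a normalised limit-reciprocal weight and
   a contamination ratio:

   Rw_m = 1 / L_m,  Wp_m = Rw_m / Σ Rw,  Sc_m = C_m / L_m,
   HPI_total = Σ_m Wp_m · Sc_m

   where L_m is the permissible limit and C_m the measured
   concentration. Water exactly at every limit scores 1. Classification
   bands: 0–0.25 negligible (excellent), 0.25–0.5 very low (good),
   0.5–0.75 low (poor), 0.75–1 moderate (very poor), > 1 high pollution
   (not fit for drinking).

2. **Deterministic ingestion health risk** (US-EPA style):
   ADI = C·IR·EF·ED / (BW·AT), HQ = ADI/RfD, HI = Σ HQ,
   CR = ADI·CSF, CI = Σ CR, with the lifetime drinking-water profile
   (BW 70 kg, IR 2 L/day, EF 365 days/yr, ED 70 yr, AT = ED·EF) as the
   default scenario.

3. **A three-algorithm regression comparison** (random forest with 15
   trees; ε-insensitive RBF-kernel SVR with ε = 0.015, γ = 1.2,
   C = 200; a 9-neuron sigmoid perceptron trained by
   Levenberg–Marquardt), scored by RMSE, MAE, MAPE (predicted-value
   denominator) and R² on a seeded 70/30 split plus k-fold
   cross-validation.

4. **Inverse-distance-weighted surfaces** of concentrations, indices
   and risks, with banded quality maps, exported as plain-text ESRI
   ASCII grids, GeoJSON polygons and PNG quick-looks.

5. **A synthetic campaign generator** (Gaussian copula over
   range-bounded marginals with season-specific inter-metal correlation
   and detection-limit censoring), so every stage is testable without
   field data.

## Worked example

Score the transcribed spring station vector in which all five metals
sit at 0.009 mg/L, against WHO limits (Cd 0.003, Cu 2, Fe 0.3, Pb 0.01,
Zn 3 mg/L):

```python
from hydrometal import (StandardsTable, ExposureProfile, hpi_total,
                        hazard_index, reference_survey)

std = StandardsTable.default()
rec = next(r for r in reference_survey()
           if r.river == "hassar" and r.season == "spring"
           and r.sample_id == "S4")

res = hpi_total(rec, std)
print("HPI total:", round(res.hpi_total, 4), "->", res.band)
print("Cd sub-index:", round(res.subindex["cd"], 4))
no_cd = hpi_total(rec, std, exclude={"cd"})
print("without Cd:", round(no_cd.hpi_total, 4), "->", no_cd.band)
risk = hazard_index(rec, std, ExposureProfile())
print("hazard index:", round(risk.hi, 4), "exceeds 1:", risk.exceeds_unity)
```

prints

```
HPI total: 2.4917 -> high/unfit
Cd sub-index: 2.2857
without Cd: 0.206 -> negligible/excellent
hazard index: 0.5954 exceeds 1: False
```

Read: the water classes as highly polluted and unfit for drinking
(index 2.49 > 1), cadmium alone contributes 2.29 of that — removing its
sub-index (weights untouched) would re-class the water as excellent —
yet the non-carcinogenic hazard index stays below 1, so no adverse
health effect is expected from ingestion at these concentrations.

The full pipeline (synthetic campaign → HPI → risk → model comparison →
correlations → maps) runs from the shell:

```sh
hydrometal all --seed 1 --outdir out/
```

```
hydrometal pipeline summary
config digest: d8f06aab18195305  seed: 1
samples: 60  stations x seasons scored: 20
max hazard index: 2.1416 (> 1: potential risk)
pollution-index band shares:
  high/unfit: 85.00%
  low/poor: 15.00%
```

(The synthetic generator spans the full observed concentration ranges,
including lagoon-like Pb up to 0.22 mg/L, so its hazard indices can
exceed those of the river stations.) Individual stages are available as
`simulate`, `hpi`, `risk`, `ml`, `maps` and `report` subcommands, all
composing through one canonical CSV schema.

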