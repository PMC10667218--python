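# Methods

## Pollution index

The index is a weighted sum of per-metal sub-indices. For metal *m*
with permissible limit *L_m* (mg/L) and measured concentration *C_m*
(mg/L):

- relative weight `Rw_m = 1 / L_m` (L/mg) — stricter limits weigh more;
- parameter weight `Wp_m = Rw_m / Σ_k Rw_k` (dimensionless, Σ Wp = 1);
- contamination status `Sc_m = C_m / L_m` (dimensionless);
- sub-index `Wp_m · Sc_m`; total = sum over metals.

The construction has a built-in calibration point: water at exactly
every limit scores 1.0, which anchors the band edges. The index is
homogeneous of degree one in the concentrations and monotone in each.
Classification is five bands with edges at 0.25, 0.5, 0.75 and 1; an
edge value belongs to the lower band, so 0.25 still classes as
negligible/excellent and anything strictly above 1 is high
pollution/unfit.

**Metal exclusion.** "What if cadmium were absent" is answered by
dropping the Cd sub-index while keeping the weights computed over the
full metal set. Renormalising the weights would instead answer "what if
cadmium had never been a parameter", which changes every other
sub-index and inflates the remainder; the un-renormalised reading is
the one under which removing a dominant metal can re-class water from
unfit to excellent.

**Defaults.** WHO drinking-water guideline limits: Cd 0.003, Cu 2,
Fe 0.3, Pb 0.01, Zn 3 mg/L. All overridable via a YAML standards table.
Censored values enter at their substitution value and the result
carries a warning per affected metal. Replicates are averaged per
station × season before scoring (per-replicate mode available).

## Health risk

Ingestion-only, point estimates. Average daily intake
`ADI = C·IR·EF·ED / (BW·AT)` in mg/(kg·day). The default profile is
the adult lifetime drinking-water scenario: BW 70 kg, IR 2 L/day,
EF 365 days/yr, ED 70 yr, AT = ED·EF days. With that AT the duration
and frequency cancel exactly (ADI = C·IR/BW); the identity is asserted
as a regression test. Presets cover ED 30 yr, ED 65 yr and IR 1.5 L/day
scenarios.

Hazard quotient HQ = ADI/RfD with standard oral reference doses
(Cd 5e-4, Cu 0.04, Fe 0.7, Pb 3.5e-3, Zn 0.3 mg/(kg·day)); hazard index
HI = Σ HQ, flagged when above 1. Carcinogenic risk CR = ADI·CSF is
computed only for metals with a slope factor; the shipped example table
(Cd 6.1, Pb 0.0085 (mg/(kg·day))⁻¹) is loaded only on an explicit flag,
because a slope-factor choice dominates any CI figure and should never
be implicit. CI is classified against the conventional acceptable band
1e-6 to 1e-4 excess lifetime cancer probability. Metals without a slope
factor are listed in the result rather than silently skipped.

## Synthetic campaign generator

Emulates the study design: 10 stations (Nfifikh S1–S2, lagoon S3,
El Maleh S4–S5/S8–S10, Hassar S6–S7), winter and spring, 3 replicates,
with per-metal concentration ranges Cd 0.005–0.01, Cu 0.005–0.01,
Fe 0.007–0.34, Pb 0.007–0.22, Zn 0.009–0.3 mg/L.

Only ranges and correlations are specified by the design, so the
marginals are uniform on their ranges and the dependence is a Gaussian
copula. The normal-score correlation is set to `2·sin(π r/6)` so that
the *Pearson* correlation between the uniform marginals hits the target
r (the standard copula attenuation inversion). Season-specific targets:
winter has a moderate common-origin block among Cd/Cu/Zn (0.727/0.607);
spring is near-singular with Cd/Fe/Zn at 0.999, Pb at 0.998 to those,
and Cu at 0.85 to everything. User-supplied matrices are repaired to
positive semi-definite by clipping eigenvalues at 1e-10 and
renormalising the diagonal; a repair that moves the matrix by more than
0.1 in Frobenius norm is rejected as a config error.

Replicates multiply the station draw by N(1, 0.02) noise — a 2%
analytical CV typical of flame AAS — clipped back into the range.
Detection-limit censoring uses a single 0.004 mg/L limit for all five
metals (a plausible flame-AAS quantification limit, chosen once; the
campaign it emulates reports censoring only as "below detection").
Substitution policies: LOD/2 (default, the common environmental-
statistics convention), zero, or drop. Spring samples at S1, S2 and the
confluence S10 are forced below detection to mirror the observed
pattern. Station coordinates are drawn uniformly in the configured
bounding box with rivers in longitude bands — the generator makes no
attempt at hydrological realism, river geometry, or spatial
autocorrelation along a channel.

Seeding: one root `SeedSequence`, spawned into one child stream per
season plus one for coordinates, so identical config + seed gives
byte-identical tables and seasons are independently reproducible.

**What passing tests show.** The generator reproduces counts, ranges,
correlation structure and censoring geometry — not the real rivers'
spatial gradients, temporal autocorrelation, or non-uniform
concentration distributions. Model-comparison results on synthetic data
demonstrate that the harness ranks and scores correctly, not that any
algorithm would perform equivalently on field data.

## Transcribed station vectors

`reference_survey()` hard-codes the station-level concentration vectors
reported in the Mohammedia campaign's narrative, under the station
labels as reported — including a label clash (S4/S5 appear for both
El Maleh and Hassar) that is preserved rather than resolved, and one
ambiguous winter sentence for Nfifikh whose positional reading puts Cu
at 0.34 mg/L while the campaign's own summary ranges cap Cu at 0.01 and
let Fe reach 0.34. Both readings are stored as tagged variants and both
enter the hazard-index bound check. Coordinates in this fixture are
synthetic placeholders (the true ones are unpublished) and only matter
for mapping demos.

## Model comparison harness

Design matrix: the target metal is predicted from the remaining four
metals plus station coordinates (plus a season indicator when seasons
are pooled). This is a data-driven inter-metal regression, not a
transport model; it exists to compare algorithms under identical
conditions.

- Random forest: 15 trees, raw features, seeded.
- SVR: RBF kernel, γ = 1.2, C = 200, ε = 0.015, z-scored features
  (scaler fit on the training part only).
- Perceptron: one hidden layer of 9 sigmoid units, linear output,
  z-scored features. Trained as a nonlinear least-squares problem on
  the flattened weights with Levenberg–Marquardt
  (`scipy.optimize.least_squares(method="lm")`), capped at 1000
  function evaluations ("epochs" maps to the evaluation budget; a
  learning rate has no role under LM and is stored but unused). When
  there are fewer residuals than parameters — MINPACK's LM requires
  m ≥ n — the trust-region reflective variant of damped least squares
  is used instead. A quasi-Newton (BFGS) optimizer is selectable.
  Non-convergence at the budget returns the best-so-far weights with a
  warning.

Metrics: RMSE = √(Σ(a−p)²/N), MAE = Σ|a−p|/n,
MAPE = 100·mean(|a−p| / |p|) — note the denominator is the **predicted**
value, so elements with p = 0 (which occur with zero-substituted
censored data) are excluded element-wise and counted in a warning —
and R² = 1 − SSres/SStot (defined as 1 at exact equality when SStot = 0).
RMSE ≥ MAE is *not* asserted anywhere: it is true per-fold but can fail
for averages across folds.

Validation: seeded 70/30 shuffle split (train size = 0.7n rounded to
nearest) plus k-fold cross-validation, k = 5 by default (a standard
choice; nothing in the design fixes k), shuffled with the same seed;
folds are disjoint and exhaustive.

## Surfaces

Power-2 inverse distance weighting on cell centers, row 0 north. Over a
study extent of ~0.3° the geometry is treated as planar after an
equirectangular local projection (longitude × cos of the mean station
latitude); the error of that approximation at this extent is far below
the interpolation uncertainty. A cell within 1e-9° of a station takes
the station value exactly; elsewhere the estimate is the weighted mean,
hence bounded by the station value range. Duplicate station
coordinates are rejected if their values conflict. IDW was chosen as
the minimal defensible interpolant for sparse station data — kriging
would require a variogram that ten stations cannot support.

Exports are deliberately plain-text: ESRI ASCII grid (readable by any
GIS), GeoJSON band polygons (grid cells dissolved per band via
shapely), PNG quick-looks. Banding uses the same five-band scale as the
index, edges to the lower band, and conserves cell counts.

## Pipeline and reporting

Per-season Pearson correlation matrices are computed on station-level
means with two-sided p-values from the t-transform of r; no
multiple-testing correction is applied, and the output header says so.
Zero-variance metals yield undefined correlations, reported as NaN with
a warning rather than an error.

`run_pipeline` chains the stages, writes one tidy CSV per stage plus
map exports, a summary of the headline checks (max HI vs 1, band
shares) and a YAML manifest with a config digest and the seed; a stage
failure propagates with the stage name and partial outputs are
retained. Identical config + seed yields an identical bundle
(checksummed in the tests; PNGs are excluded from the checksum because
image-encoder metadata is not guaranteed stable).

## Problem sizes

Statistical checks on the generator use 1000 single-replicate stations
(correlation recovery to ±0.05, ±0.01 for targets ≥ 0.99); the
model-quality checks use 50–60 samples, where all three algorithms fit
a noiseless linear or near-singular correlated target essentially
exactly. The end-to-end pipeline demo uses the 10-station two-season
three-replicate campaign (60 records).

## Known limitations

- Ingestion route only; no dermal/inhalation exposure, no Monte-Carlo
  uncertainty propagation — risk outputs are point estimates.
- The index family is fixed; no arithmetic WQI, Nemerow, or sediment
  indices.
- Slope-factor defaults are intentionally absent; carcinogenic results
  are only as good as the user's CSF table.
- The generator draws stations independently in space; surfaces built
  from synthetic data have no true spatial structure to recover.
- No kriging, basemaps, or aquifer-aware interpolation.
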