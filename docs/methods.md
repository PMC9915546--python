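# Methods

## Scope and data model

`vegrisk` analyses paired topsoil–vegetable surveys: each vegetable record
(edible part, fresh-weight metal contents) references exactly one soil
record (dry-weight totals plus pH, soil organic matter, dithionite-citrate-
bicarbonate-extractable Fe and Al oxides, and available N/P/K). The metal
panel is fixed at Cd, Cr, Cu, Pb, V, Zn in that order for all tabular
output. Loaders reject non-positive concentrations, duplicate ids, and
dangling soil references; all internal values are kept unrounded and any
display rounding happens only when report CSVs are written.

Vegetable inputs are fresh-weight concentrations. A `dry_to_fresh`
converter exists for users holding dry-weight data, but it is never applied
implicitly — silent basis conversion is a classic source of order-of-
magnitude errors in transfer factors.

## Contamination indexing

The geo-accumulation index `Igeo = log2(C_soil / (1.5 * BV))` is computed
per sample and metal; because the log of the geometric mean is the mean of
logs, the arithmetic mean of per-sample indices equals the index of the
geometric mean content (an identity the tests enforce to 1e-9). Classes
follow the Müller ladder (≤0 unpolluted; 0–1 unpolluted-to-moderate; 1–2
moderate; 2–3 moderate-to-heavy; 3–4 heavy; 4–5 heavy-to-extreme; >5
extreme) with half-open intervals, upper bound inclusive. Screening
exceedance is strict (`>`): a sample exactly at the screening value
complies, matching regulatory usage of "exceeds".

Summary statistics report both arithmetic and geometric means/SDs; the
coefficient of variation is defined as `sd_arith / mean_arith`.

## Source statistics

The correlation matrix is pairwise Pearson on raw (untransformed)
concentrations with two-sided p-values from the exact t reference
distribution (scipy); a `--log` switch transforms first, since practice
varies and trace-metal contents are log-normal. No multiple-testing
correction is applied. PCA operates on z-scored columns (the correlation
matrix), unrotated. The per-metal contribution to a component is its
squared loading as a percentage of the component's squared-loading sum, so
contributions sum to 100 per component. Zero-variance columns are a hard
error for PCA (named in the message) but only an undefined-r flag (NaN) for
correlations.

## Transfer

BAF records are exact ratios, one per vegetable × metal. Aggregation uses
the arithmetic mean (the conventional "average BAF"); a geometric-mean
option is exposed because BAF distributions are right-skewed and the
geometric mean is the more robust location estimate. Food-limit screening
is strict-exceedance against the maximum permissible levels (Cd 0.20, Pb
0.30, Cr 1.0 mg/kg fresh weight); metals without a defined limit are
reported as undefined rather than zero. BAF–property correlations pool all
species by default (stratification available), on untransformed BAFs with a
`--log` option.

## Risk engine

Deterministic risk evaluates CDI → HQ → HI at fixed contents (the species
means). The Monte Carlo engine:

- fits each metal's content distribution by method of moments on the
  arithmetic mean and SD (`sigma² = ln(1+(sd/mean)²)`,
  `mu = ln(mean) − sigma²/2`), which reproduces the input moments exactly;
- truncates to the observed [min, max] by rejection resampling, which
  preserves the log-normal shape inside the bounds (the behaviour of
  bounded log-normal assumptions in commercial risk software); an
  acceptance probability below 1e-4 aborts with a bounds diagnostic;
- draws metals independently within an iteration (no dependence structure
  is assumed between metal contents in a composite sample); each metal gets
  its own seed substream in fixed panel order, so adding a metal never
  perturbs the draws of the others;
- uses n_iter = 10,000 by default and reports the empirical 90th percentile
  with linear interpolation between order statistics (numpy's default,
  type-7 convention).

Per-metal contributions are `mean(HQ_m)/mean(HI)`, which sum to exactly 1;
contribution at the mean is preferred over contribution at the percentile
because the latter does not decompose additively. Receptors share content
draws (same seed), so adult and child risk differ only through the exposure
constants; when two scenarios differ only in IR and BW, the entire HQ table
scales by the single constant `(IR/BW)_a / (IR/BW)_b`.

The empirical observation that `P90(HI) ≤ Σ_m P90(HQ_m)` holds across
seeded configurations is verified in the suite as a sanity check with a
small violation allowance — it is a typical property of independent
positive summands at this percentile, not a theorem.

### Exposure parameters (units, defaults, provenance)

| parameter | adult | child | unit |
|---|---|---|---|
| IR (vegetable intake) | 345 | 231.5 | g/day fresh weight |
| EF (exposure frequency) | 365 | 365 | days/year |
| ED (exposure duration) | 30 | 6 | years |
| BW (body weight) | 61.8 | 23.6 | kg |
| AT (averaging time) | ED×365 | ED×365 | days |

RfD (mg/kg/day): Cd 1e-3, Cr 3e-3, Cu 4e-2, Pb 3.5e-3, V 7e-3, Zn 0.3.

These are standard exposure-handbook and US-EPA oral reference values, not
survey-specific measurements, and the shipped config flags them
`provenance: non-paper`. With AT = ED×365, ED cancels out of the CDI, so
the receptors differ only through IR/BW; the child/adult dose ratio is
(231.5/23.6)/(345/61.8) ≈ 1.76, consistent with published
receptor-stratified HQ tables for this pathway. Every report directory
embeds a manifest naming the config used.

## Synthetic-data generator

The generator emulates the statistical structure of a smelter-impacted
survey, not any particular field campaign:

- **Design**: 51 sites, species plan 11/6/5/11/5/8/5 across asparagus
  lettuce, pak choi, coriander, flowering Chinese cabbage, garland
  chrysanthemum, garlic sprout, lettuce (one vegetable per site).
- **Covariates**: pH truncated-normal (mean 5.84, SD 0.76, bounds 4.5–7.3);
  SOM, DCB-Fe/Al, available P/K log-normal and available N
  truncated-normal, all calibrated to regional-survey magnitudes.
- **Soil metals**: a two-latent-source log-linear model,
  `C_mi = BV_m · exp(L_m1 S1_i + L_m2 S2_i + ε_mi)` with smelter source S1
  loading Cd, Cr, Cu, V and mine source S2 loading Pb, Zn, both
  `Normal(1, 0.5)`, per-metal noise SD 0.3, and own-source loadings
  `L_m = ln(GM_m / BV_m)` so the expected geometric means land on the
  survey values. The shared sources plant the positive within-group
  correlations and the two-component PCA structure the source-apportionment
  stage is meant to recover.
- **Vegetables**: a log-linear BAF model
  `ln BAF = α_m + Σ_c β_cm (x_c − x̄_c) + offset(species) + η`, with
  planted negative pH (−0.6 per unit), SOM (−0.05 per g/kg) and DCB-Fe
  (−0.4 per g/kg) slopes for Cd and V, a positive available-K slope
  (+0.004 per mg/kg) for Cd, Cr, V, residual SD 0.4, and species offsets
  (+0.4 for the high accumulators garland chrysanthemum, pak choi,
  coriander; −0.3 for asparagus lettuce and garlic sprout). Intercepts α_m
  are solved analytically so the expected arithmetic-mean BAF equals the
  survey grand means (Cd 0.019, Cu 0.016, Zn 0.014, Pb 0.002, V 0.001,
  Cr 0.0003).
- **Randomness**: one seed feeds fixed-order `SeedSequence` substreams
  (covariates, latent sources, per-metal soil noise, per-metal BAF
  residuals), so generation is bit-reproducible and structurally stable
  under panel extension.

What the generator does **not** emulate: spatial autocorrelation and
distance-to-source gradients, measurement error and detection limits,
correlated vegetable-metal uptake beyond the shared soil signal,
within-site replicate structure, and the heavy single-metal GSDs of real
surveys (the planted log-variances are moderate). Passing recovery tests
therefore demonstrates that the estimators recover planted structure at the
survey's sample size — not that any particular field dataset satisfies the
model.

## Problem sizes and numerical choices

The suite's stochastic checks use 100 seeded 51-site replicates for sign
recovery and PCA-structure rates, 50 seeds for grand-mean BAF calibration
(factor-of-2 band), 100,000 draws for the raw log-normal quantile oracle
(2% band), and 10,000 iterations for the single-metal risk oracle. For the
risk oracle the content CV is set to 0.3 so the empirical-P90 Monte Carlo
standard error (~0.5%) makes the 2% band a ≥4-sigma check. Full-suite
runtime is a few seconds.

## Known limitations

- Only the vegetable-ingestion pathway is modelled: no soil ingestion,
  dermal, or inhalation exposure, and no carcinogenic slope factors.
- HQ/HI assume additive, independent toxicity across metals.
- Mean indices for two metals in the reference survey (V, Cu) are not
  reproducible from that survey's own geometric means and backgrounds
  (formula gives 1.51 and 1.11 against published 2.06 and 1.07, suggesting
  a different background value was used for V); the package always computes
  from the formula. Likewise the survey's metal-row CVs are inconsistent
  with their own printed mean/SD pairs, so the package's CV is defined as
  sd/mean and validated only on the self-consistent rows.
- Published 90th-percentile HQ tables and HI distributions for the
  reference survey require its unpublished per-sample data and appendix
  exposure parameters; the suite covers those patterns qualitatively
  (ordering, threshold crossings, child/adult ratio) on the calibrated
  synthetic design.
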