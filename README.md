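# carotlab

Response-surface optimization and bioactivity analytics for microbial
carotenoid fermentation.

`carotlab` is for fermentation and natural-product researchers who optimize
pigment production on low-cost substrates (here: cheese whey, a lactose-rich
dairy byproduct) and then characterize the pigment's stability and
bioactivity. It implements the complete statistical chain of such a study as
a tested, reusable library and CLI, with seeded synthetic-data generators
replacing the wet lab so every stage is verifiable offline:

* **Design of experiments** — canonical 3-factor Box–Behnken designs
  (12 edge-midpoints + replicated center points), coded ↔ actual level
  mapping, strict design validation.
* **Response-surface methodology** — OLS fit of the full second-order model
  Y = β0 + Σβᵢxᵢ + Σβᵢⱼxᵢxⱼ + Σβᵢᵢxᵢ², with coefficient t/p/CI inference,
  ANOVA (SS/MS/F/R²), canonical (stationary-point) analysis, a deterministic
  constrained maximum over the coded cube, verification accuracy, surface
  grids, and Welch group comparisons for one-variable-at-a-time screening.
* **Pigment analytics** — E1% extinction-coefficient quantification
  (C = A·DF·10/E1%, mg/mL) and stress-stability residuals
  (Residual% = 100·Ct/C0) with explicit not-detected handling.
* **Bioassays** — DPPH radical-scavenging efficiency with log-dose IC50
  interpolation; median-effect (mass-action) fits fa/fu = (D/Dm)^m of MTT
  viability data giving slope m and IC50 = Dm; selectivity indices
  SI = IC50(normal)/IC50(line) with literature threshold schemes.
* **MS annotation** — xanthophyll fatty-acid monoester masses
  (backbone + acyl − H2O, nominal and monoisotopic, [M−H]⁻) and neutral-loss
  fragment annotation with explicit mass-discrepancy reporting.
* **Synthetic data** — seeded generators for every stage, whose defaults are
  the packaged study's conditions, used for parameter-recovery and
  calibration testing.

A 15-run Box–Behnken dataset (cheese whey × peptone × casein, pigment yield
in mg/mL) ships as a packaged fixture, so everything below runs with no
external data.

## Worked example

Fit the packaged design and read off the whey main effect and the
whey × peptone antagonism:

```sh
carotlab fit-bbd --design src/carotlab/data/bbd_design.csv
```

```json
"X1":   {"coefficient": 0.0068875,  "standard_error": 0.00288716,
         "t_stat": 2.38556,  "p_value": 0.0627313, "ci_high_95": 0.0143092},
"X1X2": {"coefficient": -0.013125,  "standard_error": 0.00408306,
         "t_stat": -3.2145,  "p_value": 0.0236099, "ci_high_95": -0.00262916},
"anova": {"Regression": {"df": 9, "SS": 0.00192829, "F": 3.21291,
                         "significance_F": 0.105865},
          "Residual":   {"df": 5, "SS": 0.000333427, "MS": 6.66855e-05},
          "Total":      {"df": 14, "SS": 0.00226172},
          "r_squared": 0.852578}
```

Raising cheese whey by one coded step adds ~0.0069 mg/mL of pigment
(borderline, p ≈ 0.063); the strongly negative whey × peptone interaction
(p ≈ 0.024) means the two nitrogen/carbon sources antagonize each other —
high whey pays off at *low* peptone. The model explains R² ≈ 0.85 of the
response variance with 5 residual degrees of freedom.

Locate the yield optimum inside the experimental region:

```sh
carotlab optimize --design src/carotlab/data/bbd_design.csv --mode cube
```

```json
{"coded_location": [1.0, -1.0, -0.365571],
 "actual_location": [80.0, 0.5, 0.317215],
 "predicted_max": 0.0568637,
 "on_boundary": [true, true, false]}
```

The predicted maximum, 0.0569 mg/mL, sits at 80% (v/v) whey and 0.5 g%
peptone (both on the design boundary) with casein interior at ~0.32 g%.
The surface's unconstrained stationary point is a saddle, which is why the
cube-constrained search is the default.

Selectivity of the pigment's cytotoxicity, from the assayed IC50s
(PBMC reference 33.5 mg/mL; HCT-116 0.56; MDA-MB-231 3.3):

```sh
carotlab si --reference 33.5 --lines HCT116=0.56,MDAMB231=3.3 --scheme ge2
```

```json
{"HCT116":   {"ic50": 0.56, "si": 59.8214, "classification": "selective"},
 "MDAMB231": {"ic50": 3.3,  "si": 10.1515, "classification": "selective"}}
```

SI ≈ 59.8 and ≈ 10.2: both lines clear even the strict SI ≥ 10 criterion.

Other subcommands: `quantify`, `stability`, `dpph`, `ic50`, `annotate-ms`,
`simulate bbd|mtt|dpph|stability`, `surface`, `validate`, and `run` (the
fit → anova → optimize → validate pipeline with provenance-stamped JSON
reports). The same operations are available as library functions
(`carotlab.rsm.fit_quadratic`, `carotlab.bioassay.median_effect_fit`, ...)
and as scikit-learn-style estimators (`QuadraticSurface`,
`MedianEffectModel`) that compose with sklearn tooling.

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.

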