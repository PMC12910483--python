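# Methods

`carotlab` implements the statistical chain of a whey-based microbial
carotenoid fermentation-optimization workflow: a three-factor Box–Behnken
experiment optimizing pigment yield, the second-order response-surface model
fitted to it, pigment quantification and stress-stability summaries, DPPH
antioxidant kinetics, median-effect cytotoxicity IC50s with selectivity
indices, and xanthophyll-ester mass annotation. This note records the models,
the defaults and why, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Box–Behnken design (`carotlab.doe`)

For k = 3 factors the design places runs at the 12 edge-midpoints of the
coded cube — every (±1, ±1) combination of each factor pair with the third
factor at its center — plus `n_center` replicated center points (default 3,
giving the classical 15-run design). Canonical run order is the pair order
(X1,X2), (X1,X3), (X2,X3), signs (−,−), (+,−), (−,+), (+,+) within a pair,
then the center replicates; every downstream fit is order-invariant, so a
randomized run order in a user table changes nothing.

The coded↔actual mapping is piecewise linear anchored at
(−1, 0, +1) → (low, center, high). The two branches coincide for symmetric
spacing; asymmetric spacing (center off the midpoint) must be enabled
explicitly on the `FactorSpec`. The inverse mapping refuses to extrapolate
outside [low, high]. Coded user input is validated against the exact set
{−1, 0, +1}; a relaxed mode accepts any value in [−1, 1] for face-centered
variants.

The packaged design fixture uses cheese whey 20/50/80 % v/v, peptone
0.5/1.0/1.5 g% w/v, and casein 0/0.5/1.0 g% w/v as the actual levels. These
are a packaged convention chosen to reconcile the base medium (50% whey, 1%
peptone, 0.5% casein) with the reported optimum (80% whey, 0.5 g% peptone,
~0.97 g% casein); the original level table is not part of the published
record, so the actual-unit coordinates of any result should be read relative
to this convention.

## Response-surface model (`carotlab.rsm`)

The response model is the full second-order polynomial in coded factors,

    Y = β0 + Σ βi Xi + Σ βij Xi Xj + Σ βii Xi²,

ten coefficients, fit by ordinary least squares on the model matrix
[1, X1, X2, X3, X1X2, X1X3, X2X3, X1², X2², X3²]. `QuadraticSurface` is a
scikit-learn-style estimator (fit/predict, trailing-underscore attributes);
`fit_quadratic` wraps it into an immutable `QuadraticFit`.

Inference: standard errors from MS_res × diag((XᵀX)⁻¹); two-sided p-values
from the t distribution with n − 10 residual degrees of freedom (5 for the
15-run design); 95% CIs with the 0.975 t quantile (t₀.₉₇₅,₅ = 2.5706).
"Significance F" is the upper-tail F(9, n−10) probability of
MS_reg/MS_res. No lack-of-fit/pure-error split is computed by default, to
mirror the three-line ANOVA layout this workflow reports.

Because the 15-run BBD's linear and interaction columns are mutually
orthogonal with squared column sums 8 and 4, each linear coefficient equals
the ±1-level contrast divided by 8 and each interaction the (±1,±1) contrast
divided by 4; the test suite asserts this identity against the OLS solve at
1e−12, which is also a strong end-to-end check of the model matrix.

Optimum extraction comes in two forms:

* `stationary_point` — canonical analysis: solve ∇Y = b + 2Bx = 0 with B
  the symmetric quadratic-form matrix (diagonal βii, off-diagonal βij/2) and
  classify by the eigenvalues of B. The packaged surface is a saddle
  (mixed-sign pure-quadratic terms), so its stationary point is *not* the
  yield optimum — which is why the constrained search below is the default.
* `maximize_over_cube` — deterministic global maximum over [−1, 1]³: an
  exhaustive 0.01-spaced lattice scan (ties broken to the lexicographically
  smallest coded coordinates) followed by bounded L-BFGS-B refinement from
  the best lattice point (gradient tolerance 1e−12). The refinement can only
  improve on the lattice value, so the returned maximum provably dominates
  every lattice vertex; the whole procedure is bit-reproducible, which is
  why a stochastic optimizer was not used.

On the packaged dataset the constrained maximum is 0.0569 mg/mL at coded
(1, −1, −0.366), i.e. whey at its high level, peptone at its low level,
casein slightly below center. Model verification uses
accuracy% = 100 × experimental/predicted and
deviation% = 100 × |predicted − experimental|/predicted; the ratio
convention is documented here because more than one reading is compatible
with how such accuracies are usually quoted.

`compare_groups` (for one-variable-at-a-time screening summaries) reports
mean ± SE per group and two-sided Welch t p-values against a named control.
Welch's t is a convention choice — the screening comparisons this serves
state only a p ≤ 0.05 criterion — and the suite checks it against a seeded
permutation test.

## Pigment quantification and stability (`carotlab.pigment`)

Concentration from absorbance uses the percentage extinction coefficient:
E1% is the absorbance of a 1 g/100 mL solution across 1 cm, so
C (mg/mL) = A × DF × 10 / E1%. The default E1% = 2500 is the generic
carotenoid value at λmax = 435 nm and is configurable; absolute yields scale
inversely with it, so cross-study comparisons must fix it explicitly.

Stability is the residual percentage 100 × Ct/C0 against an untreated
control after 1 h at a stress condition. Values above 100% are legitimate
(acidic conditions enhance the pigment's absorbance; the packaged pattern
includes 310.5% at pH 3) and are never clipped. A destroyed sample is an
explicit not-detected marker (`None` in memory, `ND` in CSV), excluded from
means and SEs rather than coerced to 0, so alkaline-precipitation conditions
do not bias summaries. The default "fully stable" flag threshold is a mean
residual ≥ 95%.

## Bioassays (`carotlab.bioassay`)

DPPH: RSA% = 100 × (A_control − A_sample)/A_control at 517 nm. The IC50 at
a fixed incubation time (default 30 min) is found by linear interpolation on
log10(concentration) between the two concentrations bracketing 50% — serial
dilutions are geometric, so log-dose interpolation is the natural scale. An
exact 50% hit returns the tabulated concentration unmodified; if 50% is
never attained the estimate is an explicit not-reached marker carrying the
maximum RSA% achieved, never an extrapolated number.

Cytotoxicity: the mass-action median-effect model fa/fu = (D/Dm)^m, with fa
the fraction affected (1 − viability/100) and Dm the median-effect dose
(the IC50). The fit is unweighted OLS on the linearized median-effect plot
log10(fa/(1−fa)) vs log10(D), matching the method of the dose-response
software standard in this assay literature. Points with fa ≤ 0.001 or
≥ 0.999 are excluded (the logit diverges) and their indices reported.
Duplicate wells are averaged before fitting; per-dose spread is not used to
weight the regression. A line showing no cytotoxicity over the tested range
is represented as not-reached, never as an infinite or zero IC50.

Selectivity: SI = IC50(reference normal cells, here PBMCs)/IC50(cell line),
classified under the threshold schemes in common use (>1, ≥2, ≥3, ≥10).
The agar-well helper subtracts the well diameter from the total zone to give
net clearing.

## Mass annotation (`carotlab.msannot`)

Monoester formation is backbone + acyl − H2O, with light chemistry
preconditions (backbone carries an oxygen, acyl is a carboxylic acid).
Masses are computed on the nominal scale (integer masses, C=12/H=1/O=16 —
the scale on which published ester tables are printed; zeaxanthin + C14:0
gives [M−H]⁻ = 777) and monoisotopic scale (≥4-decimal isotope masses;
[M−H]⁻ is parent − 1.00783, electron mass neglected as far below any
tolerance in use). The embedded mass table covers C/H/O/N/S and raises on
anything else rather than guessing.

Fragment annotation treats each fragment as a neutral loss from the parent
and matches the loss to the nearest library formula within a configurable
tolerance (default 1.0 Da). Published ester tables sometimes print a loss
label whose formula mass differs from the observed loss by a couple of Da
(e.g. a 58 Da loss labeled C4H8 = 56 Da nominal); the annotator therefore
always reports the nearest candidate with its signed discrepancy instead of
silently adopting or silently dropping the label, and only calls a match
"assigned" inside the tolerance. Fragments within tolerance of m/z 377 can
be flagged as the characteristic carotenoid polyene-backbone fragment.

## Synthetic data (`carotlab.synthdata`)

Each generator draws from the closed-form model its downstream analysis
fits: in the noiseless limit every fit recovers its parameters to 1e−9 or
better (asserted), so any recovery failure isolates the estimator, not the
data. One root seed fans out to fixed-order per-generator `SeedSequence`
streams; outputs are bit-reproducible given (seed, config, generator
version), and consuming one stream never perturbs another.

Defaults are the study conditions of the packaged dataset: the fitted
surface coefficients as the BBD truth with noise SD √(6.67e−5) (the root
residual mean square of the packaged fit); the twofold MTT dilution series
5.6 → 0.04375 mg/mL with Dm = 0.56 mg/mL, slope m = 2 and 2% viability
noise; DPPH concentrations 1.2/3/6 μg/mL with IC50 = 6 μg/mL; and the
published stability pattern including enhancement (>100%) and ND
conditions. Where the workflow reports no raw value (the DPPH kinetic
shape, the median-effect slope), the defaults — plateau top 95%, Hill slope
1.5, rate 0.12 min⁻¹, m = 2 — are one-time realistic choices, not fitted
quantities.

What the generators deliberately do not emulate: plate-position and edge
effects, heteroscedastic or correlated replicate noise, instrument drift,
chromatographic or spectral structure, and any fermentation kinetics behind
the response surface. Passing recovery tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to real-data pathologies.

Calibration facts the suite verifies at the study noise level: Monte-Carlo
coefficient sampling SDs over 500 seeded replicates match the analytic SE
column within 15%; 95% CIs cover the true coefficients at 92–98% observed
rate; the median recovered Dm over 500 noisy replicates is within 5% of
truth. These replicate counts keep the full suite under half a minute while
leaving comfortable Monte-Carlo margin on each band.

## Numerical and interface conventions

* CSV: comma, period decimal, UTF-8, mandatory header; `ND`/empty are the
  only missing markers.
* JSON reports round to 6 significant figures (the precision of the
  coefficient tables this mirrors); full precision is kept in memory.
  Reports embed input SHA-256 checksums, options, seed and versions, and
  contain no timestamps, so identical configurations produce byte-identical
  files.
* CLI exit codes: 0 success, 2 validation error, 3 computation error.
* Known data tensions, preserved rather than patched: the printed predicted
  value 0.0048 at run 4 of the packaged design disagrees with its own
  residual column by ~1e−4 (the OLS value is 0.004913); the published
  headline maximum (0.0565–0.0567 mg/mL) and the fitted surface's
  constrained maximum (0.05686 mg/mL) differ in the last digit, and the
  published 80.1% verification accuracy is not exactly reproducible from
  any printed value pair — these are checked loosely (±2%) and documented,
  not pinned.

## Known limitations

Only k = 3 Box–Behnken designs are constructed (central-composite,
Plackett–Burman and other k are out of scope); fitting is plain OLS
(no regularization, no Bayesian variants, no desirability-function
multi-response optimization); the 4PL/Hill model is not the primary IC50
estimator; MS annotation does no isotope-pattern scoring, deconvolution or
retention-time modeling; surface plots are exported as grids, not rendered.
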