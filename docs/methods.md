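# Methods

## Compatibility scoring

The Biological Index weights the three growth parameters by their
assumed relevance to field performance of the fungus: vegetative growth
47%, conidiation 43%, germination 10%. Each parameter enters as a
percentage of the untreated control of the *same* assay; the package
computes these relative values from the control row of the input table
(the convention that reproduces the reference BI column exactly) rather
than from any external baseline. Relative values are not clipped at
100 — a treated mean that exceeds its control simply contributes more
than 100. The presentation BI is rounded to integer with ties away
from zero (the convention of printed bioassay tables; Python's banker's
rounding would differ at .5); the unrounded value is retained on the
result object. Band boundaries are taken literally: `> 66` Compatible,
the closed interval `[42, 66]` Moderately Toxic, `< 42` Toxic.

BI is computed on treatment means. Per-replicate index distributions
would need replicate-level raw data, which compatibility assays
normally report only as mean ± SE; the synthetic generator can produce
replicate-level data where that analysis is wanted.

A known ambiguity in the reference data: the conidiation control is
printed as 7.90, and that value reproduces the published BI column,
but the separately printed conidiation-inhibition percentages are
consistent with a control of 7.6. The package follows 7.90 and does
not attempt to reconcile the inhibition percentages.

## Probit concentration–mortality analysis

Model: `probit(p) = a + b·log10(conc)` with the classical +5 offset,
so `log10 LC50 = (5 − a)/b`. Choices, in pipeline order:

- **Abbott correction** is applied to treated percentages using the
  series' control mortality and floored at zero. The packaged
  reference mortalities are shipped as printed, i.e. already corrected,
  so their series carry control mortality 0; user data pass through the
  correction with whatever control rate they declare.
- **The angular (arcsine square-root) transform** is provided as a
  standalone utility for ANOVA-style analyses of percentage data. It
  is deliberately *not* applied before probit fitting: a probit of
  arcsine-degrees is not a defined quantal-response analysis, and
  fitting on corrected proportions is what reproduces the reference
  LC50s.
- **Continuity rule**: group proportions of exactly 0 or 1 are
  replaced by `1/(2n)` and `1 − 1/(2n)` so the probit transform is
  defined. With the design default n = 250 (50 mites × 5 replicate
  leaf disks) that is 0.002.
- **Duplicate concentrations** are pooled by summing deaths and
  exposures before fitting.
- **OLS fitter** (`fit_probit_ols`): unweighted least squares of
  empirical probits on log dose. Transparent and reproducible on
  paper; its parameter covariance uses the residual mean square on
  k − 2 df, so its fiducial limits use Student's t throughout.
- **ML fitter** (`fit_probit_ml`, the default): Fisher scoring /
  iteratively reweighted least squares with working-probit weights
  `w = n·z²/(P·Q)`, started from the OLS line; converged when the
  log-LC50 changes by less than 1e-8 (cap 100 iterations, after which
  a convergence error carries the last iterate). Vanishing weights
  (complete separation / infinite slope) raise rather than return a
  spurious line. Dose groups given as percentages are weighted with
  their recorded n, using exact fractional death counts.
- **Heterogeneity**: the Pearson chi-square of observed vs fitted kill
  on k − 2 df. When χ²/df > 1 the covariance and fiducial limits are
  inflated by that factor and Student's t on k − 2 df replaces the
  normal deviate — Finney's practice for over-dispersed assays.
- **Fiducial limits**: Fieller's theorem on the ratio (5 − a)/b in the
  weighted-regression form, with g = h·t²/(b²·Sxx). When g ≥ 1 the
  slope is not significantly positive and the limits are reported as
  undefined (flagged, not silently truncated). A non-positive slope is
  warned about at fit time and rejected at limit time.

On noiseless model data both fitters recover the generating line to
numerical precision and agree with each other; on the packaged
reference series they agree within 15%. The test suite additionally
cross-checks the ML fitter against statsmodels' GLM binomial-probit
estimates and a brute-force grid maximization of the likelihood.

Reference reproduction uses the 4-day cumulative mortalities: that
time point reproduces the published LC50s, and the 6-day data for the
steep mixture schemes extrapolate far below the tested range. Two
published values are recovered only approximately: scheme III's ML
estimate is 2.33 against the printed 2.40 (the OLS estimate, 2.41, is
closer — the reference software's weighting is unknown), and scheme II
comes out near 4.6 against the printed 4.20 under every standard probit
variant we tried; both remain within the tolerance the validation suite
applies (10% and 15% respectively).

## Mixture design and joint toxicity

Category weights are fractions of each sole-component concentration
ladder (80:20 means level i pairs 0.8·A_i with 0.2·B_i), not mass
fractions of the resulting mixture; mass fractions are exposed as a
derived property. The mixture dose metric is the sum of the two
component concentrations — the scale on which the published mixture
LC50s lie.

The additivity expectation ships in two variants:

- `standard`: harmonic additivity `1/E = p_A/LC50_A + p_B/LC50_B`,
  the co-toxicity-coefficient convention. It satisfies the
  pure-component identity and betweenness and is the default for new
  analyses.
- `paper`: `E = LC50_A·LC50_B/(p_A·LC50_A + p_B·LC50_B)`, i.e. the
  standard formula with the proportions exchanged (an algebraic
  identity the property tests exercise). This is the convention the
  published indices follow; it is reverse-engineered from them, it
  violates the pure-component identity (p_A = 1 does not return
  LC50_A), and selecting it emits a warning saying so. In this variant
  the expected LC50 is quantised to 0.01 mg/mL before the index is
  formed: the published indices are consistent with a two-decimal
  hand-calculation chain (visible in the 80:20 scheme, where the
  full-precision index would round to 754, not the published 755).

The index is `100·E/LC50_mix`, synergistic at ≥ 100 (boundary
inclusive), antagonistic below. Presentation rounding is again ties
away from zero.

## Synthetic data

`simulate_bioassay` draws death counts binomially under
`p = c + (1 − c)·Φ(slope·(log10(conc) − log10 LC50))` with natural
mortality `c` composed as an independent competing risk — exactly the
model Abbott's correction inverts, so correction plus fitting is
unbiased in expectation. Defaults mirror the reference design: 50
mites per leaf disk, 5 replicate disks per group, a five-step
concentration ladder, 2% natural mortality. An optional per-day
response-fraction profile emulates cumulative 2/4/6-day mortality;
per-mite uniform thresholds keep cumulative counts monotone over days.
The default simulates only the 4-day snapshot.

`simulate_mixture_experiment` builds two sole-component assays and a
proportional mixture whose true LC50 is the standard-additivity
expectation divided by an interaction multiplier (1 = additive, 3 =
threefold potentiation); the mixture slope is the mean of the component
slopes. It returns the ground truth for recovery tests.

`simulate_growth_assay` draws replicate growth measurements normally
around means declining linearly with concentration (floored at zero;
germination clipped to [0, 100]). Default control means (98.9%,
86.6 mm, 7.9×10⁷/mL), inhibition slopes and noise SDs (≈ SE·√10 of
the reference assay, which reports mean ± SE over 10 replicates)
mirror the reference magnitudes.

All generators are pure functions of (config, seed) with a single
explicit RNG stream per call; identical seeds give byte-identical
output.

What the generators deliberately do not emulate: per-mite frailty or
within-disk correlation (every mite is an independent Bernoulli
trial), spatial leaf-disk effects, dose-dependent sporulation dynamics,
and time-kill kinetics beyond the fixed per-day response fractions.
Passing recovery tests therefore show correctness of the estimators
under the assumed binomial probit model, not robustness to
over-dispersed or correlated field data — for real assays the
heterogeneity factor is the instrument that absorbs (and flags) such
excess scatter.

## Validation problem sizes

The recovery study in the test suite uses 200 simulated assays (5
groups × 250 mites, slopes drawn in 2–4, fixed seeds), checking the
median absolute log10-LC50 error (< 0.05) and 95% fiducial coverage
(within [90%, 99%]), plus 30 additively simulated mixture experiments
whose standard-variant indices must center at 100. These sizes give
stable medians and coverage proportions while keeping the whole suite
in the seconds range.

## Known limitations

- Replicate-level raw data of the reference study are unavailable, so
  its ANOVA F statistics and significance letterings are not
  reproducible and are out of scope; the enzyme-activity measurements
  (antioxidant and defense enzymes) are raw data with no computable
  generative link and are likewise out of scope.
- The `paper` additivity variant is validated only against the four
  published scheme rows; whether its proportion swap reflects the
  original authors' formula or a labeling inversion in their schemes
  cannot be determined from the published text.
- Probit only: logit or complementary log-log links are not offered.
- Two mixture components only; no isobolographic or response-surface
  (Loewe/Bliss) analysis.
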