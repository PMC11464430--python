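# Methods

## Scope and model

`microstab` implements the computation chain of an in vitro metabolic
stability study: a drug candidate is incubated with human liver microsomes
(HLMs), its concentration is measured by LC-MS/MS against a weighted
calibration curve, and the disappearance of parent compound over time is
converted into an in vitro half-life, a scaled intrinsic clearance and a
predicted hepatic extraction ratio. The package treats the instrument as a
black box: its inputs are tables of peak responses or back-calculated
concentrations, never raw chromatograms.

## Calibration

The response variable is the analyte/internal-standard peak-area ratio,
modelled as a straight line in nominal concentration. Replicate variance in
LC-MS/MS grows roughly proportionally with concentration, so the default is
1/x-weighted least squares; unweighted OLS is available. Fitting is
delegated to `statsmodels` WLS. Two reported quantities need a convention
the field does not fix precisely:

- **r² of a weighted fit** is the weighted coefficient of determination,
  1 − (weighted RSS)/(weighted TSS).
- **SD of the intercept** entering LOD = 3.3·SD(b)/a and LOQ = 10·SD(b)/a is
  by default the standard error of the intercept from the single fitted
  curve. Multi-set calibration designs (e.g. twelve curves in a day) support
  an alternative estimate — the sample SD of the twelve intercepts — via
  `intercept_sd_across_fits` and the `sd_intercept_override` argument. The
  LOQ/LOD ratio is 10/3.3 by construction under either convention.

Back-calculated concentrations may be negative near the origin; they are
preserved and left to downstream flagging, because clipping at zero would
bias the mean and SD of low-level statistics upward.

## Validation metrics

Accuracy is the percent relative error 100·(mean − nominal)/nominal;
precision is 100·SD/mean (the percent scale is used throughout, matching how
validation tables are reported); recovery is re-expressed as %RE + 100, an
identity the test suite asserts. Matrix effect compares a biological-matrix
cohort against a neat-solvent cohort, and the internal-standard-normalised
matrix effect is the ratio of the two matrix effects. Acceptance limits
default to ±15% for both %RE and %RSD, widened to ±20% at the LLOQ,
following common regulatory convention; both are configurable, as is the
specificity gate (blank signal below 20% of the LLOQ response).

## Depletion kinetics

Under first-order conditions (substrate well below Km, constant enzyme
activity) ln of percent remaining is linear in time with slope −k. Real
curves flatten late in the incubation; the package handles the plateau by
**window selection**, not by fitting a plateau model:

- *manual*: the analyst supplies [t_start, t_end];
- *auto*: prefix scan anchored at t = 0 — the longest prefix of time points
  whose OLS fit reaches r² ≥ 0.98 (default) with at least 4 points. If no
  prefix qualifies, the error instructs the analyst to choose manually.

The threshold 0.98 keeps clearly curved late segments out while tolerating
ordinary replicate noise. A limitation worth knowing: when depletion is slow
enough that the plateau bends the ln-curve only mildly within the sampled
range, a global fit can still reach r² ≥ 0.98 and the auto window will keep
the full range; the auto mode is then no worse than, but only marginally
better than, full-range fitting. Fitting uses the per-time replicate means
(summary tables report means of three incubations); the intercept is free
rather than forced through ln 100.

Downstream, t1/2 = ln 2/|slope| and

    Clint = (ln 2 / t1/2) · (mL incubation / mg protein)
            · (mg microsomal protein / g liver) · (g liver / kg body weight)

with human defaults 1 mL/mg (a 1 mg/mL protein incubation), 45 mg/g and
26 g/kg, giving mL/min/kg. Because ln 2 cancels, Clint equals
|slope| × 1170 exactly under the defaults — a composition identity the suite
checks. Clearance zones default to low < 8.6 ≤ moderate ≤ 47 < high
(mL/min/kg), a widely used scoring convention; boundary values fall in the
less-cleared class so that a compound is never promoted to a faster class by
a tie.

## Hepatic extrapolation

The three standard liver models convert intrinsic clearance into an organ
extraction ratio E_H (CL_h = Q·E_H), with Q = 20.7 mL/min/kg hepatic blood
flow, unbound fraction fu = 1 and dispersion number D_N = 0.17 as defaults,
all configurable:

- well-stirred: E = fu·Clint/(Q + fu·Clint)
- parallel-tube: E = 1 − exp(−fu·Clint/Q)
- dispersion: E = 1 − 4a/((1+a)²·e^{(a−1)/(2D_N)} − (1−a)²·e^{−(a+1)/(2D_N)}),
  a = √(1 + 4·R_N·D_N), R_N = fu·Clint/Q

The dispersion denominator is evaluated in a factored form with all
exponents non-positive, so extreme clearances cannot overflow. The models
satisfy well-stirred ≤ dispersion ≤ parallel-tube, and the dispersion model
converges to the parallel-tube limit as D_N → 0 and the well-stirred limit
as D_N → ∞; both properties are tested numerically.

The composite site lability CSL = Σk_i/(Σk_i + k_w) aggregates per-site
metabolic rates against the water-formation rate; only the combiner algebra
is in scope (per-atom rate prediction is proprietary territory of commercial
tools and out of scope).

## Greenness

The twelve-criterion assessment aggregates scores in [0, 1] with positive
weights by a weighted arithmetic mean — the published convention for this
metric family. Colour bands are rendering configuration (quartiles by
default); the quantitatively meaningful boundary is 0.75, above which a
method counts as notably sustainable. Where a criterion's weight is not
reported, it defaults to 1.

## Synthetic data

Generators emulate the statistical structure the analysis assumes:

- **Noise**: value·(1 + ε_prop) + ε_add with Gaussian ε, truncated at zero.
  Defaults used in tests: 3% proportional CV, no additive term — typical
  replicate scatter for an optimised LC-MS/MS assay. Symmetric Gaussian
  noise matches the symmetric SDs that validation tables report.
- **Calibration plates**: seven standards from 1 to 3,000 ng/mL, four QC
  levels (1, 3, 900, 2,400 ng/mL), six replicates, a true line with slope
  1.4212 response/ng/mL. The default intercept is 0.5 (small, positive): a
  negative intercept of realistic magnitude would push the noiseless
  response of the 1 ng/mL standard below zero, where the zero-floor
  truncation would break the generator's exactness contract.
- **Depletion**: C(t) = c0·(f_r + (1 − f_r)·e^{−kt}) on the grid
  0, 2.5, 7.5, 15, 20, 30, 40, 50, 60, 70 min (configurable), with defaults
  c0 = 466.85 ng/mL and k = 0.0297/min. The resistant fraction f_r models
  the late plateau phenomenologically; the analysis never fits it, mirroring
  practice (window selection works around the plateau).
- **Matrix-effect cohorts**: the matrix group's expected response is a
  configurable multiple of the neat group's, so the downstream ME recovers
  the factor by construction.

Every generator takes an explicit seed; identical (configuration, seed)
pairs are bit-identical. What passing tests on synthetic data do **not**
show: robustness to heteroscedasticity beyond the proportional model,
carryover, drift within a batch, or non-first-order (saturating) kinetics —
none of which the generators emulate.

## Numerical choices and degenerate inputs

- Least-squares fits require ≥3 distinct levels (calibration) or ≥3 points
  in the window (kinetics); singular designs raise instead of returning NaN.
- All percent metrics reject non-positive denominators explicitly.
- Report rendering rounds to 2 decimals (the convention of validation
  tables); every JSON report carries full-precision values alongside.
- Pipeline reports are byte-identical for identical configuration and seed,
  apart from the `generated_utc` timestamp field.

## Problem sizes

The bundled worked example is a 10-point depletion course, 7-level
calibration and 12-criterion greenness table; synthetic experiments in the
tests and the acceptance script use 200 seeded runs of a 10 × 3 depletion
design and Monte-Carlo checks at 1,000 replicates — sizes chosen to make the
statistical assertions stable at comfortably interactive runtimes.
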