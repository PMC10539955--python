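# Methods

## The generative model

The analyte is the methoxyamine pentaacetate derivative of glucose with one
acetate lost in the source, composition C₁₅H₂₂N₁O₉, monitored under positive
chemical ionization at m/z 360/361/362 (M+0/M+1/M+2). Its natural-abundance
mass-isotopomer pattern is the convolution over all atoms of per-element
isotope distributions, truncated at shift K = 6 (natural abundance beyond M+6
of a C15 species is < 1e-10, far below any measurement effect; truncation
error is negligible against the 0.1–1% scale of the enrichments of interest).

A production pathway with *n* solvent-exchangeable C–H positions deposits
deuterium as binomial(*n*, *p*) at body-water enrichment *p*; the labeled
spectrum is the convolution of that distribution with the natural baseline.
Excess enrichments EM1, EM2 are fractional abundances minus the unlabeled
baseline's, and R = EM2/EM1 is the observable. The site counts are n = 7
(PEPCK-GNG), 2 (glycerol-GNG), 1 (glycogenolysis), with total GNG
approximated as n = 6 on the assumption that glycerol feeds one-third of the
triose-phosphate pool.

Model assumptions worth keeping in view:

* deuterium enrichment is equal at all exchangeable sites and equals body
  water *p* (no isotope-effect discount);
* pathway populations mix at the molecule level;
* exchangeable-site deuterium is ignored in the *natural* hydrogen abundance
  of the baseline (effect < 1e-5);
* positional information is deliberately not modeled — only nominal mass
  shifts.

## Window normalization (three-ion vs full)

The instrument reports only three ions, so measured fractional abundances are
normalized over M+0..M+2. The package's default (`window="three-ion"`)
mirrors that; a `"full"`-window mode (fractions over the whole truncated
pattern) exists for analysis work. The published reference table is
reproduced to ~0.03% maximum relative deviation under the three-ion window
versus ~1.2% under the full window, which is why three-ion is the default.
Under both conventions the unlabeled (f = 0) column is exactly independent of
*p* — an algebraic cancellation, not an approximation.

## Mixture conventions and exact inversion

Mixtures can be weighted two ways, and the package implements both:

* `mixing="pattern"` (default): populations mix at the spectrum level, and
  the model weights the *unnormalized* excess numerators
  N_x = A_x − b_x·(A₀+A₁+A₂). These are exactly linear in the mixing weights
  and exactly consistent with a spectrum measured on the mixed population;
  R remains a ratio of linear forms in f, so f is recovered in closed form
  (and round-trips to 1e-6 by construction). Dilution with unlabeled glucose
  scales both numerators equally, leaving R exactly unchanged — the model
  form of dilution immunity.
* `mixing="tabulated"`: each population's window-normalized EM_x is weighted
  (the convention of the published lookup table, which it reproduces to
  printed precision). The two conventions differ by < 0.7% relative in R at
  p ≤ 8%; "pattern" is preferred wherever model and measurement must agree
  exactly.

The paper-and-pencil lookup (bracketing 0.5% *p* rows, arithmetic-mean
interpolation, then linear interpolation across the 10% f columns) is
retained as `invert_fgng_tabular` for cross-checking; it agrees with the
closed form to < 0.01 in f when *p* sits on the row grid.

## Isotope constants and the ¹³C calibration

Defaults are IUPAC representative abundances (¹³C 0.0107, ²H 0.000115, ¹⁵N
0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205). ¹³C is by far the most influential
constant for a C15 fragment, and published values span 0.0107–0.0111;
`calibrate_carbon13` picks, within that range, the value that reproduces a
known unlabeled EM2/EM1 signature (default 0.173155, giving ¹³C ≈ 0.010949).
Deuterium-exchangeable positions are not removed from the natural-abundance
hydrogen count (error < 1e-5).

## Equivalent n

Every homogeneous population has a unique R at given *p*; fitting an
ordinary-least-squares line of *n* against R over integer n = 1..7 (f = 1)
and evaluating it at a measured R gives a real-valued "equivalent n" that
summarizes mixed populations stably across *p*. Integer populations
round-trip within the fit residual (< 0.05). For the ⅔ PEPCK + ⅓ glycerol
mixture this package computes n ≈ 6.24–6.25 at p = 4.5–5%; the published
value is 6.12, with the difference attributable to the unstated line-fit and
mixing conventions behind that figure (a two-point fit changes the second
decimal, a triose-level condensation mixture gives ≈ 5.8). The curve of
equivalent n versus subpathway fraction is genuinely curvilinear:
enrichment-weighted mixing pulls it toward the heavier-labeled arm.

## Sensitivity studies

Both studies forward-simulate a perturbed population, push its R through the
standard inversion (GNG end-member n = 6), and report apparent − true f(GNG)
in percentage points. They are fully deterministic.

* **Glycerol-share variation**: the true GNG population is a molecule-level
  n = 7 / n = 2 mixture with glycerol share g ∈ [0.233, 0.433] (±0.10
  absolute around the assumed one-third), mixed with GGL at
  f(GNG) ∈ [0.20, 0.80]; default p = 0.045 (the rodent labeling regime).
  `reference="assumed"` reports the error against the g = 1/3 calculation
  instead of against truth, isolating the deviation effect from the
  integer-6 approximation residual.
* **Transaldolase / pentose-phosphate exchange**: a fraction t ≤ 0.06 of the
  glucose population gains one extra labelable site (glucose C-5) occupied
  with probability 2p(1−p) — the binomial chance of exactly one label across
  the two triose passes, always above *p* for p < 0.5. By default the
  exchange applies to the whole population; `scope="ggl"` restricts it to
  glycogen-derived molecules (gluconeogenic glucose already carries the C-5
  exchange), which is mechanistically arguable and produces much smaller
  errors.

An important structural fact governs both studies: the table's rows flatten
as f(GNG) → 1 (between f = 80% and 100% at p = 4.5%, R moves by only ~0.007),
so df/dR — and with it the effect of any forward-model perturbation — grows
by an order of magnitude between f ≈ 0.1 and f ≈ 0.9. Under the exact
inversion the glycerol study's maximum error is ≈ 31 pp (≈ 23 pp for
f ≤ 0.60) and the transaldolase study's ≈ 10 pp, the maxima sitting at the
high-f(GNG) edge where estimates clamp at 100%. The published figures for
the same studies (6.7 pp; < 4 pp; 1.03 pp) are far smaller and were produced
by an unpublished pipeline we could not reconstruct; none of the alternative
readings we tried (triose-level mixing, relative ±10% grid, error against the
assumed-share baseline, GGL-only exchange scope, linearized inversion,
different *p*) reproduces them jointly. The corresponding checks in
`tests/test_acceptance.py` assert the published numbers and fail; the
package reports what the exact model computes rather than tuning the recipe
to the printed values. Practical reading: the n = 6 assumption is benign at
the low-to-moderate f(GNG) of fed-state work, and increasingly consequential
above f(GNG) ≈ 0.7, where the fasted-state subpathway analysis (which does
not use the n = 6 approximation) is the appropriate tool anyway.

## Synthetic data

The generator emulates integrated three-ion areas: population pattern (GNG as
the ⅔/⅓ subpathway mixture by default, GGL, optional unlabeled dilution),
scaled to an arbitrary total area, with independent per-ion multiplicative
log-normal noise, bit-reproducible per seed. The noise scale is anchored to
the assay's replicate reproducibility: the default `noise_cv=0.0063` with
`noise_reference="em1"` reproduces the observed 0.63% replicate CV of the EM1
excess (the per-ion CV that realizes it is derived by first-order
propagation); `noise_reference="ion"` applies the CV to raw areas instead.
Under the default regime, 20 replicates at p = 1.25%, f = 0.5 give
SE(f̂) ≈ 0.013, consistent with the ~0.02 technical-replicate benchmark.

What the generator does not emulate: chromatographic peak shape and
integration, detector saturation / concentration effects (addressed in real
data by the empirical-baseline mode), drift, carryover, or correlated ion
noise. Passing tests therefore certify the estimators against the labeling
model, not against instrument pathology.

## Numerical choices and edge cases

* Convolutions by exponentiation-by-squaring on abundance polynomials;
  patterns validated non-negative, summing to ≤ 1 + 1e-9.
* Inversion is closed-form (ratio of linear forms); a bracketing root-finder
  serves as an independent cross-check in the tests. Estimates outside [0, 1]
  clamp with a flag; a slack of 2× the replicate SE of R suppresses the
  out-of-range flag for noise-sized excursions.
* EM1 below 1e-4 flags the ratio as unreliable rather than returning a wild
  quotient.
* Acetone standard curves are ordinary least squares; curves with
  1 − R² > 0.003 are rejected unless explicitly overridden, and sample
  responses outside the fitted range are flagged as extrapolation.
* The [2-¹³C]glycerol solver brackets q in (0, 0.5); q above the plasma
  glycerol enrichment is reported but flagged as a model violation.

## Known limitations

* The integer n = 6 approximation biases fed-state f(GNG) upward by ~3 pp
  (p = 4.5%) to ~8 pp (p = 1.25%) at f(GNG) = 0.5 when the true population is
  the ⅔/⅓ subpathway mixture; supplying the composite end-member to the
  estimator removes the bias.
* Sensitivity-study error maxima depend strongly on the inversion convention
  near f(GNG) = 1 (see above) and should be read as properties of the exact
  inversion, not as reproductions of the published figures.
* No dual-tracer deconvolution: the ²H₂O and [2-¹³C]glycerol analyses assume
  separate experiments.
* Positional isotopomers, exact-mass fine structure, and absolute production
  rates are out of scope.
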