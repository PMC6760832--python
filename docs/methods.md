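# Methods

## Scope and data model

`chemocal` calibrates a single response (the drug concentration, μg mL⁻¹)
against UV absorbance spectra sampled on a uniform wavelength grid.  Spectra
live in a `SpectraMatrix` (samples × wavelengths, AU, strictly increasing grid
uniform to 1e-9 nm); concentration layouts live in a `ConcentrationDesign`
(strictly positive μg mL⁻¹, optionally with the coded levels −2/−1/+1/+2 of
the 4-level 3-factor design).  CSV is the only interchange format: instrument
vendor formats are out of scope because no instrument files exist to test
against.

## Synthetic data generator

The generator stands in for unavailable instrument data.  Each component is a
sum of Gaussian bands a·exp(−(λ−c)²/2w²) in wavelength; mixtures obey
Beer–Lambert additivity, A(s,λ) = Σₖ cₛₖ εₖ(λ), plus iid Gaussian noise.

Defaults, chosen once:

* **Band positions** — the drug peaks at 270 nm with its two impurities at
  262 and 329 nm, the λmax values of the real compounds; the drug/impurity-A
  pair is nearly degenerate (cosine similarity ≈ 0.95 of pure spectra), which
  is the overlap structure that makes univariate analysis fail.
* **Absorptivities** — scaled so 10 μg mL⁻¹ of a pure component peaks at
  0.30–0.40 AU, inside the Beer–Lambert validity range; a 60 μg mL⁻¹ training
  mixture then reaches ≈ 2.1 AU.
* **Noise** — σ = 0.002 AU additive Gaussian, a realistic double-beam UV
  noise floor.  One integer seed drives the generator; identical seeds give
  bit-identical spectra.

What the generator does **not** emulate: the true molar absorptivities and
band shapes, baseline drift, wavelength-registration error, stray light, or
heteroscedastic detector noise.  Passing tests therefore demonstrate the
correctness of the estimators and the internal consistency of the pipeline on
idealised mixtures, not instrument-grade performance of any real assay.

The 16-mixture calibration design and 9-mixture test set are the published
concentration layouts, reproduced exactly (each analyte occupies each of its
four levels in exactly four training mixtures; all test mixtures lie inside
the calibrated concentration space).

## PLS1

NIPALS with deflation of both X and c; the regression vector is
b = W(PᵀW)⁻¹q.  A component is abandoned (rank exhaustion) when ‖Xᵀc‖ falls
below 1e-12 of its initial value; requesting more components than the data
support raises a rank-deficiency error naming the attained rank.

**LV selection.** Random 2/3–1/3 partitions (16 → 11/5, ceiling rule; drawn
without replacement), re-centering X and c inside every split, 1000
iterations by default; per-iteration RMSEP is averaged per LV count.  The
selected count is the smallest whose mean RMSEP lies within 10 % of the
minimum (plus a 1e-6 absolute floor for exact ties).  The relative window is
deliberate: past the chemical rank the mean-RMSEP curve is flat to within a
few percent (noise refitting), so a strict argmin wanders among statistically
indistinguishable minima and systematically overshoots the rank, while real
improvements in this regime are hundreds of percent.  The 10 % width follows
the PRESS-ratio parsimony tradition (an F-quantile-like threshold at these
sample sizes); it is configurable via `chemocal.pls.LV_PARSIMONY_RTOL`.

## Linear ε-SVR

The dual is written in signed coefficients βᵢ = αᵢ−αᵢ* (valid since
αᵢαᵢ* = 0 at any optimum): minimise ½βᵀKβ − yᵀβ + ε‖β‖₁ subject to Σβ = 0,
|βᵢ| ≤ C.  The solver has two phases:

1. **SMO bulk phase** — the most violating coordinate is paired with the
   partner maximising the second-order gain estimate; the 1-D subproblem
   along eᵢ−eⱼ (piecewise quadratic because of the two |·| kinks) is solved
   exactly by walking its breakpoints with derivative tests, so arbitrarily
   small optimal steps are taken exactly.  The incrementally updated gradient
   is refreshed from scratch every 64 iterations.
2. **Active-set polish** — near the optimum, pairwise updates zigzag on the
   low-rank Gram matrices typical of spectra (chemical rank ≪ samples).  The
   finisher promotes the worst KKT violators into the free set and solves
   the equality-constrained KKT system on that set directly, with a 1e-9
   proximal ridge (K is singular) guaranteeing a descent step, damped so no
   coefficient crosses zero or leaves the box.

Every fit must certify a duality gap ≤ 1e-6·(1+|objective|) — the bias is
taken from the KKT conditions on free support vectors (falling back to the
primal-optimal breakpoint when none are free) — otherwise a solver error
reports the gap.  ε is interpreted on the centered response scale.

**Hyperparameter search.** `grid_search_svr` defaults to the classical fine
grids ε ∈ {0.01, …, 1.00} step 0.01 and C ∈ {30, …, 1000} step 10; folds are
a seeded random partition into k groups of near-equal size, with centering
re-estimated on each retained set; RMSECV pools squared errors over all
samples.  Ties within 1e-9 go to smaller C, then smaller ε.  The end-to-end
pipeline uses a coarse bracketing subset (6 ε × 6 C values) instead, because
the RMSECV surface of the linear model is smooth; its cost grid extends to
1e5 since derivative spectra carry ~100-fold smaller feature magnitudes and
their dual coefficients (bounded by C) must reach correspondingly higher.

## Preprocessing

* **Centering** is always estimated on training data and applied frozen;
  inside bootstrap splits and CV folds it is re-estimated per split.
* **First derivative**: forward finite differences on the midpoint grid
  (151 → 150 points) by default; Savitzky–Golay (same-length, default window
  5, polynomial order 2) as an alternative.  For the derivative model
  variants the order of operations is derivative first, then centering — the
  derivative is a per-spectrum transform, and centering must be estimated on
  whatever representation enters the regressor.
* **OPLS**: per component, w ∝ Xᵀy; t = Xw; p = Xᵀt/(tᵀt);
  w_o = p − (wᵀp)w normalised; t_o = Xw_o; p_o = Xᵀt_o/(t_oᵀt_o);
  X ← X − t_o p_oᵀ.  Removed training scores are orthogonal to the response
  by construction (wᵀw_o = 0); the filter is idempotent (p_oᵀw_o = 1); it
  stops early with a logged notice when no orthogonal variation remains.
  Default 1 removed component, configurable — the right count is an open
  empirical question for any given data set.

## Evaluation

One RMSE formula serves RMSEC, RMSEP and RMSECV.  Recovery summaries report
the SD with divisor N (population form) by default because the published
reference tables follow that convention (their PLSR test column gives 1.320
with divisor N versus 1.401 with N−1); `ddof=1` is exposed.  The t/F/ANOVA
machinery uses two-tailed t and upper-tail F critical values at p = 0.05;
degenerate inputs (zero pooled variance with unequal means, zero denominator
variance) are flagged as infinite statistics rather than errors.

A known inconsistency in the reference tables is left as published: the PLSR
calibration column's printed RMSEC (0.8350) does not recompute from its own
taken/found values (≈ 0.334).  No test or acceptance quantity depends on it.

## Pipeline

`run_six_model_comparison` runs any subset of the six variants with one seed
controlling simulation, bootstrap and fold assignment (per-variant seeds are
derived deterministically).  Per variant it logs the chosen hyperparameters,
writes calibration/prediction tables and an RMSEP ranking as CSV plus a JSON
manifest (config hash, seeds, package version).  Identical configurations
produce bit-identical outputs.  Default problem sizes — 500 bootstrap
iterations and the 36-candidate coarse grid — keep a full six-model run in
the tens of seconds on one core while leaving the selected hyperparameters
unchanged relative to the fine-grid/1000-iteration settings on the synthetic
study conditions.

## Limitations

* The linear kernel only; nonlinear kernels are out of scope by design.
* Single-response calibration (PLS1); multi-analyte PLS2 is not implemented.
* Synthetic-data realism as described above; conclusions about the relative
  ranking of the six variants on real instrument data cannot be drawn from
  the simulation alone.
* The SVR solver is tuned for the small calibration sets this field uses
  (tens of samples); its dense Gram matrix and O(n²) refreshes would need
  caching/shrinking for thousands of samples.
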