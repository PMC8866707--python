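# Methods

## Problem setting

Calculated LDL-C substitutes a model of VLDL-C for an ultracentrifugation
or direct measurement. All estimators here share the identity
`LDL = TC − HDL − VLDL`, differing only in the VLDL-C model: a fixed
divisor (Friedewald, `VLDL = TG/5`), a strata-wise empirical divisor
(Martin, `VLDL = TG/f(TG, nonHDL)` with `f` a table of per-stratum median
VLDL-C:TG ratios), a global polynomial (NIH/Sampson), or a learned
regression (the pyramid MLP, which predicts measured LDL-C directly from
TC, HDL and TG). The workbench fits the two data-driven estimators on a
derivation cohort, selects the MLP architecture on an internal validation
split, and compares all four on an external cohort that is never touched
before final evaluation (the pipeline generates it only after all fitting
stages; the stage log records the order and tests assert it).

## Units and validity conventions

Everything is mg/dL; no mmol/L conversion is provided. Friedewald
estimates at TG ≥ 400 mg/dL are flagged out-of-validity but still
computed, so whole-range comparisons can include them. Panels with
`hdl ≥ tc`, non-positive TC/HDL or negative TG are rejected with an error
naming the field.

## The adjustable-factor table

Strata are left-closed right-open with out-of-range values clamped to the
edge strata — deterministic lookup, no dropped records. The default
geometry is 30 TG strata (15 mg/dL wide from 30 to 450) × 6 non-HDL strata
(edges 100/130/160/190/220), i.e. 180 cells; the published strata
boundaries for this kind of table are not standardised, so the edges are
configuration, not facts. Derivation: per in-cell median of
`tg / (tc − hdl − ldl_measured)` using the standard median (mean of the
two central order statistics for even n); records with non-positive
implied VLDL-C are dropped and counted. Empty cells are filled from the
nearest non-empty cell in the same TG row first (ties toward the lower
column index), then fully empty rows copy the nearest filled row; fills
are logged. Note that with noisy measured LDL the per-cell median of a
ratio is a biased estimator where VLDL-C is small (low TG), which is
precisely why a smooth learned estimator can outperform the table.

## The pyramid MLP and its selection

Candidates are hidden-width sequences that never increase with depth
(the "pyramid" constraint), i.e. multisets over the node grid; for grid
{10, 20, 30} there are 6/15/28 candidates at depths 2/4/6. Two readings of
the candidate grid are supported: one shared grid for all depths
(default of `enumerate_candidates`) and per-depth caps
({6: 10, 4: 20, 2: 30}), which the full pipeline uses as its default
search space (12 candidates) to keep the 10-fold × candidates search
tractable at cohort scale on one CPU.

Training contract: standard regression MLP — rectifier hidden units,
single linear output, MSE loss, Adam (learning rate 1e-3, batch 512,
L2 penalty 1e-4), features and target standardised with statistics from
the training partition only, early stopping on a 10% inner holdout
(patience 8), epoch cap 60 during cross-validation and 200 for the final
refits. These are configuration defaults chosen as the smallest standard
assumption set, not empirical facts about any published model.

Selection: per depth class, every candidate is scored by k-fold (default
10) cross-validated MSE with the same seed-driven fold partition for all
candidates; the per-depth winners are refitted on the full derivation set
and the tournament final picks the lowest internal-validation MSE, ties
broken toward fewer parameters, then fewer layers, then enumeration
order. With fixed seeds the whole search is reproducible end to end, and
prediction uses the package's own forward pass over stored weights, so a
serialized model predicts bit-identically after reload.

## Accuracy indices

* Bias: mean of (estimate − measured) with a one-sample t-test against 0.
  Zero error variance with zero mean is defined as t = 0.
* RMSE: `sqrt(mean(error²))`; the identity `rmse² = bias² + var(error)`
  (population variance) is property-tested.
* Pn: fraction with `|estimate − measured| ≤ (n/100)·measured`; the band
  is per-sample relative to the measured value and closed at the boundary
  (the ≤/< choice at the boundary is a declared convention).
* Concordance: per category c of measured LDL-C,
  `|{measured ∈ c and estimate ∈ c}| / |{measured ∈ c}|`. The clinical
  scheme is the five self-consistent bins <100, [100,130), [130,160),
  [160,190), ≥190 mg/dL. Empty-denominator categories are reported as
  missing (NaN), never zero, so averages stay honest.
* Grouped RMSE: per-stratum RMSE over TG bins, non-HDL bins (50 mg/dL wide
  by default, configurable) or risk vigintiles; size-weighted pooling of
  squared per-group RMSEs recovers the global RMSE exactly.

## Risk stratification

10-year ASCVD risk comes from a pluggable coefficient file: sex-specific
term lists (transforms: identity, natural log, square, pairwise product)
mapped through the inverse logit. The packaged set is a synthetic
placeholder with plausible signs and magnitudes, clearly marked
NOT-CLINICAL; validation of this module is structural and monotonic, not
coefficient-exact, and a race term is omitted by default (configurable via
the coefficient file's term list). Risk uses TC and HDL only — never an
estimated LDL — so risk strata are independent of the estimator under
evaluation. "Vigintiles" are 20 equal-frequency rank bins; ties are
assigned by stable record order and bin sizes differ by at most one (the
larger bins first).

## Synthetic cohort generator

What it emulates: a large East-Asian health-checkup population.
Defaults (derivation flavour): TC ~ N(198.3, 37.1²), HDL ~ N(54.4, 13.2²),
TG log-normal with median 105 and log-sd 0.5285 (IQR ≈ 75–153 mg/dL),
age N(48.6, 11.5²) clipped to 20–79, 53.5% male; the external flavour is
older (54.0 ± 8.9), 76.2% male, TG median 113, with higher
treatment/diabetes/smoking rates. The three lipid marginals are coupled by
a Gaussian copula with correlations corr(TC,HDL)=0.3, corr(TC,TG)=0.3,
corr(HDL,TG)=−0.4 — population-level lipid correlations of typical sign
and size, and necessary ones: with independent marginals the implied
LDL sd would be ≈ 41 mg/dL, far above the 32.4 mg/dL population target.

True LDL is generated through a VLDL divisor
`f(tg, nonhdl) = clip(4.9 + 3.6·logistic((tg−160)/65) − 0.012·(nonhdl−140), 3, 12)`
— a smooth ramp so that fixed-divisor, table and learned estimators are
meaningfully separated. The base 4.9 is calibrated once, numerically, so
the generated measured-LDL mean hits the 124.8 mg/dL population target
under the default marginals. Measured LDL adds Gaussian assay noise with
sd 7.5 mg/dL (direct homogeneous assay imprecision plus residual biology
not captured by a deterministic divisor); that noise floor is the best RMSE any
estimator can reach. Infeasible rows (hdl ≥ tc, implied LDL ≤ 0) are
redrawn, capped at 100 passes.

What it does **not** emulate: reagent/analyzer batch effects, longitudinal
visits, non-fasting samples, the real (unreported) covariate–lipid joint
distribution beyond the single copula, and pathological lipoprotein
compositions (diabetes/renal/hepatic dyslipidaemias). Passing benchmarks
therefore show that the machinery is correct and that the MLP recovers a
smooth divisor structure under realistic noise — not that it would beat
the closed-form equations on any particular real population.

Missingness is generated block-wise (demographics / lifestyle /
laboratory) and the exclusion flow removes blocks sequentially in that
fixed order, counting each record at the first block that excludes it.
Splits use floor(n·fraction) sizes with the remainder to the first
partition.

## Benchmark problem sizes

The packaged benchmark (`RunConfig()` defaults, used by the acceptance
script and the end-to-end tests) generates a 50,000-record cohort, splits
70/30, derives the table and runs the MLP search on the 35,000-record
derivation set, and evaluates externally on a 20,000-record cohort of the
external flavour — sizes chosen so the full pipeline completes in minutes
on a single CPU while leaving Monte-Carlo error well below the effect
sizes under study. Zero missingness is configured for the benchmark
cohorts; the exclusion flow is exercised by its own tests on constructed
manifests with the documented sequential counts.

## Known limitations

* The MLP backend is a CPU MLP with a fixed training budget; no
  uncertainty quantification, GPU paths, or non-pyramid architectures.
* The Martin-style table is re-derived from data; the originally published
  factor values are deliberately not reproduced.
* The placeholder PCE coefficients order individuals sensibly but are not
  calibrated to any event rate; only quantile membership is used.
* Concordance and Pn are reported without confidence intervals.
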