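# Methods

This package implements MELD (mixed effects for large datasets): a
multivariate procedure for fitting Gaussian mixed-effects models to
trial-level data with many features (EEG epochs, image stacks — any
trials x features array), with family-wise error control by permutation.
This note records the model, the numerical choices, and the places where
the procedure was genuinely open to interpretation, together with the
package's resolution and its rationale.

## The pipeline

Inputs are a design table (subject id, item id, fixed covariates) aligned
row-for-row with a trials x features matrix `Y`, plus a mixed-model
formula such as `signal ~ beh + (beh|subject) + (1|item)`.

1. **Within-subject normalization and correlation.** For each subject,
   every fixed-covariate column and every feature column is centered and
   scaled to unit sum of squares; the per-subject cross product
   `X'Y` is then the matrix of Pearson correlations between each
   covariate and each feature.  Stacking subjects gives `R`
   (`n_subjects * n_terms` rows).
2. **Fisher z and TFCE.** Correlations are variance-stabilized with
   `atanh` and each row is enhanced with signed threshold-free cluster
   enhancement (TFCE): the positive and negative parts are enhanced
   separately over thresholds `dt, 2dt, ... <= max|z|` with weight
   `extent^E * height^H * dt` (defaults `E = 2/3`, `H = 2`, `dt = 0.05`).
   Adjacency is orthogonal (von Neumann) on the feature lattice by
   default; diagonal connectivity or an explicit neighbor list can be
   supplied instead (sensor x time layouts need the explicit list).
3. **Stability selection.** Each (term, feature) element of the enhanced
   stack is tested against zero across subjects: the statistic is the
   across-subject mean divided by the SD of a subject-level bootstrap
   (default 1000 resamples).  Elements with two-sided `p >=` the
   selection threshold (default 0.05) are zeroed in every subject's row.
   No multiple-comparisons correction is applied here — the same
   selection runs inside every permutation, so the final inference
   accounts for it.
4. **Compact SVD and reduction.** The stable stack `R_s` is decomposed
   as `U S V'`, keeping only components with singular values above
   `max(m, n) * eps * S_1`.  The rank is at most
   `n_subjects * n_terms` regardless of the number of features, which is
   the scalability claim: component scores `Y_w = Y V'` reduce the
   mixed-model work from one fit per feature to at most
   `n_subjects * n_terms` fits.
5. **Mixed models per component.** Each column of `Y_w` is fit by REML
   with the user's formula (crossed random effects supported natively);
   the fixed-effect t-values form `T_s` (intercept excluded — only
   modeled terms are tested).
6. **Back-projection.** `T_f[term, j] = sum_c T_s[c, term] S_norm[c]
   V'[c, j]`, with `S_norm = S / sum(S)`.  Permutation passes divide by
   the *true data's* `sum(S)`, so their maps are scaled relative to the
   variance the observed data explained.
7. **Permutation inference.** Each permutation re-runs steps 1-6 in
   full (selection included) on data where the fixed-covariate rows are
   shuffled within each subject.  Per term, the largest `|t|` across
   features per permutation forms the term-level null; empirical
   p-values use the add-one estimator `p = (1 + #{null >= |t|}) /
   (n_perms + 1)` with ties counted against the hypothesis.  A second
   stage takes each permutation's minimum attainable p across terms and
   features (equal to the rank-based p of its own per-term maximum) and
   corrects the term-level p-values across terms.  The significance mask
   is `p < alpha` (default 0.05).

## The permutation scheme

A permutation must break the covariate-trial pairing while preserving
everything the null hypothesis does not constrain.  The package permutes
the *fixed-covariate rows* within each subject and leaves `Y` aligned
with its subject and item labels.  The alternative — moving the rows of
`Y` against the whole design — also breaks the pairing, but it
additionally destroys the cross-subject alignment of item effects: under
that scheme the permuted component scores lose all item variance, their
mixed-model standard errors collapse, and the max-statistic null is
inflated by an order of magnitude, which destroys power (measured: TPR
drops from ~0.8 to ~0.01 at the slope-0.5 / 90%-centrality operating
point).  Keeping (Y, item, subject) intact makes the condition labels
exchangeable across items within subject when the fixed effect is
absent, which is exactly the null being tested; FWER calibration is
unaffected (verified by the null simulations).

## The stability-test reference distribution

The bootstrap-SE selection statistic needs a reference distribution to
convert to the `p < 0.05` selection rule.  The default treats the
bootstrap ratio as a standard-normal deviate (the convention for
bootstrap saliences in the PLS neuroimaging literature); Student's t
with `n_subjects - 1` degrees of freedom is available via
`MeldConfig.stability_reference="t"`.  At n = 9 the normal reference
retains substantially more true signal features under clustered signal
(measured: roughly half again as many at the simulation study's middle
operating point, with correspondingly higher sensitivity), while under
dispersed signal the two references perform equally (both are limited
by the selection-bias component, next section).  Because selection is
repeated identically in every permutation, the choice affects power,
not error control.

## The selection-bias component and its effect on power

Stability selection and the SVD see the same data that the component
models are later fit on.  Under a permutation (and equally under the
global null), the few-hundred noise elements that pass selection by
chance are exactly those whose correlation with the (permuted)
covariate was consistently signed across subjects; the leading right
singular vector aggregates them into a component whose in-sample
association with the covariate is enormous (mixed-model |t| around
20-30 at the simulation's scale; verified against an independent REML
implementation).  This is not a defect of the fit — it is honest
in-sample selection bias, and because the identical selection runs in
every permutation, the max-statistic null absorbs it and family-wise
error stays calibrated (the null simulations confirm rates consistent
with alpha).  Its cost is power: the permutation null's scale is set by
the biased component (damped by the true-data singular-value sum), and
true-signal features must overcome it.  With clustered signal the true
SVD is dominated by the signal cluster and the damping is strong; with
dispersed signal the true singular-value sum is small, the bias
dominates the null, and sensitivity drops well below what the published
simulation study reports at the same nominal settings (the shipped
acceptance checks quantify the gap rather than hide it).  Practical
levers are the selection threshold and reference (stricter selection
weakens the bias at the cost of coverage); eliminating the bias proper
would require split-half or cross-fitted selection, which changes the
method.

## Mixed-model engine

The REML solver uses the penalized least-squares formulation: random
effects enter through `Z Lambda(theta) u` with `u ~ N(0, sigma^2 I)` and
`Lambda` block-diagonal, one lower-triangular relative Cholesky factor
per random term shared across that term's grouping levels (slopes are
correlated with their intercept — unstructured within-term covariance).
For a candidate theta, one Cholesky factorization of
`Lambda' Z'Z Lambda + I` profiles out `u`, `beta` and `sigma^2`
analytically, leaving a search over a handful of covariance parameters.
`Z'Z`, `Z'X`, `X'X` are precomputed once per design and reused across
all component fits and permutations.

Optimization: bounded L-BFGS-B (numerical gradients) from the standard
start (unit diagonal, zero off-diagonal).  Standalone fits
(`fit_lmer`, `LmerEngine.fit(polish=True)`) additionally run a
derivative-free Nelder-Mead search from the same start and keep
whichever found the lower criterion; on flat or multi-basin REML
surfaces the quasi-Newton path can settle in a sub-optimal basin, and
the refined path reproduces an independent REML implementation (lme4) to
~7 significant digits in fixed effects, standard errors, variance
components and the REML criterion on a crossed test problem, and matches
the closed-form balanced one-way ANOVA estimators to 1e-6.  The
permutation loop uses the fast path alone: component t-values rarely
move by more than a few percent, the same optimizer treats the true data
and every permutation identically (so the permutation calibration is
unaffected), and the loop runs several times faster.  Convergence
failures walk a fallback chain — full model, then crossed random
intercepts only, then OLS — and the status is recorded per component;
a t-value is always produced.

SEs come from the profiled information matrix
(`sigma^2 (X' V^-1 X)^-1`); no degrees-of-freedom correction is applied
because significance is calibrated by permutation, not by a t reference.

## Comparator methods

The paired t-test baseline averages trials per condition within subject
and computes the across-subject paired t at every feature.  Inference is
an exact-scheme sign-flip permutation: each permutation flips the sign
of whole per-subject difference maps, optionally applies signed TFCE
(the `t+TFCE` variant), and records the max `|statistic|` across
features.  Features with a zero across-subject SD and nonzero mean have
an infinite t; they are represented by the map's largest finite
magnitude plus one (sign kept), which preserves their dominance while
keeping the TFCE threshold integral bounded.

## Synthetic data

The generator reproduces the simulation design the method was evaluated
on: a 100 x 100 standard-normal noise field with exactly 100
signal-carrying features, 9 subjects, 50 trials each (25 per condition).
The trial signal is `s_ij = (slope + u_i^slope) x_ij + u_i^int + w_j`
with condition codes `x = +/-0.5` (A positive), subject deviations of SD
0.1 on both intercept and slope, and item intercepts `w_j ~ N(0, 1)`
shared across subjects (items are crossed with subjects: every subject
sees every item once).  Each subject's balanced A/B assignment of items
is randomized independently, as in a counterbalanced recognition-memory
design where a given word is "old" for some subjects and "new" for
others.  This counterbalancing is what makes the item intercept
estimable by `(1|item)` rather than confounded with condition; with a
fixed global item-condition assignment the item variance (SD 1.0)
enters the condition contrast's standard error directly and caps the
achievable sensitivity of *every* method far below the operating points
this generator is meant to reproduce.  The trial scalar multiplies the
binary pattern and lands in i.i.d. N(0, 1) feature noise; the noise is
deliberately unsmoothed so the true-positive set is unambiguous.
Signal geometries are deterministic: one 10 x 10 block ("central"),
four 5 x 5 blocks ("split"), twenty-five 2 x 2 blocks ("dispersed"),
and "centrality:C" layouts whose largest cluster holds C% of the 100
signal features with the remainder in 2 x 2 satellites on a regular
grid, separated by at least two empty cells so clusters never merge
under orthogonal adjacency.

What the generator does **not** emulate: spatial or temporal
autocorrelation of real neural noise (deliberately), ERP-like waveform
shape, missing data, artifacts, or unbalanced designs.  Passing tests
therefore demonstrate correctness of the machinery and calibration under
the stated generative model, not performance on real EEG.

## Problem sizes used by the test suite and the acceptance script

Full-scale replication of the published simulation grids (hundreds of
simulations, 500 permutations each) is a cluster-scale computation.  The
shipped checks run the same code at reduced replicate counts, chosen as
the package's own verification scale:

- Operating points (slope 0.5, centrality 90% and 10%): full-scale
  100 x 100 fields, 100 permutations, 1000 bootstrap resamples, a small
  number of replicate simulations (3-8 depending on the check); the
  comparison bands around the published means are the published 95% CIs
  widened by the ratio of replicate counts
  (`sqrt(1/20 + 1/n_replicates) / sqrt(2/20)` on the CI half-width).
- Null calibration: reduced 40 x 40 fields with 60 permutations for the
  mixed-effects pipeline and 50 x 50 fields with 200 permutations for
  the t-test baselines; the acceptance bound is the exact binomial
  interval around alpha = 0.05 at the simulation count actually run.
- Every structural, oracle and property check (dimensions, TFCE closed
  forms and naive-loop equivalence, REML against closed forms and a
  frozen independent reference, permutation determinism) runs at full
  stated precision — those do not depend on scale.

## Known limitations

- Missing values are not supported: drop the feature or the trial.
- The formula grammar covers additive fixed terms and
  `(expr + ... | group)` random terms only — no interactions, nesting,
  or uncorrelated-slope (`||`) syntax.
- Permutation exchangeability is within-subject; between-subject factors
  would need a different scheme and are not supported.
- The fast REML path can under-optimize flat covariance surfaces by a
  few percent in a component t-value; use `polish=True` where individual
  fits matter.
- PPV is undefined when a method flags nothing; such rows are excluded
  from PPV aggregation, never imputed.
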