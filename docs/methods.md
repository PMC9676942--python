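# Methods

## Model and assumptions

The discriminant estimates, for each nodal class g ∈ {positive, negative},
the likelihood of a patient's six-factor profile as a product of
class-conditional categorical probabilities and predicts the class with the
larger likelihood. This is a two-class naive-Bayes *likelihood* rule: class
prevalence (the prior P(Y_g)) deliberately does not enter the default
decision, so the rule answers "which class makes this profile more typical",
not "which class is more probable given base rates". An optional
prior-inclusive mode (`priors=` on `classify`/`patient_score`) adds
10·lg(prior_g) to S_g for sensitivity analysis.

The core assumption is conditional independence of the six factors given
nodal status. Real clinical factors are not independent (tumour diameter and
extracapsular spread correlate, for instance), so the likelihood product is
an approximation; its practical justification is the back-substitution
accuracy, not the factorisation itself.

## Factor categorisation

- Age dichotomised at 45 years (the TNM-staging convention for
  differentiated thyroid carcinoma).
- Diameter binned at 0.7, 1.0, 1.5, and 2.0 cm with **lower-inclusive
  half-open** bins: a 1.0 cm tumour falls in 1.0–1.5, a 1.5 cm tumour in
  1.5–2.0. The printed bin labels overlap at their shared edges and the
  original tie-handling is unrecorded; the half-open convention is this
  package's choice, consistent with the "<0.7" / "≥2.0" end labels and with
  the published worked example (1.6 cm scored with the 1.5–2.0 row).
- Records may carry raw values, categories, or both. When both are present
  they must agree — inconsistencies are reported, never silently recomputed.
  Records multifocal across different parts of the gland (upper/middle/lower
  pole, isthmus) are rejected, mirroring the derivation cohort's exclusion
  criterion.

## Scoring: exactness and rounding

Conditional probabilities are kept as exact integer ratios
(`fractions.Fraction`), so per-factor probabilities sum to exactly 1 and the
likelihood-product oracle is exact rational arithmetic.

Two scoring modes:

- `printed_1dp` (default): each cell score (lg p + 1)×10 is rounded
  **half-away-from-zero to one decimal** before summation, and patient
  scores are summed in decimal arithmetic, so sums of one-decimal cells are
  exact one-decimal numbers. This mode reproduces all 34 published cells
  with zero deviation and the worked example's S− = 37.0 exactly (the
  unrounded sum is 36.947; the published arithmetic demonstrably summed
  rounded cells).
- `full_precision`: unrounded cells. On every one of the 320 enumerable
  profiles this mode's decision coincides exactly with the rational
  likelihood-product argmax (tested exhaustively). Decisions under the two
  modes can differ only where the full-precision margin |S₊ − S₋| is below
  0.6, the maximal perturbation from rounding six cells by 0.05 each.

Zero-frequency cells make the log-score undefined; the default (α = 0)
raises an explicit error naming the cell, and Laplace smoothing
(count + α)/(total + α·J_k) is available for cohorts with empty cells. The
packaged derivation counts have none.

Ties (S₊ = S₋) predict positive and are flagged: predicting metastasis is
the clinically conservative default, and the flag preserves auditability.

## Evaluation

Back-substitution re-classifies a labelled cohort and accumulates a
confusion matrix. The printed-table summary statistic, the "mean coincidence
rate", is the **arithmetic mean of the two per-class recalls computed from
their rounded one-decimal values** — not overall accuracy. Both are
reported: on the published retrospective matrix (129/68/47/168) the mean of
rates is 71.8 while overall accuracy is 297/412 = 72.1. For the prospective
matrix (28/13/15/48) the positive recall recomputes to 68.3 at one decimal
although 68.2 was printed (and consequently a mean of 72.3 vs the printed
72.2); the package reproduces the arithmetic-consistent values and documents
the one-digit discrepancy rather than matching it.

The comparison of the two cohorts' score margins (S₊ − S₋) is implemented as
the two-sided two-sample Mann–Whitney rank-sum test at α = 0.05. The
original description names a signed-rank test "of two independent samples" —
a contradiction in terms, since signed-rank requires paired data; the
rank-sum test is the appropriate rank test for independent groups of unequal
size, and a seeded simulation in the test suite confirms its type-I error is
near the nominal 5% under identical generating parameters.

## Synthetic cohorts

The generator samples exactly the model the score assumes: a Bernoulli
nodal class (default prevalence 197/412) followed by independent categorical
factor draws from the class-conditional relative frequencies of the packaged
derivation counts (default n = 412). It therefore emulates the published
marginals faithfully but **not** the unpublished joint dependence structure
of real patients: synthetic back-substitution accuracy converges to the
analytic independence-model value (exact enumeration over all 320 profiles),
not to the published confusion-matrix cells, and passing tests demonstrate
pipeline correctness under the model, not clinical performance on real data.

Optional raw values are drawn uniformly within each category's bin —
integer years for age, a 0.1 cm grid for diameter — with the open-ended bins
truncated at the derivation cohort's observed extremes (ages 14–81,
diameters 0.2–3.8 cm), keeping categorisation round-trips exact and values
plausible. Generation is reproducible from a single integer seed, and the
full parameter set (including the seed) is written as a sidecar JSON next to
every generated CSV. A degenerate prevalence of 1 is permitted (an
all-positive cohort); tabulation still requires both classes.

## Numerical and design choices

- Rounding is half-away-from-zero throughout (via `decimal`), matching
  printed-table style; Python's builtin banker's rounding would give 71.75 →
  71.7 where the tables print 71.8.
- Scores and rates are floats whose one-decimal values are exact; patient
  score sums use decimal arithmetic to avoid float accumulation artefacts.
- Level tokens in files are plain ASCII (`lt45`, `ge2.0`, `0.7-1.0`, …) to
  avoid Unicode-dash ambiguity in the CSV interface.
- Problem sizes in the stochastic tests: parameter recovery and the
  analytic-accuracy comparison use n = 10⁵ cohorts (binomial-SE bands at 4
  SE and 99% respectively); the type-I-error check uses 1000 replicates of
  n = 100 per group.

## Known limitations

- Only the derivation cohort's marginal counts were ever published, so the
  published confusion matrices cannot be regenerated from patient-level
  data; they are validated as rates-recomputed-from-printed-cells, and the
  synthetic pipeline covers the patient-level path.
- The score table is a point estimate; no uncertainty is attached to the
  per-level scores (the original provides none, and resampling would require
  the unpublished joint distribution).
- No probability calibration, ROC analysis, or regression-based
  alternatives: the package reimplements and audits the published rule, not
  competitors to it.
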