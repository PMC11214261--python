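# Methods

This note documents the models implemented in `chemconform`, their
assumptions, the parameters that matter, and the numerical and
statistical choices made where the design was genuinely open.

## Conformal prediction core

**Model.** Inductive conformal prediction splits training data into a
proper training set (fits the underlying scorer) and a calibration set.
The p-value of a test nonconformity is its rank within the pooled
calibration list plus the test instance itself:
p = (#{α_j ≥ α_test} + 1)/(n + 1). The guarantee — error rate ≤ ε for
prediction sets {y : p_y ≥ ε} — requires only exchangeability of
calibration and test data. Classification is always *mondrian*
(class-conditional): the class-y calibration list contains only
calibration examples with true label y, scored with α(x, y). This gives
per-class validity and robustness to imbalance; pooled (non-mondrian)
calibration is deliberately not offered.

**Nonconformity measures.** Classification: `negative-distance`
(−d_y(x), the default; d_y is the decision score for class y),
`positive-distance` (+d_y(x)), `inverse-probability` (1 − P̂(y|x)) and
`probability-margin` (0.5·(1 − P̂(y|x) + max_{y'≠y} P̂(y'|x))). The
probability-based kinds need a probabilistic scorer (logistic natively;
SVC via internal Platt calibration). Validity holds for *any* fixed
measure — including the deliberately inverted `positive-distance` — but
efficiency (set size) varies greatly; the distance-based defaults are the
sensible choice for SVMs.

Regression: `abs-diff` (α = |y − ŷ|, σ = 1), `normalized`
(σ = ê(x) + β, error model ê trained on absolute proper-train
residuals) and `log-normalized` (σ = exp(ĝ(x)) + β, ĝ trained on
ln(|residual| + β)). β defaults to 0.01; it stabilises the ratio and
removes division by zero. The error model reuses the midpoint scorer's
algorithm and hyper-parameters unless overridden — for heteroscedastic
data an RBF-kernel error model is usually needed, since the conditional
residual scale is rarely linear in the features.

**What normalization buys.** Scaled intervals adapt: widths track the
predicted difficulty, so easy compounds get tighter intervals at the same
coverage. It does *not* reliably shrink the mean width at moderate ε —
an infinite-data calculation with noise scale 1 + |x₁| gives abs-diff
mean half-width 2.26 vs 2.30 for ideal normalization at ε = 0.2 (the
mean is dominated by the hardest objects, where scaling gains nothing);
normalization wins on mean width only at smaller ε and on median width
generally. The test suite asserts the adaptivity property, not a blanket
width reduction.

**Interval construction.** Half-width = α_(k)·σ(x) with
k = ⌈(1−ε)(n+1)⌉; k > n gives (−∞, ∞), so a calibration set of n
instances supports finite intervals only for ε ≥ 1/(n+1) — with n = 5
the onset is 1/6, i.e. 0.17 on a two-decimal grid, and exactly five
distinct half-width multipliers exist across ε ∈ (1/6, 1). The
`linear-interpolated` mode replaces the order statistic by linear
interpolation between adjacent calibration values (α_(0) = 0, truncated
at α_(n)), smoothing the staircase that small calibration sets produce.

**P-value variants.** `smoothed` splits ties with a factor τ ∈ [0, 1]
(default: one uniform draw per (test object, class) from a seeded
generator; τ = 1 recovers the standard count), making p-values exactly
uniform on (0, 1) under exchangeability. `linear-interpolated` pulls the
standard step function through knots at the calibration values, clamped
to 1 below the smallest and to 1/(n+1) above the largest. With distinct
calibration values it stays within 1/(n+1) of the standard p-value
everywhere; heavy ties can bridge a larger jump — an accepted property
of the knot scheme, since interpolation targets small, distinct-valued
calibration sets. Degenerate all-equal calibration needs no special
casing: the counting definition already yields p = 1 at or below the
common value.

**Predictor flavours.** The sampling strategy selects ICP (one random
split), ACP (several independent splits) or CCP (folded splits whose
calibration parts partition the data). Multi-split classification
aggregates per-split p-values by arithmetic mean (median configurable);
regression aggregates interval bounds per-bound by median (mean
configurable). Aggregation is heuristic — per-split ICPs are exactly
valid, aggregated predictors only approximately so. TCP retrains the
scorer for every (test object, tentative label) pair and ranks against
the same-label training instances; it spends no data on calibration but
costs 2n scorer fits per prediction, so it is only sensible for small
sets.

## Venn-ABERS calibration

For binary problems, an isotonic regression (least-squares monotone fit,
ties pooled; scikit-learn's PAV implementation, cross-checked in the
tests against an exhaustive search over monotone step functions) is
fitted twice over the calibration (score, 0/1) pairs augmented with the
test object labelled 0 and then 1; the fitted values at the test score
are p0 ≤ p1, one of which is perfectly calibrated. The single reported
probability is p1/(1 − p0 + p1), the log-loss-regret-minimising merge;
CVAP merges k fold-wise pairs as GM(p1)/(GM(1−p0) + GM(p1)) and reports
fold-wise min/max as the (p0, p1) envelope. No data balancing is built
in; strongly imbalanced data is the caller's problem.

## Signatures descriptor

A height-h signature is the canonical rendering of the breadth-limited
tree expansion from a root atom: children are all neighbours except the
atom a node was reached from, so ring atoms re-appear at deeper levels
and no ring-closure markers exist. Atom tokens are `[El±…]` (charge sign
repeated), bond prefixes are ``/`=`/`#`/`p`, children sort
lexicographically by their full rendering — making the string invariant
to input atom order. Hydrogens are implicit and never appear; isotopes
and stereo flags are ignored. String collisions between rings and chains
at large heights are theoretically possible under this markerless scheme
and accepted: heights 1–3 (the default) are well below where they
matter.

Feature values count (atom, height) pairs over the configured range, so
per-height counts sum to the heavy-atom count — a cheap full-matrix
invariant. The vocabulary assigns 1-based indices in first-encounter
order and is frozen at prediction time; unknown signatures are dropped
(with a per-molecule diagnostic count), never appended.

## Interpretation

The contribution of feature f is the removal finite difference
s(x) − s(x with x_f = 0), where s is the regression midpoint or the
decision score of the predicted class (the class with the largest
p-value). For linear scorers this equals w_f·x_f exactly; for kernel
scorers it is a model-agnostic approximation. Raw scores rather than
p-values are attributed, for determinism. Atom attribution credits each
occurrence's root atom with an equal share contribution/\#occurrences
(a `spread` flag divides over the occurrence's atom set instead);
normalization divides by the maximum absolute atom value, all-zero maps
stay zero. The "significant signature" is the present feature with the
largest contribution, ties broken by lexicographically smallest string.

## Evaluation and tuning

Efficiency metrics: observed fuzziness (mean p-value mass on false
labels; significance-free), average C (mean set size), single/multi/empty
ratios and a conformal confusion matrix per significance level; for
regression, coverage and mean/median width with infinite-width intervals
counted toward coverage but excluded from width summaries (their count is
reported). Calibration quality: max signed deviation of error rate from
ε, RMSE, and capped RMSE which zeroes conservative deviations
(error < ε) before averaging, so capped RMSE ≤ RMSE always. Default
significance grids are 0.01–0.30 (classification) and 0.05–0.30
(regression) in 0.01 steps.

Validation schemes: k-fold CV (stratified by default for
classification), single train/test split, and leave-one-out; repetitions
re-seed with seed + r; dispersion is reported as the across-fold standard
deviation. Grid search is exhaustive with ties broken by enumeration
order; the default RBF grid is C ∈ {2⁻⁶, 2⁻⁴, …, 2¹²} ×
γ ∈ {2⁻¹⁴, 2⁻¹², …, 2⁻⁴} (60 combinations). `scorer-only` mode
evaluates the bare scorer (macro F1 / RMSE) and never builds a
calibration store; `full-predictor` mode evaluates the conformal
objective (observed fuzziness, or median interval width at a target ε,
default 0.2 — the ε must be chosen by the user with domain knowledge,
the default is merely a sensible midpoint of the usual range).

Scorer defaults are deliberately generic (C = 1, γ = 1/n_features,
linear kernel); the tuning grid is the supported route to strong
models. Signature count features are used raw; optional standardization
applies to dense external descriptor columns only.

## Synthetic data

The numeric generators draw i.i.d. samples — exactly the exchangeability
assumption the validity guarantee rests on — from a two-class Gaussian
mixture (class means ±1 on the first axis by default, unit covariance,
exact class allocation; Bayes error Φ(−1) ≈ 0.159 at unit separation)
and a linear regression y = w·x + noise·scale(x) with the
heteroscedastic option scale(x) = 1 + |x₁|. The molecular generator
concatenates valence-safe SMILES fragments (ring digits renumbered per
fragment; bond-saturated fragments restricted to terminal positions), so
every generated molecule parses by construction. Labels encode a planted
terminal nitro group (classification; optional label-flip noise) or the
aromatic-atom count plus Gaussian noise (regression).

What these fixtures do *not* emulate: realistic chemical-space coverage,
activity cliffs, assay noise structure, scaffold-split distribution
shift. Passing validity tests on them demonstrates the correctness of
the conformal machinery under its stated assumption, not performance on
real assay data — where exchangeability is routinely strained by
temporal or scaffold structure.

## Statistical test design

Validity is checked on 2500 training rows (2000 proper-train, 500
calibration), 2000 test rows, across every nonconformity measure ×
{ICP, ACP(5), CCP(5)} × both scorer families. The tolerance around ε is
3·sqrt(ε(1−ε)·(1/m_test + 1/n_cal)): because all test objects share one
calibration set, the error level *conditional* on that set fluctuates
around ε with standard error ≈ sqrt(ε(1−ε)/n_cal) (the conformal
guarantee is marginal over calibration draws), and the binomial test-set
term alone would reject a perfectly valid predictor too often. The same
reasoning dictates that the smoothed-p-value uniformity test draws a
fresh calibration sample per test instance, making the 5000 p-values
independent so the plain Kolmogorov–Smirnov 1% critical value applies.

Problem sizes throughout the suite (hundreds to a few thousand rows,
5-dimensional features, 200-molecule descriptor checks) are chosen so
the full battery completes in about a minute while keeping Monte-Carlo
bands a few times narrower than the effects being asserted.

## Known limitations

- Aggregated (ACP/CCP) p-value and interval combination has no
  finite-sample guarantee; empirically it tracks ε well.
- The markerless signature grammar can in principle collide rings with
  chains at heights beyond the default range.
- Venn-ABERS prediction refits two isotonic regressions per test object
  (O(n_cal) each); for very large calibration sets a precomputed-CSD
  implementation would be the next step.
- TCP is O(n) scorer retrainings per prediction and is not recommended
  beyond a few hundred training rows.
- Model archives embed fitted scikit-learn estimators via pickle;
  archives are self-describing but not portable across incompatible
  scikit-learn versions.
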