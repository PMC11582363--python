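# Methods

This note records the models implemented in `roughstage`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
can and cannot demonstrate.

## Information systems

The basic container is a rough-set information system: a finite universe
of objects (patients), a finite attribute set with real-valued domains,
and designated decision (Dukes stage, ordinal 0–3), time (follow-up,
months) and event (1 = observed, 0 = right-censored) columns. CSV is the
only ingestion format: comma-separated, UTF-8, `.` decimal, header row,
first column = object id. Three small packaged tables exercise every
stage without external data. One of them stores its first two columns
exactly as the source table renders them even though the rendered header
and values disagree (the 45/35/65/36/64 column is stored under `a1`);
the ambiguity is documented in the fixture docstring rather than silently
"repaired".

## Variance inflation factors

VIF_j = 1/(1 − R²_j), with R²_j the coefficient of determination of OLS
(intercept included) of attribute *j* on all other numeric conditional
attributes. Banding: < 10 low, [10, 15) moderate, ≥ 15 high. Reduction is
stepwise: the highest VIF in the high band is removed and all VIFs are
recomputed, until the high band is empty — deleting a column changes every
remaining R², so a single pass would over- or under-delete. The decision,
time and event attributes are never candidates.

Rank-deficient designs (fewer observations than predictors, exact
collinearity) are solved by minimum-norm least squares (`numpy.lstsq`
pseudo-inverse) and flagged in the report; when the fit interpolates,
R² → 1 and the VIF is reported as `inf` with a diagnostic instead of
raising, because an infinite VIF is exactly the signal the reduction rule
needs. The worked 5-row example table is such a case (5 observations,
5 predictors + intercept): its per-attribute VIFs are not recoverable
from the data, and only the formula-level value is asserted in tests.
A small wrinkle found while verifying the worked example: the printed
eight-decimal VIF corresponds to the R² rounded at six decimals before
inverting; both the full-precision and the rounded evaluation are pinned
in the tests.

## Censored Weibull survival

Parameterization: shape η, scale λ with density
f(x) = (η/λ^η) x^(η−1) exp(−(x/λ)^η) and survival S(t) = exp(−(t/λ)^η).
The hazard rises with time iff η > 1, is constant at η = 1 (exponential),
falls iff η < 1. The proportional-hazards extension multiplies the hazard
by exp(β′X); its cumulative hazard is H(t|X) = (t/λ)^η exp(β′X), which in
rate form reads λ_rate · t^η · exp(β′X) with λ_rate = λ^(−η). Both forms
are exposed and kept consistent by construction; some presentations write
the rate form with the same symbol λ as the scale, so the conversion is
explicit in the API.

Likelihood: events contribute log h + log S, censored records log S only.
Without covariates the scale is profiled out analytically
(λ^η = Σ t_i^η / d) and the shape found by a bounded 1-D search on log η
in [−4.6, 4.6] (xatol 1e−10); with covariates, L-BFGS-B on
(log η, log λ, β) with analytic gradients, initialized at the exponential
fit with β = 0. Standard errors come from the numerically differentiated
Hessian of the analytic gradient. At least 2 events are required;
all-censored data is inestimable by design. The likelihood-ratio
statistic against the exponential null is 2(LL_Weibull − LL_exponential),
asymptotically χ²(1); tests confirm a ≈5% type-I error at n = 200 under
independent censoring.

Event imputation for records lacking an indicator: event = 1 when the
fitted CDF at the follow-up time is ≥ a threshold (default 0.5, exposed
as `--event-threshold`); observed events can be preserved with
`respect_observed`. The packaged sample's printed event column has no
stated derivation, so agreement with this rule is *measured* in tests,
never asserted.

Stage-stratified summaries fit one Weibull per stage and report S(t) at
yearly horizons with percentile-bootstrap confidence intervals (default
500 replicates, seeded). The point estimate shown next to the CI is the
bootstrap median (always inside a percentile interval); the plug-in MLE
survival is reported alongside. The bootstrap was chosen over the delta
method because it is assumption-light and the CI method was otherwise
unspecified. Pooled diagnostics: Harrell's C-index of the
stage-covariate PH risk score (via `lifelines.utils.concordance_index`),
the pooled Weibull AIC = 2k − 2LL, and the pooled LR statistic.

## RSFAS discretization

Membership: L(v_i, v_j) = 1 − |v_i − v_j| / max(v_i, v_j); 1 for equal
values. The formula is undefined for non-positive pairs (expression data
is positive); for robustness the implementation substitutes
max(|v_i|, |v_j|, 1e−12) in the denominator and clips to [0, 1] — this
guards synthetic edge cases only. Membership is scale-invariant for
positive pairs, symmetric, reflexive.

Printed proximity tables round to 2 decimals, and some of the printed
class derivations only reproduce under 2-dp rounding, so the default
rounds the matrix to `rounding_dp = 2` before comparing with α
(`--no-round` for exact comparison, with a 1e−9 float-comparison slack).
Two α-similar objects, or a chain of them, are α-identical: classes are
the connected components of the thresholded graph
(`scipy.sparse.csgraph`), which is exactly the max–min transitive
closure thresholded at α — tests verify equivalence against a
Floyd–Warshall oracle. Classes are ordered by smallest member index;
quantization ranks them by ascending class mean and assigns weights 1..k,
with the L/M/H vocabulary at k = 3, VL..VH at k = 5, and generic ranks
(plus a warning above 5) otherwise. α can be overridden per attribute,
since worked examples use 0.98 on a 5-object table and 0.97 on the
20-object one. Categorical, decision, time and event columns pass
through unchanged; the stage column is already ordinal (3..0) and is
never transformed.

Known source inconsistencies, handled by reporting instead of asserting:
the 5-object proximity table only reproduces with a constant denominator
of 45; one printed 20-object class requires membership(57, 55) ≥ 0.97
where the formula gives 0.96 (the class splits into {b7, b10} and {b11}
here); a handful of printed matrix cells (e.g. ages 61 vs 62 printed as
0.99) differ from the formula value by one hundredth.

## LSTM classifiers

A patient's ordinal attribute vector of length T_s is fed as a T_s-step
sequence with one feature per step — the only reading under which each
input token has a corresponding output token. Inputs are standardized by
the training-split mean/sd. Cells use the standard gate algebra (sigmoid
gates, tanh candidate, C_t = f⊙C_{t−1} + i⊙C̃, h_t = O⊙tanh C_t) with an
independent bias per gate; a `shared_bias` mode reuses one bias vector
across the gates, and a `literal_bracket` mode composes w·(x + u·h) for
presentations that bracket the recurrence inside the input map. The
bidirectional model runs a second parameter set over the reversed
sequence; the classifier reads the concatenation of the forward pass's
last hidden state and the backward pass's (aligned) first one. The
alternative `paper_eq20` combiner, (1 − O_t)⊙h_{t−1} + O_t⊙C̃_t, is kept
as an explicit operation for fidelity experiments; it is not part of the
trained path because the corresponding backward-path equations do not
form a consistent gradient derivation, and training instead uses exact
backpropagation-through-time (verified against central finite
differences to < 1e−4 relative error).

Softmax cross-entropy loss; optimizers adam, rmsprop, nadam (adam with
Nesterov momentum) and adamax, all implemented in NumPy and verified to
descend a convex quadratic. Default hyperparameters follow the selected
choices of the tuning grid: 100 units, 2 hidden layers (bidirectional),
100 epochs, batch 64, learning rate 0.02 (bidirectional) / 0.01
(unidirectional), dropout 0.2/0.1, nadam, 70–30 stratified split. Where
the surrounding text and the grid disagree on the learning rate, the
grid's selected value is the default. Inverted dropout is applied to
layer output sequences during training only, driven by the same seeded
generator as the batch shuffling, so identical seed + config reproduces
identical histories and parameters exactly. `epochs = 0` returns the
model at initialization with an empty history. Tie-breaks in argmax
prediction go to the lowest class index.

## Evaluation

One-vs-rest confusion counts per stage; precision TP/(TP+FP), sensitivity
TP/(TP+FN), specificity TN/(TN+FP), F = 2PR/(P+R); macro averages are
unweighted over classes (the averaging convention was otherwise
unspecified). Zero denominators yield 0 with a structured
`MetricWarning` rather than an exception so small CV folds never abort.
Cohen's kappa = (P_o − P_e)/(1 − P_e), with P_e from the marginals; the
degenerate P_e = 1 case returns NaN with a warning. KL divergence is the
standard Σ p·log(p/q) ≥ 0 on discrete distributions; the orientation
printed in some presentations (log q/p inside the sum) is its negative
and is available behind `paper_sign`. ROC-AUC is one-vs-rest with
midrank tie handling (`sklearn`), verified against an O(n²)
pair-counting oracle; classes absent from the reference labels are
flagged NaN and excluded from the macro mean. Stratified k-fold CV uses
`sklearn.StratifiedKFold` (shuffled, seeded) around the LSTM trainer.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes rather than any
particular dataset. Clinical columns: age uniform on [28, 78] (rounded),
gender ∈ {1, 2}, tumour location ∈ {1..4}, two binary adjuvant-treatment
flags. Gene columns: each probe has a printed plausible range (the 17
ranges of the packaged sample, recycled as needed); a per-gene baseline
is drawn inside the range, patients scatter around it with Gaussian sd
0.05, and the level shifts additively by `effect_size` per stage step
(direction random per gene, so some genes rise and some fall with
stage). The tight within-stage scatter is deliberate: log-scale probe
intensities within a biological group are far less dispersed than the
across-group range, and it is what makes the α-cut transitive closure
recover a handful of well-separated expression classes per gene. A
wide-uniform alternative would chain every patient into a single α-class
at realistic cohort sizes and make the discretization vacuous. For
narrow ranges combined with large effects the shifted levels can exceed
the printed range slightly; the ranges are plausibility envelopes, not
hard constraints.

Follow-up: event times Weibull(shape 1.5, scale 60 months) with the scale
multiplied by (1.0, 0.8, 0.6, 0.5) across stages 0–3 so later stages fail
earlier; a `censor_frac` fraction (default 0.3) of patients is censored
at a time uniform below their latent event time. Note that this
censoring mechanism is *informative* (the censoring time depends on the
latent event time), so Weibull fits on generator output are mildly
biased upward; parameter-recovery and test-calibration checks therefore
use independent censoring, and the survival-recovery pipeline check uses
uncensored draws. "Strong stage signal" runs use effect_size 0.8 (≈ 16
noise sd between adjacent stage levels); null runs use 0. Identical
seeds give byte-identical cohorts.

Because all informative genes are driven by the same stage variable, they
are heavily collinear, and the VIF step prunes most of them — the
end-to-end benchmark typically retains two or three genes plus the
clinical columns, which still carry the full stage signal. Passing the
scaled-down benchmark (500 patients, ≥ 0.9 held-out accuracy, shuffled
control at the majority rate) shows the pipeline's plumbing and learning
dynamics are sound; it says nothing about accuracy on real cohorts,
where stage effects are weaker, non-monotone and entangled with batch
effects the generator does not model.

## Problem sizes in the test suite

The suite favours the smallest sizes at which each statistical check is
decisive: MLE recovery at n = 2000, LR calibration over 1000 replicates
at n = 200, oracle equivalences over hundreds of random 10–14-object
systems, and the end-to-end benchmark at 500 patients with a 16-unit
single-layer BiLSTM for 30 epochs. The full suite runs in well under a
minute on one CPU.

## Known limitations

* The α-cut transitive closure is sensitive to chaining: on densely
  sampled continuous attributes (e.g. age over a 500-patient cohort) a
  single class absorbs everything, so such attributes carry no ordinal
  information downstream. This is a property of the construction, not a
  bug; per-attribute α overrides are the available lever.
* The PH covariate fit assumes time-constant proportional effects; no
  model checking beyond the exponential LR test is provided.
* The KL report on hard label histograms uses add-½ smoothing on empty
  cells to stay finite; with many classes and few samples it is a rough
  drift summary only.
* No Cox or log-logistic production fits, no Kaplan–Meier curves, no
  ensemble/stacked classifiers, no ingestion of repository series files.
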