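# roughstage

Uncertainty-aware, stage-based cancer prediction from clinical and
gene-expression tables.

Cohort tables that mix clinical covariates with microarray expression
values are noisy in a specific way: two patients are rarely *equal* on a
real-valued attribute, but they are very often *almost* equal, and a crisp
indiscernibility relation throws that information away. `roughstage`
implements a pipeline that treats this uncertainty explicitly and predicts
a patient's four-level Dukes stage of colorectal cancer, together with a
stage-stratified survival analysis:

1. **Feature reduction by variance inflation.** For each numeric
   attribute *j*, VIF_j = 1/(1 − R²_j) with R²_j from OLS of the attribute
   on the other conditionals. Attributes with VIF ≥ 15 are removed
   stepwise (worst first, VIFs recomputed each step); VIF < 10 is
   negligible, [10, 15) moderate.
2. **Censored Weibull survival.** Event times follow
   f(x) = (η/λ^η) x^(η−1) e^(−(x/λ)^η); right-censored records enter the
   likelihood through S(t) only. A proportional-hazards variant
   h(t|X) = (η/λ)(t/λ)^(η−1) e^(β′X) supplies risk scores, and the missing
   event indicator of a censored record is imputed by thresholding the
   fitted CDF. Model adequacy is judged by AIC, Harrell's C-index and the
   likelihood-ratio statistic against the exponential (η = 1) null.
3. **RSFAS discretization.** A fuzzy proximity relation
   L(x_i, x_j) = 1 − |v_i − v_j| / max(v_i, v_j) is thresholded at a
   degree of belongingness α (default 0.97) and closed transitively; the
   resulting α-equivalence classes are ranked by mean value and each
   numeric attribute is replaced by ordinal weights 1..k
   (Low/Medium/High, or Very-Low..Very-High at k = 5). Rough lower/upper
   approximations over the α-classes are available for set analysis.
4. **LSTM stage classification.** The ordinal attribute vector is read as
   a length-T_s sequence; uni- or bidirectional LSTM cells (standard gate
   equations, NumPy implementation with exact backpropagation-through-time)
   are trained with adam, rmsprop, nadam or adamax.
5. **Evaluation.** One-vs-rest precision/sensitivity/specificity/F-score,
   Cohen's kappa, KL divergence, ROC-AUC and stratified k-fold
   cross-validation.

A synthetic cohort generator with stage-shifted gene expression levels and
Weibull follow-up (stage-dependent scale, right censoring) makes the whole
pipeline runnable and testable without any external dataset; three small
printed example tables ship as packaged fixtures.

## Worked example

```python
>>> from roughstage import membership, fixture, proximity_matrix, alpha_classes
>>> round(membership(3.09, 3.04), 2)        # expression values 98% indiscernible
0.98
>>> t11 = fixture("table11")                # packaged 20-patient sample
>>> m = proximity_matrix(t11, "Age", rounding_dp=2)
>>> for cls in alpha_classes(m, 0.97, t11.column("Age")).classes:
...     print(cls)
('b1', 'b5', 'b18', 'b20')
('b2', 'b3', 'b9', 'b12', 'b13', 'b15', 'b16', 'b17')
('b4', 'b8', 'b14', 'b19')
('b6',)
('b7', 'b10')
('b11',)
```

Patients whose ages are chained by ≥ 97% pairwise similarity fall into one
α-class (75, 70, 73, 71 form the first class); each class then becomes one
ordinal weight. End to end on a synthetic 500-patient cohort with a strong
stage signal:

```python
>>> from roughstage import generate_synthetic, reduce_by_vif, quantize
>>> from roughstage import LSTMConfig, train
>>> is_ = generate_synthetic(500, n_genes=17, effect_size=0.8, seed=11)
>>> reduced, report = reduce_by_vif(is_)    # collinear genes pruned (15 removed)
>>> model = train(quantize(reduced, alpha=0.97),
...               LSTMConfig(direction="bi", units=16, hidden_layers=1,
...                          epochs=30, batch_size=64, learning_rate=0.02,
...                          dropout=0.1, optimizer="nadam", seed=0))
>>> print(model.summary())
bidirectional LSTM (1 layer(s) × 16 units, optimizer=nadam, lr=0.02, dropout=0.1, batch=64)
classes: [0.0, 1.0, 2.0, 3.0]   T_s = 7
epochs run: 30
final epoch: acc=1.0000 loss=0.0005
train-split accuracy = 1.0000   test-split accuracy = 1.0000
```

With a strong stage signal the stage-shifted expression levels separate
into one α-class per stage, so the held-out 30% split is classified
perfectly. A Weibull proportional-hazards fit on the packaged sample:

```python
>>> from roughstage import WeibullPHModel
>>> print(WeibullPHModel.from_information_system(t11, covariates=["Age"]).fit().summary())
Weibull proportional-hazards fit (right-censored MLE)
========================================================
n = 20  events = 10  censored = 10
shape η = 1.73366    scale λ = 73.27 months
rate-form λ_rate = λ^(−η) = 0.000584589
log-likelihood = -53.7461    AIC = 113.4921
covariates:
  Age          β = -0.00261  se(β) ≈ 0.02313
```

η > 1 means the hazard rises with follow-up time; β ≈ 0 says age carries
no detectable proportional effect in this 20-patient sample.

## Command line

The `rsfas-pipeline` entry point exposes each stage (`synth`, `vif`,
`survival`, `rsfas`, `train`, `evaluate`) and a full `run` driven by a
JSON/YAML config; see `rsfas-pipeline <cmd> --help`. Exit code 2 marks
validation errors, 1 runtime failures.

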