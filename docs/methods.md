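# Methods

## Problem setting

Binary classification of tabular clinical records: n subjects × p numeric
attributes plus a 0/1 outcome (1 = case).  The pipeline couples three
components — wrapper feature selection by a pelican-inspired population
optimizer (BPO), a recurrent (LSTM) classifier built from its gate
equations, and a deer-hunting-inspired optimizer (DHO) for the LSTM's
hyperparameters — around a conventional preprocessing and evaluation
protocol.

## Preprocessing

Cleaning removes exact duplicate rows, zero-variance attributes, and rows
with missing entries (median imputation is an option; treating literal
zeros in named columns as missing is opt-in via `zeros_as_missing`,
because the reference summary statistics report 0 as a genuine minimum
for several attributes).  Normalization is min-max to [0, 1], fitted on
training rows only and applied to held-out rows with the stored
parameters; held-out values outside the fitted range map outside [0, 1]
and are flagged, not clipped.  Splitting is stratified 80/20 with exact
largest-remainder allocation per class (remainder ties go to the larger
class — a deterministic, documented tie rule), and stratified k-fold CV
(scikit-learn's `StratifiedKFold`) supplies fold indices.  A 70/15/15
protocol is reachable by setting `train_fraction=0.7` and adjusting
`val_fraction`; 80/20 with a 15%-of-train validation carve-out is the
default.

## Brassy Pelican Optimization

Population of m candidate positions in a box.  Initialization is uniform:
g_ij = L_j + f·(U_j − L_j).  Each iteration places a prey uniformly in the
box, then per member:

- exploration: g ← g + f·(l − s·g) if the prey's objective beats the
  member's, else g ← g + f·(g − l), with f, s ~ U(0,1) drawn per
  coordinate;
- exploitation: g ← g + C·(1 − itr/max_itr)·(2f − 1)·g.

Candidates are clipped coordinate-wise to the box and accepted only on
strict improvement (ties keep the incumbent; NaN candidates are rejected
with a warning), which makes the best-so-far trace non-increasing by
construction.  The neighbourhood constant C defaults to 0.2 — a standard
magnitude for shrinking-radius local scans in this operator family — and
is configurable.

For feature selection the search space is [0, 1]^p; a position decodes to
a mask by thresholding at 0.5, the objective is 1 − (k-fold CV accuracy of
the masked table), all-zero masks get a sentinel objective of 2 so they
can never win, and mask fitness is memoized because the objective depends
on the position only through the decoded bits.  Ties between masks break
toward fewer attributes, then lexicographically.  Two fitness evaluators
ship: a fast logistic-regression surrogate (desk default) and the
package's own LSTM at a 20-epoch cap (full-scale default).

## LSTM classifier

Single layer with U units; gates act on [H_{t−1}, X_t]; sigmoid output
head on the final hidden state.  Tabular rows enter as a length-1 sequence
(the feature vector is the single timestep) — the minimal mapping of row
data onto a recurrent cell; `sequence_mode="timesteps"` feeds one feature
per step instead.  Loss is binary cross-entropy (standard for a sigmoid
head); gradients are exact BPTT, verified against central finite
differences to 1e-4 relative error in the tests.  Optimizer is Adam
(β1 = 0.9, β2 = 0.999, ε = 1e-8); inverted dropout on the final hidden
state during training only; early stopping returns the parameters of the
best validation epoch and halts after `patience` (default 10)
non-improving epochs or `max_epochs` (default 200).  Weights initialize
uniform in ±1/√fan-in, seeded.  Decision threshold 0.5 with the ≥
convention.

## Deer Hunting Optimization

Herd of n positions with a leader (best) and successor (second best).
Per iteration: wind angle θ = 2πδ, δ ~ U(0,1); position angle
ϑ = θ − v with visual angle v ~ U(0, π/8) (the position angle is
described only qualitatively in the source material — as the difference
between wind and visual angles — so this concrete form is a package
design choice, surfaced here); coefficients C1 = ¼·ln(j + 1/m_itr)·h with
h ~ U(−1,1), and C2 = 2c with c ~ U(0,1), refreshed per iteration.  Each
member then moves by one of three rules chosen uniformly at random:

- encircle: K_L − C2·β·|C1·K_L − K_j|
- angle:    K_L − τ·|cos ϑ|·(K_L − K_j)
- successor: K_s − C2·τ·|C1·K_s − K_j|

with β ~ U(0,2) and τ ~ U(0,1) drawn **per coordinate**: the update rules
are coordinate-wise and the coefficients are vectors; per-coordinate
draws also give the optimizer the anisotropic moves it needs to refine
all coordinates simultaneously (with scalar draws the shifted-sphere
final/initial ratio stalls around 0.16; with vector draws it reaches
0.02–0.05).  Greedy acceptance per member keeps the best trace
non-increasing.  Uniform mode mixing is itself a design choice — the
scheduling among the three rules is not prescribed — and greedy
acceptance preserves the monotone-trace guarantee under any schedule.

Hyperparameter tuning runs DHO over [0, 1]^4 decoded as
lr = 10^(−5+3p₁), batch = round(16 + 112p₂), units = round(32 + 224p₃),
dropout = 0.1 + 0.4p₄.  The objective is the RMSE of predicted
probabilities on a stratified validation carve-out (15% of the training
split), with the LSTM trained at a reduced epoch cap during fitness
evaluations; a diverging configuration receives the sentinel objective
instead of aborting the search.  The winning configuration is refit by the
pipeline at the full epoch budget.  Herd size and iteration budget default
to 30 × 50 at full scale (no reference values exist; these match common
practice for 4-dimensional boxes) and 6 × 10 at desk scale.

## Metrics

Confusion counts with class 1 positive; accuracy, precision,
recall ≡ sensitivity, specificity and F1 from the standard 2×2 formulas;
miss rate as 1 − accuracy (chosen so that the pair behaves like the
accuracy/miss-rate figures quoted together in this literature); Cohen's
kappa κ = (p_o − p_e)/(1 − p_e); RMSE of probabilities against labels;
ROC by threshold sweep over distinct scores with trapezoidal AUC, which
equals the rank-averaged Mann–Whitney statistic (tied scores traverse a
single diagonal segment).  All proportions are stored on the 0–1 scale
and multiplied by 100 only when formatting; zero-denominator ratios are
returned as flagged nulls, never silently 0.

## Synthetic data generator

The generator defines the study conditions for every simulation-based
test.  Each attribute follows a distribution truncated to its published
[min, max] with parameters solved numerically (least squares on the
closed-form truncated moments) so post-truncation mean and SD match the
published PIDD values to 1e-4 relative error.  A truncated normal is used
whenever it can fit; Insulin (SD/mean ≈ 1.44), Pregnancies and Age need
the truncated-gamma branch, whose coefficient of variation is not capped
near 1 the way a left-truncated normal's is.  Sampling is by rejection
from the parent family, so draws lie strictly inside the open interval.
A quadrature oracle over the fitted density independently verifies the
solved moments in the tests.

The outcome is Bernoulli(σ(β₀ + Σ β_k z_k)) with z the attributes min-max
scaled by their spec bounds and β₀ solved by bisection so realized
prevalence matches the target (default 0.35 — a free synthetic knob; the
published summary table gives no outcome prevalence).  Default
coefficients are mild (Glucose 4, BMI 2 on the scaled axis);
`strong_signal()` (Glucose 40, BMI 20, four noise columns) is the preset
used where experiments need a separable cohort, chosen once so the
planted Bayes accuracy comfortably exceeds 0.9.  Attributes are sampled
independently; the real PIDD's attribute correlations, zero-inflated
Insulin and integer Pregnancies are deliberately not emulated (continuous
Pregnancies keeps the moment match exact; integer rounding is optional).
Passing tests therefore demonstrate correctness of the machinery on
clean, independent, moment-matched data — not clinical performance on the
real cohort.

## Pipeline, seeds, and scale

Stage order is fixed: clean → normalize → split → select → tune → refit →
score.  Feature selection and tuning only see the training side of the
split; a leakage guard asserts that no test row's full attribute vector
appears among training rows (rows are unique after cleaning, so content
equality identifies leaks).  One master seed feeds labelled SeedSequence
substreams (synth, split, folds, bpo, dho, lstm, tune, refit), making
whole runs bit-reproducible and insulating each stage's stream from the
others' budgets.

Two presets share one code path.  `full` holds the reference budgets
(selection 40 × 150, tuning 30 × 50, 10-fold CV, 200-epoch cap).  `desk`
— the profile the test suite exercises — uses selection 10 × 20 with the
logistic surrogate, tuning 6 × 10 with a 30-epoch fitness cap, 5-fold CV
and a 100-epoch final refit; on a 768-row cohort it completes in about a
minute on one CPU.  Simulation-based tests use further reduced sizes
(e.g. tuning-versus-random-search at herd 4 × 3 iterations on 200 rows,
feature-selection recovery on a 5-attribute, 120-row table); these sizes
are stated in the tests themselves.

## Known limitations

- The optimizers are heuristic: no convergence guarantees beyond the
  monotone best-so-far trace, and results depend on seeds; the tests
  therefore assert distributional properties over seed ensembles.
- The generator's independence assumption overstates how separable
  real clinical data are; accuracy figures on synthetic cohorts are not
  clinical claims.
- The LSTM sees length-1 sequences by default, so it functions as a gated
  feed-forward network on tabular rows; the timesteps mapping is provided
  but equally ad hoc for non-sequential data.
- Discretizing continuous attributes into finite intervals ("data
  separation") is mentioned in the source material but has no consumer
  downstream and is not implemented.
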