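# Methods

## The prediction problem

Systemic lupus erythematosus (SLE) patients accrue irreversible organ
damage, scored by the SLICC/ACR damage index (SDI), a cumulative integer
that never decreases once assigned.  Given a patient's ordered clinic
visits — binary clinical, laboratory, treatment and comorbidity flags, the
SLEDAI-2K disease-activity index binarized to inactive/active, sex and age
— the model outputs the probability of developing a first damage item
(SDI ≥ 1) within the next two years.

## The recurrent model

An Elman network processes one visit per time step:

    h_0 = 0
    h_t = tanh(W_r h_{t-1} + W_i x_t)
    y_t = σ(W_o · h_t)

with hidden width `n` (default 100), input width `p` (the retained
features), `W_r ∈ R^{n×n}`, `W_i ∈ R^{n×p}`, `W_o ∈ R^n` and no bias terms
by default.  Sequences keep their native lengths — there is no padding and
gradients are backpropagated through the entire unrolled history.  Only the
final output `y_T` is supervised, with binary cross-entropy; intermediate
outputs are computed but unsupervised.

Training is per-example stochastic gradient descent with a constant
learning rate over seeded shuffled epochs, halted by *early stopping* once
the training-pool AUC exceeds 0.95 (`early_stop_train_auc`), with a hard
cap of `max_epochs` (default 100).  No momentum, weight decay, clipping or
minibatching is used; with the default learning rate of 0.005 none proved
necessary, and larger rates (0.02–0.05) made the training AUC oscillate
without converging.

### Initialization

`W_i` and `W_o` are i.i.d. uniform(−`init_scale`, `init_scale`)
(default 0.1).  `W_r` starts uniform and is rescaled so its spectral
radius equals `spectral_radius` (default 0.95).  This is the standard
prescription for giving a tanh recurrence usable memory at initialization:
a small i.i.d. `W_r` has spectral radius well below 1 and the hidden state
forgets its past within a few steps, which makes any cumulative signal —
precisely the kind of signal that motivates a recurrent model on visit
histories — unlearnable in practice.  We verified this directly: with
radius ≈ 0.3 the cross-validated AUC on cohorts with a planted cumulative
signal stayed near chance regardless of learning rate, while radius ≈ 0.95
recovers it reliably.  Radius 0 together with `init_scale` 0 yields the
all-zero network (useful in tests).

### Numerics

The per-example forward/backward kernel has a reference NumPy
implementation (`rnn_core`) and an equivalent numba-compiled fast path
(`_fastpath`) used automatically when numba is importable; the fast path
changes training time, not the algorithm.  Gradient correctness of the
reference path is asserted against central finite differences (relative
error ≤ 1e−4 over random shapes T ≤ 6, n ≤ 5, p ≤ 4).  Scores are kept in
(0, 1) by a numerically stable logistic; the loss clips scores at 1e−12
only for logging.

## Cohort selection

* **Cases**: SDI = 0 at the first visit, SDI ≥ 1 later; the model sees all
  visits strictly before the first damaged visit (label 1).  Patients
  damaged at baseline are excluded from the study.
* **Controls**: SDI = 0 at every visit, at least 5 visits, and a non-empty
  prefix after reserving the final 24 months of follow-up as the
  damage-free confirmation window; the prefix (visits at month ≤ last
  month − 24) feeds the model with label 0.  This makes the control label
  semantically parallel to the case label: "no damage in the following two
  years" was actually observed.  Damage-free patients failing either
  requirement join neither group.
* **Rare-feature filter**: binary features positive in fewer than four
  patients (ever-positive, per patient) are dropped before modelling; a
  per-visit counting variant is available by flag.
* **Encoding**: binary flags and the activity flag pass through as 0/1,
  sex as M = 1, age in years.  Age is standardized to zero mean and unit
  variance; during cross-validation the standardization is re-fitted on
  each fold's training part only, and the fitted parameters are recorded so
  leakage can be asserted in tests.

## Validation

Stratified eight-fold split (cases and controls dealt round-robin after a
seeded shuffle, so per-class fold sizes differ by at most one).  For each
fold a fresh network is trained on the other seven parts and scores the
held-out part; all held-out scores are pooled into a single set and one ROC
curve/AUC is computed from them (per-fold AUCs are available as a
diagnostic).  Thresholds are taken at every distinct observed score with
the rule "score ≥ threshold ⇒ positive"; the trapezoidal area equals the
tie-aware concordance probability, which a property test asserts.  The
operating-point report lists thresholds whose sensitivity and specificity
are both ≥ 0.7.  Per-fold training seeds are derived from the master seed
with `numpy.random.SeedSequence` spawn keys.

Static baselines (maximum-likelihood logistic regression fitted by plain
gradient ascent, and a one-hidden-layer tanh feed-forward network trained
with the same SGD/early-stopping rule) consume the features of the last
L ∈ {1, 2, 3} visits of the same usable window, concatenated; sequences
shorter than L are left-padded by repeating the earliest visit (zero
padding by flag).  With the same master seed the static and recurrent
evaluations share folds, making the comparison paired.

## The synthetic cohort generator

No patient-level data accompany the reference study, so the pipeline is
exercised end-to-end on simulated cohorts that emulate its structure:

* **Visits** quarterly with ±1 month uniform jitter; follow-up uniform
  12–120 months; every patient has ≥ 2 visits.
* **Static binary features** drawn once per patient at the prevalences of
  a damage-free SLE control population (the two features without a
  published control prevalence, thrombosis and obstetrical complications,
  use 0.08 and 0.05).
* **Disease activity**: each patient has a long-run activity propensity
  drawn Beta(μκ, (1−μ)κ) with cohort mean μ = 0.5 and concentration κ = 3
  — real cohorts contain chronically active and persistently quiet
  patients — and the per-visit flag follows a two-state chain
  P(active) = 0.8·previous + 0.2·propensity.
* **Damage**: at each visit after the first, a first damage event occurs
  with probability logistic(b₀ + Σ β_f x_f + γ·cum_activity +
  β_age·(age − 35.6)); the first event sets SDI to 1, which is then
  carried forward (the analysis only uses SDI = 0 vs > 0, so further
  accrual is not modelled).  Defaults: b₀ = −9.8, γ = 0.26 per active
  visit, β_age = 0.09 per year, all per-feature β_f = 0.  The intercept is
  calibrated so a 413-patient clinic yields roughly 40 eligible cases
  (the reference study had 38), and the effect sizes give the planted
  signal a cumulative-activity discriminability (AUC of the true count)
  in the high 0.8s — a clearly learnable but not trivial cohort.  The
  age effect mirrors the reference cohort, where cases were about eight
  years older than controls.
* Age at baseline is normal (35.6 ± 10.9 years) and advances
  deterministically with visit time; ~5 % of patients are male.

A cohort is a pure function of (configuration, seed); identical inputs
serialize to byte-identical CSVs.

### What the generator does *not* emulate

Missing values, visit-frequency dependence on disease state, death or
other informative censoring, multi-organ SDI itemization, treatment
switching, and feature-feature correlation structure (flags are drawn
independently).  Passing tests therefore demonstrate that the pipeline
recovers the signals this generator plants, not that the clinical effect
sizes of any real cohort are reproduced.

## Experiment designs (experiments module)

* `experiment_dataset` simulates an 826-patient clinic (twice the
  reference size) and subsamples eligible controls to the study's
  ~1:2.5 case:control ratio.  At the exact reference scale (~40 cases /
  ~100 controls) a single pooled-CV AUC has a standard deviation of about
  0.04 across cohort draws; doubling the clinic stabilizes the eligible
  case count while keeping the validation design unchanged.  The default
  generator, by contrast, produces ~320 eligible controls per 413
  patients — far more than the study's 94, which the study does not
  explain; the ratio subsampling restores its group balance.
* `null_calibration` permutes labels at exactly the reference group sizes
  (38 cases, 94 controls, 132 sequences) and repeats pooled CV over 20
  permutation seeds; the mean AUC must sit near 0.5.  A compact network
  (20 hidden units, 25 epochs) is used since there is nothing to learn.
* `rnn_vs_static_gap` uses the trajectory-only configuration: per-visit
  activity is an unbiased coin (persistence 0.5, no propensity
  heterogeneity), age does not enter the hazard, and the per-count
  coefficient is raised to 0.50 (intercept −13.5) so that the *only*
  signal is the cumulative count — invisible in any short static window.
  Pure count signals need more sequences for stable recovery, so this
  configuration simulates a 1652-patient clinic.  The recurrent model and
  all six static baselines (logistic and FFNN at L = 1, 2, 3) share folds
  within each of five replicates.
* `hidden_robustness` repeats pooled CV at 50 and 100 hidden units on
  shared folds over five replicates of the default cohort.

## Degenerate inputs and tie-breaks

Single-class datasets are rejected wherever an AUC is involved (training,
ROC).  All-equal scores give AUC 0.5.  The ROC's first point uses an
infinite threshold sentinel; the operating-point report only lists finite
thresholds.  A single-patient SDI distribution reports SD 0 by convention.
Identical constant samples in the Mann-Whitney test return p = 1.
Percentages round half-up to one decimal (`0.05 → 0.1`), not banker's
rounding.

## Known limitations

* The optimizer is deliberately plain (per-example SGD, constant rate);
  convergence on weak signals varies between fold/seed combinations, which
  is why the replicate experiments average over seeds.
* The early-stopping rule monitors *training* AUC, so it limits but does
  not prevent overfitting; with many noise features and small samples the
  pooled AUC can sit well below the planted signal's ceiling.
* Logistic-regression fitting is unregularized gradient ascent with a
  fixed budget (5000 iterations); on separable data the coefficients grow
  without bound, which is intended behaviour for this baseline.
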