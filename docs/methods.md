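# Methods

## The modelling problem

In a fresh IVF cycle a clinic transfers one embryo (SET) or two (DET).
Transferring two raises the chance of clinical pregnancy but also creates a
twin risk, and the two embryos of a DET do not implant independently: they
share the same uterus, the same endometrium, the same cycle. The package
implements a stacked (two-level) model of this situation, a selection rule
that maximizes predicted pregnancy subject to a twin-risk ceiling, and a
synthetic-cohort generator with a known ground truth so that every stage can
be validated against exact oracles without patient data.

## Two-level stacked model

**Level 1 — per-embryo implantation.** A gradient-boosted decision-tree
binary classifier (`max_depth` 5, `min_child_weight` 1, `learning_rate` 0.1,
`n_estimators` 100, `gamma` 0, `subsample` 0.8, `colsample_bytree` 0.8; all
overridable) is trained on one row per embryo over the 19 selected features
(16 patient-level, 3 embryo morphology grades). Label attribution:

* a SET embryo takes the transfer's pregnancy outcome;
* both embryos of a DET with 0 implantations are labelled 0, both embryos of
  a DET with 2 implantations are labelled 1;
* the two embryos of a DET with exactly one implantation are **excluded** —
  which of the two implanted is unobservable. The exclusion count is kept on
  the training table and in the model artifact.

Missing feature values are consumed natively: every split learns a default
direction for NaN at train time and applies it at predict time. No external
imputation touches the boosted-tree path.

**Level 2 — DET outcomes.** For a candidate pair, level 1 scores each embryo
(P1, P2) and two symmetric engineered features, P1 + P2 and P1 × P2, are
appended to the 16 patient features (design width exactly 18; embryo
morphology enters only through P1, P2). Two scorers are trained on all DET
records: one for clinical pregnancy (count ≥ 1), one for twin risk
(count = 2, non-pregnant DETs twin-negative). A `twin_on_all=False` switch
restricts the twin model to pregnant DETs for sensitivity analysis. Because
only symmetric functions of (P1, P2) enter the design, every DET prediction
is exactly invariant under embryo reordering.

One master seed fans out to the three scorers (seed, seed+1, seed+2), so a
fit is bit-reproducible while the row/column subsampling differs per scorer.

### Known limitation: stacking leakage

Level 2 consumes the level-1 scores of embryos that were themselves level-1
training data, so its input distribution at training time is more extreme
than at prediction time. Consequences we measured on synthetic data: the
twin model's mean prediction is exact in-sample but shifts low on held-out
DETs (≈0.16–0.19 predicted vs 0.21 observed at training sizes of
6 000–20 000), and at small cohort sizes the in-sample P1 × P2 can
quasi-separate the twin outcome in the companion regression. An out-of-fold
stacking scheme would remove this, but the implemented design deliberately
follows the direct formulation (level 2 reads the level-1 predictions as-is);
the shift shrinks as the level-1 scorer's overfitting shrinks with cohort
size.

## Selection under a twin-rate ceiling

For k available embryos, all k single plans and k(k−1)/2 unordered pair
plans are scored (SET plans carry twin risk 0 — monozygotic twinning is out
of scope). `recommend` returns the plan with maximal predicted pregnancy
among those with twin risk ≤ τ, the clinic's acceptable twin-rate threshold;
ties break toward lower twin risk, then fewer embryos, then lexicographic
embryo ids. A feasible plan always exists since SET plans are feasible at any
τ ≥ 0. `sequential_plan` models re-planning after a failed transfer:
recommend, remove the transferred embryos, repeat until none remain — the
plans partition the embryo set. `strategy_report` adds the feasibility
frontier: best achievable predicted pregnancy as a step function of τ, with
breakpoints at the distinct predicted twin risks.

## Synthetic cohort generator

The generator emulates the statistical structure of a fresh-cycle day-3
transfer cohort:

* **Marginals.** Continuous features are truncated normals at the baseline
  mean/SD (truncation at mean ± 4 SD, floored at 0 for counts and hormone
  levels; counts rounded to integers); binary features are Bernoulli at the
  baseline proportions; fragment is ordinal {0, 1, 2} and equality ordinal
  {0..4} with level probabilities reproducing their reported means (0.37,
  0.91). Attempt times of IVF is a non-negative integer with mean 0.95,
  read as prior attempts (0-based). Endometrial type A and C are two
  separate indicators. The transfer mix is DET with probability 564/5828.
  Each marginal exposes the exact mean of its generating distribution
  (analytically, including rounding and truncation), which is what the
  marginal-match tests compare against.
* **Ground truth.** The per-embryo implantation log-odds is a known function
  of the features plus a shared-patient latent receptivity term
  u ~ Normal(0, latent_sd²), latent_sd = 1.0 by default. Conditional on u
  the two embryos of a DET implant independently; marginally they are
  positively dependent, so the DET outcome is not binomial in the per-embryo
  marginals. `marginal_probability` and `joint_det_probabilities` integrate
  u out by 64-node Gauss–Hermite quadrature and serve as the exact oracles.
* **Missingness.** Completely at random at 5% per feature cell; outcome,
  transfer type and ids are never missing.

**Default truth structure.** The default effects are deliberately
non-linear, built from clinically canonical thresholds and windows: a steep
implantation decline beyond age 35; an endometrial receptive window
(10–14 mm) instead of a linear thickness slope; an FSH penalty above the
classic 10 IU/L reserve cutoff; a favourable mid-range LH window (2–8 IU/L);
a low-AFC cliff (< 7); and a fertilization-rate × cleavage-timing embryo
interaction — alongside linear effects for age, prior attempts, E2, embryo
grades and the binary indicators. This structure serves two documented
purposes: it makes the tree model's advantage over a linear classifier real
and measurable on the default cohort, and it realizes the divergence the
companion regression is meant to expose (FSH, LH and AFC carry strong
predictive signal but little marginal, regression-visible signal). The
intercept is calibrated so the expected log-odds — linear means plus the
nonlinear terms' expected contribution under independent marginals — equals
logit(0.33), giving realistic outcome rates (≈37% SET pregnancy, ≈22% DET
twin rate at the default latent SD).

**What the generator does not emulate.** Features are drawn independently,
so physiological couplings (2PN ≤ MII ≤ oocyte count, E2–follicle-count
correlation) are absent; there are no calendar-time effects, no cycle-day
dynamics, no blastocyst-stage biology, and no monozygotic twinning. Passing
tests therefore demonstrate correctness of the machinery under the stated
statistical structure, not clinical performance on real cohorts.

## Evaluation machinery

* **AUC** is the Mann–Whitney concordance probability computed from the
  rank-sum identity with mid-ranks for ties; it is tested against an O(n²)
  all-pairs count to 1e-12.
* **Repeated evaluation** re-draws a stratified train/test split (stratified
  by transfer type × implantation count; default test fraction
  3383/9211 ≈ 0.367) and fresh learner seeds per repeat — the stronger
  interpretation of repeat-averaging; `resample_split=False` freezes the
  split and varies only learner seeds. Three tasks are scored on held-out
  data: SET pregnancy (level 1), DET pregnancy and DET twin (level 2).
* **Calibration tables** use equal-width probability bins (deciles by
  default, configurable); empty bins are reported with count 0.
* **Dunn's test** is implemented directly: joint mid-rank ranking, tie
  correction Σ(t³−t)/(12(N−1)) inside the variance term, two-sided normal
  p-values. **BH-FDR** adjustment is the standard step-up. Under a simulated
  exchangeable null the per-comparison level is nominal and the
  Dunn-then-BH pipeline's family-wise rejection rate stays at or below the
  nominal level (the pairwise statistics are dependent, so the step-up is
  conservative for "any rejection").
* **Algorithm comparison** runs boosted trees, L2 logistic regression and a
  single classification tree on identical splits within each repeat, then
  Dunn + BH per task on the per-repeat AUC groups. The linear and
  single-tree baselines own a median imputation (and, for the logistic
  model, internal standardization — the raw scales span four orders of
  magnitude); the boosted trees keep native missing handling. The asymmetry
  is intentional: it is the realistic comparison between the methods as
  practitioners run them.

Under the shared-latent dependence mechanism the product P1 × P2 is already
a near-optimal *ranking* of twin risk (the latent is independent of the
features, so dependence moves calibration, not order — we measured a
0.0004 AUC ceiling gap between ranking by the true joint probability and by
the product of true marginals). The learned twin model therefore cannot be
expected to beat that baseline's discrimination; its value is in producing
threshold-comparable probabilities for the selection rule.

## Companion regression

Maximum-likelihood logistic regressions (IRLS to 1e-8 or 100 iterations,
Wald z p-values) of the selected features on SET pregnancy (19 features),
DET pregnancy and DET twin (16 patient features + P1 + P2 and P1 × P2).
Complete cases only, with the dropped count reported; separation is detected
from the fitted parameters (diverging coefficients or exploding standard
errors) and raised as an error, never returned as silent coefficients.
`significance_vs_importance` pairs each feature's p-value with its
split-count rank and flags the two directions of divergence
(important-but-not-significant, significant-but-not-important).

Split-count importance is cardinality-biased: features with many candidate
split points (continuous) accumulate counts faster than integer-coded grades
with a handful of levels, independent of signal. The planted-signal tests
account for this by planting continuous features.

## Numerical and problem-size choices

* Gauss–Hermite quadrature at 64 nodes (exact to ~1e-15 for these
  integrands); latent_sd = 0 short-circuits to the closed form.
* Test and acceptance runs use cohorts of 700–6 000 transfers and 2–30
  evaluation repeats; the acceptance script uses 5 828 transfers (the
  emulated training-cohort size), 10 repeats for task AUCs and the
  algorithm comparison, 3 training draws for the ground-truth-recovery gap,
  and 200 random instances for the selection oracle.
* All randomness flows from one master seed through
  `numpy.random.SeedSequence`; sub-seeds stay below 2³¹.
* Tie-breaks in selection are total (twin risk, embryo count, embryo ids),
  so recommendations are unique and order-independent.
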