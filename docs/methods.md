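# Methods

This note documents the models, procedures and design choices in
`tsann`: what is computed, under which assumptions, and why the open
choices were resolved the way they were.

## Problem setting

The package predicts, at a chosen *prediction date*, whether a patient
with asthma will go on to an exacerbation, using only the diagnoses,
medications and demographics recorded in the up-to-365-day *observed
window* before that date. Cohorts are built retrospectively from
long-format EHR tables; the model consumes visit sequences with
irregular inter-visit gaps.

## Cohort rules

- **Visit grouping.** All events of one patient on one calendar date
  form one visit, with codes deduplicated (presence semantics). EHR
  extracts rarely carry reliable intra-day ordering, and a
  calendar-date bag is the simplest reproducible definition.
- **Index date.** Earliest visit with an asthma diagnosis (ICD-9
  `493.xx`; ICD-10 `J45.xx` first passed through a pluggable mapping
  table) *and* a same-day medication whose class is SABA, ICS, LABA,
  LTRA, anticholinergic or ICS/LABA. Medications missing from the class
  table are treated as non-asthma drugs and logged, not errors.
- **Exacerbation date.** Earliest post-index visit where an asthma code
  is the *primary* diagnosis of an ED or inpatient encounter and an
  oral corticosteroid (OCS) is recorded the same day.
- **Label.** Case iff the exacerbation falls within 365 days of the
  index. The boundary is *inclusive* (a 365-day gap is a case): the
  phrase "within 365 days" does not specify strictness, so the
  inclusive convention was chosen and is pinned by tests.
- **Prediction date.** Training and testing set B: cases are scored at
  the visit before the exacerbation, controls at the penultimate visit
  inside the 365-day window. Testing set A (early prediction): the
  fifth visit counting the index visit as first; patients whose
  exacerbation precedes their fifth visit are excluded from set A,
  since the mode is undefined for them.
- **Inclusion/exclusion.** Adults 18–80 inclusive, male/female gender,
  parseable timestamps, at least five visits in the observed window
  `[index, prediction]`. The filter cascade is ordered (time, gender,
  age, asthma index, prediction date, visit count) and the audit maps
  every dropped patient to its *first* failing rule, so
  retained + dropped always partitions the input.

## Encoding

Codes are namespaced (`DX:`/`MED:`) and indexed against a vocabulary
built from the training split only, sorted lexicographically (index 0 =
padding, 1 = unknown). Each visit carries its whole-day gap to the
prediction date, clamped to [0, 364] — the 365-bin time vocabulary with
day as the minimum unit; the clamp can only act at the window boundary.
Demographics enter only at the prediction-date visit as tokens
(`AGE_<decade>`, `GENDER_<g>`, `RACE_<r>`); age is bucketed by decade
because a finer encoding is not needed at the cohort sizes involved.
Sequences are capped at the 50 most recent visits (configurable);
unbounded sequences are impractical and the cap never binds on the
synthetic cohorts.

## Model

Architecture as in the README: concept embedding → code-level additive
attention → elapsed-time concatenation → LSTM → visit-level additive
attention (TSANN-II) or final state (TSANN-I) → dense + optional batch
normalization → 2-way softmax. Notable choices:

- **Attention form.** Both attention layers use the additive
  (tanh-scored) form with a learned context vector — the standard
  hierarchical-attention formulation, which is what the architecture
  calls for at both the code and visit levels.
- **Activations.** Gate activations are sigmoid always (anything else
  breaks gating semantics); the LSTM candidate/output activation and
  the dense head share one configurable nonlinearity
  (tanh / ReLU / leaky ReLU, default leaky ReLU, matching the tuned
  configuration of the protocol the package follows).
- **Sizes.** Concept dimension D_c = 100 and time dimension m = 20 by
  default (the tuned values); hidden size H = 64 is a package default —
  experiments in the tests use smaller sizes (D_c = 24, m = 12, H = 24)
  which are ample for vocabularies of ~10² codes.
- **Initialization.** Embeddings uniform(−0.05, 0.05), dense/LSTM
  weights Glorot-uniform, context vectors uniform(−0.05, 0.05), all
  from one seeded generator. The padding embedding row is zero and is
  never touched by gradients (masked attention gives padded positions
  exactly zero weight).
- **Masking.** Sequences are right-padded; the recurrence carries
  state through padded visits unchanged and both softmaxes are
  masked. Consequently padding a batch never changes any patient's
  probability (verified to < 1e-12; bitwise equality is not asserted
  because reassociating floating-point sums across different pad
  lengths can differ in the last ulp).
- **Loss.** Class-weighted cross-entropy from raw logits, weights
  default 1:1 with the weighting exposed for the ~1:13 imbalance. The
  L2 penalty (default 1e-4) applies to *all* parameters, added to the
  gradient after backpropagation.
- **Differentiation.** A ~300-line reverse-mode tape over NumPy arrays
  (`tsann._autograd`). This is deliberate: the models need only a dozen
  operations, batched forward passes are fast at desk scale (an epoch
  over 1,600 patients takes roughly half a second on one CPU), and the
  test suite checks every parameter block against central finite
  differences to 1e-4 (observed agreement ~1e-10).

## Training and evaluation protocol

Stratified 8:2 train/test split; stratified five-fold CV on the
training portion; for each grid point the per-epoch fold-out AUC is
recorded (up to 30 epochs) and the (configuration, epoch) pair with the
best five-fold mean AUC wins; the model is then retrained on the full
training set for that many epochs. The full tuning grid (learning rate
× L2 × batch size × activation × batch norm × optimizer = 288 points)
is available; `desk_grid()` restricts it to one optimizer and two
learning rates for desk-scale runs. Splits are stratified — a package
choice, since stratification preserves the case:control imbalance
across folds, which matters at 1:13.

AUC is the rank-based Mann–Whitney statistic with ties counted 1/2,
computed from midranks; tests pin it to brute-force all-pairs
concordance exactly. Model comparison uses the two-sided Wilcoxon
signed-rank test on paired AUC samples; what to pair over (folds or
bootstrap replicates) is left to the caller since the emulated protocol
does not specify it. The LR baseline uses bag-of-codes counts, or
code × month-bucket counts when time is included (month as the time
unit, 13 buckets); imbalance is handled by plain random minority
oversampling — an honest, dependency-free stand-in for synthetic
oversampling, applied to the LR baseline only. Neural variants train on
the natural imbalance.

## Interpretation

Per patient, contribution c_ij = βᵢ·αᵢⱼ renormalized to total mass 1;
variants without visit attention use uniform β, flagged by
construction. Cohort-level factors assign each patient's mass to
(code, month-bucket) cells — bucket N covers gaps [30N, 30N+29] days,
so "code/N" reads "presented N months before the prediction date" —
and sum over patients. Per-patient normalization before aggregation is
a design choice: the total score then equals the number of
contributing patients and long records cannot dominate the ranking.
Temporal scatters list one point per (patient, occurrence) with the
contribution weight, subsampling patients without replacement to a
seeded maximum (default 2,000).

## Synthetic cohorts

The generator emulates the structure of a retrospective asthma EHR
cohort, not any real database's content:

- **Visit process.** Visit count 5 + Poisson(mean − 5) with mean 5.78
  (the observed average between index and exacerbation, floored at the
  five-visit inclusion rule); visit days by accumulating
  exponential gaps (mean 60 days — chosen so ~5.8 visits span most of
  the 365-day window), truncated so at least five visits fit; this
  reproduces the irregular sampling the model exists to handle.
- **Content.** Every patient's first visit carries an asthma diagnosis
  plus an asthma medication (so the index is the first visit by
  construction); background codes are drawn uniformly from a synthetic
  vocabulary (default 80 diagnosis + 40 medication codes — enough to
  make factor recovery non-trivial while keeping desk-scale runs fast),
  1 + Poisson(3) codes per visit.
- **Labels.** Logistic: logit = baseline + Σ effect over planted
  factors *active* at their realized day-gap; baseline defaults to
  logit(1/14), matching the ~1:13 case:control ratio. Cases receive a
  terminal ED visit with primary asthma diagnosis and same-day OCS;
  controls a plain trailing visit; both within 365 days of index, so
  the generator's reference visit is exactly the training-mode
  prediction date for cases *and* controls.
- **Planted factors.** A carrier fraction of patients receives the
  factor code once, at a target gap drawn from a configurable range and
  snapped to the nearest existing visit; the factor contributes to the
  log-odds only if the *realized* gap falls in its active window. The
  snap is deliberate — it makes the occurrence a real event row on a
  real visit, and it leaves some carriers just outside the window,
  which makes temporal-localization checks non-trivial.

What the generator does **not** emulate: code co-occurrence structure,
care-seeking intensity correlated with health state, laboratory values,
notes, dosage, and realistic code frequencies. Passing the recovery
experiments therefore demonstrates that the implementation learns and
localizes the signals it is told exist — not that the architecture
would achieve any particular AUC on real claims data.

## Validation experiments (sizes and expectations)

- **Signal recovery** (n = 2,000, one factor, +5 logits, carriers 50%,
  occurrences inside the active window): best-epoch validation AUC
  exceeds 0.9; the information-theoretic ceiling under this design is
  ≈0.92–0.94 because non-carriers still convert at the baseline rate.
  With permuted labels the same pipeline stays within [0.4, 0.6].
  Across generator seeds the recovered AUC varies by roughly ±0.03.
- **Time ablation** (occurrences spread over the whole window, active
  only at gaps ≤ 100 days, 5 seeds × 20 epochs): mean best-epoch AUC
  with elapsed-time embeddings exceeds the no-time ablation (observed
  gain ≈ +0.02). The gap is much smaller than the oracle gap (≈0.83 vs
  ≈0.70 for exact-day vs carrier-only scoring) because even without
  explicit time the LSTM exploits visit *order* as a recency proxy —
  the directional effect, not its magnitude, is the stable quantity at
  this sample size.
- **Interpretation recovery**: the planted code ranks first among
  cohort-level factors and ≥ 80% (observed ≈ 92%) of its temporal
  contribution mass falls inside its active window; the shortfall from
  100% is exactly the snapped occurrences that landed outside.

Problem sizes (n = 2,000 patients, 24/12/24 model dimensions, 10–20
epochs, restricted grid) are the package's chosen desk-scale study
conditions; all are configurable upward.

## Known limitations

- Gradients flow through a Python-level tape; throughput is adequate
  for 10³–10⁴ patients but not for millions.
- Batch normalization uses running statistics at inference; training
  with batch size 1 falls back to those statistics.
- The testing-set-A/B machinery is implemented and tested at the rule
  level, but the shipped experiments evaluate the training-mode cohort,
  where the generator's ground truth is exact.
- The ICD-10→ICD-9 mapping is a pluggable table; no clinical mapping
  content ships with the package.
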