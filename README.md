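# tsann

**Time-sensitive attentive neural networks for exacerbation risk prediction
from longitudinal EHR visit sequences.**

Clinical risk prediction from electronic health records has to cope with
two awkward facts: a patient's history is a *sequence of visits*, each a
bag of diagnosis and medication codes, and the time gaps between visits
are highly irregular — an event ten days before the prediction date
rarely means the same thing as the identical event ten months earlier.
`tsann` implements a hierarchical-attention LSTM that addresses both,
together with everything needed to exercise it end to end: retrospective
case-control cohort construction from raw EHR tables, sequence encoding,
baseline models, cross-validated training and evaluation, attention-based
risk-factor interpretation, and a synthetic EHR generator with *planted,
time-localized risk factors* so that every stage can be validated against
known ground truth. The concrete cohort rules target asthma exacerbation
(index date, ED/inpatient exacerbation events, oral corticosteroids), but
the model layer is disease-agnostic.

## The model

For patient *p* with visits *i* = 1..*n* in the observed window (at most
365 days before the prediction date *T*₀):

1. **Concept embedding.** Each code *j* in visit *i* maps to a vector
   *C*ᵢⱼ ∈ ℝ^{D_c} via an embedding matrix *W*_c (V_c × D_c).
2. **Code-level attention.** *u*ᵢⱼ = tanh(*W*_v *C*ᵢⱼ + *b*_v),
   αᵢⱼ = softmax_j(*u*ᵢⱼ·*u*_v), visit vector *v*ᵢ = Σⱼ αᵢⱼ *C*ᵢⱼ,
   with a learned context vector *u*_v.
3. **Elapsed-time embedding.** The whole-day gap *T*₀ − *T*ᵢ (clamped to
   the V_t = 365-bin vocabulary) indexes a time embedding matrix
   (V_t × m); the row is concatenated to *v*ᵢ. A "step" variant indexes
   by visit order instead of days; ablations concatenate zeros.
4. **LSTM.** Standard recurrence with sigmoid gates f, i, o and a
   configurable candidate/output activation (tanh, ReLU, leaky ReLU)
   over the visit sequence.
5. **Visit-level attention.** βᵢ = softmax_i(tanh(*W*_p *h*ᵢ + *b*_p)·*u*_p),
   patient summary *r*_p = Σᵢ βᵢ *h*ᵢ (variant TSANN-II); the TSANN-I
   variants use the final LSTM state instead.
6. **Output.** Dense layer with nonlinear activation (optional batch
   normalization), 2-way softmax; *P* is the exacerbation probability.

The attention weights are not just machinery: the normalized products
βᵢ·αᵢⱼ give per-patient contribution heatmaps, cohort-level ranked risk
factors by month-before-prediction bucket, and temporal scatter plots of
where in time a factor acts.

Baselines with the same data interface: `MLP`, `LSTM`, `ALSTM`
(code-averaged LSTM with one attention layer) and a bag-of-codes
logistic regression (`LR`, optionally with code × month features and
random minority oversampling).

Everything is pure NumPy on a small reverse-mode autodiff core
(`tsann._autograd`); analytic gradients are verified against finite
differences in the test suite. No GPU or deep-learning framework is
required.

## Worked example

Generate a synthetic cohort with one planted factor (code 530.81,
+5 log-odds when it occurs within 100 days of the prediction date),
build the cohort, train TSANN-I, and ask the attention weights which
code mattered:

```python
import numpy as np, tsann
from tsann.model import ModelConfig, TSANNModel, VariantSpec
from tsann import train_eval as TE, interpret as I

factor = tsann.PlantedFactor("530.81", effect_logit=5.0, active_window_days=(0, 100),
                             carrier_fraction=0.5, occurrence_gap_days=(0, 100))
sim = tsann.generate_cohort(tsann.SimConfig(n_patients=1000, seed=42,
                                            planted_factors=[factor]))
med = tsann.default_med_classes()
classes = dict(zip(med["generic_name"], med["class"]))
records = tsann.cohort.load_patients(sim.patients, sim.events)
samples, audit = tsann.apply_inclusion_exclusion(records, classes)
vocab = tsann.build_vocabulary(samples)
encoded = tsann.encode_cohort(samples, vocab)
labels = np.array([s.label for s in encoded])
print(f"cohort: {len(samples)} patients, {labels.sum()} cases, vocabulary {vocab.size}")

plan = TE.make_splits(labels, seed=0)
model = TSANNModel(VariantSpec("TSANN_I"), ModelConfig(24, 12, 24), vocab.size, seed=0)
model, history = TE.train(model, [encoded[i] for i in plan.train_ids],
                          [encoded[i] for i in plan.test_ids],
                          TE.Hyperparams(learning_rate=0.005, max_epochs=10,
                                         batch_size=64), seed=0)
print(f"validation AUC by epoch: {[round(a, 3) for a in history]}")

matrices = [I.patient_contributions(model.predict(s), s, vocab) for s in encoded]
print(I.cohort_level_factors(matrices).head(3).to_string(index=False))
```

Output:

```
cohort: 1000 patients, 450 cases, vocabulary 139
validation AUC by epoch: [0.675, 0.712, 0.745, 0.758, 0.849, 0.862, 0.858, 0.848, 0.841, 0.845]
     code  month_bucket     score  support
DX:530.81             0 40.313227      229
DX:530.81             2 17.427126      100
DX:530.81             1 16.380245       97
```

The model recovers the planted signal (AUC rises from chance to ≈0.86
against a backdrop of ~120 noise codes), and the cohort-level factor
ranking puts the planted code — in the month buckets covering its
0–100-day active window — at the top. `score` is attention mass summed
over patients (each patient contributes total mass 1); `support` is the
number of patients contributing to that (code, month) cell.

A thin CLI wraps the same pipeline: `tsann simulate`, `tsann train`,
`tsann evaluate`, `tsann gridsearch`, `tsann interpret` (see `--help`).

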