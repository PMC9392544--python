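# eegresp

Resting-state EEG classification of rTMS treatment response in depression,
built around a 1D-CNN + LSTM epoch classifier, with a synthetic-cohort
generator so the whole pipeline is testable without clinical data.

## The problem

Repetitive transcranial magnetic stimulation (rTMS) of the dorsolateral
prefrontal cortex is an established treatment for major depressive disorder,
but only some patients respond (a response being a ≥ 50 % reduction in the
BDI-II depression score over the treatment course). If responders could be
identified from a pre-treatment resting EEG, non-responders could be spared
weeks of ineffective stimulation. This package implements such a pipeline
for 19-channel 10–20 montage EEG sampled at 500 Hz:

1. **Preprocessing** — ICA-based removal of ocular/myogenic artifact
   components, a 50 Hz notch, and a 0.1–60 Hz zero-phase band-pass
   (elliptic by default, Chebyshev type-II selectable);
2. **Segmentation** — the continuous signal is cut into non-overlapping
   1 s epochs (500 samples × 19 channels), each inheriting the recording's
   label;
3. **Augmentation** — the training partition is grown ~2 % per
   cross-validation fold (≈ 20 % in total over 10 folds) with artificial
   epochs built by averaging random same-class epochs and re-injecting
   ~2 % of raw time instances from one parent;
4. **Classification** — a stacked 1D-CNN + LSTM network (below);
5. **Evaluation** — stratified 10-fold cross-validation with a global
   70/20/10 train/validation/test split, reporting sensitivity,
   specificity, accuracy, precision, F-measure, Cohen's κ, and ROC-AUC.

Five dataset definitions are supported: female pre vs post (model 1), male
pre vs post (model 2), female responder vs nonresponder (model 3), male
responder vs nonresponder (model 4), and both sexes pooled (model 5);
models 3–5 use only pre-treatment recordings.

## The network

Each epoch `x ∈ R^{500×19}` passes through valid, stride-1 1D convolutions

```
C_l^r = f( Σ_{k<s} Σ_c  x_{l+k,c} · w^r_{k,c} + b^r ),   l = 1 … L−s+1
```

and non-overlapping max-pooling `h_k^r = max(C_{kd+1}^r … C_{(k+1)d}^r)`.
The default stack is conv128(s=4) → pool4 → conv64(s=4) → pool4 →
conv32(s=4) → pool4 → conv16(s=4) → conv8(s=2) → pool2 →
LSTM50 → LSTM25 → LSTM25 → dense2(sigmoid), for 77,792 trainable
parameters. Forward pass, backpropagation and the Adam optimiser
(batch 128, cross-entropy loss) are implemented directly in NumPy, so every
run is reproducible bit-for-bit from its seed.

Because clinical EEG of this kind is not publicly available, the package
includes a synthetic generator (`eegresp.synth`): spatially correlated 1/f
background, a posterior-dominant 10 Hz alpha rhythm whose band power
carries a tunable class/session effect, plus blink, muscle, power-line and
drift artifacts, and BDI-II scores drawn per sex × response group. Setting
the class effect to zero yields an exchangeable null cohort; the package's
acceptance tests verify both that the pipeline calibrates to chance on that
null and that it recovers a strong injected effect.

## Worked example

```python
from eegresp import (RecordingSpec, TrainConfig, AugmentConfig, CrossValidation,
                     assemble_dataset, generate_cohort, make_fold_plan)
from eegresp.preprocess import cohort_model_inputs, preprocess_recording

spec = RecordingSpec(duration=30.0, conditions=("eyes_closed",))
cohort = generate_cohort(4, 4, {"female": 0.5, "male": 0.5}, spec, seed=0,
                         class_effect=2.0, sessions=("pre",))
pairs = [(p, preprocess_recording(r, seed=0))
         for p, r in cohort_model_inputs(cohort, 5)]
tensor = assemble_dataset(pairs, model_id=5)           # (240, 500, 19)
plan = make_fold_plan(tensor, n_folds=2, policy="subject_level", seed=0)
cv = CrossValidation(tensor, train_cfg=TrainConfig(epochs=10, seed=0),
                     augment_cfg=AugmentConfig(n_folds=2, seed=0), plan=plan)
print(cv.run().summary())
```

prints (about two minutes on one CPU):

```
Cross-validated metrics (2 folds, subject_level splitting)
  test epochs evaluated: 240
  aggregated confusion [tp fp / fn tn]: [117 5 / 3 115]
  sensitivity       0.975 (+/-0.012)
  specificity       0.958 (+/-0.059)
  overall_accuracy  0.967 (+/-0.024)
  precision         0.961 (+/-0.055)
  recall            0.975 (+/-0.012)
  f_measure         0.967 (+/-0.022)
  cohen_kappa       0.933 (+/-0.047)
  auc               0.997 (+/-0.004)
```

Eight synthetic subjects (half responders, strong injected alpha effect)
are preprocessed, cut into 240 one-second epochs, and classified responder
vs nonresponder under subject-level two-fold cross-validation: 232 of the
240 held-out epochs are labelled correctly, and κ ≈ 0.93 indicates
agreement far above chance. With `class_effect=0` the same run hovers at
accuracy ≈ 0.5 and κ ≈ 0, as it must.

The same flow is available from the shell:

```bash
eegresp simulate   --out-dir data --n-female 4 --n-male 4 --duration 30 --seed 0
eegresp preprocess --data-dir data --out-dir work --model-id 5
eegresp train-eval --tensor work/model5_segments.npz \
                   --provenance work/model5_provenance.csv \
                   --out-dir results --n-folds 2 --policy subject_level
eegresp report     --metrics results/metrics.json
```

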