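# rtseiz

Real-time seizure detection and multi-class seizure classification for
pediatric scalp EEG, with a synthetic-cohort generator for end-to-end
testing.

Children on long-term EEG monitoring have seizures that are easy to miss at
the bedside — infantile spasms in particular last about a second and can be
clinically subtle. `rtseiz` implements a two-stage pipeline for this
setting:

* **Stage 1 — streaming detection.** Recordings are re-referenced to the
  22-pair longitudinal-bipolar ("double banana") montage, resampled to
  200 Hz, min–max normalized from training-set statistics, and cut into
  non-overlapping 30 s chunks. A convolutional front-end embeds each
  sliding window (4 s or 12 s long, advanced 1 s at a time) and an LSTM
  head carries state across the windows of a chunk, emitting a seizure
  probability per window: `p_t = σ(w·h_t)`, `h_t = LSTM(CNN(x_t), h_{t-1})`.
  Four detector presets are provided (CNN2D+LSTM, ResNet-short+LSTM, a
  dilated variant, MobileNetV3-short+LSTM).
* **Stage 2 — classification.** Around each seizure, a clip of up to 30 s
  pre-ictal, 120 s ictal and 5 s post-ictal signal is classified into
  {normal, CAE, IESS, GN, FC} by a 5-way softmax CNN (CNN2D+LSTM, a
  bottleneck ResNet-50, MobileNetV3, or DenseNet), from raw signal or from
  a 7-band spectral feature (1–4, 4–8, 8–12, 12–30, 30–50, 50–70,
  70–100 Hz).
* **Chaining.** A threshold-and-merge rule (probability ≥ θ for ≥ m
  consecutive windows) turns Stage-1 traces into candidate events that
  Stage 2 classifies — `rtseiz run-two-stage`.

Evaluation is patient-grouped 5-fold cross-validation with AUROC / AUPRC /
F1 per seizure type and support-weighted aggregates; every reported number
is recomputable from persisted per-window score dumps.

Clinical EEG of this kind is not publicly distributable, so the package
includes a transparent synthetic generator (`rtseiz.synthetic_data`):
spatially correlated 1/f background with a posterior ~9 Hz rhythm, plus
parametric ictal morphologies per type (3 Hz spike-and-wave for CAE, a ~1 s
high-amplitude slow wave with electrodecrement for IESS, 4.5 Hz polyspike
bursts for GN, a focal 4→8 Hz chirp for FC). See `docs/methods.md` for the
model details, assumptions and limitations.

## Worked example

Generate a small annotated cohort, train a detector on one patient fold and
evaluate it on the held-out patients:

```python
from rtseiz import (SyntheticSpec, generate_cohort, ModelConfig,
                    TrainConfig, make_patient_folds)
from rtseiz.pipeline import run_detection_fold

spec = SyntheticSpec(
    n_patients={"normal": 8, "CAE": 6, "GN": 3, "FC": 3},
    recording_minutes=10.0,
    events_per_patient={"CAE": 6, "GN": 5, "FC": 2},
    seed=42)
cohort = generate_cohort(spec)

folds = make_patient_folds(
    {p.patient_id: p.group for p in cohort.patients}, k=5, seed=0)
detector, scores, metrics = run_detection_fold(
    cohort, folds, fold=0,
    model_config=ModelConfig(name="resnet_short_lstm",
                             width_multiplier=0.25,
                             recurrent_hidden=32, seed=1),
    train_config=TrainConfig(batch_size=16, epochs=5,
                             learning_rates=(1e-3,), seed=0),
    window_len_s=4)
for row, vals in metrics.items():
    if not row.startswith("_"):
        print(row, {k: round(v, 3) for k, v in vals.items()})
```

prints

```
Any {'auroc': 0.969, 'auprc': 0.94, 'f1': 0.919, 'f1_best': 0.922}
CAE {'auroc': 0.971, 'auprc': 0.939, 'f1': 0.906, 'f1_best': 0.921}
GN {'auroc': 0.964, 'auprc': 0.936, 'f1': 0.946, 'f1_best': 0.955}
```

The "Any" row scores every sliding window of the held-out patients' full
streams (no negative subsampling, so the class imbalance is the true one);
per-type rows restrict to that type's patients plus the normal controls.
AUROC 0.969 means a randomly chosen seizure window outranks a randomly
chosen non-seizure window 96.5 % of the time; F1 is reported at the 0.5
threshold with a best-over-thresholds secondary value. The per-window
`scores` table is the audit trail from which all of these numbers can be
recomputed.

The same flow from the shell:

```bash
rtseiz simulate --out cohort/ --seed 42
rtseiz train-detect --data cohort/ --out run/ --config run.yaml
rtseiz run-two-stage --data cohort/ --detector run/detector.npz --out bundle/
```

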