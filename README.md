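# mosdet

Explainable short-term stress detection from wearable electrodermal-activity
(EDA) and skin-temperature (ST) signals — an end-to-end, pure-NumPy research
pipeline:

- **`mosdet.simulate`** — synthetic cohorts of 4 Hz wearable recordings:
  sessions of 15–22 min, 10 audio stressors at uniform 52–125 s gaps,
  phasic skin-conductance responses with latency/rise/recovery structure,
  non-responder phenotypes, spurious peaks, tonic drift and noise. Every
  recording carries its ground-truth stimulus protocol.
- **`mosdet.preprocess`** — low-pass denoising, first-order 0.05 Hz
  high-pass phasic extraction, 4→1 Hz anti-aliased downsampling,
  per-channel standardization, and sliding 16 s window segmentation with
  binary stress labels.
- **`mosdet.model`** — an LSTM sequence classifier written in NumPy with
  hand-derived backpropagation-through-time: orthogonal recurrent / xavier
  input initialization, forget-gate bias 1, Adam, class-weighted
  cross-entropy, validation-loss early stopping, and subject-level
  cross-validated grid search.
- **`mosdet.augment`** — Gaussian-noise + amplitude-scale augmentation, a
  conditional GAN (or a deterministic bootstrap surrogate) for synthetic
  window generation, and the Deep Generative Ensemble (DGE): K classifiers
  trained on K disjointly-seeded synthetic merges, probability-averaged.
  An optional outer homogeneous ensemble averages M DGEs.
- **`mosdet.explain`** — Integrated Gradients (straight-line path from a
  zero baseline, right Riemann sum) per window, plus cohort-averaged global
  relevance maps; completeness gap tracked per attribution.
- **`mosdet.evaluate`** — event-based scoring of moments of stress (MOS):
  8 s merging of prediction runs, asymmetric [-2 s, +6 s] greedy matching
  to reference stressors, 8 s true-negative slots, recall / precision /
  accuracy / F1 with undefined ratios reported as absent.
- **`mosdet.cli`** — `mosdet` command with `simulate`, `preprocess`,
  `evaluate` and `experiment` subcommands; the experiment driver runs
  simulate → preprocess → DGE training → held-out prediction → event
  scoring → global attribution, over several subject-level split seeds.

Everything (LSTM gradients, GAN training, attributions) is implemented with
NumPy/SciPy only — no deep-learning framework required.

## CLI

```sh
# generate a 28-subject synthetic cohort (CSV signals + JSON protocols)
mosdet simulate --n-subjects 28 --seed 1 --out scratch/cohort

# window it
mosdet preprocess --cohort scratch/cohort --out scratch/windows.npz

# full experiment (simulation, DGE training, event evaluation, attribution)
mosdet experiment --seed 1 --out scratch/run
mosdet experiment --seed 1 --channels eda --out scratch/run_eda_only

# score a prediction stream against a protocol
mosdet evaluate --predictions preds.csv --protocol S00.protocol.json
```

`experiment` accepts a YAML config (`--config`) mirroring
`mosdet.cli.ExperimentConfig`; every stochastic stage derives its seed from
the global seed plus the stage name, so reports are bit-reproducible.

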