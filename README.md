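# stmi — motor-imagery EEG classification with Stockwell TFMs

`stmi` decodes imagined left- vs right-hand movement from sensorimotor
EEG (channels C3, Cz, C4). Imagining a hand movement suppresses the mu
(8–13 Hz) and beta (14–28 Hz) rhythms over the contralateral
hemisphere (event-related desynchronization, ERD); the pipeline turns
that signature into a classification in four stages:

1. **Time–frequency analysis** — the discrete Stockwell transform
   S[m, n/(NT)] = Σₖ X[(k+n)/(NT)] e^(−2π²k²/n²) e^(−2jπkm/N), a
   Fourier-based decomposition whose Gaussian window widens as
   frequency falls; magnitude maps of C3 and C4 are cropped to
   7–30 Hz, stacked vertically, and resized to a 220×220 image.
2. **Deep features** — a small seeded CNN (3×3 convs with 8/16
   filters, batch norm, ReLU, 2×2 max pooling) trained on the stacked
   maps; the flattened last-pooling activations give a 48,400-dim
   feature vector.
3. **Feature reduction** — semi-supervised discriminant analysis
   (SDA): LDA's scatter-ratio objective regularized by a p-nearest-
   neighbor graph Laplacian built from labeled *and* unlabeled
   samples, solved as the generalized eigenproblem
   S_b a = λ(S_t + βXLXᵀ + εI)a in the span of the training points,
   reducing to 2-D.
4. **Classification** — SVM, Gaussian discriminant, kNN, decision
   tree and random forest, each Bayesian-optimized over its
   hyperparameter space by cross-validated accuracy, fused by
   majority vote. Performance is reported as accuracy, per-class
   sensitivity/precision, and the chance-corrected kappa score
   (kappa = 2·Acc − 1 for two classes).

Trials are segmented with sliding windows (2/3/4 s, 250 ms stride)
starting at the cue, one model stack per window location, so the most
discriminative time span of the imagery period can be located. A
synthetic ERD generator (lateralized mu/beta attenuation that decays
over the trial, pink background noise) makes the whole pipeline
testable end to end without recorded data.

## Worked example

```python
from stmi.pipeline import ExperimentConfig, run_experiment, summarize_windows
from stmi.synthetic import TrialParams

cfg = ExperimentConfig(
    trial_params=TrialParams(erd_depth=0.8, erd_decay=0.15, snr=1.0, seed=0),
    n_trials=80, win_s=3.0, mi_end=6.0,   # single 3-6 s window
    cnn_epochs=30, search_iters=15, seed=1,
)
report = run_experiment(cfg)
for name, r in report.windows[0].reports.items():
    print(f"{name:14s} acc={r.accuracy:.2f} kappa={r.kappa:.3f}")
```

prints (about one minute on a laptop CPU):

```
svm            acc=100.00 kappa=1.000
discriminant   acc=100.00 kappa=1.000
knn            acc=100.00 kappa=1.000
dt             acc=100.00 kappa=1.000
rf             acc=100.00 kappa=1.000
fusion         acc=100.00 kappa=1.000
```

i.e. with a strong injected ERD (80 % contralateral amplitude
attenuation, rhythm power equal to noise power) every optimized
classifier separates the held-out trials perfectly at the first
post-cue window; setting `erd_depth=0` drops all of them to chance
(~50 %), and lowering `snr` reveals the early-window > late-window
accuracy trend caused by the ERD recovering toward the trial end.

The same experiment runs from the shell:

```bash
stmi simulate --n-trials 80 --erd-depth 0.8 --out trials.h5
stmi run --config experiment.yaml --seed 1 --out report.json
stmi report --report report.json
```

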