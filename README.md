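# tcpl — task-conditioned prompt learning for few-shot MI-EEG decoding

`tcpl` is a library and command-line tool for **few-shot cross-subject
motor-imagery (MI) EEG decoding**. It addresses the situation every practical
brain–computer interface faces: a decoder trained on a pool of subjects must
work for a *new* person after only a handful of calibration trials, because
EEG differs strongly across individuals (anatomy, electrode placement,
imagery strategy) and long calibration sessions are impractical.

Instead of fine-tuning, the decoder is *conditioned*: a small support set
`S = {(X_i, y_i)}` of `n_shot` labelled trials per class is mapped,
feed-forward, to `k` continuous **prompt tokens**

    e_i  = f_φ(X_i) ∈ R^d          (light conv encoder per trial)
    h_s  = mean_i e_i              (subject summary)
    P_s  = g_ψ(h_s) ∈ R^{k×d}      (two-layer MLP prompt generator)

which are prepended to the temporal feature sequence `H ∈ R^{T'×d}` produced
by a causal dilated **TCN** backbone, giving the Transformer input
`Z = [P_s; H]`. Prompt rows contribute keys and values in self-attention, so
every sequence token computes subject-conditioned features. Training is
**episodic meta-learning** over subjects: for each sampled support/query
split of a training subject, the loss

    L_meta = (1/|Q_s|) Σ_(X,y)∈Q_s  CE(f_θ(X; P_s), y)  +  λ‖P_s‖²_F

is minimised jointly over θ (TCN + Transformer + head), φ and ψ (Adam,
lr 1e-3, weight decay 1e-4, cosine annealing, 16 episodes per batch,
λ = 1e-4). Adapting to an unseen subject is a single forward pass of the
prompt generator — no weight is ever updated at test time.

The package also provides the standard MI preprocessing pipeline (8–30 Hz
zero-phase band-pass, 4-s epochs with 1-s pre-cue baseline correction,
amplitude-based trial rejection, resampling to 128 Hz, common average
reference, per-subject z-scoring), a synthetic MI-EEG benchmark generator
with class-dependent µ/β band-power modulation (ERD) and subject-specific
spatial mixing, and cross-subject evaluation protocols (ten-fold over
subjects, LOSO, few-shot sweeps, noise/channel robustness, ablations).

The whole model runs on a small reverse-mode autodiff engine over NumPy
(`tcpl.autograd`) — no deep-learning framework is required.

## Worked example

```python
import numpy as np
from tcpl import TCPLClassifier, make_benchmark_arrays, BenchmarkSpec

# synthetic cross-subject benchmark: 10 subjects, 4 MI classes, 16 channels
subjects = make_benchmark_arrays(BenchmarkSpec(
    n_subjects=10, n_classes=4, n_channels=16, trials_per_class=40,
    epoch_s=1.0, subject_jitter=0.3, seed=7))

train_ids = sorted(subjects)[:8]
X = np.concatenate([subjects[s].data for s in train_ids])
y = np.concatenate([subjects[s].labels for s in train_ids])
groups = np.concatenate([[s] * 160 for s in train_ids])

clf = TCPLClassifier(k=4, d=32, tcn_widths=(16, 16, 32, 32),
                     transformer_layers=2, heads=4, ffn_dim=64,
                     lr=3e-3, batch_episodes=8, episodes_per_epoch=32,
                     max_epochs=60, patience=60, n_shot=10, query_cap=16,
                     random_state=0)
clf.fit(X, y, groups=groups)          # episodic meta-training (~2 min CPU)

# adapt to an unseen subject with 10 calibration trials per class
test = subjects["S08"]
support = np.concatenate([np.flatnonzero(test.labels == c)[:10]
                          for c in range(4)])
queries = np.setdiff1d(np.arange(160), support)
clf.adapt(test.data[support], test.labels[support])
acc = (clf.predict(test.data[queries]) == test.labels[queries]).mean()
print(f"unseen-subject 10-shot accuracy: {acc:.3f}")
```

```
unseen-subject 10-shot accuracy: 0.708
```

Four-class chance is 0.25; this run reaches 0.708 on a subject the model
never trained on, from 40 calibration trials, without touching a single
weight (the second held-out subject of the same benchmark scores 0.542 —
per-subject spread is substantial at this benchmark size, which is why the
bundled experiments average over seeds and support draws).

The CLI mirrors the library:

```bash
tcpl simulate --subjects 10 --classes 4 --channels 16 --seed 7 --out data/
tcpl train --data data/ --subjects-train S00,...,S07 --shots 10 --out model.npz
tcpl predict --ckpt model.npz --support data/S08.h5 --queries data/S08.h5 --out pred.csv
tcpl evaluate --data data/ --protocol tenfold --shots 5 --out results/
```

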