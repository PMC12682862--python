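# Methods

## Problem and model

Motor-imagery (MI) EEG decoding must cope with two coupled difficulties:
strong inter-subject variability (anatomy, electrode placement, idiosyncratic
imagery strategies) and the cost of collecting per-subject calibration data.
This package implements a few-shot cross-subject decoder in which a new
subject is described to a *shared, frozen* backbone by a small set of
continuous **prompt tokens** computed feed-forward from a handful of labelled
calibration trials, instead of by fine-tuning.

The model has three parts:

1. **Task-conditioned prompt (TCP) path.** Each support trial
   `X_i ∈ R^{C×T}` is mapped by a light encoder `f_φ` (two temporal
   convolutions, kernel 3, ReLU; global average over time; linear map) to a
   d-dimensional embedding `e_i`. The subject summary is the arithmetic mean
   `h_s = mean_i e_i`, and a two-layer MLP `g_ψ` (hidden width d, ReLU) emits
   `k` prompt tokens `P_s = g_ψ(h_s) ∈ R^{k×d}`. Prompts are deterministic,
   permutation-invariant functions of the support set — they are not free
   parameters and receive gradient only through φ and ψ. Class labels are not
   consumed by this path; the summary describes the subject's signal
   statistics, not class identity.
2. **TCN backbone.** Four residual blocks of two causal dilated convolutions
   each (kernel 3, dilations 1/2/4/8, widths 64/64/128/128, ReLU, dropout
   0.1; a 1×1 convolution on the residual path where widths change). The
   receptive field is `1 + Σ_blocks 2(k−1)·δ = 61` samples. Temporal average
   pooling (stride 2 after blocks 2 and 4) plus a linear projection yields a
   token sequence `H ∈ R^{T'×d}` with `T' = T/4`; the pooling reconciles
   length-preserving causal convolutions with a shortened sequence and keeps
   the attention cost modest. Pooling can be disabled (`pool_stride=1`).
3. **Prompt-prefixed Transformer and head.** The input is `Z = [P_s; H]`.
   Layers are post-norm (LayerNorm after MHSA and after FFN), 4 layers,
   8 heads, FFN width 256, full (unmasked) attention, so sequence tokens
   attend to prompt-derived keys and values and receive subject-conditioned
   modulation. Learned absolute positional embeddings are added to sequence
   tokens only; prompts are position-free context. The head mean-pools the
   sequence tokens (prompt rows excluded by default) and applies a linear map
   to class logits. Prompts are never concatenated to raw EEG channels.

**Meta-objective.** Training is episodic: an episode is one subject's
support/query split (n_shot trials per class in the support, the rest
queries). The loss per episode is the mean query cross-entropy plus
`λ‖P_s‖_F²` (λ = 1e-4), minimised jointly over θ (backbone + Transformer +
head), φ and ψ with Adam (lr 1e-3, weight decay 1e-4, cosine annealing,
16 episodes per batch). At test time, adaptation is purely feed-forward:
prompts are computed once from the unseen subject's support set; no gradient
step touches any parameter, and query trials contribute to no statistic.

## Preprocessing

Raw cued recordings pass through: (1) zero-phase 8–30 Hz band-pass
(4th-order Butterworth, forward–backward — standard MI practice preserving
cue latency); (2) 4-s epochs from cue onset, baseline-corrected by the mean
of the 1-s pre-cue window; (3) peak-to-peak amplitude rejection (default
150 µV — a common heuristic; only the *existence* of a threshold criterion
is prescribed); (4) polyphase resampling to 128 Hz, common average
reference, and per-channel z-scoring with statistics pooled over all of the
subject's trials in the current split — never across subjects. The stage
order resample → CAR → z-score is fixed; CAR and z-scoring are pointwise and
interact with resampling only marginally. Bad channels are removed only via
an explicit configured list; no automatic detector is invented. On a test
subject, z-scoring pools support + query by default (support-only is a
configuration choice) — the statistics are per-subject and label-free, so
this does not leak class information across subjects.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, without
claiming biophysical realism:

- `S = n_classes + 2` band-limited unit-variance Gaussian sources, bands
  drawn alternately from µ (8–13 Hz) and β (14–30 Hz); sources are white
  noise filtered by the same Butterworth design as preprocessing.
- Class structure: class `c` applies a multiplicative **band-power gain**
  (default 0.3, i.e. 70% ERD) to source `c`; the remaining two sources are
  unmodulated background. Amplitudes scale with the square root of the gain,
  so the stated gain is exactly the power ratio. The modulation is constant
  over the epoch (no within-trial ERD time course).
- Subject structure: a shared base mixing matrix `B ∈ R^{C×S}` with entries
  drawn N(0, 0.5²); each subject mixes through `B + jitter·N(0,1)`. The base
  scale 0.5 is calibrated so the default jitter 0.3 puts the subject-specific
  spatial component at ~60% of the shared one: a subject-agnostic decoder
  then stays above chance but lands clearly below the ~95 % within-subject
  band-power ceiling — the transfer gap that subject-conditioned adaptation
  is supposed to close. Subjects also carry an amplitude scale drawn from
  U(0.8, 1.25). With jitter 0 all subjects share one forward model (the
  easy-transfer control).
- Sensor noise is white Gaussian (std 0.5 by default against unit-variance
  sources), matching the Gaussian-noise robustness protocol; 1/f noise is
  deliberately not modelled.
- Everything is bitwise reproducible from the benchmark seed. Channel
  dropout draws one random subset per call (montage semantics), and
  SNR-targeted noise measures signal power per trial over all channels and
  samples.

What passing on this benchmark does **not** show: robustness to real
artefacts (EMG/EOG), nonstationarity within sessions, volume-conduction
geometry, or realistic electrode montages. The suite demonstrates orderings
and mechanisms, not absolute accuracies on real corpora.

## Desk-scale study conditions

Full-size training of this model family is a GPU-scale undertaking; the
bundled experiments are sized so that complete meta-training runs on one CPU
in about two minutes each, as the package's own standard conditions
(`tcpl.experiments`):

- Benchmark: 10 subjects, 4 classes, 16 channels, 40 trials per class,
  subject jitter 0.3, noise std 0.5, **1-s epochs** (128 samples) — the
  shorter epoch keeps the TCN/Transformer cost down while leaving both µ and
  β rhythms resolvable.
- Model (`small_model_config`): the same architecture with d = 32, k = 4
  prompt tokens, TCN widths 16/16/32/32, 2 Transformer layers, 4 heads, FFN
  width 64.
- Training (`small_train_config`): lr 3e-3 (the narrower model tolerates and
  benefits from a slightly larger step), 8 episodes per batch, 32 episodes
  per epoch, 60 epochs, 10-shot episodes, query sets capped at 16 trials for
  throughput.
- Split: 8 training subjects, 2 held-out test subjects; evaluation support
  sets are nested across shot counts within a seed to reduce sweep variance.

## Numerical and design choices

- All tensors are float64; the network runs on a small reverse-mode autodiff
  engine over NumPy written for this package (`tcpl.autograd`) with exactly
  the operator set the model needs. Gradients are verified against central
  differences in the test suite.
- Softmax subtracts a detached row maximum (gradient-exact); LayerNorm uses
  ε = 1e-5; z-scoring guards zero-variance channels with a 1e-8 floor and a
  warning.
- Support-set mean pooling sums rows in a canonical sorted order so the
  pooled embedding is bitwise permutation-invariant, not merely up to
  rounding.
- Prompt initialisation: the stated small prompt initialisation is realised
  by initialising `g_ψ`'s output layer with small Gaussian weights (std
  0.01/√d) and zero bias, so *initial prompt entries* have std ≈ 0.01 while
  prompts remain deterministic outputs.
- Validation during meta-training rotates one held-out training subject per
  epoch. Because the rotating subject is seen by training in other epochs,
  validation accuracy saturates; snapshot selection therefore prefers the
  *latest* among tied epochs. A `validation="fixed"` mode holds one subject
  out of training entirely (cleaner model selection, one fewer training
  subject); rotation is the default.
- Episode count per epoch defaults to 10× the number of training subjects;
  the desk-scale conditions set it explicitly to 32.
- The ablation variants share one code path: `no_tcp` sets k = 0;
  `no_transformer` mean-pools TCN features straight into the head (without a
  Transformer there is no injection point for prompts, so the prompt path is
  absent); `no_tcn` feeds a per-sample linear projection of the raw trial to
  the Transformer.
- Noise robustness corrupts the *test subject's* support and query trials at
  evaluation time (the deployment reading); a train-time-noise variant is a
  flag. Channel reduction is a montage change and retrains per keep-count,
  because the backbone's input width is the channel count.

## Known limitations

- With only 8 training subjects, the meta-learned conditioning map is at the
  edge of what subject-level episodic training can support: run-to-run
  variance across seeds and test subjects is large, and the measured
  advantage of the prompt path over the `no_tcp` ablation at this scale is
  correspondingly noisy; the bundled experiments average over seeds and
  support draws to resolve it. The conditioning map must see enough subjects
  to generalise to new ones, so desk-scale runs are expected to
  under-represent the advantage the mechanism can deliver on large
  multi-subject corpora.
- The NumPy engine is single-threaded aside from BLAS; full-size (d = 64,
  4-layer, 4-s-epoch) training is possible but slow and is not exercised by
  the bundled experiments.
- LOSO and ten-fold protocols assume one container per subject with balanced
  classes; unbalanced designs raise explicit errors rather than reweighting.
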