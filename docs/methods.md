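# Methods

This note documents the models, assumptions and numerical choices behind
`glucospec`, in the spirit of a methods appendix: what each stage computes,
which parameters matter, what the synthetic data does and does not emulate,
and where genuinely open design questions were settled.

## Synthetic glucose traces

Proprietary GOD-strip recordings are not available, so the generator
defines the study conditions explicitly. A trace of duration `T` seconds at
`fs` Hz (defaults 60 s, 100 Hz) is

```
g(t) = baseline + drift(t) + meals(t) + noise(t),  clamped to [20, 500] mg/dL
```

- **baseline** — drawn uniformly from the class band: low 45–70, normal
  80–140, high 180–320 mg/dL. The bands do not overlap, so the classes are
  separable from the trace mean alone; a fixed two-threshold rule on the
  mean reaches ≥ 99 % accuracy. This is deliberate: it is the floor any
  learned model must clear trivially, and it makes end-to-end failures
  attributable to the pipeline rather than to an unlearnable task.
- **drift** — one sinusoid, amplitude 1–3 mg/dL, period 2–10 min, random
  phase: slow physiological wander, essentially constant within a 5 s
  segment.
- **meals** — 0–2 Gaussian bumps per trace, amplitude 5–20 mg/dL, width
  (σ) 2–6 s. Real postprandial excursions play out over tens of minutes;
  the widths here are compressed so an excursion is visible inside a 60 s
  trace. Amplitudes and widths are bounded so the worst-case shift of a
  trace mean (drift + bumps) stays within ±9 mg/dL of the baseline,
  preserving class separability by the mean.
- **noise** — white Gaussian, SD 0.5 / 3 / 12 mg/dL for low / normal /
  high. Electrochemical sensor noise grows with analyte concentration;
  making the amplitude class-dependent is also what gives the *spectrum*
  class information, since per-image normalization removes absolute level
  (see below).

Everything is a pure function of (parameters, seed); per-trace seeds and
the stratified 80/20 train/test assignment derive from one dataset seed.
What the generator does **not** emulate: insulin–glucose dynamics
(no ODE model), sensor drift/recalibration artifacts, dropouts, quantization,
circadian structure, or inter-patient variability. Passing tests therefore
demonstrate that the pipeline recovers class structure of this form — not
clinical performance on real sensor data.

`add_highfreq_noise` injects white noise rescaled so the *realized* SNR
equals the request exactly. Because glucose is strictly positive, the
output is floored at a tiny positive value; at extremely low SNR (where
excursions would cross zero) this floor distorts the realized noise power,
so the exact-SNR contract is only meaningful at moderate SNR.

## Trace → spectrogram image

1. **Wavelet denoising.** Multilevel DWT (Daubechies-4, 3 levels); detail
   levels finer than `keep_detail_from` (default: the two finest) are
   zeroed before reconstruction, removing the noisy high-frequency band
   while keeping the low-frequency signal. Family, order and level count
   are conventional choices and fully configurable. Keeping all
   coefficients reproduces the input to ~1e−8 (perfect reconstruction).
2. **Segmentation.** Non-overlapping 5 s windows; the trailing remainder is
   dropped. Each segment becomes one image labeled with its trace's class.
3. **STFT.** Gaussian window (1 s, σ = 12.5 samples at 100 Hz), 50 %
   overlap, nfft = next power of two ≥ window (128 at the defaults),
   one-sided spectrum, bin 0 = DC. Frames are windowed segments zero-padded
   to nfft; the implementation is checked against a direct O(n²) DFT to
   1e−9 and satisfies per-frame Parseval to 1e−6.
4. **Low-pass masking.** Ideal brick-wall mask in the TF plane: bins above
   the cutoff zeroed, bins at or below copied bit-identically; idempotent
   by construction. Off by default (cutoff = Nyquist).
5. **Rendering.** Magnitude → dB relative to the frame maximum, floored at
   −80 dB, min–max normalized **per image**, mapped through a perceptually
   uniform colormap (viridis) to RGB, resized bilinearly to the target
   size (default 224, 64 in the scaled-down experiments). Frequency
   increases upward, time rightward. Per-image normalization makes each
   image self-contained but erases absolute intensity — this is why class
   information must live in spectral *shape* (the noise floor relative to
   the DC ridge), not in overall brightness.

## AWBK enhancement

Each pixel of the (luminance) image is replaced by a bilateral-weighted
neighborhood aggregate: spatial Gaussian in pixel distance (σ_s = 2 px,
5×5 kernel), range Gaussian in intensity difference. Two adaptive terms:

- **Otsu gating.** A global Otsu threshold (maximizing the between-class
  variance of the 256-bin histogram, ties to the smallest level) splits
  dark background from bright signal ridges; pixels on the dark side get a
  2× larger range bandwidth (ratio configurable), smoothing the noise
  floor harder while preserving ridge edges.
- **Contra-harmonic scaling.** The neighborhood's contra-harmonic mean
  `m_s = Σx²/Σx` (computed on 1-shifted intensities to stay positive),
  relative to the global mean, scales the range bandwidth within [¼, 4]:
  brighter, busier neighborhoods smooth less.

Whether `m_s` should act inside the sum or as the normalizer is genuinely
ambiguous in the original formulation of the kernel; this implementation
uses the standard bilateral form
(normalize by the sum of weights) and uses `m_s` as the local statistic
adapting the range bandwidth — both roles are documented here and in the
docstrings. Borders use reflective padding; output is clipped to uint8.
The batch transformer (`AWBKEnhancer`) optionally (default on) applies a
final linear contrast stretch of the luminance to [0, 255], which spreads
the enhanced histogram instead of leaving it piled near the dark end; the
bare kernel function performs no stretch. Enhancement operates on
luminance only; chroma is reattached by rescaling, since the kernel is
defined on a single channel.

## CNN + Bi-LSTM classifier

Architecture per input image: `n_conv_blocks` × (valid strided convolution
→ batch norm → ReLU → 2×2 max-pool → dropout), then the feature maps are
read as a sequence (image width = time; channels × height = per-step
features), a bidirectional LSTM, additive attention pooling over time, a
fully connected layer, and a softmax head.

- **Defaults** (full-size model): learning rate 1e−5, kernel 4, 128
  filters, stride 2, 30 epochs, dropout 0.3, batch 64, Adam, 2×2 pooling,
  40 FC nodes, 3 softmax nodes, 224×224 input. An FC width of 64 is a
  common alternative and both are configurable. The task can be posed with
  two or three classes; `n_classes` is configurable (3 default; binary mode collapses low + high into
  "abnormal").
- **Scaled-down model** used throughout testing (chosen as the smallest
  configuration that cleanly separates the synthetic fixture): 64×64
  input, 32 filters, 2 conv blocks, LSTM hidden 32, 10 epochs, batch 32,
  learning rate 1e−3.
- **LSTM cell.** A standard
  LSTM cell (input/forget/cell/output gates, forget bias 1) is used
  internally; the directional combination is kept literal:
  `y_t = ω₅ ∘ h→_t + ω₆ ∘ h←_t` with learned per-unit vectors, so setting
  ω₆ = 0 yields exactly a unidirectional LSTM and the direction-reversal
  symmetry holds by construction.
- **Attention**: additive (Bahdanau-style) attention over time steps,
  toggleable off (mean pooling).
- **Loss.** One-vs-rest focal-style cross-entropy over the softmax
  outputs, `L = −t·x·(1−x′)^η log x′ − (1−x) log(1−x′)`, summed over
  classes and averaged over the batch; `t = 0.75`, `η = 2` by default
  (conventional focal-loss settings). With `t = 1, η = 0` it reduces exactly to cross-entropy.
  `t` multiplies only the positive term. The
  probability is clamped at 1e−7. Gradients flow through the full softmax
  Jacobian.
- **Batch norm** uses biased batch statistics in training (ε = 1e−5,
  momentum 0.1 for running stats) and running statistics in eval; a
  train-mode batch of one is an error, which is why training skips
  remainder batches smaller than two.
- **Training** is plain mini-batch Adam on NumPy, deterministic given the
  seed (init, shuffling and dropout all draw from one generator). An
  internal stratified validation split (15 %) tracks per-epoch accuracy;
  the best-validation parameters are restored at the end. Dropout sits
  after each pool and before the FC head.

## Transparent feature weighting

Runs post hoc over the frozen penultimate features (the attention
context): initial weights are absolute path products through the head
(`ω_x = Σ_y Σ_o |ω_xy ω_yo|`); each feature's fitness mixes validation
accuracy with an information-gain parsimony term
(`f = ω·acc + (1−ω)(1 − I_gain/tot_f)`, mix 0.5); fitness is refined for
`m_t` iterations by steps of size `η(m)·((t_u−t_l)·ϑ + t_l)` with
`η(m) = 2e^{−(4m/m_t)²}`, ϑ a logistic-map iterate (`δ′ = 4δ(1−δ)`,
seeded at 0.123, reseeded if it hits the degenerate 0.5 → 1.0 orbit), and
the step's sign taken from a masked-accuracy delta per feature (dropping a
useful feature lowers accuracy → positive sign). Features below the
(1−q)-quantile of fitness are pruned (q = 0.75, ties kept, at least one
survivor). The gradient-sign quantity, the loss hook and the run ordering were
genuinely open design points; the choices above (masking deltas for signs;
relevance-weighted per-sample loss; post-training wrapper rather than
interleaved with backprop) are this package's documented decisions.
Information gain is estimated from an equal-width 8-bin contingency table,
in bits.

## Shapley explanations

Superpixel features are contiguous rectangular patches (g×g grid,
remainders absorbed by edge patches). Coalitions are evaluated by
substituting absent patches with a background reference — the mean
training image by default, a black image optionally; no inpainting.
Exact mode enumerates all 2^M coalitions (refused above M = 16) and
satisfies local accuracy (baseline + Σφ = prediction) to 1e−9, symmetry
and the dummy axiom. Sampled mode draws random permutations (one marginal
contribution per feature per permutation; `n_samples` total draws,
≥ 10·M) and reports per-feature Monte-Carlo standard errors. Multiclass
explanations target one class's softmax probability. Overlays tint positive-φ patches pink and negative blue, alpha
proportional to |φ|/max|φ|.

## Evaluation

Confusion-matrix tallies and ROC/AUC delegate to scikit-learn (the AUC is
additionally verified against the Mann–Whitney U statistic in tests);
sensitivity/specificity/F1 come from the standard binary definitions,
macro-averaged one-vs-rest for three classes, with zero-denominator cells
reported as 0 with a warning flag. The diagnostic odds ratio
`(TP·TN)/(FP·FN)` applies the Haldane–Anscombe +0.5 correction to all
cells when an off-diagonal cell is zero, flagged. Cross-validation is
stratified k-fold at the segment level with per-fold retraining from
scratch and fold-derived seeds. (The train/test split used elsewhere is at
the *trace* level to avoid leakage between segments of one trace; the CV
protocol folds segments, trading a small amount of within-trace leakage
for per-fold class balance.)

## Scaled-down experiment sizes

The default test-time experiment uses ~200 five-second segments per class
(17 traces per class, 60 s each), 64×64 images and the reduced model; one
training takes ~20 s on a single CPU and reaches ~93 % held-out accuracy.
The imbalance experiment uses a 4:1 binary fixture (24 normal traces vs 6
abnormal, 12 epochs), the smallest size at which training reliably leaves
the all-majority solution so the loss comparison is non-degenerate. These
sizes are the package's chosen study conditions; the full-size defaults
(224×224, 128 filters, 30 epochs) remain available in `ModelConfig`.

## Known limitations

- The synthetic task is far easier than real CGM classification; results
  on this fixture are an integration check of the pipeline, not a clinical
  claim.
- The NumPy network is CPU-bound and meant for small images and datasets;
  there is no GPU path, no transfer learning, no hyperparameter search.
- Binary-mode sidecar metadata maps "abnormal" onto the nearest canonical
  label, losing the low/high distinction in saved PNG sidecars.
- The focal-loss advantage on minority recall is stochastic at these
  sizes; it is asserted as a majority vote over seeds, not per-seed.
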