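# Methods notes

This note records the modelling and numerical choices behind `lggseg`,
what the synthetic phantoms do and do not emulate, and the known
limitations. Symbols: p = pixel position (row, col), I = intensity,
x ∈ {0, 1} the per-pixel label (1 = tumor), Q the mean-field marginals.

## Pipeline model

The segmentation model is a two-stage conditional model. Stage one is
a discriminative patch classifier: P(xᵢ | 33×33 window centred at i),
trained on randomly drawn patches with a controlled tumor fraction and
evaluated densely over whole slices. Stage two is a fully connected
CRF over each slice whose unary term is the (upsampled) CNN posterior
and whose pairwise term couples every pixel pair through a bilateral
(position + intensity) and a spatial Gaussian kernel under Potts
compatibility. Morphological cleanup encodes two priors the CRF does
not: one lesion per slice (largest component) and a minimum plausible
in-plane lesion area, plus 3D continuity via a box-filter majority
vote across adjacent slices.

## Convolution padding and the dense/patch-wise contract

All 3×3 convolutions are *valid* (unpadded). The alternative — "same"
zero padding — breaks the core contract of dense inference: a patch
classifier with zero padding sees artificial zeros at its 33×33 window
border, while the same network slid over a full image sees real
neighbouring tissue, so the dense score map would not reproduce
patch-wise classification anywhere. With valid convolutions the
fully connected layers, applied convolutionally (the first as a valid
convolution over the pooled feature map, the rest as 1×1
convolutions), yield a score map whose sample (i, j) equals the patch
forward pass at centre (16+4i, 16+4j) to machine precision; the unit
tests assert this at 1e−10. The stride is 4 because of the two 2×2
max-pools; pooling uses floor division (a trailing odd row/column is
dropped), which matches the patch pipeline exactly because score
locations sit at offsets divisible by 4.

Consequences: spatial feature sizes at the fully connected stage are
5×5 (base variants) and 3×3 (deeper variants) rather than the 8×8 that
"same" padding would give, so absolute parameter counts differ from
any padded bookkeeping; counts are reported by the builder
(`PatchCNN.n_parameters`) but not asserted against external totals.

## Score-map upsampling

Dense scores are mapped back to pixel space with the Keys bicubic
convolution kernel (a = −0.5), applied separably per channel with
edge-replicated boundary taps, then clipped to [0, 1] and renormalized
so the two channels sum to 1. The `ScoreMap.origin` field records the
full-resolution coordinate of score sample (0, 0) — 16 for this
architecture family — so upsampling aligns score samples with the
patch centres they were computed at instead of assuming the map starts
at pixel 0.

## Training

- Initialization: He scheme (zero-mean Gaussian, variance 2/fan-in),
  biases zero, seeded.
- Schedule: lr(e) = lr₀ · (lr_T/lr₀)^((e−1)/(E−1)), the logarithmic
  descent from 3·10⁻³ to 3·10⁻⁵ over E = 25 epochs (defaults).
- Optimizer: mini-batch SGD with momentum 0.9. Momentum and batch size
  are not architecture constants and matter greatly in the
  small-sample regime: with batch 128 and no momentum a width-reduced
  network on 2000 patches sits at the majority-class solution for the
  whole schedule. The desk-scale experiments use batch 16, dropout
  0.25; the full-width defaults remain 128 / 0.5.
- Dropout follows each hidden fully connected layer (inverted dropout,
  disabled at evaluation), per-batch masks drawn from the training
  seed, so runs are bit-reproducible on a fixed BLAS.
- Degenerate inputs: a single-class patch set warns; a non-finite loss
  aborts with the epoch/batch/learning rate in the message.

## CRF inference

- Compatibility is the Potts indicator [xᵢ ≠ xⱼ]; the mean-field
  update for label l at pixel i adds Σ_m ω_m Σ_{j≠i} k_m(fᵢ,fⱼ) Qⱼ(l̄)
  to the unary cost and renormalizes; marginals therefore sum to 1
  after every round (asserted at 1e−9).
- **Kernel normalization.** Each kernel's message is divided by its
  per-pixel mass Σ_{j≠i} k_m(fᵢ,fⱼ) before ω_m is applied, making it a
  weighted average of neighbouring marginals. Without this the
  pairwise term scales with the slice's pixel count (thousands) while
  the unary term is bounded by −log ε ≈ 23, and inference provably
  collapses every slice to its majority label. Normalization is what
  fast Gaussian-filtering mean-field implementations effectively do,
  and it keeps the tuned weights ω ∈ [5, 10] commensurate with the
  unary scale at any image size. The raw, unnormalized update remains
  available (`normalize_kernel=False`) for study on toy grids. The
  energy E(x) and `pairwise_kernel` are reported unnormalized, exactly
  as defined.
- **Execution modes.** `dense_exact` materializes both N×N kernels
  (quadratic; refused above 100×100 px) and is the oracle. `filtered`
  computes the bilateral sum by enumerating spatial offsets over a
  truncated square window (radius ⌈3σ⌉, capped at the image extent,
  each unordered offset applied in both directions) and the spatial
  kernel by separable 1D convolution with the self-term removed. When
  the window covers the image the two modes agree to round-off; the
  acceptance tests require < 1e−6 on 8–16 px slices across the tuning
  ranges. On larger slices truncation discards only weights below
  e^{−4.5} of the peak.
- Intensities are rescaled volume-wide to [0, 255] before kernel
  evaluation, so σ_β behaves like an 8-bit gray-level bandwidth
  regardless of acquisition units.
- MAP ties (marginal exactly 0.5) resolve to background —
  deterministic and conservative.
- The CRF runs per 2D slice; 3D context enters through the fusion
  networks and the final 3D smoothing, not the graph.

## CRF parameter search

A single-pass coordinate sweep over inclusive discretized ranges
(`start:step:stop`): a random grid point is drawn from the seed, then
ω₁, σ_α, σ_β and the iteration count are scanned in that order, each
candidate evaluated with the other parameters at their incumbents and
the best retained (ties to the smaller value; candidates are scanned
in increasing order with strict-improvement updates). The evaluation
count is exactly the sum of candidate-list lengths — 27 for the
default ranges — and the incumbent's score is monotone non-decreasing
across parameters because each scan re-evaluates the incumbent
combination. One pass only; the sweep is exact for additively
separable objectives (tested against exhaustive search) and a
heuristic otherwise. The tuning objective is the unweighted mean Dice
of CRF-refined masks over the training cohort.

Kernel widths are absolute pixel quantities, so search ranges must
match the image geometry: the default σ_α range (20–70 px) suits
512×400 clinical slices where lesions span hundreds of pixels. The
desk-scale phantom study (64 px slices, lesion radii ~7–11 px)
rescales the searched ranges accordingly (σ_α ∈ {5, 15, 25}, σ_β ∈
{5, 10}, iterations ∈ {3, 7}) and likewise scales the minimum-area
threshold from 300 px to 25 px, keeping the threshold-to-lesion-area
ratio comparable.

## Phantom generator

Each phantom is an ellipsoidal "brain" of base intensity 100 on a zero
background (emulating skull-stripped input), with smooth low-frequency
texture (SD = 0.5 × noise_sd), one or more hyperintense ellipsoidal
lesions spanning ≥ 2 slices, i.i.d. Gaussian voxel noise (SD =
noise_sd, default 10), and an optional smooth ±10 % multiplicative
bias field. The lesion-minus-background gap is `contrast` × noise_sd
(background-SD units); at noise_sd = 0 the unit falls back to 1.0 so
noiseless phantoms stay separable by thresholding. Default contrast is
3 SD — an easy but non-trivial task: lesion and background histograms
overlap through the texture field, and contrast ≤ 1 makes them overlap
heavily.

What the phantoms do **not** emulate: MRI physics (no Rician noise, no
partial-volume mixing, no acquisition artefacts), anatomical context
(no ventricles, cortex or other hyperintense confounders), lesion
texture heterogeneity, or calcified subtypes. Passing the end-to-end
tests therefore demonstrates that the pipeline's machinery is correct
and that CRF refinement helps under controlled low-contrast noise — it
does not certify clinical performance.

## Desk-scale study conditions

The end-to-end experiment (`lggseg.experiments.run_phantom_study`)
fixes: 4 training + 4 test phantoms of shape (8, 64, 64); one lesion
each (semi-axes 1.5–2.5 slices, 7–11 px in-plane); base-line variant
with 8/16 filters and 64-neuron hidden fully connected layers; ≤ 2000
patches (50/slice, 40 % tumor-centred); 10 epochs; CRF tuned on the
first two training subjects with the geometry-scaled grid above. These
sizes keep the full study at minutes on one CPU while leaving the task
genuinely noisy.

## Known limitations

- The 3×3×3 box smoothing ignores the strong slice-spacing anisotropy
  (2 mm vs 0.47 mm) and is **not idempotent**: each pass further
  erodes structures only 2–3 slices thick. Only the two removal stages
  (largest component, area filter) are idempotent; the smoothing
  stabilizes only once thin structures are gone.
- The area filter is calibrated in pixels, not mm², and removes true
  lesion slices whose cross-section is genuinely small (ellipsoid
  tips) — an inherent property of the rule, visible on phantoms.
- Mean-field is a local variational scheme: no bound on the energy
  gap, and the filtered mode's truncation adds (exponentially small)
  additional approximation on large slices.
- Late fusion triples the convolutional parameters without weight
  sharing; at desk scale it is undertrained relative to early fusion
  and is exercised for contract correctness, not compared for quality.
- Dense training is CPU-bound NumPy; full-width variants (64/128
  filters, 4096-neuron layers) build and run but are not practical to
  train at clinical scale here.
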