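# lggseg

Automatic segmentation of low-grade gliomas (LGG) in T2-FLAIR brain MRI,
built as a classic two-stage pipeline: a patch-based convolutional
neural network proposes per-pixel tumor probabilities, and a fully
connected conditional random field (CRF) refines them against the image
before morphological cleanup. A seeded synthetic-phantom generator
makes the whole pipeline runnable and testable end-to-end without any
clinical data.

LGG are WHO grade I–II brain tumors. On T2-FLAIR they appear
hyperintense and fairly uniform, but their contrast against surrounding
tissue is low and their size, shape and location vary widely, which is
why a pixel classifier alone produces ragged, poorly localized borders
— and why a pairwise model over the full image helps.

## Method

**Patch CNN.** Training images are sampled into 33 × 33 patches labeled
by the class of their centre pixel, with deliberate class imbalance
(about 50 patches per slice, about 40 % of them tumor-centred) because
tumor voxels are a tiny fraction of the brain. The architecture family
has two blocks of 3 × 3 convolutions (ReLU) each followed by a 2 × 2
max-pool, then three fully connected layers ending in a 2-way softmax;
variants deepen the blocks (2 → 3 convolutions) and/or widen the hidden
fully connected layers (256 → 4096). Three-slice context (z−1, z, z+1)
can be fused either *early* (as input channels of one pathway) or
*late* (three independent convolutional pathways concatenated before
the fully connected layers). Training uses He ("improved Xavier")
initialization, dropout after each hidden fully connected layer, and
mini-batch SGD for 25 epochs with a log-spaced learning-rate schedule
from 3·10⁻³ to 3·10⁻⁵. At test time the fully connected layers are
applied convolutionally, so a whole slice is scored in one pass at
spatial stride 4 (the two pools), and the score map is upsampled back
to full resolution with the bicubic convolution kernel. The CNN is
implemented in NumPy, including training; no deep-learning framework is
required.

**Fully connected CRF.** With unary potentials θᵤ(xᵢ) = −log P(xᵢ)
from the CNN and Potts pairwise potentials weighted by two Gaussian
kernels —

θₚ(xᵢ, xⱼ) = [xᵢ ≠ xⱼ] · ( ω₁ exp(−|pᵢ−pⱼ|²/2σ²_α − |Iᵢ−Iⱼ|²/2σ²_β)
\+ ω₂ exp(−|pᵢ−pⱼ|²/2σ²_γ) )

— the energy E(x) = Σᵢ θᵤ(xᵢ) + Σ_{i≠j} θₚ(xᵢ, xⱼ) is minimized
approximately by mean-field inference. The package ships both an exact
O(N²) dense implementation (the oracle) and a fast truncated-window
filtered implementation that matches it to 1 × 10⁻⁶ whenever the
window covers the image. The four free parameters (ω₁, σ_α, σ_β, and
the iteration count; ω₂ and σ_γ are held fixed at 5) are tuned by a
single-pass coordinate sweep over discretized ranges — 5:5:10,
20:5:70, 3:1:10, 5:1:10, i.e. (2, 11, 8, 6) candidates and exactly 27
objective evaluations — maximizing mean Dice over the training cohort.

**Postprocessing and metrics.** Per slice, only the largest 8-connected
component is kept and discarded unless strictly larger than 300 px;
the stacked mask is then smoothed with a 3 × 3 × 3 box filter
rebinarized at 0.5. Results are scored per case in 3D by DSC
= 2TP/(FP+2TP+FN), PPV = TP/(TP+FP) and sensitivity = TP/(TP+FN).

## Worked example

The end-to-end study on synthetic phantoms (4 training + 4 test
subjects, volumes 8 × 64 × 64, one hyperintense ellipsoidal lesion per
subject at 3 noise-SDs of contrast; a width-reduced base-line network
with 8/16 filters trained on ≤ 2000 patches for 10 epochs):

```python
>>> from lggseg.experiments import run_phantom_study
>>> res = run_phantom_study(seed=42, verbose=True)
trained: final loss 0.0371, error 0.0138
tuned CRF params: CRFParams(omega1=10.0, omega2=5.0, sigma_alpha=5.0,
                            sigma_beta=5.0, sigma_gamma=5.0, iterations=7)
>>> [round(d, 3) for d in res.raw_dsc], round(res.raw_mean, 3)
([0.884, 0.853, 0.63, 0.616], 0.746)
>>> [round(d, 3) for d in res.refined_dsc], round(res.refined_mean, 3)
([0.838, 0.916, 0.772, 0.703], 0.808)
```

The raw CNN mask (thresholded, upsampled scores) reaches a mean test
Dice of 0.746; CRF refinement with parameters tuned on the training
phantoms, followed by the morphology stage, lifts it to 0.808 — the
qualitative behaviour the pipeline is built around: the CRF trades a
little overlap on already-clean cases for large gains on noisy,
over-segmented ones. Runs in a few minutes on one CPU.

The same stages are available from the shell:

```sh
lggseg simulate --config config.yaml --out cohort/
lggseg train    --config config.yaml --cohort cohort/ --out model/
lggseg tune-crf --config config.yaml --cohort cohort/ --model model/ --out tuned/
lggseg segment  --config config.yaml --model model/ \
                --volume cohort/test/phantom-004.nii.gz \
                --crf-params tuned/crf_params.json --out seg/
lggseg evaluate --pred seg/phantom-004_seg.nii.gz \
                --truth cohort/test/phantom-004_mask.nii.gz --out metrics/
```

## Limitations

The phantoms emulate geometry, contrast and noise — not MRI physics;
skull stripping and bias-field correction are assumed done upstream.
See `docs/methods.md` for modelling choices, parameter meanings and
known limitations.
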