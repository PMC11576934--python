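# Methods

This note records the model, the concrete realizations chosen where the
design was genuinely open, the synthetic-data assumptions, and the numerical
conventions. It states nothing the tests or `scripts/acceptance.py` do not
themselves compute.

## Network

Each of the three per-plane networks is a UNet-type 2D F-CNN operating on
multi-slice stacks (default thickness 7, fed as input channels). The layout:

```
[T1-CDB*  T2-CDB*] -> fusion -> interp(native -> base) ->
encoder CDBs with 2x2 max-pool (x4) -> bottleneck CDB ->
decoder CDBs with index-preserving unpool + maxout skip (x4) ->
interp(base -> native) -> output CDB(concat with input skip) -> 1x1 classifier
```

- **Competitive dense block (CDB).** Four sequences of PReLU → 3×3
  convolution → batch normalization. After every sequence the output
  competes (elementwise maximum) with the running representation whenever
  channel counts agree; the first convolution of a block may change the
  channel count, in which case no maxout is applied there. In the
  modality-specific input blocks and the second encoder block the first
  PReLU is replaced by a BN over the raw inputs (`input_variant`).
- **Channel widths.** The first and last scale level use the `outer` width,
  all inner scales the `inner` width. Widened hetero-modal configuration:
  80 inner / 64 outer; narrow single-modality baseline: 64 inner / 32 outer.
- **Skip connections.** Decoder blocks fuse the unpooled features with the
  encoder skip by elementwise maximum (channel counts match, no extra
  parameters). The *output* block is the exception: the decoder features
  interpolated back to native resolution (inner width) and the input-block
  skip (outer width) have different channel counts, so they are
  concatenated, and the output block maps `inner+outer -> inner` channels;
  the 1×1 classifier maps `inner -> n_classes`. With four convolutions per
  CDB this realization reproduces the published parameter budgets of the
  two configurations above (2.58 M and 1.51 M as recomputed by
  `scripts/acceptance.py`), which is how the wiring was fixed among the
  alternatives the architecture description leaves open.
- **Fusion.** Two global scalar weights, initialized at 0.5, absolute values
  taken at use time (sign flips during optimization are harmless). Absent
  modality ⇒ exact passthrough of the present branch, with zero gradient to
  the fusion weights.
- **Resolution-normalization.** Bilinear interpolation with half-pixel
  (align-corners-false) coordinates, target size `round(H·s)` with
  `s = (native/base)·jitter`. Downscaling is not injective on integer grid
  sizes (pigeonhole), so the op records the source grid size and the
  `to_native` direction restores it exactly — the same convention as
  interpolating to the skip tensor's size. With `s = 1` the operator is the
  exact identity.
- **Pooling.** 2×2 max-pool, stride 2, floor on odd sizes; the decoder
  unpools to the recorded pre-pool shape using the stored argmax indices.
- **Classifier.** 1×1 convolution, no activation; softmax at inference.
  Class axis = background + LUT order (lateral-merged LUT for sagittal).

The whole stack (conv via im2col + BLAS, BN, PReLU, maxout, pool/unpool,
bilinear resize as an explicit separable linear operator, AdamW) is
implemented in numpy with hand-written backward passes, verified against
finite differences in the test suite.

## Training

- **Loss.** Median-frequency-weighted cross-entropy plus soft Dice, summed
  with equal weight. Class weights: `w_c = median(f)/f_c` over classes with
  nonzero frequency. The soft-Dice term uses the squared-denominator form
  `(2·Σpg + ε)/(Σp² + Σg² + ε)`, ε = 1e-6, averaged over foreground
  classes: self-agreement is exactly 1 and a class absent from both
  prediction and target contributes no penalty.
- **Optimizer.** AdamW; decoupled weight decay (1e-4) applied to convolution
  kernels only (biases, BN affine terms, PReLU slopes and fusion weights are
  not decayed). Full-scale schedule: lr 0.05 → 0.005 after 70 of 100
  epochs, batch size 16.
- **Modality dropout.** Per training example, uniform over {T1+T2, T1-only,
  T2-only} from epoch 10 onwards; before that, always both. Within a batch,
  examples sharing a mode run as one sub-batch and gradients are combined
  with their batch fractions, preserving per-example semantics.
- **Augmentations.** Random affine (translation ±15 mm, rotation ±10° per
  axis, uniform scale 0.85–1.15), applied identically to all modalities and
  nearest-neighbour to labels; multiplicative bias field `exp(P(x))` with an
  order-3 polynomial over [-1,1]³ coordinates and coefficients U(-0.5, 0.5);
  external scale augmentation resamples volumes to a sampled voxel size;
  internal scale jitter multiplies the resolution-normalization factor by
  U(0.85, 1.15), drawn once per batch.
- **Randomness.** One master seed spawns independent named streams
  (dropout, scale, shuffle, plus per-phantom streams in the generator), so a
  run is bit-reproducible on one CPU thread from (seed, config, dataset).

## Inference

Per plane the network emits softmax probabilities per slice at native
resolution. Sagittal expansion *copies* the merged probability to both
lateral classes (per-voxel sums may exceed 1); renormalization happens once,
inside view aggregation, so the fixed 0.4/0.4/0.2 weights keep their
semantics. Argmax ties break towards the lowest class index (background
first, then LUT order). Structure volumes are plain voxel counts × voxel
volume; no partial-volume compensation. Working-resolution inference
(`--work-res`) resamples the images, predicts, trilinearly upsamples the
*soft* probabilities to the native grid, renormalizes and only then takes
hard labels. T2-only inference is allowed but emits a warning, being the
weakest input mode in our own phantom experiments as well.

## Conform and I/O

Volumes are reoriented to a fixed (L, I, A) axis order (sagittal/axial/
coronal = array axes 0/1/2) and image intensities are clipped to the
[0.1, 99.9] percentile window and mapped to [0, 1]; a volume already inside
[0, 1] passes through unchanged, making conform exactly idempotent; constant
volumes map to zero. Label volumes are reoriented only. NIfTI affines with
shear above 1e-3 are refused; nibabel's sform-over-qform preference applies.
The multi-slice count (7) and this normalization are package choices — the
underlying method description does not pin them down.

## Metrics

- Dice and VS on binary masks; both-empty pairs are defined as 1,
  empty-vs-nonempty as 0. `Dice ≤ VS` holds for every pair.
- HD95 uses the border voxels of each mask (6-connectivity erosion
  difference), Euclidean distances in mm with anisotropic voxel sizes, the
  95th percentile with linear interpolation between order statistics, and
  the symmetric max of the two directed values. Empty masks raise an
  undefined-metric error rather than returning 0. The same border and
  percentile conventions are used by the brute-force oracle in the tests, so
  the equivalence check is exact (1e-9 mm).
- ICC(A,1) from the two-way ANOVA mean squares (McGraw & Wong), CI from the
  standard F-based interval; degenerate (zero-variance) tables are flagged.
  The implementation matches pingouin's ICC(A,1) row to 1e-6 in the tests.
- Region/global aggregates are unweighted means over structures present in
  at least one of the two maps; absent-in-both structures are flagged and
  excluded.
- Paired comparisons use the two-sided Wilcoxon signed-rank test
  (exact/normal per scipy) with Bonferroni correction; all-zero differences
  are flagged degenerate instead of significant.

## Phantoms

The generator emulates exactly the statistics the method relies on: two
co-registered channels with partially inverted contrast (ventricle dark on
pseudo-T1, bright on pseudo-T2), a shared smooth texture added to one
channel and subtracted from the other (negative within-structure
correlation, the signal the fusion module can exploit), i.i.d. Gaussian
noise (σ = 0.03 by default), optional smooth multiplicative bias, mirrored
lateral pairs, and scenes defined continuously in mm so the *same* scene can
be rasterized at several voxel sizes (0.8 and 1.0 mm in the tests) with
physically consistent volumes. It does **not** model MRI physics (no
k-space, sequences, partial volume at interfaces, motion or defacing
artefacts), head anatomy or population variability, so passing phantom tests
demonstrates the mechanics of the pipeline — hetero-modality, resolution
independence, metric correctness — not clinical-grade accuracy on real MRI.

## Scaled-down study sizes

Full-scale training (100 epochs, GPU cohorts) is out of scope. The
end-to-end experiments use a fixed toy protocol chosen a priori: 8 training
phantoms and 4 held-out scenes at 32³ / 0.8 mm, coronal plane only, 16
inner / 8 outer channels, 20 epochs, batch 16, AdamW lr 0.01 → 0.001 at
epoch 14 (the full-scale 0.05 is a large-batch GPU setting; a ten-fold
smaller rate is the standard choice at this batch/model size), modality
dropout from epoch 10, everything seeded. Under these conditions held-out
mean foreground Dice is ≈0.99 for T1+T2 and T1-only input, ≈0.91 for
T2-only, and the 0.8 mm-trained model loses <0.01 Dice at 1.0 mm — the
qualitative pattern (T1 carries the task, T2 alone is weakest,
resolution-normalization generalizes across voxel sizes) matching the
full-scale findings the method was designed around.

## Known limitations

- Training is CPU-bound numpy; full-resolution cohort training is not the
  target use.
- Volumes are raw voxel counts (no partial-volume compensation, no eTIV).
- T2→T1 registration, defacing robustness and QC outlier detection are out
  of scope; inputs must be co-registered.
- BN statistics during the fusion-weight warm-up follow ordinary train-mode
  batches; no special freezing is applied.
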