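# hypoparc

Hetero-modal, voxel-size-independent 2.5D segmentation of the hypothalamus
and adjacent structures from brain MRI, with a synthetic phantom generator
and a full accuracy/reliability metric suite.

## The problem

The hypothalamus is a small diencephalic region whose sub-unit volumes
(anterior / middle / posterior sub-regions, plus adjacent structures such as
the fornix, optic system, hypophysis and epiphysis — 24 labels in total) are
of wide interest in population neuroimaging. Two practical obstacles get in
the way of automated sub-segmentation:

1. **Missing modalities.** Pipelines that require a fixed input combination
   (say, T1w *and* T2w) cannot process the many subjects for whom only a T1w
   scan exists.
2. **Voxel-size mismatch.** A CNN trained at one isotropic resolution
   (e.g. 0.8 mm) degrades badly on scans acquired at another (e.g. 1.0 mm).

`hypoparc` implements a single model that addresses both: a UNet-type 2D
F-CNN of competitive dense blocks (CDBs) applied in 2.5D fashion (one
network per anatomical plane, with multi-slice input, ensembled by a
weighted view average of 0.4 axial / 0.4 coronal / 0.2 sagittal), extended
with

- a **fusion module**: each modality passes through its own first encoder
  CDB, and the feature maps are merged by a normalized learnable weighted sum

  ```
  F_fused = |W_T1| / (|W_T1| + |W_T2|) · F_T1  +  |W_T2| / (|W_T1| + |W_T2|) · F_T2
  ```

  with both scalar weights initialized at 0.5. Zeroing one weight makes the
  fused features *exactly* equal to the remaining branch, which is how a
  missing modality is handled at inference — the model is hetero-modal:
  T1-only, T2-only and T1+T2 inputs all work. During training, **modality
  dropout** (uniform over the three input combinations, per example, after a
  10-epoch warm-up) teaches the network all three modes.

- **network-integrated resolution-normalization**: the first and last scale
  transitions bilinearly interpolate feature maps between the native
  in-plane voxel size and a fixed internal base resolution (1.0 mm), so the
  inner network always operates at one scale while segmentation is emitted
  at the native grid. Internal scale jitter of this transition acts as an
  augmentation.

Because lateralization cannot be seen in sagittal slices, the sagittal
network predicts lateral-merged classes (24 → 15) and its probabilities are
copied back to both lateral descendants before view aggregation.

Training uses a median-frequency-weighted cross-entropy plus soft-Dice loss,
AdamW (weight decay 1e-4), a step schedule (lr 0.05 → 0.005 after 70 of 100
epochs at full scale), and affine / bias-field / external-scale
augmentations. The evaluation suite provides Dice, volume similarity (VS),
the 95th-percentile Hausdorff distance (HD95, in mm, anisotropy-aware),
two-way absolute-agreement single-measure intraclass correlation ICC(A,1)
with F-based confidence intervals, and paired Wilcoxon signed-rank tests
with Bonferroni correction.

Everything — network layers, backprop, AdamW — is implemented in numpy, so
the package runs anywhere scientific Python runs; runtimes are sized for
desk-scale phantom studies, not GPU-scale cohorts.

## Synthetic phantoms

There is no public annotated MRI for this task, so the package ships a
generator of co-registered pseudo-T1/T2 phantom pairs with ground-truth
labels. Scenes are defined *continuously* in millimetres (ellipsoids and
capsule tubes: a midline ventricle, mirrored lateral pairs, tube-like
"optic" structures) and rasterized at any voxel size, with partially
inverted contrast between the channels, shared anti-correlated texture,
Gaussian noise and an optional polynomial bias field. A 6-label toy scene
supports minutes-scale training; a 24-label scene exercises the full lookup
table.

## Worked example

```bash
hypoparc simulate --n 4 --res 0.8 --scene toy --seed 7 --out data
hypoparc train    --data data --out ckpt --plane coronal --epochs 12 --inner 16 --outer 8 --seed 0
hypoparc predict  --t1 data/phantom003_t1.nii.gz --t2 data/phantom003_t2.nii.gz \
                  --ckpt-dir ckpt --lut data/lut.txt --out seg
hypoparc evaluate --pred seg/segmentation.nii.gz --ref data/phantom003_labels.nii.gz \
                  --lut data/lut.txt --out report
```

`seg/volumes.csv` then holds voxel-count volume estimates (voxel count ×
voxel volume in mm³):

```
label_id,name,region,voxel_count,volume_mm3
1,Ventricle,others,397,203.264009086609
2,L-Nucleus,hypothalamic-middle,328,167.93600750732432
...
```

and `report/metrics.csv` the per-structure and aggregate similarity scores
against the ground truth, e.g.

```
 label_id        name     dice       vs  hd95_mm
        1   Ventricle 0.901798 0.901798 0.800000
        4 L-Optic-tube 0.981752 0.985401 0.400000
       -1       global 0.874618 0.879385 0.902411
```

(Dice/VS near 1 and HD95 below one voxel indicate close agreement; this is
a 12-epoch demonstration model.) A fuller experiment — 20 epochs on 8
phantoms, 4 held out — reaches a mean foreground Dice of **0.99 with T1+T2
input, 0.99 with T1 only and 0.91 with T2 only**, and loses less than 0.01
Dice when the same scenes are segmented at 1.0 mm instead of the 0.8 mm
training resolution (these runs are executed by `tests/test_acceptance.py`).

Omitting `--t2` runs the T1-only path; `--mode` forces a specific input
combination; `--work-res` runs the network at a chosen working resolution
and trilinearly upsamples the *soft* labels back to the native grid before
taking the argmax (hard labels are never interpolated).

## Layout

- `src/hypoparc/lut_io.py` — NIfTI I/O, conform (canonical LIA-like axes,
  robust intensity rescaling), lookup tables, lateral-label merging, 2.5D
  slice stacks
- `src/hypoparc/network/` — layers with hand-written backprop, fusion
  module, resolution-normalization, CDBs, the F-CNN, checkpoints
- `src/hypoparc/train_engine.py` — losses, class weights, augmentations,
  modality dropout, AdamW, the training loop
- `src/hypoparc/infer_engine.py` — per-plane prediction, sagittal unmerge,
  view aggregation, volume reports, working-resolution inference
- `src/hypoparc/seg_metrics.py` — Dice / VS / HD95 / ICC(A,1) / paired tests
- `src/hypoparc/phantom.py` — continuous-scene phantom generator
- `src/hypoparc/cli.py` — `hypoparc simulate|train|predict|evaluate`

See `docs/methods.md` for the modelling choices and their rationale.
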