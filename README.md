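# histossm

Binary classification of H&E histopathology tiles (normal vs. abnormal)
with an encoder–decoder network whose blocks fuse a depthwise-separable
convolution *local* branch with a bidirectional linear state-space
(*scan*) global branch. An entropy-based uncertainty map computed at the
encoder bottleneck modulates the fusion weights in the decoder, and an
auxiliary calibration loss (1 − Pearson correlation between the
uncertainty map and the per-position classification-error map) is added
to class-weighted, label-smoothed cross-entropy.

The package ships with:

- **Macenko stain standardization** (`histossm.stain_norm`) — optical
  density decomposition, stain-vector estimation from the principal
  plane of the OD cloud, concentration scaling to a target profile.
- **Synthetic H&E tile simulator** (`histossm.synthetic_data`) —
  Beer–Lambert rendering of hematoxylin/eosin concentration canvases
  with class-dependent morphology (regular gland rings vs. pleomorphic
  clusters), per-patient stain jitter, and patient grouping; the full
  pipeline is buildable and testable with no external data.
- **Patient-independent data handling** (`histossm.data_pipeline`) —
  whole-patient 70/15/15 splitting, minority oversampling, and
  training-time augmentation (crop, flips, rotation, Gaussian noise).
- **NumPy autograd core** (`histossm.autograd`) — a small reverse-mode
  engine with numba-accelerated state-space scan kernels; no deep
  learning framework is required.
- **Training harness** (`histossm.harness`) — AdamW, cosine annealing
  with linear warm-up, early stopping on validation F1, ablation
  variants, checkpointing.

## CLI

```bash
# synthetic cohort (PNG tiles + manifest.csv)
histossm generate-data --out-dir cohort --n-patients 40 \
    --tiles-per-patient 10 --tile-size 64 --seed 0

# Macenko standardization of a tile directory
histossm normalize-stains --input-dir cohort --output-dir cohort_norm

# train / evaluate (desk-scale profile; --variant 1..5 for ablations)
histossm train --data-dir cohort --desk --seed 0 --checkpoint model.npz
histossm evaluate --checkpoint model.npz --data-dir cohort --subset test

# ablation table over variants and seeds
histossm ablate --data-dir cohort --variants 1,5 --seeds 0,1,2
```

Model and training options can also be given as YAML (`--config`), with
`model:`, `train:`, and `augment:` sections mirroring the
`ModelConfig`, `TrainConfig`, and `AugmentParams` dataclasses. The
documented full-scale defaults are 224×224 tiles, 64 base channels,
AdamW at 1e-4 with 5 warm-up epochs, batch 32, 100 epochs; the
`--desk` profile shrinks everything to single-CPU scale.

## Ablation variants

1. full model; 2. fixed decoder fusion weight 0.5 (no uncertainty
modulation); 3. scan-only blocks (no local convolution branch); 4. no
skip connections; 5. variants 2+3 combined.

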