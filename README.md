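# ribseg

Segmentation and detection of thin, small-area lesions (rib-fracture-like
cracks) in 2D CT slices.  The model is a residual-encoder U-net with two
optional modules:

* **HDDC bottleneck** — parallel cascades of 3×3 dilated convolutions
  (default rates 1/3/5) tapped through 1×1 projections and superimposed,
  enlarging the deepest receptive field without striding;
* **CAM skip fusion** — per-channel average pooling of skip and decoder
  features along height and width, a shared C→C/r bottleneck transform,
  and per-row/per-column sigmoid gates applied to the skip features before
  addition to the decoder features.

Training minimizes a compound loss `(1−θ)·BCE − θ·log(Dice)` (default
θ = 0.2) with momentum SGD (0.9 momentum, 5e-4 weight decay).  Evaluation
is lesion-level: probability map → threshold → connected components →
bounding boxes → greedy matching to ground-truth components, giving
TP/FP/FN, precision/recall/F1, plus aggregate pixel Dice.

Everything runs on CPU: the network and optimizer are implemented on a
small NumPy reverse-mode autodiff engine (`ribseg.nn`), and all learning
tests run on seeded synthetic rib phantoms — no data download required.

## Library overview

| module | contents |
| --- | --- |
| `ribseg.io_preprocess` | `WindowSpec`, `apply_window` (HU→[0,1]), `extract_slices` (slice filter: ≥100 annotated pixels), manifest read/write |
| `ribseg.synthetic_phantom` | seeded rib phantoms: bright elliptical rib ring, thin dark crack lesions, off-ring distractors |
| `ribseg.network` | `ModelConfig`, `CamFuse`, `Hddc`, `CompositeResUNet`, `receptive_field` |
| `ribseg.objective_metrics` | `cross_entropy_loss`, `dice_coeff`, `compound_loss`, `detection_metrics` |
| `ribseg.postprocess` | `binarize`, `mask_to_boxes`, `merge_boxes`, `match_to_truth`, overlays |
| `ribseg.training` | `TrainConfig`, `train`, `evaluate_model`, `run_ablation`, checkpoints |
| `ribseg.nn` | NumPy autodiff: conv2d (stride/dilation), transposed conv, maxpool, batchnorm, SGD |

## CLI

```bash
ribseg phantom --n 200 --out data/phantoms --seed 0 --image-size 64
ribseg preprocess --image case.nii.gz --mask case_label.nii.gz --out data/case
ribseg train --manifest data/phantoms --epochs 5 --learning-rate 0.1 \
             --checkpoint model.npz --log-csv history.csv
ribseg evaluate --checkpoint model.npz --manifest data/phantoms \
                --per-image-csv per_image.csv
ribseg ablate --manifest data/phantoms --seeds 0,1,2 --out ablation.csv
ribseg predict --checkpoint model.npz --image slice.png --out preds/
```

Configs are YAML (`TrainConfig.to_yaml` / `--config`); CLI flags override
config keys.  Ablation switches (`use_hddc`, `use_cam`) and the θ sweep
are plain config fields, so the variant grids are reproducible one-liners.

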