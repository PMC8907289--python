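# duograde

An asymmetric dual-encoding-path 3-D convolutional network for binary tumor
grading from paired, co-registered MR volumes (contrast-enhanced T1 and
T2-FLAIR), together with everything needed to exercise it without clinical
data: a synthetic two-channel phantom generator, the preprocessing chain,
a leakage-free k-fold cross-validation harness, and the evaluation
statistics (confusion metrics with Grade II positive, ROC/AUC, per-fold
ranges, location-stratified accuracy, and the tumor-volume ratio
R = V_T1CE / V_T2FLAIR).

The network is implemented in pure NumPy (im2col convolutions, hand-written
backward passes, Adam) so the package runs on a single CPU with no deep
learning framework.

## Modules

| module | contents |
| --- | --- |
| `duograde.phantom` | `PhantomConfig`, `Subject`, truncated-normal R sampling, two-channel subject/cohort generation with a planted grade signal and a volume-ratio confound |
| `duograde.imgio` | `Volume3D`/`RoiTensor`, NIfTI I/O, resampling (to reference grid / isotropic), mask volumes, R ratio, centroid ROI cropping, z-score normalization |
| `duograde.netspec` | `NetConfig`/`LayerSpec`, per-level filter allocation (18:2 vs 10:10), network unrolling with shape checks, Glorot truncated-normal init, deterministic `predict` |
| `duograde.network` | the NumPy layer engine (Conv3D, ReLU, Dropout, MaxPool3D, Dense, softmax/cross-entropy, Adam) |
| `duograde.train` | `TrainConfig`, fold construction (each subject tested exactly once), rotation augmentation, `train_fold`, `cross_validate` |
| `duograde.evaluation` | confusion counts, accuracy/sensitivity/specificity, ROC + trapezoidal AUC, fold ranges, stratified accuracy, misclassified-R summary, comparison tables |
| `duograde.cli` | `generate`, `preprocess`, `run`, `report`, `compare` subcommands |

## CLI

```bash
# 96-subject synthetic cohort (55 Grade I / 41 Grade II) with NIfTI + manifest
duograde generate --n 96 --grade1 55 --grade2 41 --seed 7 --out cohort/

# preprocess to fixed-shape two-channel ROIs
duograde preprocess --manifest cohort/manifest.csv --out rois/ --shape 64

# cross-validate the five model variants (desk-scale example)
duograde run --manifest cohort/manifest.csv --out results/ \
    --variants acr,scr,tc_ab,tc_a,tc_b --k 10 --epochs 50 \
    --shape 32 --levels 2 --fc 64,16,2

# recompute all metrics from prediction CSVs alone
duograde report results/acr_predictions.csv --out report.json
duograde compare results/*_predictions.csv
```

Variants: `acr` = asymmetric dual path (18:2 filters), `scr` = symmetric dual
path (10:10), `tc_ab`/`tc_a`/`tc_b` = single path on both / T1-CE-only /
FLAIR-only channels.

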