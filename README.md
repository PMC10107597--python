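# tsdnet

A stereo spatial screening classifier for small 2-D image collections,
implemented in pure numpy on a minimal reverse-mode autodiff core.

The model scores a shallow convolutional feature map from three
directions (horizontal, vertical, depth), normalizes each score array
along its direction's axis and rescales it to [0, 1]. The resulting
weight maps drive two hard screening stages:

* **Cross feature screening** — directional weights are combined in
  pairs, cross-averaged per branch, and compared to two gate thresholds
  (`t1`, `t2`). Every feature point is classified as important,
  secondary or redundant via 0-1 masks that partition the map exactly;
  gated copies of the feature map are concatenated into three level
  features `f1`/`f2`/`f3`.
* **Semantic-guided decoupling** — the elementwise Euclidean norm of the
  three weight maps (bounded by √3) is thresholded at `t1` and `t3` to
  screen the shallow map and a deep map derived from the secondary
  features.

A fusion head adds the projected important/redundant/shallow-screened
streams, concatenates them with the deep-screened stream along a
sequence axis, and classifies with a 1-D convolution, an affine map and
softmax. Gate masks are constants during backpropagation: eliminated
positions contribute exactly zero downstream and pass no gradient.

Evaluation uses overall accuracy (OA), average per-class recall (AA)
and two kappa variants — the literal published count-based formula
(`printed`) and standard Cohen's kappa (`standard`).

## CLI

```bash
# generate a seeded synthetic dataset (blob-count / texture-frequency / ring-lesion)
tsdnet synth --out data --classes 3 --per-class 50 --size 64 --seed 0

# add a stratified 7:1:2 train/val/test split column to labels.csv
tsdnet split --data data --ratios 7,1,2 --seed 0

# train from a YAML run config; writes checkpoint, logs, metrics
tsdnet train --config run.yaml --data data

# evaluate a checkpoint on a split
tsdnet eval --run runs/default --data data --split test --out results

# threshold-grid and feature-knockout ablations (default grid: the six
# published triples)
tsdnet ablate --config run.yaml --data data --knockouts f_3 --out ablation.csv

# nine-tile attention heatmap panel + CSV grids for one image
tsdnet viz --run runs/default --image data/images/class0_00000.png \
    --out panel.png --csv-dir grids
```

A run config looks like:

```yaml
model:
  image_size: 64
  backbone_widths: [8, 16, 32]
  d_fuse: 64
  n_classes: 3
  thresholds: {t1: 0.5, t2: 0.3, t3: 0.5}
  seed: 0
optimizer: adam
learning_rate: 0.0001
batch_size: 16
epochs: 30
seed: 0
out_dir: runs/default
```

## Acceptance

The binding acceptance criteria are property-based and live in
`tests/test_acceptance.py` (exact mask partition/reconstruction, loop
oracle equivalence for both screening chains, softmax contracts,
threshold monotonicity, metric fidelity, seeded learning sanity on the
reduced 64×64 model, the ablation harness, and byte-exact end-to-end
reproducibility). The report script runs a fast self-check and writes
the (empty) numeric-target object:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/tsdnet/
  autograd.py    reverse-mode autodiff on numpy arrays
  layers.py      Dense / Conv2D / Conv1D and Adam
  attention.py   tri-directional attention weights
  screening.py   dual-gate cross feature screening
  decoupling.py  combined-magnitude screening
  fusion.py      fusion head and the end-to-end model
  metrics.py     OA / AA / kappa (printed + standard)
  synthetic.py   seeded synthetic datasets and the 7:1:2 split
  train.py       training/evaluation loops, run artifacts
  viz.py         nine-tile attention heatmap panel
  cli.py         tsdnet synth/split/train/eval/ablate/viz
```
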