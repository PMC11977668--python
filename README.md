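# sparsemil

Sparse-attention deep multiple-instance learning (MIL) for classifying
megapixel microscopy images from image-level labels only.

## The problem

Histopathology images shot through a microscope eyepiece (e.g. with a
smartphone adapter) are megapixel-scale, carry only an image-level
normal/abnormal label, and show a bright circular tissue field on a dark
surround.  Training a CNN on the full image is infeasible and patch-level
labels do not exist.  MIL resolves this: each image is a **bag**, its
equal-sized non-overlapping patches are **instances**, and a bag is
positive iff at least one instance is positive.

## The method

A small shared CNN encoder (*Subnet 1*, five same-padded conv stages with
global average pooling, 245,792 parameters) maps every patch to a
128-vector.  A dense head (*Subnet 2*, 33,281 parameters) scores either
each instance (IMIL) or the aggregated embedding (EMIL).  Aggregation is
max pooling or attention pooling: a two-layer attention module turns each
embedding into a logit `v_i`, and a probability transform turns the logit
vector into attention weights.

The softmax `softmax(v)_i = exp(v_i) / Σ_j exp(v_j)` keeps every instance
strictly positive.  The **sparsemax**

    sparsemax(v)_i = max(v_i − τ(v), 0)

is the Euclidean projection of `v` onto the probability simplex: instances
below the threshold `τ(v)` receive *exactly zero* attention and are
discarded.  Two penalties sharpen the attention distribution `a`:

    R_L0  = λ_L0 · #{i : a_i ≠ 0}         (support-size penalty)
    R_mer = λ_mer · Σ_i a_i log a_i        (entropy penalty)

and the training objective is

    Loss_reg = Loss_no_reg + R_L0 + R_mer

with `Loss_no_reg` a reverse-class-weighted binary cross-entropy on the
bag probability.  Five variants are assembled: `EMIL_A`, `EMIL_M`,
`IMIL_A`, `IMIL_M` (max-pool variants: 279,073 parameters; softmax
attention variants: 312,354) and `IMIL_SA` (sparsemax attention, same
topology as `IMIL_A`).

The networks and their backpropagation are implemented in a compact NumPy
core (`sparsemil.nn`); a seeded synthetic-bag generator renders
histopathology-like images with known per-patch ground truth so that the
whole pipeline is testable without any data download.

## Worked example

```python
import numpy as np
from sparsemil import assemble_model, count_parameters, sparsemax_transform, softmax_transform

print(count_parameters(assemble_model("IMIL_SA", 86)))   # 312354
print(count_parameters(assemble_model("IMIL_M", 86)))    # 279073

v = np.array([1.6, 1.1, 0.2, -0.4])
print(np.round(softmax_transform(v), 4))                 # [0.5029 0.305  0.124  0.0681]
res = sparsemax_transform(v)
print(res.probabilities, res.support_size)               # [0.75 0.25 0.   0.  ] 2
```

The softmax spreads attention over all four instances; the sparsemax
assigns exact zeros to the two weakest, which is the mechanism the IMIL_SA
variant uses to discard non-informative patches.

Train on a synthetic cohort from the command line:

```sh
sparsemil generate --n-images 120 --seed 1 --out data/
sparsemil train --manifest data/manifest.csv --variant IMIL_SA \
    --patch-side 86 --lr 0.005 --lambda-l0 0.005 --lambda-mer 0.005 \
    --mer-sign -1 --epochs 15 --seed 1 --out runs/imil_sa
sparsemil evaluate --manifest data/manifest.csv \
    --checkpoint runs/imil_sa/checkpoint --split test --out runs/imil_sa/eval
sparsemil params IMIL_SA      # 312354
```

## Layout

- `sparsemil.aggregation` — softmax/sparsemax transforms, L0/entropy penalties, pooling operators
- `sparsemil.nn` — NumPy layers (conv, pooling, dense, dropout) with backprop and SGD
- `sparsemil.models` — Subnet 1/2 and attention module; the five MIL variants; parameter counting
- `sparsemil.bags` — field-of-view crop, patch tiling, CSV manifests, patient-wise splits
- `sparsemil.synthetic` — seeded histopathology-like bag generator with per-patch truth
- `sparsemil.training` — the regularized objective, SGD loop, lr sweep, metrics
- `sparsemil.experiments` — the end-to-end synthetic study
- `sparsemil.cli` — `sparsemil generate | train | evaluate | predict | params`

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
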