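# Methods

## Model

Each image is a bag; its non-overlapping square patches (side `ps`, read
row-major from the top-left, border remainder discarded) are instances.
The standard MIL assumption applies: a bag is positive iff at least one
instance is positive.  All instances pass through a shared CNN encoder
(**Subnet 1**): conv 16×5×5 → maxpool 3×3 → conv 32×3×3 → maxpool 2×2 →
conv 64×3×3 → maxpool 2×2 → conv 128×3×3 → maxpool 2×2 → conv 128×3×3 →
global average pool.  Convolutions are same-padded with stride 1 and ReLU;
pooling is non-overlapping with floor division, so the smallest supported
patch side (the pipeline requires ≥ 32) survives all five stages; the
global average pool makes the 128-dim embedding independent of patch side.
Weight sharing across instances keeps the parameter count independent of
bag size: Subnet 1 has 245,792 parameters.

**Subnet 2** (dropout 0.5 → dense 256 ReLU → dropout 0.5 → dense 1
sigmoid; 33,281 parameters) produces a probability — per instance in
instance-based MIL (IMIL), or once on the aggregated embedding in
embedding-based MIL (EMIL).  The **attention module** (dense 256 tanh →
dense 1 sigmoid; 33,281 parameters, dropout-regularized like Subnet 2)
produces one logit per instance from the Subnet 1 embedding; softmax or
sparsemax turns the logit vector into attention weights.  Five variants:
EMIL_M / IMIL_M (max pooling, 279,073 parameters), EMIL_A / IMIL_A
(softmax attention, 312,354), IMIL_SA (sparsemax attention, same topology
and count as IMIL_A).

The final Subnet-2 dense layer has a single sigmoid unit: that is the only
width for which the totals 279,073 / 312,354 reconcile with the component
sums (245,792 + 33,024 + 257 [+ 33,281]), and a scalar bag probability is
what binary cross-entropy needs.  Input channels are 3 (RGB), likewise
forced by the first-conv count (1,216 = (5·5·3+1)·16).

The attention logit passes through a sigmoid before the probability
transform, which confines logits to (0, 1).  A logit gap of 1 — exactly the
gap at which sparsemax saturates to one-hot — is therefore reachable only
asymptotically; `attention_sigmoid=False` removes the sigmoid for
ablation.  In IMIL attention variants the attention weights multiply the
instance probabilities, not their logits.

## Objective

`Loss_reg = Loss_no_reg + R_L0 + R_mer`, where `Loss_no_reg` is binary
cross-entropy on the clipped bag probability (clip 1e-7), weighted by
reverse class weights `w_c = (n_neg + n_pos) / (2 n_c)` computed from
training-bag counts.

- `R_L0 = λ_L0 · #{i : a_i ≠ 0}` is evaluated on the **post-transform**
  attention probabilities, where the sparsemax produces exact zeros
  (pre-transform sigmoid logits are never exactly zero, so counting them
  would make the penalty constant).  The exact count is piecewise constant
  and contributes zero gradient almost everywhere; it still enters the
  loss value and model selection.  A differentiable surrogate
  `λ Σ (1 − exp(−a_i²/σ²))`, σ = 0.01, is available behind the
  `l0_smooth` flag.
- `R_mer = mer_sign · λ_mer · Σ a_i log a_i` (natural log, `0 log 0 := 0`).
  With `mer_sign = +1` (the default) the term is written exactly as the
  penalty formula reads; since `Σ a log a ≤ 0` on the simplex, minimizing
  it *raises* entropy.  `mer_sign = −1` selects the entropy-*minimizing*
  direction that the "make the attention sparser" intent suggests.  Both
  are tested; the default keeps the formula as printed and documents the
  tension rather than silently resolving it.

Sparsemax is computed by the sorted-threshold rule
`τ = (Σ_{j≤k} v_(j) − 1)/k` with `k` the largest feasible support size;
ties at the threshold are safe because the support test uses strict
inequality.  Its backward pass uses the exact Jacobian (`I − 11ᵀ/k` on the
support, zero off it).  A brute-force oracle that enumerates every
candidate support set provides the independent check in tests.

## Training protocol

Plain SGD (momentum 0, weight decay 0 — both configurable), batch size one
bag, training bags reshuffled every epoch, online augmentation by
horizontal and/or vertical flips with probability 0.5 each, 50 epochs by
default.  The learning-rate sweep facility trains one model per grid point
from identical initial weights (default grid 1e-6…5e-3, eight points) and
selects by validation ROC-AUC.  Across epochs the weights of the
best-validation-AUC epoch are kept, with ties going to the later epoch:
desk-scale validation sets are small enough that the AUC saturates and
ties are frequent, and among equally-ranked epochs the most-trained model
is the better bet (in particular its attention distribution has had the
longest to sharpen); whether one
should instead report the final epoch is undocumented in the protocol this
follows — best-validation is this package's choice and is recorded as
such.  Thresholded metrics (accuracy, recall, precision, F1) use 0.5 with
positive = abnormal; AUC uses the trapezoidal ROC integral, which equals
the normalized Mann–Whitney U with half-credit ties.  All randomness
(shuffling, flips, dropout, initialization) derives from one integer seed;
repeated runs with the same seed are bitwise identical.

## Numerical core

No deep-learning framework is used: `sparsemil.nn` implements the layers
in NumPy with hand-written backward passes.  Convolutions run as im2col
matrix products, materialized a few images at a time so the column buffer
stays cache-resident; the backward pass re-materializes the columns chunk
by chunk.  The first layer of Subnet 1 skips the gradient with respect to
its input (nothing upstream needs it).  Max-pool backward routes gradient
through every window entry equal to the maximum; exact ties essentially
occur only on post-ReLU zero plateaus, where the conv activation gradient
is zero anyway.  Parameters are float32 for speed; every layer also runs
in float64, which the finite-difference gradient tests use.  Softmax uses
max-subtraction; the logistic is evaluated in its numerically safe split
form.  Initialization is Glorot uniform.

## Synthetic data

The generator emulates the acquisition geometry at desk scale: 774-px
square images (1/16 the pixel count of the real 3096-px crops), a bright
eosin-pink tissue texture inside a circular field of view spanning the
image (radius fraction 0.5), near-black surround, per-pixel Gaussian noise
(sd 8 on the 8-bit scale), and a smooth texture field whose spatial
frequency is jittered by a 0.8–1.2 magnification factor, mimicking the
unrecorded magnification variability of eyepiece photography.  Positive
images receive 1–4 planted abnormal patches — dense clusters of
dark-purple blobs echoing hyperchromatic nuclei — confined to grid cells
inside the field of view; the per-patch truth grid is recorded.  Cohorts
default to 40 patients with 2–4 images each, positive fraction 0.747 and
patient-wise splits of fractions (0.64, 0.09, 0.27), mirroring the
1331-image study composition (846/116/369, ~3:1 abnormal:normal).  Labels
are assigned by count rounding, so a 100-image cohort at fraction 0.75 has
exactly 75 positives.

The palette and blob density are chosen so that a linear classifier on
mean patch color separates planted patches from normal ones essentially
perfectly — the task is learnable by design, which is what makes the
end-to-end acceptance run meaningful.  Deliberately *not* modelled: stain
chemistry and its variation, focus blur, tissue morphology, multi-grade
abnormality subtypes.  Passing the synthetic study therefore demonstrates
that the optimization, attention, and evaluation machinery work end to
end, not that the method reaches any particular accuracy on real tissue.

The patient-wise splitter deals patients greedily (seeded order, largest
first, empty splits served first) to the split whose running positive
fraction stays closest to the global one, subject to image-count quotas.

## Desk-scale end-to-end study

`sparsemil.experiments.run_synthetic_experiment` trains IMIL_SA
(λ_L0 = λ_mer = 0.005, the mid-grid values of the sparsity sweep,
`mer_sign = −1` so the entropy penalty promotes the localisation the
experiment measures) for 15 epochs at learning rate 0.005 on 120
synthetic bags (side 774, patch 86, 81 instances per bag — the same bag
size as the largest real patch configuration).  The 15-epoch budget and
120-bag cohort keep the run in the ten-minute range on one CPU; the
learning rate was fixed once by sweeping this scenario with the package's
own facility (0.1 diverges; 0.02–0.05 learn the ranking but oscillate too
much for the attention distribution to sharpen; 0.002 undertrains —
0.005 was the sweep's winner on both counts), since per-dataset winners
do not transfer.  Reported: held-out AUC and accuracy, and the mean
attention mass that positive held-out bags place on their planted
abnormal patches (localisation without any patch-level supervision).

Three empirical findings from this scenario shaped defaults and are worth
recording.  First, dropout on the attention path is essential, not
cosmetic: without it the attention sharpens on arbitrary early features,
the sparsemax zeroes the truly abnormal patches, and — since off-support
coordinates receive zero gradient — they can never recover; the dropout
noise keeps the support broad while the instance scorer is still
learning.  Second, SGD momentum (0.9) destabilises the bag-at-a-time
protocol here and stays off.  Third, the smooth L0 surrogate causes the
same premature support collapse as removing dropout when enabled from
epoch 0, so the default keeps the exact (gradient-free) count.
Attention localisation develops slowly, long after the bag-level ranking
is perfect: the support first stays near-full, then contracts as the
instance scores separate; the acceptance run reports the attention mass
this process reaches within the 15-epoch budget.

## Known limitations

- The exact L0 term is gradient-free; its effect enters only through the
  loss value and model selection unless the smooth surrogate is enabled.
- The attention sigmoid bounds logit gaps below 1, so sparsemax reaches
  exact one-hot attention only in the saturated limit.
- Non-divisible image sides lose the border remainder strip (the study's
  patch sides all divide 3096, so this affects only user data).
- Tissue-region segmentation, magnification estimation, stain
  normalization, and whole-slide pyramidal formats are out of scope.
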