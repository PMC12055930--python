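# Methods

## Problem setting

Semi-supervised volumetric segmentation with severe category imbalance:
a handful of densely labeled 3-D volumes, a larger pool of unlabeled
volumes, and per-category voxel counts spanning two or more orders of
magnitude (in abdominal CT, a liver can outweigh an adrenal gland by a
factor of several hundred).  Conventional co-training treats all
categories alike, so rare categories receive almost no gradient signal
and are easily destroyed by pseudo-label noise.

## Model

Two segmentation students `f_A`, `f_B` (identical topology, different
random initialisations) are trained under cross-pseudo-supervision: each
is supervised by the other's argmax pseudo-labels on the joint
labeled+unlabeled batch.  Each student has an exponential-moving-average
(EMA) teacher that produces the pseudo-labels used for augmentation.

Two per-category weight vectors steer training:

* **Distribution weight (DisW).**  From the batch pseudo-labels, per-
  category voxel counts `psi_k` give ratios `r_k = max(psi)/psi_k` and

      w_dis_k = log(r_k) / max_rho log(r_rho),

  so the rarest category gets 1 and the most frequent 0.  The vector is
  smoothed across iterations, `W_t = beta W_{t-1} + (1-beta) W_hat_t`,
  with `beta = 0.99`.

* **Confidence-difficulty weight (CDifW).**  A sliding window (length
  `tau = 50`) of per-iteration, per-category Dice scores `zeta` yields a
  population-stability-index-style statistic: log-ratios of consecutive
  scores are summed separately over non-improving (`d_u`) and improving
  (`d_l`) steps, and

      d_k = ((d_u + eps) / (d_l + eps)) ** alpha,       alpha = 0.5

  is < 1 for categories being learned, 1 for flat trajectories, > 1 for
  deteriorating ones.  The difficulty weight is `w_dif_k = (1 - zeta_k) d_k`.
  Separately, softmax confidence on labeled voxels of their own category
  is averaged per category and EMA-smoothed (`beta = 0.99`); the
  information score `s_k = (1 - c_k) / max(1 - c)` is 1 for the least
  confident category.  The combined weight is `w_cdif_k = s_k**gamma *
  w_dif_k` with `gamma = 0.2`.

Model A consumes CDifW, model B DisW; the heterogeneity of the pair is
the point.  Ablation variants (`CDifW-CDifW`, `DisW-DisW`,
`CDisW-CDisW`, `CDifW-CDisW`, where CDisW applies the information score
to DisW) are reachable through `train.weight_a` / `train.weight_b`.

* **Double-mix pseudo-label (DMP) augmentation.**  For each unlabeled
  patch, categories are sampled with replacement from the weight-induced
  distribution (one draw per category by default; background excluded
  from sampling unless configured otherwise), a binary mask marks voxels
  whose teacher pseudo-label falls in the sampled set, and the unlabeled
  content is hard-pasted onto a labeled partner patch:

      x_m = x_u . M + x_l . (1 - M),    y_m = y_pseudo . M + y_true . (1 - M).

  Two DMP operations run per iteration — pair A from CDifW and teacher
  A's pseudo-labels, pair B from DisW and teacher B's — so rare and
  difficult categories are transplanted into labeled context far more
  often than chance.  CutMix, CutOut and ClassMix are provided as
  unweighted baselines (`dmp.baseline`).

* **Losses.**  With `L_s = L_Dice + 0.5 L_CE` (weighted soft Dice,
  normalised by the weight sum; weighted cross-entropy, per-voxel weight
  indexed by the target label):

      supervised:  (1/N_L)(1/K) sum_i [L_s(W_cdif, p_A, y) + L_s(W_dis, p_B, y)]
      cps:         (1/(N_L+N_U))(1/K) sum_q [L_CE(W_cdif, p_A, yhat_B)
                                             + L_CE(W_dis, p_B, yhat_A)]
      mixed:       L_s(W_cdif, p_A^m, y_m_A) + L_s(W_dis, p_B^m, y_m_B)

  The mixed term is written without a 1/K factor (and is averaged over
  the batch); the total is

      L = L_sup + L_mix + theta * exp(-5 (1 - min(e/E,1))^2) * L_cps

  with `theta = 0.1` and a Gaussian ramp of `E = 40` epochs by default.
  Pseudo-labels are constants: no gradient flows through the model that
  produced them.

* **Inference** tiles the volume with overlapping patches, averages the
  two students' logits with overlap-count normalisation, and argmaxes
  per voxel (ties to the lowest index).

## Defaults and their rationale

| parameter | default | meaning |
|---|---|---|
| `weights.beta` | 0.99 | EMA smoothing of DisW and confidence |
| `weights.alpha` | 0.5 | outlier damping of the difficulty ratio |
| `weights.gamma` | 0.2 | exponent of the information score |
| `weights.tau` | 50 | Dice-history window (iterations) |
| `weights.epsilon` | 1e-8 | smoothing of the difficulty ratio |
| `train.theta` | 0.1 | unsupervised-loss coefficient |
| `train.lr`, `momentum` | 0.03, 0.9 | SGD with poly decay, power 0.9 |
| `train.mu` | 0.99 | EMA-teacher momentum |
| `train.patience` | 30 | early-stopping threshold (epochs) |

The default architecture is a four-level encoder-decoder with channels
(8, 16, 32, 64) on 32^3 patches — small enough to train on a CPU.
`DMPFConfig.full_scale()` selects the full-resolution recipe (five
levels up to 512 channels, 128x128x64 patches, 32x32x16 stride).

## Numerical choices

* **EMA convention.**  The teacher update is applied as
  `teacher <- mu*student + (1-mu)*teacher` (`ema.convention = "paper"`),
  which for large `mu` keeps the teacher near the current student; the
  conventional mean-teacher form (`mu` on the history) is available as
  `"conventional"`.  Both are implemented because the two conventions
  differ only by transposing `mu`, and which is intended is genuinely
  ambiguous; the printed form is the default.
* **Difficulty statistic edge cases.**  Dice values are floored at 1e-4
  before log-ratios (a zero score early in training would be `ln 0`).
  When the un-learning sum is negative and `alpha` is non-integer the
  base of the power is negative; the absolute value is used and a
  warning emitted — the magnitude is the meaningful quantity.
* **Stabilisation.**  The raw difficulty statistic is unbounded: a
  window containing only deterioration drives `d` to roughly
  `eps**-alpha` (about 1e4 at the defaults), and feeding such a weight
  into the cross-entropy diverges SGD within a few iterations at desk
  scale.  The training loop therefore caps consumed weight vectors at
  `weights.max_weight = 10`, rescales the confidence-difficulty vector
  to max 1 so both weight streams share the [0, 1] scale of the
  distribution weight (heterogeneity comes from the ordering, not the
  magnitude), and clips gradients to a global L2 norm of
  `train.grad_clip = 5` per model.  The weight-formula functions
  themselves are exact; only the training loop applies cap and rescale.
* **Mixing warmup.**  `dmp.warmup_iters` (default 0) delays the mixed
  loss.  The mixed term carries no ramp, so at short training horizons
  it pastes iteration-0 teacher pseudo-labels — pure noise — into
  labeled patches under rare-category weights, which can destroy both
  students before they learn anything.  Long full-scale schedules
  absorb this; short desk-scale runs should set a warmup of roughly
  half the run.
* **Zero-count categories** in the distribution weight are floored to
  one voxel; all-equal counts return the uniform vector; a fully
  confident category set returns a uniform information score.
* **Soft-Dice smoothing** is 1e-5 in numerator and denominator; the
  weighted Dice is normalised by the weight sum so the weight scale does
  not change the loss scale (the weighted CE deliberately does scale).
* **Losses are evaluated in float64** on the float32 network outputs so
  that loss values are reproducible to 1e-10 against independent
  reference computations.
* **Patch sampling.**  With probability 0.7 a labeled crop is centred on
  a random voxel of a uniformly chosen present foreground category
  (forced-foreground sampling); otherwise crops are uniform.  Without
  this, rare categories at desk-scale patch sizes receive essentially no
  supervised signal in either the weighted or the uniform arm.
* **Absent categories.**  Validation Dice for categories absent from
  both prediction and truth is excluded from means; the average surface
  distance of an empty-vs-nonempty pair is the volume diagonal (finite
  worst case).

## The synthetic phantom generator

Phantoms are analytic shapes (ellipsoids, tubes, three-sphere blobs) on
a cubic grid with requested per-category voxel fractions; decades-spaced
fractions (0.2 / 0.02 / 0.005 / 0.001 by default) reproduce a >= 100x
voxel-count spread.  Intensities are category means in [0, 1] plus
Gaussian noise (sd 0.05); a per-category boundary-blur knob smooths the
intensity transition around a category, which monotonically degrades any
intensity-driven segmenter on it — the generator's proxy for boundary
difficulty.  The generator is deterministic under its seed.

What the phantoms do **not** emulate: anatomical texture, inter-subject
variability, acquisition artefacts, anisotropic spacing, or inter-organ
context.  Passing the end-to-end benchmark therefore shows the
framework's machinery works and helps rare categories under imbalance;
it says nothing about absolute Dice levels attainable on clinical CT.

## The desk-scale benchmark

`dmpf.benchmark.run_imbalance_benchmark` trains the full framework and a
uniform-weight, no-mixing CPS baseline on the same cohort: 16 volumes of
64^3 voxels, 12.5% labeled, four foreground categories at fractions
0.2/0.02/0.005/0.001, a two-level (6, 12)-channel network on 16^3
patches, 300 iterations, learning rate 0.1 (the short schedule and tiny
network need a larger step than the full-scale default 0.03), a decay
horizon of twice the budget, and a 150-iteration mixing warmup.  The
comparison is paired — both arms share the cohort, architecture and
sampling — and is evaluated as mean Dice of the two rarest categories on
held-out phantoms, repeated over three seeds.  Problem sizes were chosen
so the whole benchmark runs in minutes on one CPU.

## Known limitations

* The network is a compact numpy implementation; it trains desk-scale
  models in minutes but is not meant for full-resolution clinical
  workloads.
* With the printed EMA convention and `mu = 0.99`, teachers track the
  students almost exactly, so teacher pseudo-labels are nearly student
  pseudo-labels; the `"conventional"` switch restores slow teachers.
* At 300 iterations the rare-category Dice has high seed-to-seed
  variance; the benchmark asserts the direction of the effect, not its
  size.
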