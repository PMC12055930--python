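# dmpf — double-mix pseudo-label framework

Semi-supervised 3-D segmentation for **category-imbalanced** volumes:
a few densely labeled volumes, many unlabeled ones, and per-category
voxel counts spanning orders of magnitude (think liver vs. adrenal gland
in abdominal CT).  Plain co-training lets rare categories starve; this
package counteracts that with two per-category weight estimators and a
weight-guided pseudo-label mixing augmentation.

## Method in brief

Two students `f_A`, `f_B` train under cross-pseudo-supervision (each
supervised by the other's argmax pseudo-labels), with EMA teachers
producing pseudo-labels for augmentation.  Per iteration:

* **DisW** (distribution weight): from pseudo-label voxel counts
  `psi_k`, `w_dis_k = log(max psi / psi_k) / max_rho log(max psi / psi_rho)`,
  EMA-smoothed — rare categories get weight near 1.
* **CDifW** (confidence-difficulty weight): `w_cdif_k = s_k^gamma (1 -
  zeta_k) d_k`, where `d_k = ((d_u + eps)/(d_l + eps))^alpha` is a
  population-stability statistic of the recent Dice trajectory `zeta`
  (window `tau = 50`) and `s_k` is the normalised `1 - confidence`
  information score from EMA-smoothed softmax confidence.
* **DMP**: sample categories proportionally to a weight vector, mask the
  teacher pseudo-label, and hard-paste unlabeled content onto a labeled
  patch — `x_m = x_u.M + x_l.(1-M)`, `y_m = y_pseudo.M + y_true.(1-M)`.
  Model A mixes by CDifW, model B by DisW.
* **Loss**: `L = L_sup + L_mix + theta·ramp(e)·L_cps` with
  `L_s = L_Dice + L_CE/2`, weighted by the two streams, and a Gaussian
  ramp on the unsupervised term.

Inference averages both students' logits over sliding windows and takes
the per-voxel argmax.  Full details and all defaults: `docs/methods.md`.

## Worked example

```python
from dmpf.benchmark import benchmark_config, benchmark_spec
from dmpf.model import DoubleMixModel

cfg = benchmark_config(seed=1, full_framework=True)   # desk-scale recipe
spec = benchmark_spec(seed=1)      # 64^3, fractions 0.2/0.02/0.005/0.001
model = DoubleMixModel.from_synthetic(spec, n_volumes=16,
                                      labeled_fraction=0.125, n_val=2,
                                      config=cfg)
results = model.fit(max_iterations=300)
print(results.summary())
```

```
Double-Mix Pseudo-label Framework — training summary
========================================================
iterations run        : 300
epochs run            : 7
categories (incl. bg) : 5
weight streams        : A=cdifw  B=disw
augmentation          : dmp
best val mean Dice    : 0.4200
final total loss      : 0.8509 (sup 0.4592, mix 0.3904, cps 0.6508)
final category weights (w_dis / w_cdif):
  category 0: 0.0741 / 0.6099
  category 1: 0.1211 / 0.5793
  category 2: 0.5610 / 0.9782
  category 3: 0.8031 / 0.1738
  category 4: 0.9295 / 1.0000
```

The phantom cohort has a 200× voxel-count spread between the largest
and smallest foreground category.  The distribution weights `w_dis`
order the categories exactly by rarity (category 4, the 0.1% category,
near 1; background near 0), while `w_cdif` tracks which categories are
*currently hard*: category 4 — rare and barely learned — carries the
maximal confidence-difficulty weight, while category 3 happened to be
well segmented in the most recent labeled crops, so its difficulty
weight dipped.  `results.predict(volume)` segments a new volume;
`results.loss_log` / `results.weight_log` hold the per-iteration
trajectories as DataFrames.

A command-line interface wraps the same pipeline:

```bash
dmpf simulate --out cohort/ --n-volumes 16 --labeled-fraction 0.125
dmpf train --data cohort/ --out run/
dmpf infer --ckpt run/checkpoint.npz --in cohort/vol_010.nii.gz --out seg.nii.gz
```

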