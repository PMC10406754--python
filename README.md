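# segsat

**How many training images does a segmentation model actually need?**

`segsat` analyses how test performance of a 3D medical-image segmentation
model saturates as the training set grows.  Given per-case agreement metrics
at a series of dataset sizes, it fits the exponential-plateau learning-curve
model

```
D(x) = D_max − (D_max − D_0) · e^(−k·x)
```

where `x` is the number of training+validation images, `D_max` is the maximum
achievable Dice, `D_0` the minimum Dice, and `k` the exponential rate
constant, and reports the **plateau point** — the smallest dataset size at
which the fitted curve comes within a tolerance (default 0.01 Dice) of
`D_max`:

```
x_plateau = ⌈ ln((D_max − D_0)/tol) / k ⌉
```

It is aimed at groups building custom segmentation datasets (e.g. kidney and
renal-tumor masks on CT or MR for nnU-Net-style training) who want to know
when annotating more cases will stop paying off.

The toolkit covers the full evaluation workflow around the curve fit:

- **Metrics** — per-case Dice, Jaccard, true positive rate, symmetric mean
  surface distance (mm), and structure volumes (mL) between reference and
  predicted NIfTI label volumes.
- **Ensembling** — per-voxel majority vote over cross-validation fold
  predictions with a deterministic tie rule.
- **Plateau fitting** — bounded nonlinear least squares, closed-form plateau
  point, an *extrapolated* flag when the plateau lies beyond the observed
  sizes, and a stability analysis that refits while progressively dropping
  the largest dataset sizes.
- **Agreement statistics** — predicted-vs-reference volume regression,
  Bland–Altman percent-difference analysis, and paired t-tests of per-case
  Dice between dataset sizes.
- **Synthetic data** — seeded kidney/tumor phantoms, degraded predictions
  hitting a requested Dice, and learning-curve draws from a known plateau
  law, for testing and for trying out the workflow without patient data.

## Worked example

Simulate a learning curve whose true parameters are `D_max = 0.85`,
`D_0 = 0.40`, `k = 0.02` (five folds per size at sizes 50–300, fold noise
SD 0.02 Dice), then fit it with a stability check:

```
$ segsat simulate curve --seed 42 --out curve.csv
wrote 36 observations to curve.csv
$ segsat fit --curve curve.csv --drop-largest 2 --out fit.json
d_max=0.8540 d_zero=0.4007 k=0.01907 plateau_x=201
```

The fit recovers the generating parameters to within the fold noise and
estimates that performance plateaus at 201 training+validation images (the
noiseless curve gives exactly 191 = ⌈ln(0.45/0.01)/0.02⌉).  `fit.json`
additionally reports `max_dmax_gap = 0.005` across the dropout refits with
`stable = true`: removing the 300- and 250-size observations barely moves
the estimated plateau, so the curve has genuinely flattened.

The volumetric side of the workflow runs on directories of NIfTI label maps
(background/kidney/tumor = 0/1/2 by default, configurable via `--labels`):

```
$ segsat simulate folds --seed 42 --k 5 --out sim
$ segsat ensemble --pred sim/fold0 ... --pred sim/fold4 --out ens
$ segsat evaluate --ref sim/reference --pred ens --out metrics
 label  dice_mean  jaccard_mean  tpr_mean  msd_mm_mean  ref_volume_ml_mean ...
kidney   1.000000      1.000000  1.000000     0.000000               5.185
 tumor   0.967952      0.937895  0.963243     0.172494               0.925
```

Here five fold predictions degraded to ~0.85 tumor Dice each fuse into an
ensemble reaching 0.97 — majority voting cancels the independent fold errors.
`segsat agree` then compares predicted and reference volumes (regression
slope/R², Bland–Altman bias ± SD in percent) and runs paired t-tests of
per-case Dice between consecutive dataset sizes.

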