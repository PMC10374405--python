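# cardiomapseg

Automated left-ventricular myocardium segmentation for cardiac T1 and T2
parametric maps, rebuilt end to end on synthetic data: a phantom generator
with known ground truth, an encoder–decoder segmentation network trained
with a two-phase map/weighted-image curriculum, a deterministic
mask-to-contour post-processing pipeline, and the full agreement-metric
suite (Dice, IoU, Hausdorff, mean surface distance, mapping-value
statistics, ICC).

## The problem

Parametric cardiac mapping measures tissue relaxation times pixel by pixel:
a T1 map is fitted from ~8 inversion-recovery weighted images via
`S(t) = A − B·exp(−t/T1)`, a T2 map from 3 T2-prepared echoes
(TE = 0/25/55 ms) via `S(TE) = S0·exp(−TE/T2)`. Clinical use requires
epi- and endocardial contours of the LV myocardium on every short-axis
slice (basal, midventricular, apical), which is slow and subjective to draw
by hand. This package implements the automated route: a U-Net-style network
predicts a 3-class mask (background / LV cavity / myocardium), and a
deterministic pipeline converts the mask into smooth contours —
boundary tracing → Teh–Chin dominant points → roundness/area filtering of
spurious regions → convex-hull repair of C-shaped cavities → periodic
B-spline resampling — so that contour-based distance metrics are accurate.

Because clinical CMR data cannot be redistributed, everything here runs on
a synthetic cohort: annular phantoms with analytic truth contours,
generated through the same signal equations the scanner uses, with noise,
elliptical anatomy, slice-dependent size (apical smallest) and occasional
C-shaped thin-wall cavities.

## Network

Three presets (all NumPy, trained with Adam, soft-Jaccard loss over the
foreground classes, cosine-annealing schedule with warm restarts, and a
curriculum that trains on maps + weighted images first and parametric maps
only afterwards):

| preset          | encoder                        | decoder              | params |
|-----------------|--------------------------------|----------------------|--------|
| `resnet50-like` | 50-conv residual (bottlenecks) | 8 convs, 5 up-stages | 32.5 M |
| `original-unet` | classic double-conv            | symmetric, up-convs  | 31.0 M |
| `small-resnet`  | reduced residual (factor 8)    | 3 up-stages          | 0.1 M  |

The small preset exists so the full train→predict→fit→evaluate loop runs in
minutes on one CPU core.

## Worked example

```bash
python examples/01_simulate_and_fit_maps.py
```

```
noise sigma   0.0:  myocardial T1 median  1000.0 ms  (truth 1000), T2 median  50.00 ms  (truth 50), failed pixels 0
noise sigma  20.0:  myocardial T1 median   994.0 ms  (truth 1000), T2 median  50.22 ms  (truth 50), failed pixels 0
```

The per-pixel fits invert the signal models exactly without noise and stay
within ~1 % at 2 % additive noise. The post-processing ablation
(`examples/03_mask_to_contours.py`) shows what each contour-fitting stage
buys on a mask corrupted with a spurious blob and a C-shaped cavity:

```
no post-processing     worst-contour HD  43.64 mm
+ interpolation        worst-contour HD  43.64 mm
+ filtering            worst-contour HD  12.37 mm
+ hull correction      worst-contour HD   2.37 mm
```

Filtering removes the blob's contribution to the Hausdorff distance and the
hull correction closes the C-shaped cavity, landing near the rasterization
floor (~1–2 mm at 1.5 mm pixels). `examples/05_agreement_metrics.py` prints
the metric identities: the same 1 px boundary shift costs more Dice on the
ring-shaped myocardium (0.839) than on the disk-shaped cavity (0.943) —
the reason epi- and endocardial Dice are reported separately — and ICC(2,k)
of three simulated raters with variance components planted for 0.9 is
recovered as 0.922 (CI 0.890–0.950).

There is also a thin CLI over the same functions:

```bash
cardiomapseg generate --n-cases 10 --seed 1 --out data/
cardiomapseg train --dataset data/ --epochs 20 --out runs/r1
cardiomapseg predict --dataset data/ --model runs/r1 --out preds/
cardiomapseg evaluate --dataset data/ --pred-dir preds/ --out report/
cardiomapseg ablate --out ablation.csv
```

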