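# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical choices that matter.

## Pipeline overview

Per cell line, four evidence streams are computed and combined:

| stream | measurement | resistance direction |
|---|---|---|
| calcein kinetics | accumulated mean green fluorescence over the spheroid mask, trapezoidal integral over the acquisition window (a.u.·h) | low accumulation → high efflux → resistant |
| dose–response | mean IC50 rank across shared drugs within the cohort | high rank → resistant |
| ROS | decay flag: fitted linear slope of the DCFDA series < 0 with p < 0.05 | no observable ROS decay → resistant |
| flow cytometry | mean inhibitor retention ratio MFI(inhibitor)/MFI(control) over MDR1/MRP1/BCRP | ratios near 1 → inhibition ineffective → resistant |

The final score is a weighted sum of 0–1 terms, default weights
0.4 / 0.3 / 0.2 / 0.1 in the order above, class thresholds 1/3 and 2/3.
No published numeric decision rule exists for this integration — the
source material describes the classification narratively — so the rule
is a declared surrogate whose requirement is reproducing the qualitative
orderings; the weights actually used are logged in every report, and
missing evidence streams are dropped with the remaining weights
renormalised rather than imputed.

Cohort normalisation is min–max with the most sensitive end mapped to 0
and the most resistant to 1; a cohort of one cannot be normalised and is
flagged instead.

## Spheroid segmentation

The segmenter is a dilated fully convolutional network: 13 3×3
convolution layers in five blocks (2/2/3/3/3 layers), per-block dilation
rates 1/2/4/8/16, no spatial downsampling, so the score map keeps input
resolution while the receptive field grows to ±90 px. The five block
outputs are concatenated channel-wise and passed through dropout and two
1×1 classification layers. Training minimises class-weighted
cross-entropy (background:foreground 1:10; log clamped at 1e-7) with
Adam at learning rate 1e-4, batch size 2, up to 20 epochs, and 8×
augmentation by the square symmetries (four rotations × optional flip).

Published settings retained: the layer grouping, 3×3 kernels, the 1:10
class weighting, Adam at 1e-4, the 20-epoch budget, and 512×512 as the
default input size. Free choices (dilation schedule, 64-channel default
width, dropout placement/rate, batch size) follow the cited architecture
family's conventions and are all config-exposed.

**Weight-corrected decision rule.** Training with a 1:10 foreground
weighting is equivalent to shifting the class prior by that factor, so
plain per-pixel argmax systematically dilates the predicted mask by
~2 px. Inference therefore thresholds the foreground probability at
w_fg/(w_fg+w_bg) = 10/11, which restores the unweighted Bayes decision;
this lifted held-out Dice from ~0.87 to ~0.95 at the reduced scale.
Post-processing: 3×3 binary closing (2 iterations), largest connected
component, hole fill — the target is always a single spheroid.

**Reduced configuration.** Tests and the acceptance script train at
128×128 with 8 channels per block, dropout 0.15 and 12 epochs; the
implementation is plain NumPy (im2col + BLAS GEMM, manual backprop) and
this scale trains in minutes on one CPU while still separating the
network from the Otsu baseline on high-inhomogeneity frames (held-out
Dice ≈ 0.95 overall; baseline ≈ 0.99 on clean frames but ≈ 0.84 at
amplitude 0.6). Dropout 0.5 — a sensible default at 64 channels — is
too aggressive for the 8-channel reduced net and is lowered there.

The classical comparator is Gaussian smoothing (σ=2) → Otsu threshold →
morphological closing → largest component → hole fill.

## Synthetic data: what it emulates

*Kinetics.* Intracellular dye follows uptake at rate `u` against
first-order efflux `e`: `C(t) = u·t` when `e = 0`, else
`(u/e)(1 − exp(−e·t))`. Penetration into the spheroid is
phenomenological: the dye front reaches normalised depth
`δ(t) = δ_max(1 − exp(−k_p t))` from the boundary; deeper voxels decay
exponentially with length scale 0.05 radii, producing rim-only
fluorescence when `δ_max` is small. Default phenotypes (a.u., hours):

| phenotype | u | e | δ_max | k_p | ros_init | ros_decay |
|---|---|---|---|---|---|---|
| sensitive | 1500 | 0.05 | 1.0 | 0.5 | 800 | 1.0 |
| moderate | 1400 | 0.12 | 0.7 | 0.3 | 0 | 0 |
| resistant | 1000 | 1.5 | 0.15 | 0.3 | 0 | 0 |

These were fixed analytically, before any test was written, so that the
12-h accumulated calcein orders sensitive > moderate > resistant with
the moderate line mid-range (12-h mean fluorescence ≈ 10800 / 7600 / 200
a.u.), ROS decay occurs only in the sensitive line, and the resistant
line shows the rim-only pattern.

*Images.* Phase contrast renders a bright disk (sigmoid boundary,
softness in px) on a noisy background; a 2-octave smoothed random field
multiplies the **whole** frame as illumination inhomogeneity, so at high
amplitude bright background outshines dim spheroid regions — the
specific failure mode of global thresholding. 16-bit pixel range,
frame interval 20 min by default (the acquisition protocol states both
15 and 20 min; the interval is a parameter). In the seeding-density
study the boundary softness scales with the radius so the rendered rim
is the same fraction of every spheroid; per-pixel mean fluorescence is
then size-free, which is the biological premise that study probes.

*Plates.* Corrected well signal = blank + V(c)/100 × (control − blank)
with V(c) from the 4PL; Gaussian noise on A490. Control signal 1.2,
blank 0.05 absorbance units. Synthetic true IC50 tables follow the
published qualitative pattern only (the resistant line highest for all
three drugs, 2-D methotrexate equal across lines, spheroids ≥
monolayers); dose ranges are cisplatin 3.33–333 µM, doxorubicin
170–17000 µM, methotrexate 2.2–220 µM, 8 log-spaced doses × 3
replicates.

*Flow.* Per tube, green intensity is log-normal with median =
baseline × retention ratio (log10 sd 0.35); PI is a live/dead log-normal
mixture (medians 10² and 10⁴). Dead events lose 80% of the green
signal, which is what makes gating consequential.

*What it does not emulate:* reaction–diffusion transport, cell-level
heterogeneity, photobleaching, necrotic-core optics, spectral spillover
or debris/doublet events. Passing tests therefore demonstrate that the
pipeline recovers known structure of this statistical family, not
instrument-grade performance on real microscopy or FACS data.

## Numerical choices

- **Accumulated calcein** has no published formula; the trapezoidal
  time-integral is primary (robust to frame-interval changes; exact on
  piecewise-linear series), the final-frame value is kept as an
  alternative endpoint. Frames whose mask is empty are dropped and
  logged, not interpolated.
- **4PL fitting** parameterises log10 IC50, runs 5 starts across the
  dose range, and reports the relative IC50 (inflection), not the
  absolute-50% crossing. Flat responses (dynamic range < 10% of top)
  return `converged=False`. The 90% CI is profile likelihood: SSR
  threshold `SSR_min (1 + F(1, n−4)/(n−4))`, bracketed outward and
  solved by Brent's method; an interval side that never crosses within
  ±3 decades of the dose range is reported at that search bound.
- **"Significantly large" 2D-vs-MCS difference** is undefined in the
  source; the declared rule is disjoint IC50 CIs **and** fold ≥ 2,
  both configurable.
- **PI gating** uses the KDE valley between the two most prominent
  log-PI modes (2% prominence), falling back to the 99th percentile
  with a warning when the distribution is effectively unimodal or the
  valley is shallower than 25% of the flanking modes. Median of an even
  count is the mean of the middle two.
- **ANOVA/Tukey** use `scipy.stats.f_oneway`/`tukey_hsd`; the
  all-values-identical case returns F=0, p=1 explicitly. Significance
  stars use the conventional 0.05/0.01/0.001 tiers; the source figures'
  legend ("**p < 0.05, *p = 0.019") is internally inconsistent and is
  not replicated literally.
- **Determinism**: every generator and the training loop are pure
  functions of (spec, seed); fixed-seed pipeline reruns are
  byte-identical JSON.

## Problem sizes

Tests and the acceptance script use 128×128 frames (radius 0.22–0.38 of
the frame), 40 training / 10 held-out segmentation frames, 20 seeds for
kinetics/ROS rates, 100 simulated plates for IC50 recovery, 10,000
flow events per tube, and 10 cohort seeds for end-to-end recovery.
These sizes were chosen as the smallest at which the compared quantities
are stable; the library defaults (512×512, 64 channels) remain available
for larger runs.

## Known limitations

- The NumPy network trains single-threaded; the full 512×512/64-channel
  configuration is supported but slow without a GPU framework.
- The resistance classes are cohort-relative (min–max normalisation):
  the classifier orders lines within a cohort, it does not calibrate an
  absolute resistance scale.
- FCS binary ingestion is not implemented; flow events are consumed as
  tidy CSV tables.
- The moderate/high class boundary sits at score 2/3; cohorts whose
  middle line is kinetically close to the resistant one can produce
  adjacent-class confusions (observed confusions are adjacent only).
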