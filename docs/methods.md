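# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `pamvasc`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## RF preprocessing

An OR-PAM C-scan is a real-valued array `samples[time, lateral, frame]` with
a temporal sampling rate and a lateral raster step (default 3 µm, the
scanner step that also sets the system's quoted resolution).

**Bandpass (30 kHz – 50 MHz default).** The order-4 Butterworth *power*
response — the squared magnitude, equivalent to forward–backward
filtering — is applied spectrally per A-line. A recursive (filtfilt)
realization is the conventional choice, but a 30 kHz high-pass has a
settling time of tens of microseconds while an A-line lasts a few
microseconds: the IIR output would be all edge transient. The spectral
realization has the identical passband, is exactly zero-phase (envelope
peaks do not move), and attenuates a tone at twice the upper edge by ≈48 dB.

**Envelope, MIP, dynamic range.** The per-A-line analytic-signal magnitude
(Hilbert transform) is projected along time by maximum intensity. Display
compression maps `[max − 45 dB, max]` linearly in dB onto `[0, 1]`. A
compressed image records its window in `MIPImage.dynamic_range_db`, and
`apply_dynamic_range` is a no-op on an already-compressed image — this is
what makes the operation idempotent; a second linear-in-dB rescale of
already-compressed values would not be. The first and last ~1% of each
A-line are excluded from envelope-accuracy tests (Hilbert edge artifacts).

## Spectral mean frequency

Per included A-line, a Hann-windowed one-sided periodogram; per pixel, the
average periodogram over a `window_px × window_px` (default 5×5)
neighborhood of *included* A-lines; per image, the power-weighted centroid
of the spectrum averaged over included pixels. The robustness rule gates
A-lines on their envelope maximum: below the image's
`noise_floor_quantile` (default the median), or identically zero, an A-line
is background and contributes nothing. The gate quantile and window are
explicit, testable parameters. The transducer's own band shapes every
spectrum identically and is deliberately not deconvolved; mean-frequency
comparisons across images are therefore relative, which is how they are
used.

The phantom model ties spectra to absorber size: a finite absorber of
diameter *d* low-passes the emitted pulse with a Gaussian of time constant
`τ = d / 2c` (c = 1500 m/s), so the spectral centroid decreases strictly
with absorber diameter — the direction the biology predicts for enlarged
tumor vasculature.

## Segmentation

Fixed, parameterized pipeline: min–max rescale (absorbs any constant
offset) → CLAHE (clip 0.01) → rolling-ball background subtraction (radius
25 px) → Otsu or local-mean threshold → removal of objects under 10 px →
topology-preserving thinning (`skimage.morphology.skeletonize`). Thinning
occasionally leaves fully set 2×2 junction blocks; a cleanup pass deletes
one pixel per block, preferring pixels whose remaining neighborhood stays
connected (ring-connectivity test), so skeletons are strictly thin.
Interactive algorithm choice is deliberately excluded: every parameter
lives in `RunConfig` and the run manifest records the configuration hash.

## Diameter mapping and morphometry

Local vessel diameter at a centerline pixel is **twice the exact Euclidean
distance transform** of the binary mask, times the pixel pitch. This is a
closed-form definition, and the test suite holds the implementation to
exact agreement (integer squared distances) with an exhaustive
nearest-background search at every centerline pixel.

The 11 morphometric features are sample statistics of the diameter
distribution (mean, SD with ddof = 1, median, mode on a one-pixel-wide
histogram with ties to the smallest bin, min, max, skewness, kurtosis) plus
mask densities (vessel area fraction, centerline length per area,
junction-cluster count per area). All skeleton pixels enter the diameter
statistics, including those near junctions.

## Skeleton graph and topology features

Pixels are classified by neighbor count under **m-adjacency** (mixed
adjacency from digital topology): orthogonal neighbors always count, a
diagonal neighbor counts only when neither corner-completing pixel is set.
Plain 8-counting misclassifies the slab pixel next to a T-junction (its
redundant diagonals to the stem inflate its degree), which would absorb one
crossbar pixel into each junction cluster and bias the branching interval
short; under m-adjacency an H-shaped fixture with a 40-step crossbar yields
a branching interval of exactly 40 px. One m-neighbor = endpoint, two =
slab, three or more = branch pixel; adjacent branch pixels merge into one
branch node. Segments are traced from node pixels through slabs; length is
1 px per orthogonal step and √2 px per m-valid diagonal step. A connected
component with no branch node is *isolated*; a closed junction-free loop is
anchored by a degenerate endpoint-kind node and still counts as isolated.

Features: segments per mm², total length (mm) per mm², isolated centerline
length per µm² (the fragmentation surrogate), branch nodes per mm², and the
branching interval — the mean length of segments whose **both** ends are
branch nodes, i.e. the typical junction-to-junction span. An image without
any such segment records the interval as missing (NaN, with a warning) and
is excluded from analyses of that feature; no imputation.

## Synthetic data

The generator defines the study conditions; its defaults are fixed.

**Vessel phantoms.** Trees grow as jittered directed walks (1 px steps,
angular jitter SD 0.08 rad/step) that spawn children with probability
0.04/step at bifurcation angles of 0.9–1.5 rad; a tree that stochastically
fails to branch gets one forced child, so every tree is a branching
structure. Defaults: 320² px at 3 µm, 2 trees, ≤ 8 branches each, branch
length ~U(0.6, 1.4)·300 µm, diameters per branch from N(20, 4²) µm
truncated at 2 px, 10% isolated-fragment length fraction, additive Gaussian
background noise (SD 0.03 of vessel amplitude). Tubes are rendered by
stamping disks of the branch radius along the centerline, and walks stop a
radius short of the frame so no tube is clipped. Fragments are short walks
placed with clearance from everything else so they stay disconnected after
rendering.

**Ground truth is realized, not nominal.** Diameter statistics are measured
on the clean rendering — twice the EDT at the generator's own centerline
pixels — so rasterization (up to ±1 px, i.e. ±10% at 30 µm) is not baked
into recovery targets; lengths are path step sums; branch nodes are realized
children.

**Calibration phantoms** (`calibration_spec`) serve diameter-recovery
experiments: unbranched, gently curving tubes (length 8× diameter, diameter
SD 15%, no fragments, 512² px). Where projected tubes cross or merge, the
medial axis shortens and per-pixel diameter is ill-defined — a real property
of 2D projections, not an estimator defect — so *calibration* is assessed on
clean tubes while the branching generator exercises topology. For the same
reason the measured skeleton length of branching phantoms runs ~10–15%
below the summed generator path length (junction merge zones), which is why
the measured isolated-length fraction of a 0.2-fraction phantom lands
slightly above 0.2.

**RF phantoms.** Gaussian-modulated cosine pulses (carrier 40 MHz, spectral
SD 15 MHz, sampling 250 MHz) at listed A-line positions, optional
absorber-size low-pass, optional white noise; the FFT centroid of the
noise-free prototype pulse ships with the phantom as the oracle value.

**Feature tables.** Class-conditional multivariate normal (exchangeable
correlation 0.3) over the five selected features, truncated at zero by
per-row rejection. Default shifts are ±1.5 SD in the disease directions
(lower mean frequency; higher diameter mean/SD, isolated length, branching
interval); `default_effects(0)` gives an exact null and
`default_effects(6)` essentially disjoint classes. The 1.5 SD default is a
moderate-separation regime chosen to mimic clearly different but
overlapping class distributions; it is not fitted to any empirical dataset.

What the generator does **not** emulate: surface bleeding artifacts, depth
effects, scan-geometry distortion, spatially correlated speckle, or any
acoustic/optical propagation physics. Passing tests demonstrate the
estimators are correct on data satisfying the generative assumptions; they
do not certify robustness to those real-world artifacts.

## Feature screening and selection

Welch's unequal-variance t-test, computed from the closed form with
Welch–Satterthwaite degrees of freedom and two-sided p from the Student-t
survival function; two zero-variance groups with equal means give t = 0,
p = 1. Screening keeps features with raw p < 0.05 (no multiple-testing
correction — the screen feeds a cross-validated classifier rather than
standing as inference). Pruning is greedy in ascending p (ties broken by
name): accept a feature only if its |Pearson r| with every accepted feature
is below 0.5, stop at k = 5. Missing values use pairwise-complete
observations, consistent with the branching-interval missingness rule.

## Similarity network, embedding, classifier

**Cosine similarity.** Rows of the selected-feature table are L2-normalized
as-is — no per-column standardization by default, with `zscore=True` as the
documented alternative — so for nonnegative features all similarities lie
in [0, 1]. Raw-scale cosine is dominated by the largest-scale feature and
concentrates near 1; this is a property of the representation that the
framework works with, not around.

**Force-directed layout.** In-package weighted Fruchterman–Reingold:
attraction `w·d²/k`, repulsion `k²/d`, `k = 1/√n`, linear cooling from 0.1
over 500 iterations, seeded initial positions, and **no final rescaling**,
so equilibrium distances genuinely decrease with similarity (a library
layout that rescales to a fixed box would destroy this). Edge weights are
similarities raised to a contrast exponent (default 32) plus a small linear
leak (0.01·S): the exponent spreads the near-uniform raw-cosine weights
into visible cluster structure, the leak keeps every pair weakly attractive
so two-node equilibrium distances remain strictly monotone in similarity.
Both are layout-only display parameters; they never touch the classifier.
The in-sample logistic boundary on the 2D coordinates is a visualization of
separability, deliberately separate from the cross-validated classifier.

**Similarity-summary LOOCV.** Each fold removes one sample completely: the
(n−1)×(n−1) similarity matrix yields, per training sample, four attributes —
mean and SD of similarity to the normal/benign cluster and to the EC/EIN
cluster, with the sample's own self-similarity (identically 1) excluded
from its own cluster's statistics. Logistic regression (lbfgs, ridge
λ = 1e-6 so perfectly separable folds converge, **balanced class weights**)
is fit on those attributes; the held-out sample's attributes come only from
its similarities to the training samples. Balanced weighting matters: with
a 3:1 class ratio, an unweighted intercept tracks each fold's base rate,
which shifts systematically with the held-out sample's own class and biases
pooled out-of-fold AUC below chance under label permutation; balancing
removes most of that artifact (the residual small-sample LOOCV pessimism is
intrinsic). Fold computation is exposed as a pure function of
training-only inputs (`fold_probability`), which is what the leakage audit
exercises. AUC is the Mann–Whitney rank statistic with ties counted ½,
computed from the n pooled out-of-fold probabilities; the confusion matrix
uses the 0.5 threshold with EC/EIN as the positive class.

## Pipeline and problem sizes

`run_extract` produces one feature row per input (RF HDF5 and/or MIP TIFF),
isolating per-file failures; an image with an empty vessel mask is excluded
and logged, and when RF data are present a structural-stage failure
downgrades to spectral-only features rather than dropping the row.
`run_full` chains selection (or a caller-fixed feature list — appropriate
when extreme separation makes all informative features correlate through
the class), similarity, layout, boundary and LOOCV into a report with CSV,
JSON and figure outputs, all carrying the configuration hash.

Test and acceptance problem sizes — 320²–512² phantoms, 40-sample tables,
100-seed recovery sweeps, 200 permutation replicates, 1000 Welch null
replicates — were chosen to make sampling error small relative to the
tolerances tested while keeping the full suite in a few minutes on one
core.

## Known limitations

- Per-pixel diameters in merged or crossing tube regions are systematically
  inflated, and skeleton length there is shortened; per-image means on
  branching networks inherit a small bias (quantified above).
- The branching interval follows the junction-to-junction reading: segments
  with an endpoint terminus do not enter it. Images without any
  junction-to-junction segment lose that feature.
- Raw-scale cosine similarity is dominated by the largest-scale feature;
  the `zscore` switch exists precisely because this convention is a
  substantive modeling choice.
- The LOOCV null retains a small pessimistic bias after class-weight
  balancing; permutation nulls, not 0.5, are the right reference for small
  n.
- Probabilities are not calibrated; only ranks (AUC) and the fixed 0.5
  threshold are interpreted.
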