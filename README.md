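# pamvasc

Quantitative vascular analysis of optical-resolution photoacoustic
microscopy (OR-PAM) scans, built for separating normal/benign endometrium
from malignant and premalignant tissue (endometrial cancer, EC, and
endometrial intraepithelial neoplasia, EIN) by the architecture of its
microvasculature.

OR-PAM images hemoglobin absorption with micron-scale lateral resolution, so
a C-scan of the endometrial surface is effectively a map of its capillary
bed. Tumor-associated angiogenesis leaves measurable fingerprints there:
enlarged and more heterogeneous vessel calibers, fragmented networks with
more disconnected vessel length, sparser branching, and lower photoacoustic
spectral content (bigger absorbers ring at lower frequencies). `pamvasc`
turns raw RF C-scan volumes into those fingerprints and into a
cosine-similarity classification framework over them.

## What it computes

Starting from an RF volume (A-line samples × lateral × frame, default band
30 kHz–50 MHz, 3 µm raster step) or directly from a maximum-intensity
projection (MIP):

1. **Preprocessing** — zero-phase Butterworth bandpass, Hilbert envelope,
   MIP, 45 dB display dynamic range.
2. **Segmentation** — CLAHE → rolling-ball background subtraction → Otsu (or
   adaptive) threshold → despeckle → topology-preserving thinning to 1-px
   centerlines.
3. **Morphometry** — local vessel diameter as twice the exact Euclidean
   distance transform at each centerline pixel, `d(x) = 2·EDT(x)·Δ`, plus 11
   per-image summaries (mean/SD/median/mode/min/max/skewness/kurtosis of
   diameter, vessel area fraction, centerline density, intersection
   density).
4. **Network topology** — skeleton graph (endpoints, branch nodes, segments,
   isolated components) under m-adjacency, giving branch counts, total
   branch length, area-normalized isolated branch length, and the branching
   interval (mean centerline distance between adjacent junctions).
5. **Spectral analysis** — pixel-wise Hann periodograms with noise-gated
   sliding-window averaging; image mean frequency as the power-weighted
   centroid `f̄ = Σ f·P(f) / Σ P(f)`.
6. **Classification** — per-image feature vectors are L2-normalized and
   compared by cosine similarity `S_ij = x̂_i · x̂_j`; the similarity network
   is embedded in 2D by a weighted force-directed layout with an in-sample
   logistic boundary, and classified by leave-one-out cross-validation where
   each fold trains logistic regression on four similarity-summary
   attributes (mean and SD of similarity to each class cluster), reporting
   pooled out-of-fold AUC and the 0.5-threshold confusion matrix.

A `synthetic_data` module generates every input with ground truth — vascular
phantoms grown as stochastic branching trees rendered as
distance-transform-consistent tubes, RF pulse phantoms with known spectral
centroids, and two-class feature tables — so the entire pipeline is testable
without patient data.

## Worked example

```python
from pamvasc import similarity_classifier as sc, synthetic_data as sd

table = sd.generate_feature_table((10, 30), seed=0)     # 10 normal/benign, 30 EC/EIN
sim = sc.cosine_similarity(table, list(sd.SELECTED_FEATURES))
cv = sc.loocv(sim)
print(f"AUC {cv.auc:.3f}  sensitivity {cv.confusion['sensitivity']:.2f}  "
      f"specificity {cv.confusion['specificity']:.2f}")
```

prints

```
AUC 0.780  sensitivity 0.73  specificity 0.60
```

meaning: on this particular draw from the generator's default class
contrasts (lower mean frequency, larger/more variable diameters, more
isolated length, longer branching intervals in the diseased class), the
leave-one-out classifier ranks 78% of diseased–healthy pairs correctly and,
at the 0.5 probability threshold, recalls 22/30 diseased and 6/10 healthy
samples. Performance varies draw to draw at these moderate effect sizes
(mean AUC ≈ 0.9 over repeated tables); widening the class shifts via
`sd.default_effects(effect_size_sd)` drives it to 1.0.

The same study runs from the shell:

```bash
pamvasc simulate features --seed 0 --out run/
pamvasc classify --features run/features.csv --seed 42 --out run/results/
```

which writes the similarity matrix, 2D embedding, ROC points, report JSON
and publication-style figures into `run/results/`. `pamvasc simulate
phantom|rf`, `preprocess`, `segment` and `extract` cover the imaging half of
the pipeline.

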