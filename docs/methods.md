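# Methods

`alscape` models 3D activity landscapes (ALs) — surfaces that combine
compound similarity (as position in a 2D projection of chemical space) with
potency (as altitude and color) — and asks whether the *topology* of such a
landscape (smooth, rugged, or heterogeneous) can be recognized from rendered
images by machine-learning classifiers. This note documents the models,
parameter choices, and numerical conventions, and what the synthetic
benchmark does and does not show.

## Compound data and similarity

Compounds carry a fixed-length binary fingerprint (default 1024 bits; any
folded substructure fingerprint works, and an ECFP4-style Morgan plug-in is
provided for SMILES input via rdkit) and a potency as pKi. Similarity is the
Tanimoto coefficient Tc(A,B) = |A∩B| / (|A|+|B|−|A∩B|); distances are 1−Tc.
Classes are filtered to remove singletons: a compound is kept iff it has
Tc ≥ 0.4 to at least one other class member. Because neighborship is mutual,
one pass is exact.

Reference landscapes exaggerate one topology per class:

* **smooth Ref-AL** — compounds with q1 ≤ pKi ≤ q3 (closed interquartile
  interval; quantiles by linear interpolation between order statistics, the
  "type 7" rule). Potency extremes — and with them most activity cliffs —
  are stripped; roughly half the class remains.
* **rugged Ref-AL** — sort by potency (ties by id), partition into seven
  consecutive bins of near-equal count (remainder to the earliest bins), keep
  bins 1, 3, 5, 7. Exactly ⌊4n/7⌋–⌈4n/7⌉ compounds remain, the full potency
  range is retained, and the alternating potency bands sharpen
  discontinuity.

The unmodified (filtered) class is the **heterogeneous** variant. These
three labels are what the classifiers predict.

## Projections

Both projections minimize a stress between pairwise Tanimoto distances and
Euclidean distances in the plane; reported stress is the normalized Kruskal
form sqrt(Σ(d̂−d)²/Σd²).

* **MDS** — SMACOF stress majorization: random initialization (4 restarts),
  Guttman transform updates, tolerance 1e-6, max 300 iterations. Raw stress
  is non-increasing per iteration (asserted in tests). Realistic Tanimoto
  matrices are not 2-embeddable, so final stress around 0.25–0.3 is normal;
  planted planar configurations are recovered to Procrustes error < 1e-3.
* **Neuroscale** — a parametric RBF network: Gaussian units on the Tanimoto
  distance to k center fingerprints (centers by k-medoids, width = median
  center–center distance), linear output map. Weights are initialized by
  least-squares regression onto an MDS embedding and refined by L-BFGS on
  the raw stress of the composed map. k is chosen by seven-fold
  cross-validation of held-out stress (stress over all pairs touching a
  held-out compound); with a single candidate the CV is skipped. The desk
  default is k = 20, enough to resolve six clusters with two potency modes
  each.

Embeddings are gauge-fixed by `canonical_orient`: centered, rotated to
principal axes, each axis reflected so its coordinate skew is non-negative
(falling back to the sign of the extreme coordinate when skew vanishes).
This makes azimuth angles comparable across landscapes.

## Surfaces and color

The potency hyper-surface is a Gaussian-process posterior mean: squared-
exponential kernel times a signal variance, plus white noise, hyperparameters
by marginal-likelihood maximization with 3 restarts. Length-scale bounds are
set relative to the embedding span (1e-2–1e2 of the bounding-box diagonal)
and noise is bounded in [1e-8, 1]; `normalize_y` centers the targets. The
surface is evaluated on a regular grid (default 100×100 in the library,
60×60 in the desk pipeline) over the bounding box padded 5 %.

Colors follow a fixed absolute gradient: green at pKi ≤ 5.75, red at
pKi ≥ 8.75, yellow at the 7.25 midpoint, piecewise-linear in between and
clamped outside. A flat-yellow "band" reading of the interior range is
available as `ColorMap(mode="band")`, but the continuous gradient is the
default since a gradient is what makes mid-range potencies distinguishable.

## Rendering and image variants

Surfaces render off-screen (Agg) at 1200×800 by default (600×400 in the
desk profile), axes suppressed, white background, one image per azimuth
{0°, 90°, 180°, 270°} × elevation {0°, 35°, 65°, 90°} per projection. Two
conventions keep images *comparable*, which is what topology classification
feeds on:

* all images of a collection share one z-axis range (the union of surface
  ranges, padded 5 %), so a flat smooth Ref-AL stays visually flat instead
  of being stretched to fill the frame;
* the content crop box is the union of per-image content boxes (padded 2 %),
  shared across the collection, for the same reason.

Cropped images are resized (bilinear, aspect not preserved) to 360×220.
Reduced-information variants are computed after crop/resize so the feature
length is constant: grayscale (0.299 R + 0.587 G + 0.114 B), black/white
(Otsu), Sobel (the vertical G_y = [[−1,−2,−1],[0,0,0],[1,2,1]] convolution,
absolute value, rescaled; borders by edge replication), and Canny (via
scikit-image; hysteresis thresholds default 100/200 in 8-bit gradient
units). A single-channel image flattens row-major to 360·220 = 79,200
features in [0,1].

Otsu scans all 256 thresholds for the maximum between-class variance; ties —
which occur exactly when the optimum falls in a gap between separated
modes — resolve to the mean tied threshold, and constant images return
their own level with an all-zero mask.

## Classifiers and protocol

Activity classes are split half/half (19/19 at full scale; 6/6 in the desk
profile) so every image of a class sits on one side: class-level leakage is
impossible by construction. Each trial re-splits with a fresh derived seed;
results aggregate over trials as mean ± sample standard deviation.

* **SVM** — one-against-one SVC, grid over C ∈ {0.01, 0.1, 1} × kernel ∈
  {linear, polynomial, RBF}, features standardized inside the CV pipeline
  (statistics from training folds only). Selection CV is tenfold by default
  and threefold in the desk profile; the winning point is refit once with
  Platt-scaled probabilities.
* **Random forest** — grid over trees {50, 100} × min split {2, 5} × min
  leaf {1, 3}, tenfold CV, seeded.
* **CNN** — implemented in NumPy (no deep-learning framework is a
  dependency): three 3×3 convolution blocks (leaky-ReLU, 2×2 max-pool,
  dropout), two dense layers, softmax over the three labels, categorical
  cross-entropy, Adam, batch 32 (16 desk), early stopping on validation
  loss (patience 5/8, max 50/40 epochs). Hyperparameters (leaky-ReLU alpha,
  dropout ∈ {0, 0.1, 0.3}, dense sizes ∈ {16, 32, 64, 128}, learning rate
  from a wide grid including intentionally untenable values) are selected on
  an internal stratified 80/20 split of the training images, sampling up to
  a configurable budget of grid points; a candidate whose training produces
  non-finite losses/gradients or parameter blow-up (>1e8) is scored as
  failed and skipped. Full-scale channels are 32/64/128; the desk profile
  uses 8/16/32 with a single grid point. Backpropagation is verified against
  central-difference gradients.

CNN inputs are block-**minimum** downscaled (factor 4 → 55×90) and inverted.
Landscape features are thin dark strokes on a white background; mean or
bilinear downscaling visibly washes them out, while min-pooling keeps every
stroke and inversion puts the background at zero activation.

Evaluation: subset accuracy (exact-match mean), support-weighted F1,
multiclass MCC in Gorodkin's confusion-matrix form, one-vs-rest ROC AUC per
label plus a micro average pooling all (sample, label) decisions, and the
3×3 confusion matrix (rows = truth; row-normalized diagonal = per-label
recall).

## Synthetic activity classes

The generator emulates the statistical structure the method consumes, not
chemistry: a class is k = 6 clusters (analog series) of 1024-bit prototypes
at 8 % bit density; members flip each bit independently with probability
0.01, keeping within-cluster Tc around 0.8 and inter-cluster Tc near 0.05.
Each cluster owns a latent 2D coordinate on a jittered Latin-hypercube grid;
members jitter around it (σ = 0.015, truncated at 1.5 σ).

* **smooth** topology: potency is a linear ramp of the latent coordinates
  scaled to the pKi range (default 5–10) plus truncated noise
  (σ = 0.2, clipped at 1.5 σ). The truncations give a hard guarantee: no
  pair with Tc ≥ 0.6 differs by ≥ 1 pKi, hence zero planted cliffs.
* **rugged** topology: each cluster splits into two potency modes separated
  so that the gap after noise is at least ΔpKi = 2.5 (cliffs). The
  high-potency mode additionally flips a dedicated 2 % bit set — cliff
  partners are distinct analogs (Tc ≈ 0.7), not identical structures. This
  matters: without the bit shift both modes project to the same 2D point and
  the GP correctly explains the cliff as observation noise, flattening the
  surface.
* **heterogeneous**: half the clusters follow each rule.

Surface fixtures (base level plus well-separated Gaussian bumps on the unit
square) provide analytic ground truth for rendering and edge-detection
tests.

What passing the benchmark shows — and does not. The synthetic classes make
topology the *only* systematic difference between variants; real activity
classes add assay noise, analog-series size imbalance, scaffold effects and
potency-range differences between targets, none of which are emulated.
Results on the benchmark therefore validate the pipeline mechanics and the
direction of the effect (smooth recall highest, rugged vs heterogeneous
hardest), not absolute accuracies on public compound data.

## Desk-scale profile and problem sizes

The default `ExperimentConfig` is sized for a single CPU: 12 synthetic
classes × 150 compounds, the 0°-elevation collection over both projections
(24 images per class, 288 total), 600×400 renders on 60×60 surfaces,
5–10 trials. The benchmark reported by `scripts/acceptance.py` runs 5 trials
of SVM and CNN on a 6/6 class split (144 test images per trial). Full-scale
settings — 38 classes, 1200×800 renders, all-view collections, tenfold SVM
CV, 32/64/128 CNN channels with the full hyperparameter grids — are plain
config overrides.

## Known limitations

* Rendering determinism is guaranteed per matplotlib/Agg version, not
  across backend versions.
* The Neuroscale training algorithm (L-BFGS on the composed-map stress with
  an MDS-regression warm start) is one reasonable choice among several; the
  classic shadow-targets iteration would fit the same contract.
* The SMACOF embedding of Tanimoto matrices retains stress ≈ 0.25–0.3;
  azimuth semantics rely on `canonical_orient`, which is only as stable as
  the embedding's principal axes.
* RF is implemented and tested but not part of the default benchmark
  configuration.
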