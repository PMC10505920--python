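# Methods

## Scope and model of the assay

`spherotype` quantifies morphogenesis of matrix-embedded multicellular
spheroids from hourly phase-contrast time-lapse imaging (one field per
well, 72 h by default). The readout is the frequency of two morphology
classes — compact **Spherical** versus invasive **Hyper-protrusive**
(radial protrusions into the surrounding matrix) — per condition and
6-hour time chunk, compared against a control condition with
replicate-stratified statistics. Because raw assay images of this kind
are generally not public, the package ships a synthetic-data generator
that emulates the statistical structure the analysis relies on; every
downstream stage is validated against the generator's ground truth.

## Synthetic data generator

Each spheroid is a disk of initial radius drawn uniformly from 10–14 px
that grows linearly, R(t) = R0·(1 + g·t) with g = 0.01 per frame
(≈ 1.7× radius over 72 h). A spheroid adopts the Hyper-protrusive class
once, at birth, with condition probability `p_hyper` (an optional onset
hour delays the protrusive rendering); protrusive spheroids carry 4–8
radial spikes of length 0.5–0.9 R that taper from an angular base width
of 0.12–0.25 rad to a point. The disk-plus-spikes model is the simplest
geometry with a monotone solidity/form-factor signature of matrix
invasion; a Fourier-star boundary would blur that contrast.

Rendering is schematic phase contrast: mid-grey background (0.35), dark
halo ring (0.15, 3 px), bright body (0.65–0.90) textured with a smoothed
speckle field, additive Gaussian camera noise (s.d. 0.02 of full scale),
intensities clipped to [0, 1]. No optical physics is attempted — the
classifiers only need separable features. Out-of-focus events are
whole-frame Gaussian blurs (σ = 3 px by default) over runs of 3–6
consecutive frames, occurring in a well with probability `p_outfocus`;
this mimics focus drift rather than per-object defocus. Centroids
perform a seeded random walk (step s.d. 1 px/frame), clamped so objects
never touch the field border. Placement is rejection-sampled to forbid
overlap; when a field cannot hold the requested count the surplus
objects are dropped with a warning (≈ 7–8 large protrusive objects fit a
256-px field, versus the 12 requested by default — the density cap is a
free choice, since the source assay does not report end-point density).

The replicate hierarchy is `n_experiments` biological replicates ×
`wells_per_condition` technical replicates × `spheroids_per_well`
objects, with one independent random stream per
(seed, experiment, condition, well) tuple, so output is bit-identical
across runs and independent of iteration order.

What the generator does **not** emulate: spheroid fusion and splitting,
cell-scale texture, matrix fibres, z-stacks, fluorescence, camera drift,
and uneven illumination. Tests passing on synthetic data therefore
demonstrate the correctness of the measurement and inference machinery
under the stated generative model, not segmentation robustness on real
phase-contrast images.

## Segmentation and tracking

Gaussian smoothing (σ = 1 px) → global Otsu threshold → hole filling →
8-connected labelling → removal of components below 200 px² or touching
the border. Global Otsu suffices because the intensity model keeps
bodies brighter than background and halo; a larger smoothing σ
measurably erodes the bright body against its dark halo (σ = 2 biases
disk areas by ≈ −6%, σ = 1 by ≈ −3%). Coordinates are 0-based (row,
col); areas are pixel counts.

Tracking is greedy nearest-centroid linking between consecutive frames
with a 15 px/frame gate; candidate pairs are sorted by (distance, object
id) for deterministic tie-breaking. Objects that disappear (fully
invaded, lost focus, dropped by the size filter) end their tracks and
simply stop contributing to later chunks. Identity swaps between
adjacent objects are not resolved — with the default drift (1 px/frame)
and non-overlap placement, link purity against ground truth exceeds
0.95.

## Feature vector

One row per (track, frame), 24 features across the six families the
classification uses, with stable column names (rules files reference
them verbatim):

* **Shape/size** — Area; Perimeter (length of the marching-squares
  contour polygon after a 5-point circular moving average, which removes
  the staircase bias of pixel-edge counting: a radius-30 digital disk
  scores FormFactor 0.99, a 101-px square 0.80 vs the π/4 ideal);
  FormFactor = 4πA/P²; Eccentricity and Solidity from region moments and
  the convex hull; EquivalentDiameter; mean/max/s.d. of
  boundary-to-centroid radii.
* **Brightness** — mean, s.d., median absolute deviation of masked
  pixels.
* **Texture** — Haralick ASM, Contrast, Correlation and Entropy from a
  grey-level co-occurrence matrix quantized to 64 levels over the masked
  per-object intensity range, accumulated symmetrically over the four
  principal directions at distance 3 px, counting only pixel pairs with
  both ends inside the mask (a mask-restricted GLCM is not available in
  the installed image libraries, so it is implemented here). Masks too
  small to support any pair return the neutral constant-image values
  (ASM 1, Contrast 0), logged.
* **Granularity** — percentage of masked intensity removed between grey
  openings with disks of radii 1, 2, 4, 8, 16 px,
  G_r = 100·(I_{r−1} − I_r)/I_0. Digital disks of increasing radius are
  not perfectly nested, so opened totals are forced monotone (running
  minimum), guaranteeing G_r ≥ 0 and ΣG_r ≤ 100.
* **Movement** — per-frame and cumulative centroid displacement along
  the track (0 at birth).

One caveat found during validation: on a *full* object mask the
brightness s.d. can **rise** under defocus, because blur mixes the dark
halo into the boundary; in the object interior it falls, and GLCM
contrast falls monotonically either way, so focus classification is
unaffected. The exact feature menu is a compact documented subset per
family rather than the full CellProfiler catalogue; any separating
subset serves the classifiers equally.

## Fast Gentle Boosting

Gentle boosting with depth-1 regression stumps and symmetric multi-class
coding y_{i,c} = ±1. Each round searches every feature and every unique
observed value as a strict-`>` threshold, fits per-class branch values
as weighted means of y (always in [−1, 1]; clipped against float
cancellation), and selects the stump minimizing the weighted squared
error, ties broken by (error, feature index, threshold) — the search is
exact, vectorized via per-feature cumulative weight sums. Weights update
as w ← w·exp(−y·f) with per-class renormalization; the exponential loss
is therefore non-increasing (property-tested). Default 50 rounds with
early stop at zero training error; a constant feature matrix raises "no
informative split". Prediction is the argmax of summed branch scores and
depends only on the ordered rule list, so a model exports losslessly to
a plain-text rules file (12 significant digits) and new data can be
classified from the rules alone. Classification is two-stage: a focus
model (appearance features only: brightness, texture, granularity) flags
OutOfFocus object-frames, which are retained but excluded — with logged
counts — from the phenotype model (shape/size features).

The operator-in-the-loop labelling of the original workflow is replaced
by generator ground truth: training galleries of single-spheroid frames
(default 300 per class for the pipeline, 600 per class for the
benchmarks) are rendered, segmented and labelled from truth.

## Statistics

Classified object-frames are binned into 6-h chunks (72 hourly frames →
12 chunks, labelled 1–6 h … 67–72 h; a trailing partial chunk is kept
and logged). Two layers are computed per (condition, replicate, chunk):
the displayed proportion is the within-chunk mean of per-frame
Hyper-protrusive proportions; the counting unit for inference is one
count per tracked object per chunk (its majority label, ties to the
positive class), which avoids frame-level pseudo-replication. Where the
counting unit is genuinely ambiguous this choice is isolated behind the
aggregation function's parameters.

For each non-control condition and chunk a 2×2×K table (condition ×
phenotype, stratified by biological replicate) feeds:

* **CMH test** — statistic [Σ_k(a_k − E_k)]²/Σ_k V_k with the
  hypergeometric mean and variance per stratum, χ² with 1 df, no
  continuity correction (matching the R default used for this readout);
  degenerate margins give p = 1, flagged. For K = 1 the statistic equals
  (N−1)/N times Pearson's χ², an identity used as a test oracle.
* **Breslow–Day test** — homogeneity of the odds ratio around the
  Mantel–Haenszel pooled estimate ψ̂; the fitted a-cell per stratum is
  the margin-feasible root of the quadratic in ã, χ² with K−1 df, no
  Tarone correction (the DescTools default). A degenerate ψ̂ (zero
  numerator or denominator) triggers a Haldane 0.5 correction of all
  cells, flagged. Agreement with the statsmodels implementation is
  asserted to < 1e−6 in the tests.
* **Bonferroni** — p_adj = min(1, m·p), with family size m = (non-control
  conditions) × (chunks); the two complementary phenotypes count once.
  The Breslow–Day family is adjusted with the same m, and the
  "homogeneous" flag (the heatmap's black dot) is BD p_adj ≥ α = 0.05.

Effects are reported as log₂ fold change of pooled proportions (finite
only when both proportions are positive, otherwise flagged NA), the
control condition as z-scores of its chunk proportions across chunks
(z = 0 when the s.d. is 0). Object areas are additionally z-scored per
chunk against the control distribution and averaged per condition — a
pixel-size-invariant growth readout.

## Problem sizes and numerical choices

The bundled benchmarks use 600 labelled objects per class (70/30
stratified split, 50 rounds) for each classifier, and 20 + 20 seeded
simulation runs at 3 replicates × 4 wells × 12 requested spheroids ×
72 frames for the power and type-I checks of the inference layer; the
power/type-I ensemble uses the generator's truth tables directly
(`render=False`), which exercises simulation, chunking and statistics
without re-rendering 40 full image sets, while a fully rendered
end-to-end run is checked separately in the pipeline tests. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; reruns are bit-identical.

## Known limitations

* Segmentation defaults are tuned to the synthetic contrast model;
  real phase-contrast data would need parameter review (and possibly
  adaptive thresholding, deliberately not implemented).
* The tracker does not resolve merges, splits or identity swaps.
* Truth matching for training uses nearest centroids (≤ 10 px), which
  assumes the non-overlap guarantee of the generator.
* The CMH counting unit (object-chunk) treats objects as independent
  within a replicate; well-level clustering is not modelled.
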