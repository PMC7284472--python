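# Methods

This note documents the models, conventions and numerical choices behind
`weedvision`, and what its synthetic experiments do and do not show.

## Segmentation

A pixel is classified as vegetation when its green component strictly
dominates red and blue and reaches an absolute 8-bit threshold:

    plant(x, y)  <=>  R(x,y) < G(x,y)  and  B(x,y) < G(x,y)  and  G(x,y) >= T

with `T = 140` by default (configurable in [20, 250]). The two dominance
clauses are strict; the threshold clause is inclusive. The binary mask is
cleaned by a morphological closing with a disk structuring element
(radius 1 by default — a disk avoids directional bias), then decomposed
into connected components under 8-connectivity; components below
`min_object_area = 50 px²` are discarded as speckle. The size filter and
connectivity are deliberate defaults, not canonical values, and both are
configurable. Coordinates are 0-based row-major; bounding boxes are
half-open `(row0, col0, row1, col1)`.

## The 302-feature descriptor

Per object: 127 color + 144 GLCM texture + 2 histogram + 29 shape = 302.
The histogram pair is counted as part of a 146-entry texture block; the
registry (`weedvision.registry`) fixes names, groups and order, and can
be dumped to JSON for auditing.

**Color (127).** Six color spaces: RGB, HSI, HSV, YIQ, CMY, YCbCr (hue
in degrees [0,360); YCbCr in the digital 16–235/16–240 range). Mean and
standard deviation of all 18 channels (36), per-channel skewness (18),
mean/std of the RGB chromaticities Rn, Gn, Bn (6), mean/std of ten
pixelwise RGB vegetation indices — ExG, ExR, ExB, ExGR, CIVE, NDI, VEG,
MExG, GLI, RGRI (20), mean/std of channel-excess indices in the five
non-RGB spaces (30) and of CIVE applied to those spaces (10), RGB
kurtosis and range (6), and mean luminance (1). The channel-excess
indices (e.g. `EXY-YIQ`, `ExM-CMY`) are reconstructions: no printed
formula exists for them, so they are defined analogously to ExG as
`2·c_i − c_j − c_k` after rescaling each space's channels to [0, 1] by
their nominal ranges. `CIVE-HSV` and the other non-RGB CIVE variants
apply the CIVE coefficients to the same rescaled channels.

**Texture (144 + 2).** Gray conversion is the luminance
`0.299R + 0.587G + 0.114B`. Gray values are quantized to 8 levels over
the object's own intensity range (8 keeps the co-occurrence matrices of
small objects populated) and indexed 1..8. The co-occurrence matrix at
distance d and orientation θ counts pixel pairs at displacement
(0,+d), (−d,+d), (−d,0), (−d,−d) for θ = 0°, 45°, 90°, 135°; pairs are
restricted to pixels inside the object mask, then symmetrized and
normalized to sum 1. 36 statistics are computed per matrix.
Log-base conventions follow the printed formulas this block reproduces:
entropy and the marginal entropies use log₂, difference entropy and the
HXY terms use ln, sum entropy uses log₂ (the printed formula says only
"log"). The information measure of correlation
`(ENT − HXY1)/max(Hx, Hy)` therefore mixes bases exactly as printed;
the test oracles mirror the same convention. The "inverse difference"
and "inverse difference normalized" denominators are typeset ambiguously
in the source material (`1+[i−1]`) and are implemented in the standard
|i−j| forms. Histogram features are the gray-level histogram entropy
(bits, 256 bins) and the smoothness `1 − 1/(1+σ²)` with σ computed on
[0,1]-scaled gray.

**Shape (29).** Length L and width W come from the minimum-area rotated
rectangle of the pixel centers, each side corrected by +1 px, so an
axis-aligned n×m block reports exactly (max, min). Elongation
`(L−W)/(L+W)`, `WL = W/L`, compactness `CMP = p²/(4πA)`, circularity,
convexity (convex-hull perimeter over object perimeter), solidity,
eccentricity, extent, ellipse axis lengths, equivalent diameter, the
seven Hu moments, Euler number, maximal Feret diameter and a few ratio
descriptors. The perimeter estimator is the Crofton formula with four
directions: a raw 8-connected chain length overestimates a digital
circle's circumference by ~5%, which squares to an ~11% bias in CMP,
while the Crofton estimator leaves a rasterized radius-30 disk within
~2% of CMP = 1.

## Stereo correspondence and fusion

Correspondence is object-level, not pixel-level: with objects already
segmented per channel there is no need for a disparity map. A first
optimal one-to-one assignment (Hungarian algorithm on centroid
distances) estimates the median column disparity; the assignment is
re-solved after compensating it and pairs with residual distance above
`max_offset` (default 30 px) are dropped, unmatched objects reported.
This reconstruction is deterministic and exact on non-overlapping
scenes.

Matched vectors fuse entrywise: arithmetic `(L+R)/2` and geometric
`sqrt(L·R)`. The geometric mean is only defined for positive values, so
each feature column is min-max shifted to [1, 2] over the fusion pool
and the shift parameters persisted; in the shifted domain the AM–GM
inequality guarantees the arithmetic category dominates the geometric
one entrywise. Without a shift, the geometric mean is sign-consistent
(`sign·sqrt(|L·R|)` for same-sign entries, arithmetic fallback for
mixed signs).

## MLP engine

A small feed-forward network with 1–2 hidden layers, per-layer transfer
functions (tansig = tanh, logsig, satlins = clip to [−1,1], purelin),
and a linear 3-unit output trained on one-hot targets under summed
squared error. Inputs are z-score normalized with training-portion
statistics only. Three batch trainers:

- **Levenberg–Marquardt**: Gauss–Newton steps `(JᵀJ + μI)δ = −Jᵀr` with
  the exact per-sample Jacobian, μ adapted ×10/×0.1, stop on gradient
  < 1e−9 or μ > 1e10, iteration cap min(epochs, 100).
- **Rprop** (iRprop−): step sizes 0.07 initial, η⁺ = 1.2, η⁻ = 0.5,
  bounds [1e−6, 50].
- **Gradient descent** (plain or momentum 0.9) with bold-driver step
  control: the rate halves whenever the loss rises, so a fixed rate
  cannot diverge on wide inputs.

Prediction is the argmax of the output activations (softmax scores are
exposed for ROC use); ties resolve to the lowest class index. Training
is fully reproducible from the seed.

## ANN-PSO feature selection

Particles live in [0,1]^n with the canonical global-best update,
c1 = c2 = 2, inertia 1 with damping 1, velocities clamped to ±0.1 of the
range; defaults are 30 particles and 20 iterations. A position decodes
to a subset by thresholding at 0.5 (variable-size subsets, with an
argmax fallback so the subset is never empty), or by top-k positions
when a fixed cardinality is configured. Fitness is the validation
accuracy of a 10-neuron tansig LM network on a stratified 70/15/15
split, optionally minus `parsimony_weight` accuracy points per selected
feature. Whether the 6-feature outcome of the original study was fixed
or emergent is unknowable from the published material; both mechanisms
are exposed, and the reproduction preset (`reproduction_preset`) pins the
cardinality at 6 — a penalty of order 0.01/feature cannot pin an exact
cardinality within 20 iterations over 302 dimensions.

## ANN-BA architecture search

The bees algorithm searches the network design space (layer count,
5–25 neurons per layer, transfer functions, training algorithm,
learning rule). Scouts sample uniformly; the best sites recruit
neighborhood perturbations (neuron counts nudged within a shrinking
radius, categorical knobs swapped with probability 0.3), elite sites
more intensively. Spec fitness is mean validation accuracy over
stratified 3-fold CV on the training portion — a single small validation
split saturates at 100% on separable data and cannot rank specs — and
the winner is retrained on the full training portion. Default budget is
20 scouts / 5 sites / 2 elite / 10+5 recruits / 50 iterations, all
configurable; failures during a site's training are logged and scored 0.
The KNN reference uses k = 5 (unstated in the source material),
Euclidean distance on z-scored features, majority vote with ties broken
by smallest mean neighbor distance then lowest class index; its ROC
score is the neighbor vote fraction.

## Evaluation

Confusion matrices are 3×3 with rows = actual, columns = predicted, in
class order (rice, narrow-leaf, wide-leaf). Overall accuracy is
100·trace/total rounded half-up to two decimals to mirror tabulated
reporting. ROC curves are one-vs-rest threshold sweeps on continuous
scores with trapezoidal AUC; repetition statistics are the sample mean
and sample (ddof = 1) standard deviation.

## Synthetic scenes: what they emulate and what they do not

The generator renders three classes on a soil background: rice and
narrow-leaf weeds as thin rotated super-ellipses of similar size that
differ in hue and in the spatial frequency of a brightness stripe
pattern along the leaf — deliberately making them the confusable pair —
and wide-leaf weeds as broad ellipses. The right frame is the same
scene shifted horizontally by a fixed disparity with independent
per-pixel Gaussian photometric noise (sd 3 by default, clipped to
[0, 255]). Plant pixels satisfy the segmentation rule by construction
and soil pixels violate it, objects do not overlap, and the left/right
correspondence is exact — so segmentation, labeling and matching ground
truth are unambiguous.

This means passing tests demonstrate the internal correctness and
determinism of the pipeline, and the qualitative orderings (fusion not
hurting, the optimized network matching the reference) on separable
data. They do not demonstrate field performance: real paddy scenes have
occlusion, specular water, shadows, within-class variability and
imperfect correspondence, none of which are modeled. The published
field-data figures are treated as fixed worked examples (their
confusion matrices are verified arithmetically), not as reproduction
targets.

## Experiment sizes

The end-to-end stereo experiment uses 10 seeds × 6 stereo frame pairs
(360×480 px) × 9 objects per frame, PSO selection with 8 particles ×
5 iterations at fixed cardinality 24, and a bees budget of 6 scouts ×
2 iterations — sizes chosen so the full study runs in a few minutes on
one core while keeping ~17 held-out objects per category and seed. The
selection-recovery study uses 150-sample tables with 3 informative +
29 noise columns at 6σ separation, 10 particles × 8 iterations. The
acceptance script's preset run uses a 150-sample, 302-column table with
6 informative columns at 4σ.

## Known limitations

- The scene renderer is deliberately minimal (no occlusion by default,
  i.i.d. noise, hard object boundaries); it is a correctness harness,
  not a photorealistic simulator.
- Levenberg–Marquardt materializes the per-sample Jacobian; it is meant
  for the small networks searched here (hundreds to a few thousand
  parameters), not for wide inputs with large hidden layers.
- The channel-excess color indices outside RGB are reconstructions and
  should not be compared numerically against other implementations.
- One-vs-rest AUC is reported per class; no macro/micro multiclass AUC
  aggregation is provided.
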