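# Methods

This note documents the models, conventions and numerical choices behind
`maseg`, and what its synthetic-data experiments do and do not demonstrate.

## Imaging model and the phantom generator

The pipeline assumes AOSLO-style acquisitions: a stack of aligned grayscale
frames (intensities scaled to [0, 1]) in which perfused structures — MA
bodies and capillaries — show frame-to-frame intensity fluctuation from
moving blood cells, while the avascular background is static. The phantom
generator (`maseg.phantom`) emulates exactly the statistics the pipeline
consumes:

* **Flicker** is i.i.d. zero-mean Gaussian noise added per frame to the
  fixed structural intensity of every perfused pixel, with standard
  deviation `flicker_amplitude` (default 0.12 of the dynamic range). The
  perfusion map only measures temporal variance, so any zero-mean model
  with controlled variance is sufficient; temporal correlation of real
  blood flow is deliberately not modeled.
* **Background noise** is a single spatial Gaussian field (σ default 0.05)
  frozen across frames — static, as aligned-and-averaged tissue appears.
* **Structural contrast** is modest and *negative* in the raw frames
  (structures at 0.40 vs tissue at 0.65 of the dynamic range): perfused
  structures become bright only in the perfusion map and after the color
  inversion of the enhanced image, as in the real modality.
* **Distractor vessels** flicker identically to MA vessels but are excluded
  from the ground-truth mask; they reproduce the main confound of the
  segmentation task (background capillaries of similar size and contrast).
* **Geometry.** Bodies are disks, ellipses or fusiform (lens-shaped, two
  mirrored circular arcs) with `diameter` defined as the caliber of the
  largest inscribed disk; parent vessels are constant-width strokes from
  the body to the frame border (capillaries continue beyond any real crop);
  everything is rasterized on the integer pixel grid with the strict
  predicate `distance < D/2`. Default ranges (body caliber 20–40 px,
  vessel width 8–16 px, one or two MAs and one or two distractors on a
  128-px frame, 75 frames) correspond to the ~1 µm/px working resolution at
  which MA bodies of 20–100 µm and capillaries of ~8–16 µm are imaged.
* A seed fixes the full bundle bit-for-bit; overlapping bodies or
  sub-pixel vessel widths are rejected as ill-posed ground truth.

What passing phantom tests does **not** show: robustness to eye-motion
artifacts, optical blur, frame misalignment, non-Gaussian speckle, or
thrombosed (partially non-perfused) MAs — none of which the generator
emulates.

## Preprocessing conventions

* The perfusion map is the per-pixel temporal standard deviation with the
  **population convention** (ddof = 0); the choice is immaterial downstream
  because the map is min–max normalized, but it is fixed and tested.
* Min–max normalization maps a constant image to all zeros ("no signal")
  rather than dividing by zero.
* The denoise–enhance chain applies, in order: non-local-means denoising
  (patch 7, search window 21, strength 0.1× the dynamic range),
  normalization, CLAHE (clip limit 0.01, 8×8 tiles), gamma correction
  (γ = 0.8). The literature behind this modality names the algorithms but
  not their parameters, so all are exposed in `EnhanceParams`. The chain is
  applied to the perfusion channel only; the enhanced-image channel gets
  its own local-mean smoothing (window 5 px, odd, reflective border).
* Channel order of the two-channel image is fixed: 0 = enhanced,
  1 = perfusion. Images resample bilinearly, masks by nearest neighbor
  (preserving binarity).

## Augmentation reading

The augmentation count (63 sources × N = 32 → 2016 pairs) forces the
interpretation that rotation is a *deterministic enumeration* — one output
per angle 2πk/N — while flips (p = 0.5 each axis) and the scale factor
(uniform in (0.7, 1.4)) are drawn per rotation slot from the seeded stream.
Rotation is about the image center on a fixed canvas; scaling re-fits by
center-crop/zero-pad; vacated regions are filled with 0, matching the dark
static background.

## Network, loss and training policy

The network is a 5-level U-shape: a stem convolution block, five
pool-and-convolve encoder stages, and five decoder blocks (two 3×3
convolutions + ReLU each) that upsample (nearest ×2), concatenate the
matching encoder feature and convolve, ending in a 1×1 convolution with
sigmoid. It is implemented directly in NumPy with explicit
backpropagation — verified against finite differences to machine
precision — which keeps the package free of any deep-learning framework
and bit-reproducible on CPU. Two width presets exist: `efficientnet-b3`
(stage widths mirroring that feature pyramid, decoder (256,128,64,32,16))
and `tiny` for CPU-scale work. Pretrained encoder weights are not bundled;
`pretrained=True` raises.

The loss is `mean-BCE + α·(1 − softDice)`, α = 0.2. Conventions chosen
where the loss is often written loosely:

* BCE carries the standard negative sign and is normalized **per pixel**
  (mean, not sum) so α keeps the same meaning across image sizes.
* The Dice term uses **soft** Dice on probabilities (Σxy etc.) — the hard
  count is not differentiable — with +1 smoothing in numerator and
  denominator against empty masks, and enters as `1 − Dice` so the loss
  decreases as segmentation improves.
* Probabilities are clipped to [ε, 1−ε] (ε = 1e-7) before logarithms.

Training uses Adam (lr 0.001, weight decay 1e-8, classic L2-on-gradient),
batch 16 (8 at test scale), up to 200 epochs, and a plateau scheduler: after
`patience = 5` epochs without a validation-loss improvement the learning
rate is multiplied by 0.1. The returned model is the best-validation-loss
checkpoint. Non-finite losses abort with a diagnostic.

**Split protocol.** ⌊n/5⌋ images are reserved for test (reproducing 17 of
87 when n is not divisible by 5); the pool is shuffled once and divided
into 10 near-equal folds, each serving once as validation — 63:7:17 for
n = 87. Images are assigned at random, not grouped by subject; a grouped
split is a known refinement not implemented here.

## Postprocessing conventions

* Threshold 0.5 with `≥` mapping to foreground (measure-zero for sigmoid
  outputs, but fixed for testability).
* Fragment clearing removes 8-connected components with area **strictly
  below** 1024 px at 512×512 (a component of exactly 1024 px survives);
  at other working resolutions the default scales with the pixel area.
  8-connectivity is the tolerant choice for thin diagonal vessels.
* Ensembling selects the `n_selected = 3` highest validation-Dice models of
  `n_models = 10` (ties break toward the lower model index) and takes the
  pixel-wise OR. Clearing is applied per model before the union by default;
  union-then-clear is available by flag since the stage order is a genuine
  open choice.

## Morphometry

For each 8-connected component: the medial-axis skeleton and the Euclidean
distance transform give medial radii `d_i` (distance from skeleton pixel to
the nearest background pixel — no half-pixel contour correction, so pixel
calibers carry a ≤1 px positive bias that is exact for even-parity bands);
LC = 2·max d_i, NC = 2·mean of the 10 smallest d_i (all of them when the
skeleton is shorter), BNR = LC/NC. Distances are float pixels; µm values
are emitted only when the caller supplies a scale.

Three guards make NC usable on rasterized masks:

1. **Pre-smoothing**: a radius-1 binary opening before skeletonization
   (skipped if it would erase the object). Staircase boundaries otherwise
   sprout dendritic skeleton branches whose small radii corrupt NC.
2. **Spur pruning**: up to 3 terminal pixels are removed from every
   skeleton branch (length config-exposed).
3. **Border flagging**: a skeleton point whose distance to the image edge
   is ≤ its radius may have its true nearest background outside the frame;
   such points are excluded from the caliber statistics (with fallback to
   all points if every point is flagged). Without this, the open ends of
   border-cut vessels would bias NC low.

A single isolated pixel degenerates to N = 1, d₁ = 1.

## Scaled-down experiments

CPU-scale study conditions used by the test suite and the acceptance
script: 44 phantoms per replicate (32 train / 4 validation / 8 held-out),
two-channel inputs at 64×64, the `tiny` encoder, batch 8, 30 epochs, three
replicates with different seeds (median reported). The fragment-clearing
threshold scales to 16 px at 64×64. Morphometry recovery uses 20
single-MA phantoms, since per-MA truth matching is only unambiguous when
each mask contains one lesion. The cross-validation driver
(`run_cv_ensemble`) trains one model per fold and is exercised at one
epoch per fold in the tests; its selection and union logic is
scale-independent.

## Known limitations

* The NumPy network is CPU-bound and meant for small images; the
  full-width preset is architectural parity, not a performance claim.
* NC assumes the 10 smallest radii fall on the neck/vessels, which holds
  for correct segmentations with attached vessels but not for masks of
  isolated round bodies, where NC approaches LC.
* Phantoms do not model optical or motion artifacts (above), so reported
  Dice values characterize the pipeline's machinery, not clinical
  performance.
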