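# Methods

`episeg` implements an IHC-supervised pipeline for segmenting epithelium in
H&E-stained prostate histology. The supervision idea: a section stained with
H&E, then destained and restained with P63/CK8-18 immunohistochemistry, shows
the same tissue twice — once in the routine stain, once with all epithelium
chemically highlighted (CK8/18 via DAB marks glandular epithelial cytoplasm;
P63 via NovaRED marks basal-cell nuclei, present in benign glands only). Colour
deconvolution of the IHC image therefore yields a pixel-level epithelium
reference standard without manual outlining, and after registering the H&E
scan onto the IHC scan those masks supervise an H&E segmentation network.

## Stain model

Stains obey the Beer–Lambert law: in optical density, `OD = -log(I / I0)`,
stain contributions add linearly, `OD = M c`, with `M` the 3×S matrix of unit
stain colour vectors and `c` the per-stain concentrations. `stains.deconvolve`
inverts this system per pixel (Moore–Penrose inverse; for the 3-stain
matrices used here this is an exact inverse).

Numerical choices:

* Intensity floor `1/255` of the white point before the log, capping OD at
  `-log(1/255) ≈ 5.54`; avoids `-log(0)` on saturated pixels.
* Negative concentrations (noise, out-of-gamut colours) are preserved in the
  `ConcentrationMap` so deconvolution stays linear; they are clipped to zero
  only where a physical quantity is needed (mask thresholding).
* Default vectors: Ruifrok–Johnston haematoxylin `(0.650, 0.704, 0.286)`,
  eosin `(0.072, 0.990, 0.105)` and DAB `(0.268, 0.570, 0.776)`. NovaRED has
  no published consensus vector; the shipped default `(0.450, 0.800, 0.397)`
  (normalised) is a red-brown estimate with strong green absorption. All
  vectors are configuration, not constants: stain colour depends on the
  scanner and protocol, and slide-specific vectors should be substituted when
  known. The H&E matrix adds Ruifrok's orthogonal-residual third vector to
  make the 3×3 system invertible.
* The "epithelium channel" is the pixel-wise sum of the DAB and NovaRED
  concentrations: basal cells are epithelial, so both markers count.

## Reference-mask generation

`maskgen.ihc_reference_mask` chains: clip-negative → sum named channels →
threshold → binary closing → binary opening → optional polygon corrections.

* Default OD threshold 0.15 on the combined channel. Stain intensity varies
  substantially between slides, so an Otsu alternative (`otsu=True`) derives
  the threshold from the channel histogram instead.
* Structuring elements are discs of radius 1 px at the 0.48 µm/px working
  resolution for both closing and opening — the smallest non-trivial
  elements; the errors they are meant to remove are single-pixel cracks and
  speckle. Tiles are reflect-padded before morphology so border pixels behave
  as if the tile continued (a tile is a window into a slide, not an island).
* Corrections are simple polygons with a target label (`epithelium`,
  `background`, or `artefact`, the latter mapping to background since stained
  debris is not epithelium). Rasterisation uses pixel centres on the 0-based
  grid; self-intersecting polygons are rejected by index. Later polygons win
  on overlap (file order = precedence), and the changed-pixel fraction is
  reported — the analogue of auditing how much tissue human correctors
  relabelled.
* The tissue detector thresholds the summed OD of all three colour channels
  (default 0.10) and fills holes; glass background and empty gland lumina sit
  at the white point and fall below any positive threshold. This is a
  deliberate, simple stand-in for a learned tissue-background segmenter; it
  is exact on the synthetic data and adequate for tiles, not for scanner
  artefacts on real WSIs.

## Registration

The H&E image (moving) is registered onto the IHC image (fixed) — masks are
produced in the IHC frame and warped into the H&E frame. Because the two
renderings share structure but not colours, the data term is the Normalised
Gradient Fields (NGF) distance

    D(F, M) = mean_x [ 1 − ⟨∇F, ∇M⟩² / ((|∇F|² + ε²)(|∇M|² + ε²)) ]

which scores only the alignment of gradient directions and is invariant to
monotone intensity rescaling as ε → 0. The deformation is regularised by
curvature, `S(u) = ½ mean |Δu|²` per displacement component, which is zero
for affine fields — the regulariser penalises only non-affine bending.

Chain: grayscale → affine (multi-resolution NGF minimisation with a coarse
translation sweep; identity returned if nothing improves) → dense
nonparametric descent on `NGF + α·curvature` over a 4-level pyramid →
patch-wise refinement with optimised merging. Displacement fields use the
backward convention (fixed-frame pixel → moving-frame sample position),
row-major, 0-based pixel centres.

Numerical choices, each of which mattered in practice:

* **ε** defaults to 1% of the fixed image's intensity range per pyramid
  level.
* **Grayscale pre-smoothing** (σ = 0.5 px). NGF treats every gradient
  direction as signal; uncorrelated sensor noise at the finest level
  otherwise dominates the distance. Heavier smoothing (σ = 1) measurably
  biases recovered edges; σ = 0.5 was the best accuracy on synthetic pairs
  with known warps.
* **α = 30** (curvature weight). With weak regularisation (α ≈ 0.1) the
  optimiser reaches a *lower* NGF value than the true deformation by fitting
  noise — the data term alone cannot identify the smooth restaining warp.
  Restaining deformations are physically smooth, so strong curvature
  weighting is the correct prior; on synthetic pairs it roughly halves the
  displacement error.
* **Sobolev (smoothed-gradient) descent** (σ = 4 px): the raw pointwise
  gradient direction is full of incoherent local minima; smoothing the
  *update direction* (not the objective) makes steps spatially coherent and
  lets descent ride the global-translation valley. Armijo backtracking on the
  true objective preserves the accept-only-improvement contract.
* **Gradient floor**: dense descent stops when `max|g| · n_pixels < 0.1`.
  The mean-normalised NGF gradient scales as 1/n; below this floor the
  remaining "gradient" is resampling/discretisation artefact and stepping on
  it only drifts the field (observable as ~0.15 px drift when registering an
  image to itself).
* **Laplacian**: 5-point stencil with linear-extrapolation boundary rows, so
  affine fields have exactly zero curvature including at the border.
* **Patch merging**: each patch is refined independently, then the merged
  field minimises `Σ_p w_p|φ − φ_p|² + µ Σ_x v(x)|Δφ(x)|²` with raised-cosine
  patch windows `w_p` and `v` the local inter-patch disagreement (weighted
  variance of the patch fields). Where patches agree the data term pins the
  merged field to the common solution exactly (single patch and identical
  patches are bit-exact pass-throughs); smoothing acts only in overlap
  regions that actually disagree.

On synthetic multimodal pairs (same geometry, different stain rendering,
known smooth warps of max 5 px) the full chain recovers the deformation with
a mean error of ~0.1–0.3 px over tissue; accuracy is verified against the
numerically inverted generating field (`registration.invert_field`,
fixed-point iteration).

## Networks

Two U-Net variants with three shared modifications: residual (additive)
shortcuts inside every two-convolution block (1×1 projection when channel
counts change), bilinear-interpolation up-sampling followed by a 3×3
convolution instead of transposed convolution, and "same"-padded
convolutions so the output mask matches the input size (a patch side must be
divisible by `2^(depth−1)`).

* IHC net: depth 5, filters (32, 64, 128, 256, 512) — 8.99 M parameters.
* H&E net: depth 6, filters (16, 32, 64, 128, 256, 384) — 7.35 M parameters.
  The extra level buys receptive field (which helps reject stained debris);
  the per-level filter counts are lowered so the deeper net is still the
  smaller one. With the residual projections and up-path convolutions
  counted, a 512-wide bottleneck would not have achieved that, hence 384.

Blocks are conv–BN–ReLU, conv–BN, shortcut add, ReLU. Initialisation is He
normal under a caller-supplied seed; the whole forward pass is deterministic
NumPy, so identical seeds give bitwise-identical untrained outputs.

Whole-image inference tiles the image with overlapping windows and discards a
halo from each tile; with a halo at least the receptive-field half-width
(32 px for the depth-3 test net) tile interiors agree with a whole-image pass
to float32 precision. The binary mask is the per-pixel argmax with exact ties
resolved to background.

The compute backend (`episeg.nn`) is a small NumPy engine — im2col + BLAS
convolutions, batch normalisation, 2×2 max pooling, an exact separable
bilinear ×2 up-sampler with its adjoint, weighted softmax cross-entropy and
Adam — with hand-written backward passes, verified against central-difference
gradients. It is sized for the desk-scale experiments here, not for
GPU-scale training.

## Training

* Loss: per-pixel weighted softmax cross-entropy. The class-occurrence
  weights are `w = 1 / (2 max(f_c, f_min))`, where `f_c` is the fraction of
  the patch occupied by the pixel's class and `f_min = 1/(patch area)` floors
  the weight when a class has only a few pixels; the map is then renormalised
  to mean exactly 1, which makes the loss magnitude independent of the class
  mix (balanced patches get unit weights; the conservation is asserted for
  every emitted patch). This is the mechanism that makes patches containing
  only a few isolated tumour cells matter to the gradient.
* Sampling: `uniform_over_classes` draws the centre-pixel class uniformly
  from {epithelium, background}, then a centre uniformly within that class
  (falling back to the other class, with a logged warning, if a slide lacks
  one); `artefact_oversampled` samples centres over tissue with annotated
  artefact regions given 3× density (the factor is configuration; the intent
  is to concentrate supervision where non-specific staining causes false
  positives). Patches overhanging the border are completed by mirror
  padding.
* Augmentation: flips, 90° rotations, random scaling, additive Gaussian
  noise, Gaussian blur, brightness/contrast/saturation, and
  haematoxylin–eosin colour-space perturbation (deconvolve → scale channel
  concentrations → re-render). Geometric transforms are applied identically
  to image, labels (nearest) and weights; photometric ones to the image only.
* Optimisation: Adam, β1 = β2 = 0.99, initial rate 5e-4, batch size 1. The
  validation loss is evaluated before training (the plateau baseline) and
  after each epoch; after `patience` consecutive epochs without improvement
  (tolerance 1e-4) the rate is halved and the counter resets — patience 5
  for the IHC setting, 10 for H&E. The realised rate sequence is a
  deterministic function of the validation sequence
  (`training.simulate_lr_schedule` reproduces it exactly), and the
  best-validation weights are restored at the end. Validation loss, not F1,
  is the plateau signal — the conventional choice; nothing here depends on
  the difference.

## Evaluation

Pixel counts with epithelium positive; accuracy, F1 (Dice) and Jaccard with
`F1 = 2J/(1+J)` asserted as an identity. An optional exclusion mask removes
pixels from scoring — used for gland-level reference data that includes
lumina: everything failing the total-OD tissue criterion (background and
empty lumina) is excluded. Degenerate regions: with no true positives, F1
and Jaccard are 1 if nothing was predicted or expected positive, else 0; a
fully-excluded region is an error, not a silent zero. Stratified reports
give N, mean ± sd (min, max) of per-region F1 and mean accuracy/Jaccard per
stratum; the aggregate accuracy/Jaccard columns are per-region means to match
the F1 column, with a pooled-pixel alternative behind a flag.

## Synthetic data

The generator produces the study conditions for every test: 256–512 px
tiles at a nominal 0.48 µm/px containing benign glands (epithelial ring,
thin basal layer, empty lumen), small malignant glands (no basal layer,
smaller lumen) and single-cell strands (no lumen, the grade-5-like pattern),
placed without overlap by rejection sampling; all masks derive from the
generating geometry. Rendering goes through the package's own Beer–Lambert
forward model, so deconvolution is exact by construction before sensor noise
(σ = 0.012 additive Gaussian) is added. The two modalities share geometry:
nuclei positions are common; the fibrous stroma texture — the same physical
collagen — appears as eosin in H&E and as faint haematoxylin counterstain in
IHC. Epithelial eosin levels overlap the stroma texture range, so H&E
segmentation genuinely requires context (nucleus density, structure), not a
colour threshold. Artefact blobs (corpora-amylacea-like debris) are placed
only inside lumina and take up DAB despite not being epithelium — the false
positive source the correction workflow exists for. Restaining deformation
is a smooth random field (Gaussian-filtered noise, normalised to a maximum
displacement, default smoothness 20–40 px).

What the synthetic data does *not* emulate: real stain variability between
slides and within slides, scanner artefacts, tissue folds, inflammation,
out-of-focus regions, and the sheer scale of whole-slide images. Passing
tests therefore demonstrate the correctness and internal consistency of the
algorithms, and that the two-stage supervision design works when its
assumptions hold — not clinical-grade segmentation accuracy on real slides.

## Desk-scale experiment sizes

The end-to-end experiments run the full design at sizes chosen for a single
CPU: the headline two-stage run trains a depth-3, 8-filter U-Net on 64
patches of 128×128 from 8 tiles (labels from the IHC pipeline, warped into a
deformed H&E frame by the generating field, standing in for the registration
output), 35 epochs, and scores pooled F1 on three held-out tiles against
geometric truth (≈ 0.93 at the default seed). The supervision-quality
comparison trains corrected vs artefact-corrupted label arms (identical
seeds and initialisation, 96 px patches, 10 epochs, 3 repeats) on
artefact-laden scenes and compares held-out F1; the corrected arm wins
consistently, mirroring the motivation for manual mask correction. These
sizes are the package's own defaults; all are parameters of
`episeg.experiments`.

## Known limitations

* The NumPy training engine is single-threaded BLAS; it trains toy nets in
  minutes but is not a route to the full-size networks.
* The tissue detector is threshold-based; heavily pigmented artefacts on
  real slides would pass it.
* Registration hyper-parameters were chosen on the synthetic generator; real
  restained pairs (different noise, partial tissue loss) may need α and the
  smoothing scales revisited.
* NovaRED's stain vector is an estimate; on real slides measure it (e.g. from
  a single-stain control) and override the preset.
* The patch-merge solver smooths only where patches disagree; it does not
  re-evaluate the image data in the overlap, so it cannot fix a patch that
  converged to a wrong local optimum.
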