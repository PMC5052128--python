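# Methods

`slicseg` implements a minimally-interactive pipeline for segmenting a
single organ (the motivating case is the placenta) from sparsely sliced,
motion-corrupted MRI volumes acquired in multiple views. This note records
the model, the numerical choices, what the synthetic data emulates, and the
limits of what the tests demonstrate.

## Phase 1 — single-volume segmentation

The user draws foreground and background scribbles in one *start slice*.
Every pixel is described by features of the 9×9 patch centred on it
(reflect padding at slice edges):

* intensity mean and standard deviation (2 features; alone they form the
  "low-level" set used by the `lowlevel` ablation);
* four Haralick statistics — contrast, correlation, energy, homogeneity —
  of an 8-level gray-level co-occurrence matrix, averaged over the four
  symmetric unit offsets (0°, 45°, 90°, 135°). The patch is quantized
  between its own min and max, which makes these features invariant to the
  per-slice multiplicative gain that corrupts interleaved acquisitions;
* seven Haar-wavelet summaries of the patch's leading 8×8 crop: mean
  absolute detail coefficient of the six subbands of a 2-level orthonormal
  2D transform, plus the level-2 approximation mean (a constant patch of
  value *c* maps to approximation 4 *c*).

The classifier is an **online random forest**: N = 20 trees of maximum
depth D = 10. Online bagging replaces the bootstrap — each incoming sample
is replicated k ~ Pois(λ), λ = 1, independently per tree. A leaf stores
weighted class counts; its posterior is the positive fraction; the forest
posterior is the plain average over trees (an untrained leaf returns 0.5).
The classic batch algorithm does not say when an online node should split;
here a leaf buffers its samples and splits once it holds ≥ 20 (weighted)
samples of both classes and its depth allows, choosing the
information-gain-maximising split over ⌈√F⌉ random features × 10 random
thresholds drawn uniformly within the buffered range. Buffers are capped at
10⁴ rows per leaf (splits beyond that use the buffered subset). Every tree
owns an RNG stream spawned from the forest seed, so results are independent
of tree iteration order and bit-reproducible.

The forest posterior feeds a per-slice **CRF**: data term −log p (posterior
clamped to [10⁻⁶, 1−10⁻⁶]) plus a contrast-sensitive Potts term
λ₁ B_ij [c_i ≠ c_j] over the 8-connected in-plane neighborhood, with
B_ij = exp(−(I_i−I_j)²/2σ₁²)/dist(i,j) and dist in mm (under 4-connectivity
the 1/dist factor would be vacuous, which is why the neighborhood is
8-connected). Defaults λ₁ = 40, σ₁ = 2.5. The binary energy is submodular,
so one s–t min cut yields the exact global optimum. Scribbles are hard
constraints in the start slice only.

**Propagation**: from the start slice the segmentation spreads in both
directions independently, each direction with its own copy of the
start-slice forest (this removes any dependence on processing order). After
a slice is segmented, new training data are harvested automatically from
its labels: the morphological skeleton of the foreground as positive
samples and the background eroded by a disk of radius 10 px as negative
samples — both deliberately far from the boundary, so a small labeling
error is unlikely to contaminate the training set. Harvesting uses the
largest connected component of the previous labels (the organ is a single
structure; islands are artifacts). The forest is updated online (skipped by
the `offline` ablation) and the next slice is predicted and regularised.

A direction stops when the foreground falls below `stop_min_fg_px = 20`
pixels (the organ has ended) **or** exceeds `stop_growth_factor = 2` times
the start-slice area. The second trigger is this package's addition: the
start slice lies in the organ's widest region, so such growth can only mean
the self-training has failed (observed failure mode: a mislabeled rim
contaminates the harvested skeleton and inflates by ~1.5× per slice until a
whole slice flips foreground). The offending slice is discarded and the
direction halts. Slices never reached keep probability 0 and label 0.

**Ablation variants** differ from the full pipeline in exactly one
component: `offline` never updates the forest after the start slice;
`lowlevel` uses only the two intensity features; `nocrf` replaces the CRF
by thresholding at 0.5, keeping the largest connected component, then
morphological opening and closing with a disk of radius 2 (the radius is
this package's choice).

## Phase 2 — multi-volume refinement

K volumes of the same subject, acquired in different views, are segmented
jointly by one min cut over the union of all voxels. The energy keeps each
volume's data term (−log P_k from phase 1) and in-plane intensity term, and
adds two couplings:

* **inter-slice** (within a volume): face-adjacent voxels of consecutive
  slices, weighted λ₂ exp(−(ΔP)²/2σ₂²)/dist with dist = slice spacing;
* **inter-volume**: each voxel is paired with its physically nearest voxel
  in any *other* volume (rigid view transforms map grids into a common
  space; pairs are deduplicated), weighted λ₃ exp(−(ΔP)²/2σ₃²) with no
  distance factor — the constant weight of these edges is folded into λ₃.

Defaults λ₂ = 10, λ₃ = 3, σ₂ = 0.005, σ₃ = 0.08. Both couplings use
probability contrast rather than intensity, which makes them robust to the
appearance differences between slices and between views. Note what this
implies: with σ₂, σ₃ this small, the couplings act only where the two
posteriors already roughly agree (|ΔP| ≲ 2σ). The refinement therefore
arbitrates *label* disagreements in regions of agreeing probability —
smoothing jagged through-plane surfaces and rescuing slices where one
volume's per-slice CRF went wrong while its posterior stayed moderate — but
it cannot overturn a confidently wrong posterior. Discrepancies between
views are penalised softly rather than constrained away because the
inter-view alignment is never perfect.

With K = 1 the inter-volume term is empty and the refinement reduces to a
3D probability-based smoothing of a single volume.

## Exact min cut on scipy

No dedicated graph-cut library is assumed; the solver is
`scipy.sparse.csgraph.maximum_flow`. Float costs are scaled to integers.
The solver's internals are 32-bit, so the scale adapts per problem:
`scale = min(2²¹, (2³¹−16)/(max node incident cost + 1))`, keeping every
capacity below 2³¹ while retaining ~5·10⁻⁷ absolute resolution per term at
the default scale. Hard constraints get a terminal capacity of
`1 + (sum of all other capacities incident to that node)` — a minimum cut
can never pay it, which is exactly the "effectively infinite" semantics —
without risking overflow. The cut partition is recovered by breadth-first
search on the positive residual graph. Exactness is verified against
exhaustive enumeration on ≥ 200 random instances in the test suite.

## The phantom: what it emulates, and what it does not

Because the pipeline's inputs are clinical scans that cannot be shipped,
the `phantom` module generates studies with known ground truth. One
continuous scene is sampled on each view's grid, so the inter-view
transforms are exact by construction (emulating externally registered
volumes). The scene and acquisition model:

* **object**: a crescent (sphere minus off-centre sphere) or ellipsoid,
  ~60–70 mm across, in a 96 mm cube; every slice's cross-section is
  connected;
* **boundary**: intensity ramps linearly from background to foreground
  level over ±2 mm around the surface (point-spread/partial-volume blur),
  and all texture fades proportionally inside the ramp. As a result the
  noiseless phantom is *exactly* separable by a threshold at the midpoint
  of the class means — the blur widens the uncertain band without moving
  the crossing;
* **contrast**: foreground 120, background 60–107 in arbitrary units — a
  deliberately weak-boundary regime (the clinical problem this method
  targets), with noise σ = 2.5 so that same-tissue neighbor differences
  match the CRF contrast scale σ₁ = 2.5;
* **texture**: the background holds three stripe-textured bright blobs
  (confounding tissue; capped below the class midpoint so separability
  survives) over a slowly undulating base; the foreground carries a fine
  ~2.5 mm speckle. These give the gain-invariant GLCM features real
  discriminative content;
* **per-slice gain**: a multiplicative log random walk with increment
  sd 0.015 per slice, anchored at the middle slice — the slow
  inhomogeneity of interleaved acquisition. Offline-trained classifiers
  degrade with distance from the start slice under this drift;
* **motion**: each slice is independently translated in-plane by a
  N(0, 1 mm) shift, baked into both intensities and ground truth —
  the residual misalignment that survives registration;
* **views**: view k's sparse axis points along a different common axis
  (cyclic permutation), and the default spacings are 1×1×4 mm and
  1×1×6 mm — complementary through-plane resolution, as with axial and
  sagittal acquisitions.

Auto-generated scribbles follow the skeleton of the eroded foreground and
(for background) a band close to the organ, as a careful user would; point
order is recorded so prefixes of a stated length are well defined.

The phantom reproduces the geometric and statistical failure modes the
method addresses — weak boundaries, confusable texture, slice-wise gain,
inter-slice motion, anisotropy — but not MRI physics, anatomy, or
view-dependent contrast. Two consequences for interpreting results: the two
views' posteriors are near-identical functions of one scene, so the
inter-volume coupling has genuinely complementary information only where a
view's propagation degrades; and phase-1 accuracy on the phantom
(Dice ≈ 0.90–0.92, sub-voxel boundary error) is higher than on clinical
data, which leaves the refinement less room to improve than in the
motivating setting. The measured refinement effect on healthy seeds is a
~0.002 Dice decrease (the inter-volume edges couple the two views' boundary
rims at motion-misaligned positions), and a substantial increase exactly
when a view's propagation fails. On this phantom the CRF weight λ₁ is also
load-bearing: dividing it by 4 costs ≈ 0.09 Dice, a sharper response than
the flat robustness the method exhibits on higher-contrast data.

## Evaluation metrics

Dice overlap 2|A∩B|/(|A|+|B|) (both-empty is an error); average symmetric
surface distance in mm with surfaces defined by face-connectivity
(mask voxels with a 6-neighborhood background neighbor; image borders count
as background) and exact Euclidean distances via spacing-aware distance
transforms; Fleiss' kappa over ≥ 2 raters treating each voxel as a subject
rated into two categories (observed agreement = mean pairwise agreement per
voxel; chance agreement = sum of squared overall category proportions).
Kappa is pooled over the voxels of one grid; when several volumes are
compared, compute it per volume and aggregate explicitly.

## Problem sizes used by the tests

The acceptance suite runs the end-to-end study on 96×96×24 two-view
phantoms over 10 seeds, the ablation comparison on the same geometry
(single view, 10 seeds), and the parameter-robustness sweep on 3 seeds with
phase-1 results shared across the coseg-only parameter variations. Unit
tests use 48–80 px grids. Exhaustive-enumeration checks cover all 2⁹–2¹⁶
labelings of small random instances.

## Known limitations

* Binary segmentation only; one foreground structure per volume.
* The online split rule (accumulate-then-split) is one of several
  reasonable adaptations of batch forests; trees never restructure, so a
  badly placed early split persists (mitigated by the ensemble).
* Self-training can still fail on a slice whose appearance jumps; the
  growth guard truncates such failures instead of repairing them.
* Inter-volume correspondences are nearest-voxel pairs under rigid
  transforms; per-slice motion inside each volume is not corrected when
  pairing, so coupled boundaries carry that misalignment.
* The CLI reads whole volumes into memory; very large studies (≫ 512³)
  would need streaming feature extraction.
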