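# Methods

`lobule3d` reconstructs the principal components of liver lobule tissue —
bile canaliculi (BC), sinusoids, nuclei, hepatocytes, hepatic stellate
cells (HSC), Kupffer cells (KC), and the central/portal veins (CV/PV) —
from co-registered multi-channel 3D fluorescence stacks, and derives a
single-cell morphometric atlas from the reconstruction.  This note records
the models, the defaults and why they were chosen, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Data model

All volumes are isotropic voxel lattices in `(z, y, x)` order with a
physical voxel edge of 0.3 µm by default (the acquisition scale the
pipeline is designed for).  Physical coordinates are `index ×
voxel_size_um`.  Anisotropic input is rejected rather than resampled: every
downstream step (distance transforms, radii, meshes) assumes isotropy, and
silent resampling would move every measurement.

Channels are named semantically: `dapi` (nuclei), `phalloidin` (actin:
cell borders, BC, sinusoid walls), `cd13` (BC), `flk1` (sinusoids),
`desmin` (HSC), `f480` (KC), plus `cv_mask`/`pv_mask` for the large veins
and `v_cd13`/`v_flk1` for virtually stained channels.

## Virtual staining

Two tubular networks (BC, sinusoids) are predicted from the single
phalloidin channel by a 3D convolutional encoder–decoder with U-Net
topology: 3 encoder–decoder levels, 3×3×3 convolutions with ReLU,
max-pooling downsampling, learned 2×2×2 transposed-convolution upsampling,
skip connections by concatenation, and a linear 1×1×1 regression head.  It
is trained on non-overlapping 64³ patch pairs (phalloidin → target
channel) with stochastic gradient descent, momentum 0.9, learning rate
0.05, batches of 8, for up to 100 epochs; the loss is mean squared error
(the canonical regression loss — nothing in the problem demands a robust
or perceptual loss), and the weights with the best validation loss are
retained.  No augmentation is applied; the train report records this.

The network is implemented directly on numpy arrays with explicit
backpropagation; convolutions are evaluated as im2col matrix products so
the arithmetic runs in BLAS.  This keeps the dependency surface small and
makes training bit-reproducible for a fixed seed on one platform.  The
filter width is configurable (64 per layer at full scale); desk-scale runs
and the test suite use 8 filters and 32³ patches, which train in minutes
on one CPU while exercising the identical code path.

Full-stack inference tiles the volume with an 8-voxel overlap and blends
overlapping predictions with linear ramp weights; a volume that fits in
one tile is processed in a single pass, and the tiled result equals the
direct one there.  Input normalization (percentile (1, 99) to [0, 1]) is
part of the model state: the same affine map is stored in the checkpoint
and applied at prediction time.

Prediction quality is scored by voxelwise Pearson correlation against a
reference channel, by the signal-to-background ratio (SBR: mean intensity
over the reference foreground ÷ mean over the background, foreground by
Otsu of the reference), and by intensity profiles along user-drawn 3D
segments.

## Segmentation

Structures are segmented by **maximum-entropy (Kapur) thresholding**: the
cut of the 256-bin histogram maximising the summed Shannon entropies of
the normalized sub-histograms below and above the cut, ties to the lowest
level.  The implementation is verified exactly against an exhaustive
search over all cuts.

Locality: thresholds are computed on overlapping blocks (default 64³,
stride half a block) against a shared intensity scale and trilinearly
interpolated into a smooth threshold field.  Two robustness rules matter
in practice:

* a block whose intensity spread is below half the global spread contains
  no full-contrast structure; it inherits the global threshold instead of
  entropy-splitting its own noise;
* each entropy cut seeds a few intermeans (ISODATA) iterations — threshold
  → midpoint of the two class means, repeated to convergence.  On
  PSF-blurred structures the raw entropy cut sits low on the blur ramp and
  inflates thin structures by a halo roughly one blur-sigma thick; the
  class-mean midpoint lands at half-maximum, which is the unbiased surface
  for a blurred step edge.  The refinement is disabled for DAPI, whose
  foreground intensities span the ~4× ploidy range: there the class-mean
  midpoint would sit above the dimmest diploid nuclei, so DAPI is
  percentile-clipped (1, 99) first (compressing the bright classes) and
  thresholded with the plain entropy cut.  DNA content is integrated on
  the raw channel, never the clipped one.

Cleanup is closing (radius 1), 3D topological hole filling, optional
opening (default off — a radius-1 opening measurably erodes 2-voxel
tubes), and removal of components below a minimum volume (default 0.5 µm³).
A constant image yields an empty mask.

**Nucleus splitting** is a distance-transform watershed: seeds are h-maxima
of the Euclidean distance transform (default depth 0.3 µm, suppressing
digitisation maxima), ties broken deterministically by label order.  Every
foreground voxel gets exactly one label and foreground is conserved.

**Meshes** come from marching cubes at the 0.5 iso-surface of each label
(padded so border-touching objects close), relaxed with Taubin smoothing —
a constrained two-pass Laplacian that preserves volume to first order
(default 10 iterations, relaxation 0.1).  Mesh volume agrees with voxel
counting within 10 % for objects larger than ~10³ voxels.

**Cell expansion**: hepatocyte bodies are grown from their nucleus seeds by
a marker-controlled watershed on the phalloidin intensity, masked away
from all other structures (veins, both networks, HSC/KC bodies).  A
binucleate cell initially splits into two basins with no real membrane
between them; adjacent basins are therefore merged when the mean
phalloidin intensity on their shared interface is unusually low.  The
merge threshold is found from the interface-mean distribution itself
(Otsu, capped at 0.7× the median wall intensity so that a field with no
spurious interfaces merges nothing).  Cells touching the image border are
flagged `edge_object` and excluded from per-cell statistics, since partial
cells bias volume and contact metrics.

## Centerline graphs

Tubular masks are thinned to one-voxel skeletons (topology-preserving 3D
thinning).  Every skeleton voxel becomes a graph node; 26-adjacent voxels
are joined by edges carrying their Euclidean step length.  Spur branches
shorter than twice the local radius at their base junction are pruned as
thinning artifacts.  Node radii are read from the Euclidean distance
transform of the mask with two sub-voxel refinements: the distance is
maximised over the node's 3³ neighborhood (thinning can leave the skeleton
one voxel off the medial axis of a thick curved tube), and a quarter voxel
is subtracted (the net of the half-voxel centre-to-surface offset and the
average over-coverage of a rasterised tube).  On rasterised capsule
networks of radius 2–8 voxels this recovers generating radii with a pooled
median relative error well under 10 %; thin 2-voxel tubes are the hardest
case (+digitisation bias ≈ 0.2 voxel).

Connectivity is the number of connected components of the node graph; a
network is fully connected iff there is exactly one.

## Morphometry

* **Shape**: per-object axis lengths from the eigen-decomposition of the
  voxel covariance (a solid ellipsoid with semi-axis *a* has second moment
  *a*²/5), elongation = 1 − A3/A1 with A1 ≥ A2 ≥ A3, so a sphere scores 0
  and a filament approaches 1.  The literature also prints the inverted
  ratio 1 − A1/A3, which is negative for non-spheres; that variant is
  available as `elongation_formula="as_printed"` for auditability, but the
  bounded form is the default.  Single-voxel objects score 0 by convention.
* **DNA content**: the integral DAPI intensity over each nucleus's voxels
  (the voxel-domain equivalent of integrating inside the surface mesh),
  with the median outside-nuclei intensity × voxel count subtracted and
  floored at 0.  Raw and corrected values are both reported, since the
  integral is offset-sensitive.
* **Ploidy**: classes 2n/4n/8n/16n by rounding log₂(content / reference).
  The diploid reference can be fitted automatically by a 1D k-means whose
  four centers are constrained to the ratios 1:2:4:8 — the geometric
  constraint encodes genome doubling — with several quantile-anchored
  starts (the alternating fit has local optima when diploids are not the
  dominant class); the lowest within-cluster cost wins.
* **Nuclearity**: nucleus → cell by maximal voxel overlap (ties to the
  lower cell id); a cell's class string is `k×pn` from its nucleus count
  and their maximal ploidy class, with a `mixed` flag for heterogeneous
  multinucleates.
* **Volume fraction**: structure ∩ tissue / tissue, where tissue is the
  field minus the CV and PV masks.
* **Contact surfaces**: a cell's surface is its 6-connected boundary
  shell; a surface voxel contacts a structure if any structure voxel lies
  within `contact_radius_um` (default 0.3 µm = one voxel — the minimal
  consistent reading of "contact"; configurable).  Percentages per
  structure are independent, so a voxel may count toward several.
* **Contact sites**: the contact region of an object pair is the set of
  first-object voxels within the contact radius of the second; its
  26-connected components are the sites.  Counts are reported per pair and
  per object in both orientations, since "sites per KC" and "sites per
  HSC" differ.
* **Inter-nuclear distance**: surface-to-surface, not centroid-to-centroid
  — a 2 µm proximity criterion is far smaller than a nuclear diameter, so
  centroid distance cannot be meant.  Touching nuclei score 0 (adjacent
  voxels are one step apart, and one voxel step is subtracted).  Per
  type-pair the nearest-neighbor distribution and the fraction below the
  proximity threshold (default 2 µm) are reported.

The atlas joins per-cell and per-nucleus records with per-(type,
parameter) mean, s.e.m. (sd/√n; 0 with an n = 1 flag for singletons), and
n, excluding edge objects, with the config hash and seeds as provenance.

## Zonation

The CV→PV coordinate is the normalized two-sided distance transform
c = d_CV / (d_CV + d_PV), 0 on the CV surface and 1 on the PV surface —
the simplest field with the required boundary values; a straight-axis
projection variant is available behind `zonation_mode` for comparison.
The implementation branches on the smaller distance so that swapping the
veins yields the complement to machine precision (the equidistant midline
is exactly 0.5).  Vein voxels are undefined (NaN).  Objects are assigned
to one of ten equal-width zones (zone 1 at the CV) by their mean
coordinate, `zone = 1 + floor(c·n)` clamped; network radii are zonated
per centerline node, since a radius-versus-position profile needs
per-node positions.  Profiles report per-zone mean ± s.e.m. and n, with a
voxel-weighted variant (zone structure volume / zone tissue volume) for
volume-fraction profiles.

## Synthetic lobule generator

The generator emulates the six-marker panel between two vein cylinders at
opposite x-ends of the field, with full ground truth (masks, instance
labels, centerline graphs, per-nucleus ploidy and DNA content, per-cell
nuclearity), so that every downstream stage has a parameter-recovery test
against known truth.

* **Tube networks** are random smoothed spline paths spanning the field,
  with branches rooted on the existing network so the result is one
  connected component; masks are unions of capsules stamped with exact
  fractional-center inclusion (no lattice-rounding dilation), and the
  generating chain (positions + radii) is returned as the oracle graph.
  This is statistical structure sufficient to test connectivity, radius
  and zonation code — not a physiological vascular model.
* **Hepatocytes** grow simultaneously from minimum-separation seeds
  (nearest-seed geodesic flooding of the free space), giving convex-ish
  space-filling cells with an exact requested count.  Each cell gets 1 or
  2 ellipsoidal nuclei per the binucleation fraction (two-nucleus
  placement retries with relaxed separation before falling back, so the
  realised fraction tracks the requested one), a ploidy class per the
  configured fractions, and a DNA content = class multiplier × base with
  10 % lognormal jitter.
* **HSC/KC** are thin curved capsules with a nucleus bulge, placed with
  density ∝ c^a(1−c)^b along the CV–PV coordinate — KCs with an interior
  hump (a = b = 2), HSCs U-shaped toward both veins (a = b = −0.5),
  reproducing the anti-correlated zonal pattern of the two populations.
  Cells keep a 4-voxel mutual gap so neighbours remain resolvable after
  PSF blur, as real sparse NPC populations are.
* **Rendering**: DAPI intensity is uniform per nucleus with integral
  proportional to true DNA content (scaled so a typical diploid nucleus
  is near unit intensity); phalloidin is the union of hepatocyte boundary
  shells (0.55), sinusoid wall shells (0.78) and the BC mask (1.0) — the
  brightest, tube-shaped phalloidin structure is the BC, which is what
  makes virtual staining learnable from this channel; the four marker
  channels are their structure masks.  All stained channels are blurred
  with a Gaussian PSF (default σ = 0.2 µm) and corrupted with additive
  Gaussian noise (default sd 0.04 of the unit signal); the vein masks
  pass through clean.

Default study conditions: 128³ voxels at 0.3 µm (a 38.4 µm cube — a
scaled-down lobule section sized for one CPU), 90 hepatocytes of ~400 µm³
(ploidy 2n/4n/8n at 60/30/10 %, 30 % binucleate), sinusoids of mean radius
1.35 µm (~9 % of tissue volume), BC of 0.62 µm (~3 %), 16 HSCs and 16 KCs.
Real adult tissue has larger cells (~4500 µm³), a denser sinusoidal bed
(~25 %) and thousands of cells per field; the miniature keeps the same
relative geometry (tubes thinner than cells, NPCs sparse and elongated) at
tractable size.

**What passing recovery tests shows — and does not.**  Recovery of
generator parameters demonstrates that the measurement chain (threshold →
split → expand → count/measure) is unbiased under the generator's imaging
model: uniform staining intensity, Gaussian PSF and noise, no shading,
no autofluorescence, no clearing artifacts, convex-ish cells.  Real tissue
violates all of these to some degree, so passing here validates the code,
not biological accuracy on any particular dataset.

## Numerical choices

* Axis order `(z, y, x)` everywhere; 26-connectivity for foreground
  throughout (consistent with the thinning operator); watershed ties by
  label order for reproducibility.
* One seeded RNG stream per generation; identical parameters + seed give
  bit-identical images.  Training is curve-reproducible for a fixed seed
  on one platform; everything else is bit-reproducible, which the run
  manifest checks via artifact checksums.
* Degenerate inputs are defined, not fatal: constant image → empty mask;
  empty mask → empty skeleton/labeling; single-voxel object → elongation
  0; a nucleus type with no partner is skipped with a warning.

## Limitations

* The active-mesh machinery of interactive reconstruction tools is
  replaced by measurable surrogates (Taubin smoothing for surface
  refinement, marker-controlled watershed for cell expansion); the
  contracts preserved — smooth closed surfaces, nucleus-seeded space
  partition — are what the tests verify.
* Denoising/shading correction beyond an optional Gaussian hook is out of
  scope; heavily shaded real stacks would need external preprocessing.
* The ploidy reference fit assumes classes at genome-doubling ratios; a
  population with aneuploid intermediates would need an unconstrained
  mixture model.
* Apical/lateral/basal membrane subdomains and neighbor counts are not
  computed; the atlas exports per-group tables for external statistics
  rather than performing hypothesis tests.
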