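# Methods

`perimac` quantifies the spatial relationship between tissue
macrophages and the vasculature of a sensory ganglion in 3D
light-microscopy volumes, and caveolar vesicles/fenestrae in 2D
EM-scale images. Because the classification rules act on segmented
masks, the package ships a first-class synthetic tissue generator with
exact ground truth; every rule is validated by recovering that truth.

## Geometry primitives

All quantities are computed on integer label volumes with per-axis
voxel spacing in μm (axis order z, y, x; anisotropy allowed). Voxel
centres sit at `(index + 0.5) · spacing`.

* **Volume** — voxel count × voxel volume.
* **Percent volume** — 100 × object voxels inside the tissue mask /
  tissue voxels.
* **Contact area** — strict 6-face adjacency between two disjoint
  masks, each shared face weighted by its physical area. Face counting
  was chosen as the normative definition because the classification
  threshold is a physical area (μm²), not a voxel count; the threshold
  itself is configurable to absorb differences against other
  conventions.
* **Distances** — Euclidean, from a query centroid to the nearest
  target voxel centre; zero when the centroid's voxel is itself target.
* **Diameter** — the Euclidean distance transform (EDT) is evaluated on
  the medial axis and doubled; since the EDT to the nearest background
  voxel *centre* overestimates the radius to the physical surface by
  about half a voxel, the local diameter is `2·EDT − mean(spacing)`.
  The medial axis is the EDT ridge (26-neighbourhood local maxima of
  the distance transform, tolerance 0.3 × min spacing) rather than a
  topological thinning: iterative 3D thinning erases tubes of even
  voxel diameter whose axis falls between voxel planes, which is the
  common case for sub-voxel-positioned vessels, while the EDT ridge
  marks exactly the voxels whose distance value is the local radius.
  Per-branch diameter is the mean over the branch's medial voxels
  (mean, not max, because the classification rule is per-vessel). On
  analytic cylinders with radii 1–10 μm the branch diameter is within
  one voxel spacing of truth (tested).
* **Connectivity** — object labelling defaults to 26-connectivity;
  contact is always 6-face.
* **Surface coverage** — the fraction of a vessel's boundary voxels
  with a cover voxel within one face-or-edge (18-connected) step;
  the tolerance is configurable.

## Vessel typing

Branches are classified along the arteriovenous axis by marker status,
diameter and surface position:

| class | rule |
|---|---|
| artery | ACTA2⁺, diameter > 10 μm, off the tissue surface |
| vein | ACTA2⁺, diameter > 10 μm, on the tissue surface |
| a-cap | ACTA2⁻, diameter < 10 μm, PLVAP⁻ & CLDN5⁺ |
| capillary | ACTA2⁻, diameter < 10 μm, PLVAP⁻ & CLDN5⁻ |
| v-cap | ACTA2⁻, diameter < 10 μm, PLVAP⁺ & CLDN5⁻ |

Inequalities are strict: a branch at exactly 10 μm matches no rule and
is reported unassigned with a flag, never silently resolved. Likewise
PLVAP⁺ & CLDN5⁺ is a marker conflict and flags the branch. When only
one zonation marker is supplied the capillary split is binary (PLVAP
preferred, CLDN5 as fallback) and the mid-zone class cannot be
expressed; with both markers the doubly-negative mid-zone is reported
as plain capillary. "On the surface" means the strict majority of the
branch's medial-axis voxels lie within a boundary shell of the tissue
mask; the shell depth defaults to 15 μm and is configurable, as no
canonical depth exists.

Marker positivity is a strict inequality on the branch-mean intensity
against either an absolute threshold or an automatic split at the
largest gap of the per-branch mean distribution; a constant channel
with the automatic policy is an error, not a silent call.

The expert-annotation pathway back-projects a 2D class mask drawn over
the z-projection onto the 3D vasculature; each branch takes the
majority class of its voxels, with ties and unannotated majorities
reported unassigned. A limitation inherent to the workflow: a branch
that is almost completely occluded by another vessel in the chosen
projection cannot be recovered by any annotator. The validation
therefore constructs its synthetic expert annotation the way a person
works: the projection axis in which the vessels are most
distinguishable is chosen first, and within it each pixel is assigned
to the branch that most depends on it, so thin vessels are traced over
the large ones they cross.

Zonation profiles are per-class voxel-mean intensities (not per-vessel
means; the choice is documented here because either reading is
possible), normalized within a specimen to the maximal class (%max),
which makes them invariant to global intensity rescaling.

## Macrophage quantification

* **Identity** — DRG macrophage if ≥ 30% of the object volume lies in
  the neuronal soma-rich region (inclusive threshold); otherwise fiber
  macrophage if ≥ 30% in the fiber-rich region; otherwise other. The
  soma rule is evaluated first, so an object straddling both regions is
  DRG.
* **Association** — perivascular when total vessel contact area ≥
  10 μm², parenchymal otherwise. The printed rule (<10 / >10) leaves
  exactly-10 undefined; ≥ → perivascular is declared normative and the
  threshold is configurable.
* **Segment assignment** — a perivascular macrophage belongs to the
  vessel class with which it shares the most contact area; an exact
  tie breaks to the class whose medial axis lies nearest the cell
  centroid; a residual tie is flagged unassigned. "Most closely
  associated" has no canonical definition; this one is recorded in the
  run metadata.
* **Morphology** — the equivalent ellipsoid is fitted from the second
  central moments of voxel centres in physical μm; eigenvalues map to
  radii by `radius = √(5λ)` (the uniform-solid-ellipsoid convention, so
  a digitized solid ellipsoid reproduces its own radii — calibrated in
  the tests: a radius-8 ball gives elongation and sparseness 1 within
  5% and 10%). Elongation = a/b; sparseness = ellipsoid volume /
  object volume. Planar, linear or < 4-voxel objects raise an error
  naming the degeneracy.
* **Uptake** — object MFI over the tracer channel, normalized to the
  median intensity of tissue voxels excluding all macrophages and
  vessels. The median is the default background statistic (robust to
  bright structures); the mean is available by configuration.
  Background is computed per volume (specimen).
* **Subset** — CD163⁺/⁻ by strict threshold on the object MFI,
  absolute or automatic largest-gap over the cohort.

## EM quantification

Vesicles are detected with a deterministic multiscale
Laplacian-of-Gaussian detector on the inverted image after
subtracting a local median background (window wider than the largest
vesicle), which suppresses membrane bands and shading that otherwise
dominate the large scales. Candidates whose core-to-surround intensity
drop is below 25% of the robust dynamic range are rejected as
responses to extended structures. The blob scale maps to diameter by
`d = 2√2·σ` and is refined by equivalent-disc area of the connected
dark component at the detection centre (falling back to the scale
estimate when the two disagree by more than a factor of two). A
trained instance-segmentation model would play this role on real
micrographs; the classical detector is fully deterministic and ships
with no weights.

Detections are restricted to the endothelium by the mask value at the
centre pixel (boundary pixels count as inside). Size classes: single ≤
100 nm < fused (the exact boundary goes to single; the printed rule
leaves it undefined); the boundary is configurable. Per-image metrics:
counts per class, density per μm² of endothelial cytoplasm, and the
percent of cytoplasm area covered by the vesicle discs.

Fenestrae are measured as the percent of the luminal lining length
occupied by gaps. Lining paths are ordered pixel chains; a chain of n
pixels measures n pixel-lengths (summed Euclidean steps rescaled by
n/(n−1)), so axis-aligned gap lengths are exact in pixels.

## Synthetic data generator

The generator emulates exactly the statistical structure the rules
consume, not microscope physics (no point-spread function, no
clearing-optics artefacts, no agent-based biology, no realistic EM
texture). Consequences for interpretation: passing tests demonstrate
the correctness of the measurement and classification machinery under
known geometry and contrast, not segmentation performance on real
images (segmentation masks are inputs to this package, produced
upstream).

Vessels are capsule primitives (straight tubes with hemispherical
caps) in a 160³-voxel volume at 0.5 μm isotropic spacing — the voxel
size is a configurable default chosen as typical for confocal stacks
of cleared tissue. Arteries (radius 6–8 μm) enter from the z=0 face —
the nerve-fiber side — and run interior; veins (6–8 μm) run parallel
to the far face with centrelines ~8 μm under it, so the surface rule
discriminates them; capillary-calibre branches (1.5–2.5 μm; four per
capillary class by default) fill the interior clear of the 15 μm
surface shell. Diameters therefore straddle the 10 μm rule by
construction. Marker class means (e.g. ACTA2 200 on artery/vein vs 5
elsewhere; CLDN5 falling and PLVAP rising along the axis) are
separated by ≥ 6 noise SD at the default noise (additive Gaussian,
σ = 5, clipped at zero — the simplest model that exercises
thresholding), and the truth marker status is derived from the same
largest-gap split the classifier uses.

Macrophages (106 by default, across identity × association × subset
cells) come in three shapes — spheres, prolate capsules (cigar), and
spiders (a core with 3–6 thin arms ~1.2 voxels thick, giving
sparseness well above 2). Perivascular cells are placed
constructively against a chosen branch and the realized contact area
is verified by face counting and recorded as-is (discretization makes
exact targets unattainable); the target band 15–45 μm² keeps every
object ≥ 20% clear of the 10 μm² threshold. Parenchymal cells keep a
verified ≥ 3 μm clearance from all vessels. Identities are controlled
by planting ≥ 80% of each body in its target region (threshold 30%,
again with margin). Fiber-identity perivascular cells are planted on
arteries, the class that reaches the fiber-rich slab by construction.
Perivascular tracer uptake is painted from a per-class mean that
increases strictly artery → vein (20/40/60/100/120 against background
10), realizing the arteriovenous uptake gradient; the CD163 channel
encodes subsets at 150 vs 5.

Placement is rejection sampling with bounded retries and explicit
failure; cells never overlap or touch (1-voxel halo), so labels are
unambiguous. Perivascular cells are placed before parenchymal ones and
large-footprint shapes first, otherwise crowding along the vessel
walls can strand a spider. Randomness is stage-keyed
(`default_rng([seed, k])`, k = 0 vessels / 1 macrophages / 2 noise) so
any stage regenerates independently and the whole tissue is
bit-reproducible.

EM scenes are 400×600 px at 2 nm/px: an endothelial ribbon (rows
150–250) on a brighter background, the luminal lining along its upper
boundary, hard dark discs of 60–140 nm inside the ribbon (plus two
decoys outside), fenestrae carved as notches of exactly known pixel
length, and Gaussian noise at SNR 5 (contrast 90 / σ 18). Diameters
below 2 px at the configured resolution are rejected as unresolvable.

## Problem sizes and numerical choices

Default study conditions: one 160³ tissue volume (80 μm cube),
16 branches, 106 macrophages; 20 EM scenes for detector evaluation;
200 random ≤ 11³ volumes for the brute-force oracle battery; the
determinism check reruns the full pipeline twice on a 140³ volume.
These sizes were chosen so the whole validation is a desk-scale
computation while every rule still sees all of its cases.

Tie-breaks and boundaries are all documented above and echoed into
`run_metadata.json` on every run. Objects are never silently dropped:
the report accounts every macrophage as classified, unassigned
(flagged) or failed (e.g. degenerate morphology), and the counts
reconcile with the cohort size.

## Known limitations

* The generator's vessels are non-branching capsules; topological
  centreline analysis (artery-to-vein path ordering) is out of scope.
* Surface-coverage and contact-area conventions are voxel-face based;
  mesh-based (marching-cubes) areas would differ by a few percent on
  curved surfaces.
* The annotation pathway cannot recover a branch that is almost fully
  occluded in the chosen projection (an annotator could not either).
* The EM detector assumes roughly circular, locally dark vesicles on a
  slowly varying background; heavily textured real micrographs would
  need a trained detector in its place, with the downstream masking,
  size-class and density logic unchanged.
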