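# Methods

## Problem and scope

`abtomo` counts asbestos bodies (AB) in reconstructed 3D micro-CT volumes
of lung tissue and converts the counts to the clinical burden unit AB per
gram of dry lung. It consumes reconstructed grey-level volumes;
acquisition, phase retrieval and tomographic reconstruction are out of
scope, as are chemical fibre identification and detection of uncoated
fibres below the resolution limit.

## Volume model and conventions

A volume is a 3D scalar grid with an isotropic voxel size in µm. Axis
order is (plane, row, column) with the plane index along the rotation
axis, matching TIFF stack page order; offsets are 0-based. Voxel size is
always user-supplied metadata — TIFF resolution tags are unreliable for
synchrotron data and are ignored. The probed tissue volume is
V_c = (voxel count) × (voxel size)³ × 10⁻¹² cm³.

Chunked processing splits along the plane axis with an overlap; the last
chunk is shifted backwards when extents do not divide evenly, so coverage
is guaranteed (consecutive chunks then share at least, not exactly, the
requested overlap). Objects are assigned to the unique chunk owning their
centroid, with ownership boundaries at overlap midpoints. If the overlap
is at least the largest object extent, every owned object lies entirely
inside its chunk and chunked results are bit-identical to whole-volume
results; choosing the overlap is the caller's responsibility (a safe
default is the maximum expected AB length divided by the voxel size).

## Detection and morphometry

Foreground is an inclusive grey window [grey_lo, grey_hi]; components are
labelled under 26-connectivity by default because thin oblique fibres
fragment under 6-connectivity. Per object:

* principal axes are eigenvectors of the voxel-coordinate covariance;
* extent along each axis is (max − min voxel-centre projection) + 1 voxel,
  so a single voxel has extent one voxel and no object degenerates to zero
  length; extents are sorted L1 ≥ L2 ≥ L3;
* length = L1, width = (L2 + L3)/2, aspect ratio = length/width,
  sphericity = L3/L1 (the equal-axes notion; Wadell's surface-area form is
  available separately as `wadell_sphericity` for QC but plays no role in
  filtering, since voxel-face area counting biases it);
* solidity = voxel volume / convex hull volume, with the hull built on
  voxel cube **corners** (interior voxels are pruned first). Corner hulls
  guarantee solidity ≤ 1 for digitised solids — hulls of centres can
  exceed the voxel volume for boxes — at the cost of a half-voxel halo
  that biases solidity low for curved objects (a digitised ball of radius
  12 voxels measures ≈ 0.89, not 1); thresholds are calibrated under this
  convention.

Filters run in a fixed order — size (voxel count bounds), sphericity
(≤ max), solidity (≥ min), aspect ratio (strictly > min, default 3),
border policy — and the first failing rule is recorded per object, so
rejection ledgers and per-stage counts are deterministic and auditable.

Default thresholds (min size 200 voxels, max 2×10⁵, max sphericity 0.5,
min solidity 0.5, min aspect ratio 3) are phantom-calibrated stand-ins:
real-instrument settings depend on scanner, energy and reconstruction and
must be optimised per instrument; they live in the run configuration,
never in code. Objects touching the volume border are included by default
and flagged, so either counting convention can be applied downstream.
Counting is always 3D; projections exist only for visual QC, and the suite
checks that a max projection of a dense phantom merges objects (2D
component count ≤ 3D accepted count).

## Burden conversion

N_gdw = (N_c/V_c) × D_dw / (V_s · O_c · R_wv), with defaults V_s = 2.3,
R_wv = 0.916 g/cm³, D_dw = 10, O_c = 1. The classical relation is
sometimes typeset as N_gdw = N_g × D_dw = N_c/(V_c·V_s·O_c·R_wv), which is
dimensionally inconsistent as a single fraction; published burden tables
are consistent with the form implemented here (the fraction gives N_g, the
per-gram-wet value, which D_dw then scales to dry weight). Replicate
densities are summarised by mean and sample SD (n−1; three replicate
volumes is the typical design and the spread genuinely reflects tissue
heterogeneity, often ~50% of the mean).

The orientation correction for thin-section counting assumes fibre
orientations uniform on the sphere: a length-L fibre intersects a T-thick
section with probability ∝ T + L·E|cosθ| and E|cosθ| = 1/2, giving
O_c = 1 + L/(2T). This reconstruction is validated only against its own
Monte-Carlo slab-intersection oracle (agreement within 3 SE over a grid of
L ∈ {5,10,20,40} µm, T ∈ {3,5,10} µm); it is a pluggable model, and O_c is
exactly 1 for 3D volume counts regardless of length. D_dw can be measured
per sample from wet and dry masses (`compute_ddw`). The exposure flag
compares N_gdw with the European Respiratory Society marker 10³ AB/g_dw
(strict inequality).

## Morphometry statistics

Quartiles use linear interpolation between order statistics (the common
"type 7" rule), recorded in the output metadata. Fences sit at
q1 − 1.5·IQR and q3 + 1.5·IQR; whiskers are the extreme *data members*
inside the fences and outliers are listed individually. Under heavy ties
an interpolated quartile can exceed every in-fence member, so
q3 ≤ whisker_hi is not guaranteed in pathological cases; the implementation
keeps whiskers as data members, matching standard box-plot practice.

The log-normal length fit is the closed-form MLE (mean and 1/n-SD of the
logs). Goodness of fit is reported as a KS distance, not a p-value: with
parameters estimated from the same data the standard KS p-value is
anti-conservative, and the claim being supported is descriptive
log-normality, not a test decision. Table means are arithmetic means of
accepted objects (lengths/widths could alternatively be medians; means are
used and so labelled).

## Phantom generator

The generator defines the synthetic study conditions:

* **Fibres**: capsules (cylinder + hemispherical caps), lengths log-normal
  with µ_log = ln 20 µm, σ_log = 0.4 (arithmetic mean ≈ 21.6 µm, inside
  the 19–24 µm range typical of coated fibres), widths normal 3.5 ± 0.2 µm
  truncated positive (reported transverse AB dimensions cluster at
  3.3–3.6 µm), orientations uniform on the sphere. The beaded coating is
  modelled as an *inward* sinusoidal radius modulation (amplitude 0.2,
  period 3 µm): the local radius varies in [R(1−a), R], so the nominal
  width 2R remains the measurable maximum transverse extent — widths in
  published morphometry are measured on the beaded body. No branching or
  curvature.
* **Placement**: rejection sampling; every capsule must fit inside the
  volume with a one-voxel margin and clear every other fibre by ≥ 2 voxels
  beyond the sum of radii (segment–segment distances, vectorised). This
  guarantees one 26-connected component per fibre, so ground-truth count
  equals component count and recovery tests are exact. Spatial clustering
  on alveolar walls, seen in real tissue, is not modelled.
* **Scene**: grey levels on an uncalibrated [0,1] scale — tissue 0.30, air
  voids 0.05, AB and distractors 0.90, additive Gaussian noise SD 0.05 —
  chosen so contrast filtering is non-trivial but solvable; a detectability
  contract (AB grey > tissue + 5·noise SD) is enforced. Air spaces are
  dark balls of 125–150 µm radius (alveoli/bronchioles are a few hundred
  µm across, larger than the default field of view, so they appear as
  clipped spheres). Distractors are near-spherical bright blobs below the
  size filter (radius 0.3–0.6 µm) and oversized diffuse bright regions
  (radius 15 µm) above it; both are placed clear of fibres so they never
  merge with one. Fibres are painted last, then noise. All randomness
  derives from one integer seed via independent seed-sequence streams, so
  phantoms are bit-reproducible.

What the phantom does **not** emulate: partial-volume edge blur,
phase-contrast fringes, ring artifacts, capillary-bed texture,
fibre clustering and contact, and grey-level calibration drift. Passing
recovery tests therefore demonstrates the correctness of the counting
logic and morphometry under the stated geometric/noise model, not
instrument-ready threshold values.

## Recovery metrics

Detections are matched to truth greedily by centroid distance (tolerance:
half the true length + 2 µm, one detection per fibre). Sensitivity is
computed over *qualifying* fibres — those whose true aspect ratio exceeds
the filter threshold — because the counting rule itself defines
low-aspect-ratio objects out of the target class (with σ_log = 0.4 about
5% of generated fibres fall below aspect ratio 3; a detector enforcing the
rule must not be penalised for excluding them). Any accepted object
matching any truth fibre counts as a true positive for the
false-discovery rate. Mean-length accuracy compares accepted objects with
the matched truth records. At the default study conditions (256³ voxels at
0.332 µm, 100 fibres, noise SD 0.05) the suite requires sensitivity
≥ 0.95, FDR ≤ 0.05 and mean length within max(1 voxel, 5%).

## Problem sizes in the test suite

Test phantoms use 96³–256³ grids with 4–100 fibres, 30-fibre 350-plane
volumes for 5-chunk stitching checks, 5 000 fibres (sampled, not rendered)
for distributional checks, 10⁴ draws for the log-normal MLE check, and
1.5×10⁵–2×10⁵ Monte-Carlo segments per orientation-correction grid point —
sizes at which every statistical tolerance (3 SE bounds, KS at α = 0.01)
is well-powered while the whole suite stays fast.

## Known limitations

* Thresholds shipped as defaults are phantom-calibrated, not
  instrument-calibrated.
* Two AB in physical contact segment as one object (the generator excludes
  this by construction; real high-burden tissue does not).
* Solidity carries the corner-hull half-voxel bias described above; it is
  consistent between calibration and use but not comparable with
  centre-hull implementations.
* The length measure (extent + 1 voxel along the principal axis) slightly
  shortens beaded capsules whose tips fall in a radius trough (mean bias
  ≈ R·a, about one voxel at defaults).
* Chunked counting assumes no object is longer than the chunk overlap;
  violations are not detected automatically.
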