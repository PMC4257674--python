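# Methods

## Coordinate conventions

All positions are physical micrometres in a right-handed frame with the
origin at the stack corner at the skin surface and z increasing into the
tissue. Voxel indices are 0-based; a voxel's physical position is its
centre, and the origin coincides with the centre of voxel (0,0,0), so
physical = index × spacing. Voxel spacing is always supplied per modality
and may be anisotropic — intravital two-photon stacks are typically
stretched in z relative to the serial-section reconstruction, and the
stretch factor is not known a priori, so it is never assumed.

Landmark sets enforce unique ids, a minimum inter-landmark separation
(default 1 µm — two closer landmarks indicate a digitisation error, since
that is below the optical resolution budget of deep two-photon imaging),
and a surface band for NIRB marks (default 20 µm: branding happens at
z ≈ 0, but EM processing legitimately displaces the branded surface by up
to ~10 µm in the default deformation, so the band is generous).

## Transform families and fitting

Four nested families are fitted by least squares between paired landmark
sets (source = in-vivo frame, target = block frame):

* **rigid** — translation + proper rotation only; the SVD (Kabsch)
  solution of the orthogonal Procrustes problem. If the unconstrained
  optimum is a reflection, the smallest singular direction is flipped and
  a warning logged, because a reflection implies an axis flip between the
  modalities that should be fixed upstream.
* **similarity** — adds one global scale (Umeyama closed form); the
  first-order model of fixation shrinkage/swelling. Scale is reported,
  never silently enabled inside "rigid".
* **affine** — general linear part by ordinary least squares; captures
  anisotropic stretch/shear.
* **thin-plate spline (TPS)** — the Bookstein warp in 3D:
  f(x) = A·x + t + Σ wᵢ U(‖x − cᵢ‖) with the biharmonic kernel
  U(r) = r (the 3D fundamental solution; not the 2D r² log r). The
  coefficients solve the bordered system [[K, P], [Pᵀ, 0]] per output
  axis, with side conditions Σwᵢ = 0 and Σwᵢcᵢ = 0 guaranteeing bounded
  behaviour at infinity. λ = 0 gives exact interpolation of every paired
  landmark, which matches how the warp is used on curated landmark sets;
  λ > 0 smooths noisy pairings.

A numerical point worth recording: U(r) = r is of *negative* type on the
side-condition subspace, so the smoothing term enters the kernel block as
K − λI (equivalently, kernel −r with +λI, which is the convention scipy's
RBF interpolator uses). With K + λI the system passes through a
singularity at intermediate λ and the fitted warp degrades
non-monotonically; with K − λI the bending energy −Σ wᵀKw decreases and
the control-point residual increases monotonically in λ, and predictions
agree with `scipy.interpolate.RBFInterpolator(kernel="linear", degree=1,
smoothing=λ)` to machine precision at every λ.

Degeneracy is detected from the singular-value ratio of the centred
source coordinates (< 1e-8): collinear configurations reject rigid and
similarity fits, coplanar ones reject affine and TPS. Minimum pair
counts: 3 (rigid/similarity), 4 (affine), 5 (TPS). All fits are
deterministic; there is no random initialisation anywhere.

## Accuracy bookkeeping

The residual report gives per-landmark offset vectors target −
transform(source), magnitudes, RMS and max. The targeting accuracy proxy
is the leave-one-out (LOO) docking error: for each pair, refit on the
remaining pairs, predict the held-out source landmark, record the
distance to its true target. The median LOO error is attached to every
docking and compared against a fixed 20 µm reference line — the order of
magnitude at which predicting one structure's position inside a
chemically processed block is realistic. The reference is a flag
threshold, not a guarantee.

Docked ROI points farther than 25% of the landmark bounding-box diagonal
outside the landmark hull are flagged (splines extrapolate poorly);
docking still runs.

The NIRB coarse alignment fits translation + rotation about z from ≥ 2
paired surface marks; the z translation is fixed to 0 because the marks
carry no depth information, and any residual z offset is reported, never
corrected. It initialises pair suggestion and is never used for docking
depth.

## Sectioning arithmetic

A scheme is an ordered list of section blocks (count × nominal thickness,
kind ∈ {500 nm thick LM, 60 nm thin EM, ~240–300 nm semi-thick
tomography}) plus an optional trailing periodic unit. Depth intervals are
half-open (z_start, z_end] µm from the block face and abut exactly;
thickness is treated as nominal and exact, with a per-scheme
`thickness_scale` (default 1.0) exposed for calibration against measured
feed. Cutting artefacts, lost sections and folds are not modelled.

When a docked depth window is translated into section indices, a depth
that falls exactly on a section boundary is assigned to the deeper
section, and the window is widened by the docking's accuracy estimate on
both sides. `sections_covering` is plain ceil(window / thickness) with a
1e-9 nm slack absorbing binary-float noise in exactly divisible windows.

## Landmark candidate detection

Vessel bifurcations: the binary tubular mask is thinned to a 1-voxel
centerline (scikit-image 3D skeletonization), converted to a µm graph
with 26-connectivity, and every node of degree ≥ 3 becomes a candidate.
Junction voxels arrive in small clusters, so candidates within a merge
radius (default 3 µm — below typical inter-landmark spacing, above voxel
noise) collapse to their centroid. Thinning systematically displaces the
junction of thick tubes toward the parent branch, so by default each
junction is refined to the least-squares intersection of the incident
centerline rays (PCA lines fitted to skeleton nodes in a 2.5–12 µm
annulus), falling back to the raw position when fewer than three branches
resolve or the correction exceeds 6 µm. This brings localisation of
~4 µm-radius forks from ~2.7 µm error to well under 1 µm.

Fiber cross-points: fibers rarely touch exactly in 3D, so a "crossing" is
the midpoint of the closest-approach segment of any two fibers whose
minimum segment-to-segment distance is below a gate (default 2 µm),
merged within the same 3 µm radius. Hair follicles are not auto-detected;
they can be entered manually as OTHER landmarks.

Pair suggestion is mutual nearest neighbours under a coarse transform
with a distance gate and feature-class matching, and is always flagged
as requiring review — it automates the correlation step, it does not
replace curation.

## The synthetic study

The generator emulates the volumes this workflow operates on: a block
270–440 µm in xy and 60–200 µm deep containing a recursive binary vessel
tree (L split levels → 2^L − 1 bifurcations; root radius 4 µm decaying by
0.78 per level, segment length 60 µm decaying by 0.75 — venule-to-
capillary calibre in rodent dermis), a collagen meshwork of smoothed
random-walk polylines confined to a band in the upper dermis (where
collagen is densest; this also makes the meshwork cross often enough to
supply cross-point landmarks), cells placed near vessels (invading cells
cluster around the vasculature), and a 4-corner NIRB frame at z = 0. Two
daughter branches must diverge by ≥ 30° after boundary steering or the
fork is re-drawn: branches that never separate are not a real,
recognisable bifurcation. Everything is reproducible bit-for-bit from
(params, seed).

EM processing is modelled as global scaling about the volume centroid
plus a small number of Gaussian displacement bumps
Σ aₖ exp(−‖p − cₖ‖²/2wₖ²); with unit scales and no bumps the model is the
identity, and the non-affine displacement is bounded by Σ‖aₖ‖. Landmark
observation adds per-axis Gaussian noise and independent dropout per
modality, with ids preserved so the ground-truth pairing stays known.

The default scenario fixes: 400×400×150 µm extent; L = 3 (7
bifurcations); 30 fibers; 6 cells; global scales (0.95, 0.95, 0.95) —
the linear shrinkage chemical fixation typically causes; 3 bumps of up to
8 µm per-axis amplitude and 120 µm width — smooth and non-homogeneous, as
tissue distortion is, and strong enough that a rigid overlay visibly
fails while the TPS overlays exactly; detection noise sd 2 µm; dropout
0.1; 12 bifurcation/crossing landmarks retained for pairing. The bump
amplitude and the localisation noise are free parameters of the
simulator (no measured values exist for them); they are justified only by
producing leave-one-out docking errors of the same order as the ~20 µm
accuracy the workflow can claim.

What passing simulated tests does *not* show: the generator does not
model optics or PSFs, photophysics, segmentation errors that are
spatially correlated with anatomy, section compression/loss, or
modality-specific z-stretch (the latter can be emulated by an extra
z-scale in one frame's voxel geometry). Real landmark mislocalisation is
likely anisotropic (worse in z) and operator-dependent; the isotropic
noise here is a first-order stand-in.

## Problem sizes

The test suite and the acceptance script run the default scenario for 20
seeds (~10 paired landmarks each), fit-recovery and oracle checks on
point sets of n ≤ 20, and detection recall on 20 rasterized
160×160×90 µm trees at 1 µm voxel spacing — sizes chosen so the whole
suite completes in about a minute on one CPU while still exercising every
code path at realistic landmark counts.

## Known limitations

* Fiber-crossing detection is an O(n²) scan over fiber pairs; fine for
  the tens of fibers that are practically digitised, not for thousands.
* Skeleton-based fork detection can miss a bifurcation whose daughter
  tubes fuse with a nearby branch (anastomosis-like overlap creates
  cycles and absorbs the junction); across the 20-seed recall benchmark
  this costs about one fork in 140.
* The 20 µm reference accuracy is a fixed flag line, not a per-study
  error model; the honest per-study estimate is the LOO median.
* Equivalence with any particular commercial landmark-warp module cannot
  be asserted — only with the published thin-plate-spline formulation.
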