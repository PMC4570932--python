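# Methods

## Measurement model

The package treats a fluorescence z-stack as a non-negative intensity grid
on an anisotropic lattice with spacing (dz, dy, dx) in μm; dz is typically
1.25–2× the in-plane pixel size on commercial systems, and all geometry is
computed in physical coordinates with the voxel-centre convention (index
i ↦ (i + 0.5)·spacing). ROIs are 0-based, half-open axis-aligned boxes, one
per (single or dividing) cell; automatic cell segmentation is deliberately
out of scope — rectangular per-cell crops are the input contract.

### Membrane potential

Per cell the two marker channels are compared voxel-wise inside a cell
mask: the channel sum is blurred with a Gaussian (σ = 5 px, applied
in-plane per z-slice by default; a 3D mode scales σ_z by dx/dz) and Otsu-
thresholded. Summing both channels makes the mask robust when the red
marker is cytosolic; the blur merges the speckled mitochondrial signal into
one cell-sized region. The statistic is the Pearson correlation r over the
masked voxels of the whole 3D crop, plus R² = r² of the least-squares fit
red ~ green. No background subtraction is performed by default: jointly
dark voxels inside the mask contribute a correlation floor that is part of
the measurement's observed behaviour (a histogram-mode background
correction is available behind a flag). Cells with > 1% of masked voxels at
the channel maximum are flagged as saturated, not excluded. A helper
estimates the minimum number of cells per group for a two-sample
comparison of PCC means at a requested power, using the pooled-SD Cohen's d
and the two-sided normal-approximation power equation (an exact
noncentral-t refinement is intentionally omitted; the approximation is
accurate to ±1 cell at the effect sizes of interest).

### Morphology

The green (structure) channel is Otsu-thresholded (256 bins over
[min, max]; ties to the lowest threshold; foreground strictly above) and
partitioned into connected components, 26-connectivity by default — thin
tubules sampled coarsely along z fragment spuriously under 6-connectivity.
Objects with volume < 0.1 μm³ are discarded as artefacts (an object of
exactly 0.1 μm³ is retained). Objects touching the ROI border are kept,
since ROIs are whole-cell crops; a flag can drop them.

**Surface area.** A surface voxel has at least one of its six faces not
shared with another foreground voxel. Raw exposed-face summation
overestimates smooth surfaces (a digitised sphere exposes 6πr² of faces
against a true 4πr²), so each surface voxel is assigned to one of 15 local
configuration classes — how many z faces (0–2) and lateral faces (0–4) are
exposed, with the two-lateral case split into adjacent (convex edge) and
opposite (1-voxel sheet) only when no z face is exposed — and each class
contributes its summed face area times a per-class correction factor.
Factors are calibrated once by least squares against analytic areas of
digitised spheres (radii 5–40 px, two lattice offsets) at z/xy anisotropy
ratios 1.0, 1.6 and 2.0, and frozen in a table shipped with the package
(`scripts/calibrate_surface_table.py` regenerates it; at run time factors
are interpolated linearly in dz/dxy and clamped to the calibrated range).
Two constraints shape the fit: the single-exposed-face classes are pinned
to factor 1 (with all in-plane neighbours present the local surface is
flat, so the face area is exact), and a ridge (strength 0.3) pulls factors
toward 1. Without them the fit is ill-conditioned — correlated classes
trade factor mass, spheres come out < 1% wrong but flat-faced bodies −27%.
The constrained table estimates sphere areas within ≈ 2.5% (r ≥ 5, both
anisotropies) and box areas within ≈ 4.4% (20×30×40 and larger); the
residual box deficit comes from edge voxels, whose configuration is
indistinguishable from a 45° staircase slope, and vanishes as object size
grows. No local-configuration estimator can be exact for both orientations
simultaneously; the compromise is biased < 5% for both body types at the
scales of interest.

**Descriptors.** All variances are population variances (divide by n).
With centroid c, voxel distances d(k), surface-voxel distances r(j),
volume V = n·dz·dy·dx and estimated area A:

- compactness = Var[d(k)] / V (μm⁻¹) — low for balls, high for tubes;
- distribution isotropy: for each coordinate axis the axial distance of
  every voxel from the axis through the centroid is taken (e.g. for x, the
  distance in the (y, z) components); the descriptor is the sum over the
  three axis pairs of the larger/smaller ratio of the second moments of
  these axial distances. Each ratio is ≥ 1, so the value is ≥ 3 with
  equality for rotationally symmetric bodies. A zero moment (perfectly
  linear object) is reported as +∞ and excluded from cell-level means.
  The ratios are deliberately orientation-free (max/min): a fixed-order
  convention would dip below the rotational-symmetry minimum for oblate
  objects.
- IPQ = V / ((4/3)π (A/4π)^{3/2}) ≤ 1, and sphericity = π^{1/3}(6V)^{2/3}/A,
  both 1 for a sphere; algebraically sphericity³ = IPQ², which the tests
  assert as a cross-check of the two codings. Digitisation can push
  sphericity marginally above 1 for near-ideal spheres.
- radius variance = Var[r(j)] (μm²), 0 in the ideal-sphere limit; on
  digitised spheres the normalised value (by the squared mean surface
  radius) falls monotonically with radius, ≈ 4×10⁻⁵ at r = 40 px.

**Cell and population level.** Relative volumes Vs sum to 100 per cell
(post-filter); f = Σ{Vs : Vs ≤ 20} — the ≤ (not <) threshold follows the
method's formula rather than its looser prose, and is configurable.
Per-cell descriptor means are weighted by object surface area, countering
the over-representation of small fragments (inherently compact and
spherical). Populations report mean f ± SEM over cells (equivalent to the
ratio-of-sums form when each cell's Vs sums to 100) and a Vs histogram with
bin width 10, summing Vs per bin so each cell contributes 100 in total.

## Synthetic scenes

The generator emulates the package's inputs, not the optics of any
particular microscope. One cell = an ellipsoidal cytosol filling ~90% of a
28×56×56 grid at (0.2, 0.1, 0.1) μm spacing — a ~5.6 μm yeast-like cell
imaged with 200 nm sections and 100 nm pixels — holding ~2 μm³ of
mitochondria as non-overlapping capsules (tubes, radius 0.18 μm; 0.30 μm
for the main network piece) or balls, placed by rejection sampling with a
0.35 μm surface clearance so PSF blur cannot merge designed objects.
The green channel carries foreground 1000 over background 20 on the
objects; the red channel puts (1−φ)·foreground on the objects and spreads
the delocalised fraction φ uniformly over the cytosol, conserving the
integrated signal. Each channel is blurred with a Gaussian PSF (σ = 1 px
in-plane, scaled by dx/dz along z) and degraded with Poisson shot noise
(1 photon per intensity unit; scale 0 disables) plus Gaussian read noise
(σ = 2% of foreground) — an SNR of ~25–30, at which Otsu segmentation is
stable. Seeds are mandatory and all randomness flows through
`numpy.random.default_rng`; identical specs give byte-identical stacks, and
multi-cell series derive per-cell seeds from a `SeedSequence`.

Fragmentation series are designed analytically before rasterisation: a
target f is split into fragment shares of ~8–14% (never closer to the 20%
threshold than 14%, so pipeline noise cannot flip a designed fragment's
classification) plus one remainder object; targets in (80, 100) are
rejected as infeasible since the remainder itself would classify as a
fragment. Round-tripping rendered 30-cell series through the full pipeline
recovers per-cell f within ±3 of the design at targets 0, 20, 45 and 100
(the tests assert ±5).

What the scenes do **not** model: structured-illumination reconstruction
artefacts, depth-dependent PSF and spherical aberration, photobleaching,
autofluorescence gradients, cell-to-cell expression variability, and true
branched network topologies (the "network" is a zig-zag capsule chain).
Passing tests therefore demonstrate the correctness of the measurement
pipeline on controlled geometry and noise, not robustness to every
real-microscopy artefact; on real data the absolute PCC floor and the
exact f calibration depend on acquisition settings.

## Numerical choices and edge cases

- Otsu: 256 bins over [min, max]; constant volumes raise a dedicated
  error; equal-variance plateau ties resolve to the lowest threshold.
  The mask is intensity > threshold, and masks are invariant under positive
  scaling of all intensities.
- 32-bit input stacks are linearly rescaled so the volume maximum maps to
  65535 before thresholding, putting them on a common footing with native
  16-bit acquisitions.
- Problem sizes: validation uses digitised spheres up to r = 40 px,
  30-cell series for fragmentation recovery and 5×6-cell series for the
  delocalisation direction — sizes at which every statistic is stable and
  the entire suite runs in well under a minute per property.
- Degenerate cells (no objects above the volume filter, flat intensity,
  zero channel variance) are flagged per cell and never abort a batch run;
  the CLI exits non-zero only on run-level failure.
- SEM over fewer than two cells is reported as missing (None/NaN), not an
  error.

## Known limitations

- The surface-area estimator's class weights are a global compromise
  between curved and flat bodies (see above); sub-voxel meshing (marching
  cubes) would be more accurate but is out of scope by design.
- The fragmentation index is threshold-based and insensitive to morphology
  within the fragment class; it is intended to be read together with the
  shape descriptors, which is why the per-cell tables carry both.
- PCC-based MMP is a snapshot measurement; it cannot resolve kinetics
  faster than the maturation/import timescale of the markers.
- The power helper assumes normally distributed group means and equal
  group sizes.
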