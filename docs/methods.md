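# Methods

## The 2D detector

A compound-eye image is dominated by the quasi-periodic ommatidial
lattice. A hexagonal lattice contributes three fundamental gratings to
the 2D Fourier transform, 60° apart in orientation and all at radial
frequency `2/(√3·a)` for centre spacing `a` (a square lattice contributes
two, 90° apart, at `1/a`). The detector:

1. **Power spectrum.** The image is mean-subtracted, tapered with a 2D
   Hann window (suppressing leakage from the non-periodic frame borders)
   and transformed; peak search operates on the log power spectrum, which
   by the Wiener–Khinchin theorem is equivalent to amplifying periodic
   structure through the spatial autocorrelation. The raw (untapered)
   complex FFT is kept alongside for filtering.
2. **Fundamentals.** Candidate peaks are local maxima of the lightly
   smoothed (σ = 1 bin) log spectrum in one half-plane, outside a DC
   exclusion of `4/min(image dimension)` cycles/px (the DC lobe spans
   several bins after windowing). A candidate is significant if its raw
   log power exceeds `median + k·MAD` of its radial band (logarithmically
   spaced annuli; `k = 5`). Two numerical guards matter in practice: the
   MAD is capped at 0.5 decades, because in noiseless images the
   inter-peak power sits at the numerical floor and the raw MAD of the
   bimodal band distribution would veto genuine peaks (white noise has a
   log-power MAD of ≈ 0.33 decades, safely below the cap); and the
   statistics are computed on the *unsmoothed* log power, because in
   small images the smoothed peak skirts occupy most of a thin annulus
   and inflate its median. Candidates must also lie within 2 decades of
   the brightest candidate — the fundamentals of a spot lattice dominate
   the off-DC spectrum, whereas residual leakage bumps near DC are
   orders of magnitude weaker. Accepted peaks are taken lowest-frequency
   first, skipping near-duplicates (within half the accepted peak's
   frequency) and harmonics (within 10% of 2× or 3× an accepted peak's
   frequency vector). Requesting 2 instead of 3 fundamentals supports
   square lattices and noisy images whose third axis is ambiguous.
3. **Low-pass reconstruction.** The inverse FFT keeps frequencies up to
   1.25× the largest fundamental: all fundamentals pass, first harmonics
   at 2× are blocked. The reconstruction is computed from the untapered
   FFT, so the mean brightness and the spatial layout are preserved.
4. **Local maxima.** All 8-neighbourhood maxima of the smoothed image
   (plateaus reduce to their centroid) are suppressed greedily so that no
   two accepted maxima are closer than 25% of the FFT-derived diameter;
   the brighter maximum wins, then the top-left-most — a deterministic
   ordering. Maxima whose height above the image mean falls below 25% of
   the median maxima height are discarded: the low-passed lattice pattern
   continues faintly past the outermost ommatidia and rings at the frame
   border, producing shallow ghost maxima well separated (≈ 10× lower
   prominence on synthetic lattices) from true lens centres. An optional
   mask (white silhouette, foreground = brighter than half the mask
   maximum) removes maxima outside the eye. Sub-pixel quadratic
   refinement is available behind a flag and off by default.
5. **Diameters.** The per-centre lens diameter is the *median distance
   to lattice neighbours* (centres within 1.5× the FFT diameter; for a
   hexagonal lattice that is the six adjacent ommatidia). The inverse
   fundamental frequency itself is deliberately not used as the
   diameter: it measures the row spacing `√3·a/2 ≈ 0.87·a`, not the
   centre spacing, and serves only to set search radii. It is exposed as
   `fft_diameter_px`.

## The degradation benchmark

Resolution is degraded by bin-averaging (each output pixel an exact
`b×b` block mean; trailing partial blocks dropped, so block means stay
exact), contrast by an affine compression of the 8-bit brightness
distribution about its mean to a target RMS contrast — defined as the
standard deviation of intensities after normalizing the 8-bit range to
[0, 1] — followed by requantization. Only contrast reduction is allowed.
The sweep records relative count and relative diameter against the
undegraded reference (measured diameters are rescaled by the bin size
first); a failed detection is recorded as a relative count of zero. The
count threshold is the lowest pixels-per-diameter whose relative count
exceeds half the sweep maximum. For the diameter threshold we use
"relative diameter within 50% of the full-resolution baseline": a
*decrease* past 50% of baseline is a failure, not a success, so the
deviation-from-baseline reading is the only self-consistent one. On
synthetic lattices the count threshold lands at ≈ 4 px/diameter, above
the Nyquist limit of 2, and detection collapses below it.

## The 3D pipeline

Input is a stack of TIFF slices (or a prebuilt point cloud) prefiltered
to crystalline-cone density; a configured density range replaces
interactive range picking, and voxel indices scale to µm.

**Sphere fit.** Linearized algebraic least squares followed by one
Gauss–Newton pass on the geometric residuals; coplanar point sets are
rejected as degenerate. With the cone layer curving smoothly this is
accurate to machine precision on noiseless shells.

**Canonical section frame.** The cloud is rotated so its centroid
direction (from the fitted centre) sits at elevation 0, azimuth 0 —
keeping the eye away from the spherical poles — with elevation measured
from the x–y plane ([−90°, 90°]) and azimuth in the x–y plane
((−180°, 180°]). The roll about the viewing axis is then fixed from the
data (the most off-axis point goes to azimuth +90°), which makes the
frame, and therefore every histogram and grid computed in it, a pure
function of the cloud's geometry: all scalar outputs are equivariant
under rigid motions of the input to ~1e−12.

**Cross-section.** Point radii are modelled as a smooth function of
elevation and azimuth: a median-binned angular grid (about 40 bins per
axis), nearest-filled, box-smoothed and bilinearly interpolated; if the
angular extent is degenerate the constant fitted radius is used with a
warning. The working shell is exactly the central 50% of residuals,
selected by rank with ties broken by point index, so the member fraction
is 0.5 within 1/N on any input.

**Rasterized detection.** The shell is processed in half-overlapping
90°×90° angular windows (configurable); each window is recentred so its
centroid faces the projection equator before forming a 2D count
histogram of (elevation, azimuth), which avoids extreme spherical
warping. Histogram bins are a quarter of the expected angular lens
diameter, taken from configuration (`lens_diameter_guess_um / R`) or
from a first coarse pass of the 2D detector. Detected maxima map back to
3D through the nearest shell point in the projected plane; duplicates
from overlapping windows merge when closer than half a lens diameter in
the projected *angular* plane (two detections of one cone can sit
anywhere along its radial extent, so 3D merging would miss them).

**Clustering and repair.** Every point is labelled by its nearest centre
in the locally metric chart (azim·cos(elev), elev); cluster centroids are
3D means. Skewed cones overlap in projection and get split among
neighbours, so clusters with ≥ 10% of points whose 3D nearest neighbour
belongs to a different cluster are flagged, and each flagged cluster's
neighbourhood of 6 nearest clusters is re-partitioned: a seeded
differential-evolution search over two plane-orientation angles
minimizes the mean projected point-to-centre distance plus the mean
cluster aspect ratio (longest/shortest 3D semi-axis via SVD). Because
neighbouring cones are nearly parallel and elongated, the optimum is
near the plane orthogonal to their shared axis, where projected clusters
are compact. A repair is committed only if it leaves < 5% problematic
points in the neighbourhood and improves on the original labels.

**Per-cone measures.** Adjacency uses mutual proximity below 1.5× the
median nearest-centroid distance (robust at eye borders, where Delaunay
adjacency degenerates). Lens diameter is the mean distance to adjacent
centroids. The ideal axis (local surface normal) is the average of the
plane normals of all centroid triplets among the cone and its adjacent
neighbours, oriented outward; the cross products are averaged
*unnormalized* (area weighting) because near-collinear triplets have
noise-dominated normal directions and would otherwise dominate the
average. The anatomical axis is the principal SVD semi-axis of the
cluster's points closest in angle to the ideal axis, oriented the same
way; skewness is the angle between the two, and the skew-adjusted
diameter is `D·cos θ_s`. Clusters with fewer than 4 points cannot
support an SVD axis; they inherit the ideal axis and are flagged. For IO
work each anatomical axis is replaced by the mean axis of all clusters
within 5 lens diameters (configurable); this suppresses the high
variance of raw axes while preserving gradients, at the cost of dragging
border axes inward — which is why the *raw* axes are used for the
projected field of view.

**IO angles.** The total anatomical IO angle of an adjacent pair is the
exact 3D angle between the two averaged axes — independent of any
reference frame, which keeps it rigid-motion invariant. Its horizontal
and vertical components split that total along the local tangent basis
defined by a configured anatomical "up" vector (default: the scan's +z),
scaled so the hypotenuse identity `Δφ = √(Δφ_h² + Δφ_v²)` holds exactly;
slab-by-slab projection onto vertical and horizontal section planes
yields the same components to first order in the angle. Pair orientation
is the direction of the centroid displacement in the same tangent basis,
folded to (−90°, 90°]. Pairs beyond 5× the median total angle are marked
outliers: they stay in the spreadsheet but are excluded from summaries.
Angular summaries are reported as median (IQR) since the distributions
are skewed.

**Oval-eye analysis.** Orientation modes come from a kernel-smoothed
histogram on (−90°, 90°] with wraparound (2° bins, 6° kernel, modes at
least 30° apart); pairs within 15° of a mode contribute to it. The
combined horizontal component pools the horizontal angles of diagonal
pairs with *half* the horizontal angles of horizontal pairs; the
combined vertical component pools the vertical angles of diagonal pairs.
Mode radii use `R = D/Δφ` with the pooled mean diameter; component radii
use the displacement the component actually subtends (half a diameter
horizontally, `√3/2` of a diameter vertically for diagonal pairs), which
is what makes the `R_v = 3·R_h` construction recoverable. The printed
diagonal/horizontal radius ratio of an ideal oval eye is reported from
the data, never assumed.

**Field of view.** Each cone's raw anatomical axis ray is intersected
with a sphere of configurable radius (default 10 cm, a behaviourally
relevant fixation distance) about the eye centre; the FOV is the angular
extent of the intersection directions, horizontally and vertically. Rays
missing the sphere are excluded and counted. The FOV is insensitive to
the projection radius beyond ~50 eye radii.

## The synthetic generators

Gratings are exact sinusoids; lattice images are sums of Gaussian spots
at hexagonal (or square) lattice nodes, clipped to the frame with a
default margin of half a spacing (so border spots are neither truncated
nor continued past the frame), plus optional white noise. Synthetic eyes
place cones on a toroidal surface patch looking along +x — vertical arcs
of radius `R_v`, equatorial horizontal arc of radius `R_h`; equal radii
give a sphere — at hexagonal angular spacing `D/R` with the azimuthal
step widened away from the equator so the physical centre spacing stays
`D`. Each cone is a line segment of points running inward from the
surface along its axis (surface normal, optionally tilted by a constant,
a positional field, or toward a target point), with isotropic Gaussian
jitter. Defaults: 30 points per cone, cone length `2D`, jitter σ = 1 µm —
a cleanly separated cone layer comparable to a well-stained scan at a
few µm voxel size. Every generator is bit-reproducible given its seed,
and ground truth (centroids, axes, per-point membership) is returned in
pipeline units.

What the generators deliberately do *not* emulate: intensity
inhomogeneity and uneven exposure across a scan, contact or fusion
between neighbouring cones, tissue other than the cone layer, lattice
defects and acute zones, and refraction. Passing tests therefore
demonstrate correct geometry and segmentation behaviour under controlled
conditions, not robustness to staining artefacts; on real scans the
density prefilter and mask quality dominate.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_fundamentals` | 3 | lattice axes sought (2 for square lattices / noisy images) |
| `cutoff_factor` | 1.25 | low-pass cutoff over max fundamental frequency |
| `min_distance_factor` | 0.25 | maxima separation over FFT diameter |
| `prominence_factor` | 0.25 | maxima height gate over median height |
| `significance_k` | 5 | reciprocal peak threshold in (capped) MADs |
| `window_deg` | 90 | rasterization window |
| `neighborhood_radius` | 5 | axis-averaging radius, in lens diameters |
| `section_width` | 1 | IO sectioning width, in lens diameters |
| `vertical_axis` | (0,0,1) | anatomical up in scan coordinates |
| `projection_radius_mm` | 100 | world-referenced FOV sphere |
| `seed` | 0 | feeds every stochastic step (cluster repair) |

## Known limitations

* The anatomical-axis noise floor (~1° median on clean synthetic eyes at
  1 µm jitter) sets the smallest detectable skew; skews below ~2° are not
  distinguishable from zero.
* Lens diameter is measured between cone centroids, slightly inside the
  lens surface; for strongly curved small eyes this underestimates the
  surface diameter by up to a few percent.
* Neighbourhood averaging biases IO components low within one
  neighbourhood radius of the eye border; median summaries over the
  whole eye are affected at the few-percent level, and small patches are
  affected more.
* Strongly skewed ommatidia can still be mis-segmented (the repair step
  only re-partitions; it cannot create or remove cluster seeds), and
  eyes with transitioning or strongly non-hexagonal lattices are out of
  scope, as are refraction-corrected (functional) optics — all IO angles
  and skews here are anatomical.

## Problem sizes

The test suite and examples use lattice images of 512² px with 45–4600
ommatidia, and synthetic eyes of 500–3000 cones (15–90 thousand points);
the full suite runs in well under a minute on one CPU. These sizes put
every estimate's sampling error well below the test tolerances while
keeping runs quick; the pipeline itself has no size-dependent logic and
has been run on 3000-cone eyes in a few seconds.
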