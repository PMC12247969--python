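# Methods

## Measurement model

A bilayer imaged in a tomogram presents two density maxima — the
phospholipid head-group (PHG) layers — on either side of the membrane
mid-surface. `memthick` models a density line scan across the membrane as

    f(x) = baseline + A₁ G(x − μ₁; σ₁) + A₂ G(x − μ₂; σ₂),

with G a unit-height Gaussian, and reports the thickness as the peak
separation μ₂ − μ₁. This PHG peak-to-peak spacing is deliberately *not*
the full bilayer width (head-group electron density peaks sit inside the
outer membrane boundary); it is the quantity that density-based
measurements of reconstituted vesicles report, which makes cellular and
in-vitro numbers comparable.

Assumptions built into the model:

* the mesh approximates the bilayer mid-surface well enough that the
  scan direction (the face normal) crosses both leaflets near
  perpendicularly — oblique crossings inflate the apparent separation;
* density is locally symmetric enough that two Gaussians plus a constant
  baseline capture the profile over ±10 nm; large adjacent densities
  (proteins, neighboring membranes closer than ~10 nm) violate this and
  are the main cause of rejected fits;
* head groups are density *maxima*. Tomogram sign conventions differ, so
  polarity is an explicit input (`peaks_bright`/`peaks_dark`/`auto`);
  auto-detection probes 500 random triangle centers and compares their
  mean density with the volume mean.

## Scanning and averaging

Scans run from −10 nm to +10 nm along each unit face normal in 0.25 nm
steps (81 samples), trilinearly interpolated; samples outside the volume
are dropped from the fit, not imputed. A single tomographic scan is far
too noisy to fit, so:

* **global thickness**: all per-face scans of a surface are averaged
  unweighted, then fitted once;
* **local thickness**: each face's scan is averaged with every face
  within a 12 nm geodesic radius, weighted w(d) = 1/(1 + d). Each
  neighbor's scan is taken along its *own* center and normal (not
  re-projected), and scans are computed once per face and reused, so a
  surface costs O(faces × neighborhood).

Distances here are *geodesic* — shortest paths through the face-adjacency
graph (faces adjacent iff they share an edge; edge weight = Euclidean
distance between face centers). Euclidean balls would leak across closely
apposed membranes such as opposing crista leaflets ~20 nm apart; graph
distance cannot leave the surface. The same metric drives the 8 nm edge
exclusion (faces within 8 nm of a boundary face are dropped — densities
near open mesh edges are corrupted by missing-wedge artifacts), with a
`euclidean` fallback available via `edge_margin_metric`.

## Fitting

Nonlinear least squares (unweighted, over valid samples) with:

* initialization: the two highest strict local maxima of a 3-sample
  moving-average smoothing, restricted to ±6 nm; σ starts at 0.7 nm,
  amplitudes at peak-minus-minimum, baseline at the scan minimum; if two
  clean maxima are not found, a symmetric ±1.8 nm start is used;
* bounds: μ within 1 nm of the scan ends, σ ∈ [0.3, 3] nm, A > 0;
* acceptance: optimizer success **and** 1 nm ≤ μ₂ − μ₁ ≤ 8 nm with both
  peaks in range. Anything else is returned as a non-converged in-band
  result — never an exception — because implausibly wide "thicknesses"
  are exactly the failure mode density methods must refuse to report.

Because the Gaussian means interpolate between samples, recovered
separations are accurate far below the 0.25 nm step (noiseless phantom
bias < 0.005 nm).

## Statistics

Triangles vary in area, so per-surface summaries are area-weighted: the
per-surface statistic is the **area-weighted median** of per-face
thicknesses (smallest value whose cumulative area reaches half the
total). Groups of surfaces are summarized as mean ± 1.96·SE across their
per-surface medians, and compared pairwise with the two-sided
Mann–Whitney U test — surfaces, not triangles, are the observations,
since per-face values within a surface are strongly spatially correlated
by construction (the 12 nm kernel). The U test uses exact enumeration
when a sample is small (min(n, m) ≤ 8, or n + m ≤ 12) and there are no
ties, otherwise the normal approximation with midrank-tie and continuity
corrections. No multiple-testing correction is applied by default
(pairwise p-values are reported raw); a Bonferroni switch exists.

Curvedness stratification assigns faces to quantile bins
(0–0.5, 0.5–0.9, 0.9–0.95, 0.95–0.99, 0.99–1) by midrank empirical
quantile, making the partition invariant under monotone transforms of
curvedness; the contrast of interest is the top bin against the rest.

## Subcompartment classification

IMM faces are classified from their Euclidean center-to-nearest-center
distance to the OMM, relative to the per-surface *mode* distance (1 nm
area-weighted histogram bins; ties go to the lowest bin, since the IBM is
the closest compartment): excess < 4 nm → IBM, 4–14 nm (closed interval)
→ crista junction, > 14 nm → crista body. Center-to-center distance is
accurate to roughly a face diameter, small against the 4/14 nm
thresholds. Labels that cannot be computed geometrically (rough vs smooth
ER) are attached per surface or per face from user input.

## Patches

Particles are assigned to their nearest face (k-d tree; equidistant ties
break to the lowest face index) and rejected beyond 24 nm — the height of
an ATP synthase — to prevent cross-assignment between membranes. Patches
are 12 nm geodesic discs around the assigned faces. Randomized controls
match the particle-patch count, draw centers uniformly over eligible
faces (by count; faces are near-uniform in area after remeshing — an
area-weighted option exists), and enforce > 12 nm Euclidean separation
between centers by rejection sampling (seeded, deterministic). Patch
profiles extend from −10 to +30 nm along normals curated to point toward
the particle (random patches keep the component's consistent orientation);
per-patch thickness and curvedness summaries are area-weighted means.

## The phantom generator

Phantoms emulate exactly the features the measurement relies on: two
Gaussian density shells (σ = 0.8 nm, a realistic head-group width at
~1 nm voxels) at a known separation around an analytic mid-surface,
rendered at the 0.998 nm voxel size of a typically binned tomogram,
plus optional Gaussian blobs (macromolecule stand-ins) and i.i.d.
Gaussian voxel noise. Signed distances are computed analytically per
geometry — never from the mesh — so ground truth is exact and independent
of the code under test. The default plane is oriented obliquely to the
voxel grid (unit normal (2,1,2)/3): real membranes have no preferred grid
alignment, and an axis-aligned plane is a degenerate best case for
trilinear interpolation. The standard noisy condition is
amplitude/noise_sigma = 3, calibrated so that single-triangle fits are
unreliable while 12 nm-averaged fits converge — the regime that motivates
local averaging.

What the phantoms do *not* emulate: CTF modulation, missing-wedge
anisotropy (noise is isotropic and white), membrane crowding beyond the
two-slab/cristae geometries, realistic protein shapes, and segmentation
error (phantom meshes lie exactly on the mid-surface). Passing phantom
tests therefore demonstrates the correctness and precision of the
measurement machinery under known conditions, not the accuracy of any
particular biological dataset, where mesh placement error and anisotropic
artifacts add real variance.

## Problem sizes and defaults

| parameter | default | notes |
|---|---|---|
| scan range / step | ±10 nm / 0.25 nm | 81 samples per scan |
| averaging radius | 12 nm geodesic | weight 1/(1+d) |
| edge margin | 8 nm geodesic | boundary faces at distance 0 |
| separation band | [1, 8] nm | fit acceptance |
| patch radius / cutoff / control separation | 12 / 24 / 12 nm | |
| voxel size (phantoms) | 0.998 nm | binned-tomogram scale |
| phantom SNR | 3 | amplitude / noise σ |

Test and acceptance runs use planar meshes of roughly 1–2 thousand faces
in 64³–96³ volumes and a subdivision-3 icosphere (1280 faces) in a 127³
volume — sizes chosen so the full suite exercises every code path on a
single CPU in about two minutes while keeping per-surface statistics
well-populated (hundreds of retained faces after edge exclusion). The
group-discrimination study uses 6 surfaces per condition, matching a
realistic per-condition tomogram count.

## Known limitations

* Thickness is peak-to-peak PHG spacing; leaflet-resolved measurements
  and profile deconvolution (CTF correction) are out of scope.
* The dual-Gaussian fit assumes one bilayer in the ±10 nm window;
  membranes closer than ~10 nm to each other corrupt the baseline.
* Mode-distance classification needs the IBM to dominate the IMM area;
  heavily vesiculated inner membranes may need a hand-set mode.
* STAR particle input reads a single data loop with
  `rlnCoordinateX/Y/Z` in voxels of a user-stated pixel size; richer
  STAR dialects are not parsed.
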