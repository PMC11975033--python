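# Methods

## Coordinate frame and atlas model

All quantities live in a single atlas frame with fixed axis semantics:
axis 0 rostro-caudal (X), axis 1 dorso-ventral (Z), axis 2 medio-lateral
(ML). The atlas is an isotropic integer label volume (0 = background) plus a
region table forming a tree (unique ids and acronyms, one root, no cycles);
each leaf carries a functional category (motor / sensory / behavior /
other). Voxel `i` along any axis covers the half-open interval
`[i·s, (i+1)·s)` μm, indices 0-based; a physical point maps to the voxel
`floor(p/s)`, so points exactly on a gridline belong to the upper voxel and
no point is ever ambiguous. The midline is defined as half the ML extent of
the grid. These conventions are validated at load time; CCFv3-style volumes
at any isotropic resolution are supported (the voxel size for cell lookup
versus volume rasterization is a configuration choice, not hard-coded).

## Section registration

Each section is modeled as a plane affinely embedded in atlas space:
`q = A·p + b` with `A ∈ R³ˣ²`, `b ∈ R³` (9 parameters). The fit minimizes
`Σ‖A·pᵢ + b − qᵢ‖²` over ≥3 control-point pairs via an orthogonally-based
least-squares solve (`numpy.linalg.lstsq`); the minimizer is unique unless
the pixel points are collinear, which is detected from the smallest singular
value of the centered pixel coordinates (relative tolerance 1e-10) and
raised as a degeneracy error. The per-section root-mean-square residual (μm)
is stored with the transform. The 3×2 form permits oblique planes; nothing
constrains sections to exact coronal orientation, though the synthetic
generator produces coronal ones. No nonlinear warping is modeled: the
assumption is that within-section distortion is small relative to bin
widths, which holds for the binning task but would not for voxel-accurate
cytoarchitecture work.

## Mediolateral binning

Each cortical hemisphere is divided into 5 equal-width bins from the midline
to the lateral edge of cortex in the same AP slice; bin 0 is cingulate,
bins 1–2 medial, bins 3–4 lateral cortex. The anchor choice (midline →
lateral cortical edge) makes the most medial bin sit against the midline,
matching the anatomical reading of "cingulate = most medial bin". Explicit
tie rules, applied everywhere: a soma exactly on the midline is assigned to
the right hemisphere; bins are half-open in distance-from-midline with the
exact far edge clamped into bin 4; cells lateral of the extent are flagged
`in_extent = False`, excluded from counts but preserved in the output table.
For sections without atlas support (e.g. early-postnatal brains lacking a
reference atlas) the same rule accepts user-supplied per-section extents.
Axis summaries report the arithmetic mean and SEM (sample SD with the n−1
denominator over √n) of the rostro-caudal and dorso-ventral coordinates per
group; single-member groups report a null SEM with a warning rather than an
error.

## Injection-volume reconstruction

The surface of an injection site is the boundary of the 3D Delaunay
triangulation of the pooled outline vertices — equivalently their convex
hull (`scipy.spatial.ConvexHull`), oriented outward. This is the unique
parameter-free surface for a point cloud; true injection sites can be
mildly concave, so reported volumes are upper bounds in that case. Uniform
Laplacian smoothing then moves each vertex by `λ·(mean of topological
neighbors − vertex)` per iteration (defaults: 10 iterations, λ = 0.5 —
mild smoothing that cannot collapse or self-intersect a convex mesh;
recorded in provenance). A full step (λ = 1) on a tetrahedron maps each
vertex to the centroid of the other three, an affine map with determinant
−1/27; orientation is re-fixed after smoothing so enclosed volume stays
positive, and the 1/27 volume ratio is used as a closed-form regression
check. Smoothing contracts convex surfaces monotonically, so smoothed
volumes are systematically below the raw hull volume — deliberately, as the
smoothing exists for display-quality surfaces, and quantitative volume
checks use 0 iterations.

Rasterization keeps exactly the voxels whose **centers** lie inside the
closed surface (no partial-volume weighting), on a grid anchored at the
atlas origin so injection solids and structure masks share indices.
Containment is an axis-aligned ray-parity test vectorized over columns of
voxel centers; ray origins are offset by a fixed irrational sub-voxel
fraction (≈1e-4 of the mesh extent) so rays cannot pass exactly through
mesh edges — gridline-aligned geometry (the exact-cube fixture) is handled
without simulation-of-simplicity machinery, at the cost of displacing test
points by ≲0.1 μm, far below any voxel size in use. Percent overlap is
`100·|A∩B|/|B|` on identical grids; mismatched voxel sizes are an error,
not an implicit resample.

Numerical behavior: the voxelized volume of an ellipsoid (radii 800/600/500
μm) is within 5 % of `4/3·π·abc ≈ 1.0053 mm³` at 100 μm and within 2 % at
50 μm. Surface sampling matters for such checks: the hull of n *random*
surface points underestimates the enclosed volume by O(n^(−2/3)) (≈2 % at
n = 500), so convergence fixtures sample the surface on a Fibonacci lattice
(deficit ≈0.3 % at n = 1000) to isolate rasterization error from sampling
error. Synthetic injection *outlines* keep random sampling, which better
emulates hand-drawn boundaries.

## Axon-collateral quantification

Per section and region, the signal is the masked intensity sum
`Qᵢ = Σ Rᵢ·Sᵢ` with `Rᵢ` a binary mask and `Sᵢ` the non-negative signal
channel; integer inputs are summed in int64, so results are exact. Region
size is the active-pixel count of the mask. Segmentation masks are inputs
(exported by an external segmentation tool); masks of different regions may
overlap at boundaries — overlaps are counted and logged, never rejected,
since the upstream segmentation makes no exclusivity guarantee. Raw sums
are summed across sections per (animal, region) **before** normalizing by
the animal total (a single animal-level denominator, rather than averaging
per-section fractions, so sections with little tissue are weighted by their
actual signal); fractions are therefore invariant to any global intensity
rescaling of an animal and sum to 1 per animal by construction. A
zero-total animal is an error naming the animal.

## Connectivity maps

Group statistics are mean ± SEM of the per-animal fractions; a (group,
region) pair missing for some animal is imputed as 0 for that animal before
averaging (dropping it would bias means upward). Map rules, all strict
inequalities: node iff mean·100 > 1; edge iff mean·100 > 5; edge thickness
`min(mean·100, 20)/20` — linear to the cap, the minimal scaling law
consistent with a stated cap, recorded in the map metadata. A region at
exactly 1 % is excluded. Bubble values equal the group-mean fraction.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions for every test:

* **Toy atlas** — 60×40×80 voxels at 100 μm (0.192 Mvoxel, small enough for
  brute-force voxel oracles in seconds): a symmetric dorsal cortical shell
  spanning ML 500–7500 μm (midline 4000 μm) over AP slices 6–33, and seven
  8×8×8 nucleus blocks (MRN, SC, PAG / SPV, IRN, PARN, GRN) with a
  two-level hierarchy and categories, corners jittered ±2 voxels per seed on
  slots spaced so blocks can never overlap or touch the cortex.
* **Sections & cells** — 4 coronal sections with random in-plane frames
  (rotation, 2–5 μm/px anisotropic scale, offset); 5 control points each,
  exact unless pixel noise σ > 0. Cohorts realize *exact* planted class
  counts (largest-remainder apportionment; default 1000 cells/group with
  cingulate/medial/lateral = 0.25/0.60/0.15 for the medial-projection group
  and 0.05/0.15/0.80 for the lateral group, mirroring the qualitative
  medial-vs-lateral contrast such experiments are designed around). Cells
  sit at relative bin positions in (0.05, 0.95), so recovery is exact at
  σ = 0 by construction and robust to sub-half-bin jitter.
* **Injections** — ellipsoid surfaces with closed-form volumes; truth
  overlaps come from an independent per-voxel scan of the ellipsoid
  inequality, re-runnable from recorded parameters alone.
* **Axon images** — per (section, region) masks cut from atlas slices and a
  per-section signal channel with Poisson counts at per-pixel rate
  `λ = f·T/N` (f planted fraction, T = 2×10⁶ expected counts per animal, N
  mask pixels across that animal's 6 sections — every region ≥1.4×10⁵
  expected counts, giving relative sampling error ≪ the 0.02 absolute
  recovery tolerance). Poisson, not Gaussian, noise: non-negative with
  variance scaling like photon counts. A no-noise mode writes λ itself for
  exact-identity tests.

Not emulated: optical blur and background autofluorescence, bleed-through,
section damage/folding, nonlinear tissue deformation, segmentation errors
(masks are taken as correct), and concave injection geometries. Passing
tests therefore demonstrate correctness of the *quantification chain* under
known geometry and counting noise — not robustness to upstream imaging or
segmentation artifacts.

## Pipeline and determinism

The pipeline stages (register → map cells → reconstruct volumes → quantify
axons → connectivity) draw no random numbers; all stochasticity lives in
the generators, which are deterministic per seed (`numpy.random.default_rng`).
A YAML config is validated before any stage runs (threshold ordering
0 ≤ include ≤ edge ≤ cap, positive voxel size, λ ∈ (0,1]) and serialized —
defaults included — into `provenance.json`, which deliberately contains no
timestamps so identical config + inputs reproduce byte-identical outputs.
Problem sizes throughout (0.19 Mvoxel atlas, 2000 cells, 10³–10⁴-voxel
solids, 6 animals × 6 sections) were chosen so that every brute-force
oracle and the full suite run in seconds on one core while keeping Poisson
and binomial sampling errors an order of magnitude below the tolerances
they are checked against.

## Known limitations

* Convex-hull surfaces upper-bound concave injection sites; no alpha-shape
  reconstruction is offered.
* Percent overlap requires matching grids; there is no implicit resampling
  between atlas resolutions.
* The midline is the geometric ML center of the grid; atlases cropped
  asymmetrically would need an explicit midline override (not currently
  exposed).
* Hemisphere assignment and binning assume the ML axis is axis 2 as
  declared; volumes with permuted axes must be converted on import.
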