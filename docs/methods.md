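# Methods

This note records the models, conventions, numerical choices and known
limitations behind `tmeprox`, in the order the pipeline runs.

## Coordinates, units, regions

All geometry is continuous Cartesian in microns, y increasing downward
(image convention). Areas are reported in mm² (1 mm² = 10⁶ μm², one
constant in `core_io`). Marker positivity enters as precomputed binary
flags; a fixed-cutoff helper (`call_positivity`) exists for callers holding
raw intensities, but no gating model is fit — positivity calling belongs to
the upstream segmentation software.

The intratumoral region (IT) is the union of the annotated tumor polygons
minus exclusion polygons. The peritumoral region (PT) is the outward
Euclidean dilation of the tumor union by the band width (default 100 μm)
minus the tumor and exclusions, clipped to the tissue polygon when one is
supplied. Dilation uses round buffer joins with 64 segments per quarter
circle; at that resolution the polygonal band area is within ~0.01% of the
analytic Minkowski area (perimeter·w + πw² for convex shapes), and the test
suite additionally checks it against a 1-μm rasterized distance-transform
oracle. Because bands are built from the *union*, nearby tumor nodules never
double-count overlapping band area. Interior holes of annotated tumors
receive an inner band automatically (the dilation shrinks holes); tissue
clipping is the only mechanism that suppresses banding at specimen edges.

Boundary ties are deterministic: the tumor is a closed set, so a cell
exactly on the tumor border is IT; a cell exactly on the outer band edge is
PT; exclusion takes precedence over both. Cell region labels depend only on
the centroid. Exclusions are removed from numerator (cells) and denominator
(area) of every density, so necrotic foci bias nothing.

## Densities, area fraction, PD-L1 score

A density is (marker-positive cells with the region label) / (region area
in mm²). TOTAL is the pooled IT+PT count over the pooled area — a union
region, not the mean of two densities. The PD-L1 area fraction is positive
pixels / tissue pixels with excluded pixels removed from both sides; the
pixel size must be supplied by the caller, never read from image headers.
The pathologist-style score bins percent-positive per compartment (tumor
cells, immune cells, or both, resolved from assigned lineages) into
<1%, 1%, 2–4%, 5–9%, 10–19% and ten-point bins thereafter, with the
binomial positive call at ≥1%.

## Serial-section registration

Markers stained on consecutive 4-μm sections are brought into one frame by
landmark registration: matched fiducial pairs, least squares. The rigid and
similarity fits are closed-form orthogonal Procrustes (SVD); reflections are
disallowed for those models and raise an error recommending the affine
model, except when the landmark cross-covariance is rank-deficient (e.g.
two landmarks), where the free singular direction is chosen reflection-free.
The full affine fit is a rank-checked linear solve. The achieved RMSE (μm)
is always returned; when it exceeds the 20-μm proximity radius a warning is
raised, because cross-section proximity counts then carry alignment error
of the same order as the effect being measured. Deformable registration is
out of scope — cut-to-cut tissue distortion beyond an affine map is an
acknowledged, unquantified error source.

## Proximity metrics

The headline metric counts source-marker cells having at least one
target-marker cell within the radius (default 20 μm), normalized by the
total TME (IT+PT) area; a source cell counts once regardless of how many
targets are near. The comparison is strict `<` by default, with an
`inclusive` flag for the `<=` convention. Distances are
centroid-to-centroid by default; `edge_mode="surface"` subtracts both cell
radii (floored at zero) to approximate membrane-to-membrane distance, with
the caveat that the two conventions differ by at most r_source + r_target.
Queries run on a k-d tree and are exact; the brute-force O(n²) scan lives
in the test suite as an independent oracle, never in the implementation.

When source and target populations come from the same physical section, a
dual-positive cell appears in both and is excluded as its own neighbor
(matched by cell id) — otherwise every PD-1+PD-L1+ cell would trivially
count at distance zero, precisely the artifact a distance-based metric is
meant to avoid. Populations from different (registered) sections have no
such identity and nothing is excluded.

## Phenotyping

Lineages are assigned by prioritized marker rules; the highest-priority
match wins and multi-rule matches are tallied as ambiguous. The default
hierarchy is tumor (NSE+) → CD8 T → Treg (CD4+FoxP3+) → CD4 Teff → B
(CD20+) → macrophage (CD68+) → other; NSE first prevents immune-marker
bleed on tumor-adjacent segments from eating tumor cells. PD-1 is kept
orthogonal to lineage, so tumor-cell PD-1 (a real, if rare, phenomenon) is
representable. Hot-spot selection takes the k fields richest in immune
cells, ties broken by field id. The default high-power-field area is
0.335 mm² (a 20× field of 0.65 × 0.52 mm); it is configurable because
instrument fields vary and no single value is canonical.

## Cohort statistics

Group comparisons use the two-sided Mann–Whitney U test: exact enumeration
when the pooled sample is ≤16 without ties, otherwise the normal
approximation with tie and continuity corrections. The continuity
correction makes the asymptotic p mildly conservative; the permutation-null
test asserts calibrated type-I control rather than exact uniformity for
this reason. Chi-square is Pearson's with optional Yates correction for
2×2. Quartiles are rank-based (competition ranks, quartile =
ceil(4·rank/n)), so tied specimens fall in the lower quartile and sizes
differ by at most one without ties. No multiple-testing correction is
applied by default (comparisons are reported unadjusted); a
Benjamini–Hochberg helper exists.

"Controlling proximity for the marginal densities" is not a uniquely
defined operation; the implementation regresses proximity-density ranks on
the two marginal density ranks (least squares with intercept) and compares
the residuals between responder groups with the Mann–Whitney test. The
result is labeled as this interpretation in its output. An exact fit
(proximity a deterministic function of one density) leaves numerical noise
that is not exchangeable, so residuals below 10⁻⁸·n are snapped to zero and
a degenerate all-zero residual vector returns p = 1.

## Synthetic TME generator

The generator exists because studies of this kind deposit no cell-level
data; it produces specimens with the statistical structure the analysis
assumes, so tests exercise the real pipeline end to end.

*Geometry.* The tumor border is a radial Fourier perturbation of a disk
(default mean radius 450 μm, relative roughness 0.12, six harmonics with
1/√k amplitude decay); outlines that self-intersect are regenerated with
damped roughness. An optional necrotic exclusion blob occupies a configured
fraction of tumor area (5% in the cohort presets); cells falling in it are
thinned to 20% residual debris, exercising the EXCLUDED path.

*Point processes.* Tumor cells are homogeneous Poisson inside the tumor
(default 2000 cells/mm², a dense small-round-blue-cell tumor). Immune cells
follow an inhomogeneous Poisson process with intensity λ₀·exp(−d/τ) in
distance d from the tumor–stroma interface on both sides (decay τ = 75 μm),
emulating interface-enriched infiltrates; sampling is exact thinning of a
homogeneous proposal. Immune lineage shares default to CD8 0.45 / CD4 0.30
/ CD20 0.08 / CD68 0.07 (archival preset: CD8 = CD4 = 0.42 so the CD8+PD-1+
and CD4+PD-1+ densities come out comparable); FoxP3 is Bernoulli(0.22)
within CD4; PD-1 is Bernoulli per immune cell, independent of lineage.

*PD-L1 modes.* In adaptive mode every cell's PD-L1 probability is
logistic(α + β·c) where c is its PD-1+ neighbor count within 20 μm
(β = 0.9) — ligand induced where the infiltrate attacks. In constitutive
mode PD-L1 is Bernoulli on tumor cells only, independent of the
infiltrate. Given a target PD-L1+ count, α (or the Bernoulli p) is solved
by root finding over the cells inside the analysis region, so the expected
within-TME count equals the target by construction. This is what makes the
proximity metric discriminating in simulation: at matched marginal PD-1 and
PD-L1 densities, adaptive specimens put systematically more PD-1+ cells
within 20 μm of a PD-L1+ cell than constitutive ones.

*Cohort presets.* Each specimen draws total-TME density targets for CD8+,
PD-1+ and PD-L1+ cells from lognormals around the group medians
(responder-like: 70.7 / 264 / 855.4 cells/mm², σ = 0.55 / 1.0 / 0.7,
adaptive PD-L1; non-responder-like: 6.7 / 216.6 / 245, σ = 0.9 / 0.8 / 0.7,
constitutive PD-L1), with z truncated at ±2.5 to keep the spread near the
anchor ranges. The CD8 distributions overlap heavily by design, so CD8
density does not separate the arms. The immune peak intensity is solved
from the CD8 target via a 20-μm grid integral of the interface-decay kernel
over the realized IT+PT geometry, and the PD-1 probability from the ratio
of targets — expectation matching by construction, not rejection sampling.
All downstream metrics are computed by the real pipeline, never by
shortcut formulas.

*Serial sections.* Section B is a random rigid transform of section A
(rotation σ = 3°, offset σ = 40 μm) plus per-cell Gaussian jitter (1 μm)
and Bernoulli dropout (0.1), with noiseless fiducial landmark pairs and the
ground-truth transform returned for registration tests.

*Determinism.* Each specimen uses `numpy` Philox/PCG streams seeded by
(cohort seed, specimen index), so cohorts are bit-reproducible and
insertion-order independent.

*What the generator does not emulate* — and hence what passing tests do not
show about real data: segmentation and positivity-calling errors, staining
batch effects, anisotropic tissue deformation between sections beyond a
rigid map, spatial clustering of immune cells beyond interface decay
(tertiary lymphoid structures, perivascular cuffs), specimen-to-specimen
geometry diversity beyond blob roughness, and any link between viral status
and the infiltrate. Cohort-level conclusions from simulation are statements
about the pipeline's correctness and power under the modeled structure, not
evidence about patients.

## Problem sizes and runtime

Default synthetic specimens carry ~2,000 cells over ~1.2 mm² of TME, and a
17-vs-8 cohort simulates in about a second; the cohort-structure test runs
100 independent cohorts. The acceptance script runs one full cohort, thirty
separation-rate cohorts and sixteen archival specimens in under a minute on
one CPU.

## Known limitations

* Proximity across serial sections inherits registration error; the 20-μm
  warning threshold is a heuristic, not a correction.
* The pathologist PD-L1 score is computed from the same flags as the
  digital density — any systematic difference between human and digital
  positivity calls is not modeled.
* Rank residualization is one reading of "density-adjusted"; stratification
  or matching would be alternatives, and with n ≈ 25 none is powerful.
* The quartile tie rule (ties to the lower quartile) can unbalance quartile
  sizes when many specimens tie exactly.
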