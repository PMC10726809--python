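# Methods

This note records the models, estimators, numerical choices and known
limitations behind each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Coordinate and unit conventions

Label volumes are `(nz, ny, nx)` grids of non-negative integers, 0-based,
with the center of voxel `(k, j, i)` at physical `(k·dz, j·dy, i·dx)`
nanometers. The default spacing (10, 10, 50) nm matches serial block-face
SEM acquisition with fine in-plane sampling and a coarser sectioning step.
Spacing lives in a JSON sidecar (`dx_nm`, `dy_nm`, `dz_nm`) rather than in
TIFF tags, because resolution metadata written by segmentation tools is
unreliable. Morphometric outputs are in µm, µm² and µm³.

## 3D morphometry

**Volume** is voxel count × voxel volume — exact with respect to the
segmentation, and used as the oracle in tests.

**Surface area** comes from a marching-cubes isosurface at level 0.5 of
the Gaussian-smoothed indicator field (σ = 1.5 voxels per axis, in index
space). Raw marching cubes on binary data reproduces the voxel staircase
and overestimates a sphere's area by roughly 20% at the default
anisotropic spacing; because the blurred indicator of a half-space crosses
0.5 exactly at the true surface, the anti-aliased estimator is unbiased on
locally flat boundaries with curvature bias of order (σ/R)², and measures
a 0.5 µm sphere's area to about 0.3%. Objects so thin that blurring
removes the 0.5 crossing (e.g. single voxels) fall back to the unsmoothed
isosurface, which is still closed. No smoothing is ever applied to the
mesh itself. The naive exposed-voxel-face area (~1.5× too high on
spheres) is retained in the test suite as an upper-bound oracle.

**Perimeter** is reported as the mean over occupied slices of the exposed
in-plane boundary-edge length (4-connectivity within a slice; an exposure
toward a missing y-neighbor contributes dx, toward a missing x-neighbor
dy). The mean makes the quantity intensive — comparable between objects
spanning different numbers of sections — while the per-object sum is kept
as an auxiliary column (`perimeter_total_um`) for workflows that prefer a
total.

**3D length** is the maximal Feret diameter: the largest pairwise distance
between surface-voxel centers in physical coordinates, computed on the
convex hull for tractability (with a brute-force fallback for degenerate
point sets). Center-to-center distances undershoot the true outer extent
by up to one voxel; phantom tests therefore allow one z-step of slack.
A skeleton-based geodesic length (which would differ for curved
mitochondria) is deliberately out of scope.

**Sphericity and MCI.** Ψ = π^⅓(6V)^⅔/SA. Two MCI normalizations
circulate; the original `vincent` form SA³/(16π²V²) is the default, and
the `sphere_normalized` form SA³/(36πV²) ≡ Ψ⁻³ is available. Every output
row records which variant produced it.

**Connected components** default to 26-connectivity, matching manual
tracing that bridges diagonal contacts between sections. Components are
found independently within each input label, so distinct touching objects
are never merged, and are renumbered in raster-scan order of their first
voxel for determinism.

## 2D TEM morphometry

Area is pixel count × pixel area; reported perimeter is the exposed
pixel-edge length (a single 10 nm pixel has perimeter 0.04 µm).
**Circularity** 4πA/P² instead uses a Crofton 4-direction perimeter
estimate: the raw edge count measures Manhattan boundary length, which
would deflate a perfect disc's circularity to π²/16 ≈ 0.62, while the
Crofton estimate converges to the Euclidean length for smooth outlines.
The trade-off is a bias of order 10% on axis-aligned polygon phantoms
(directional estimators undercount straight axis-parallel boundary).
Circularity is capped at 1.0, as in ImageJ's particle analyzer, because
digital estimates can exceed 1 for objects a few pixels across.

**Aspect ratio** is the axis ratio of the second-moment-equivalent
ellipse, with the 1/12-pixel variance of the square pixel footprint added
to the moment matrix — a single pixel is then exactly 1, and degenerate
one-pixel-wide objects stay finite.

**Cristae score** (ordinal 0–4): 0 — no sharply defined cristae; 1 — more
than 50% of the cross-section lacks cristae; 2 — more than 25%; 3 — at
most 25% lacking but irregularly shaped cristae; 4 — at most 25% lacking
and regular cristae. The published rubric leaves exactly 25% unassigned
(score 2 requires "over 25%", 3–4 say "less than 25%"); this
implementation assigns 25% to the 3/4 branch, preserving the strict
inequality of score 2. Cristae "surface area" from a 2D micrograph is
reported as cross-sectional area; no 3D extrapolation is attempted.
Quadrant subsampling during acquisition is a manual step; the pipeline
records a `sampled_region` tag but does not simulate it.

## Cohort statistics

Two units of analysis are supported and must be chosen explicitly:
per-animal means (each animal one dot; the whole-cohort convention) or
per-mitochondrion pooling (the in-vitro panel convention). They imply very
different degrees of freedom, so there is no silent default.

The unpaired *t* uses the pooled-variance Student form — the classical
two-group test, and the form whose machinery Fisher's protected LSD
reuses — with Welch available behind a flag. Mann–Whitney p-values are
exact (full enumeration of group assignments, tie-safe via 0.5-counting)
for combined n ≤ 12, and use the normal approximation with tie correction
above that. Fisher's LSD builds pairwise t statistics on the pooled
within-group mean square with its df; all pairwise p are emitted, with a
`protected` flag recording whether the omnibus gate (p ≤ 0.05) passed.
Star annotations use the inclusive thresholds p ≤ 0.05/0.01/0.001/0.0001.

Percent-of-total histograms use half-open bins with the last bin closed;
exact float percentages are returned, and a largest-remainder rounding
helper keeps displayed percentages summing to exactly 100. Mito-otyping
sorts objects ascending by volume (ties by object id) into a row-major
grid, so the montage layout is deterministic.

## qPCR (∆∆Ct)

Technical replicates are averaged; replicate SD above 0.5 cycles is
flagged, never auto-dropped (no exclusion rule exists in the protocol).
∆Ct = Ct_target − Ct_reference per sample; ∆∆Ct = mean ∆Ct(experimental)
− mean ∆Ct(control); fold change = 2^(−∆∆Ct), so negative ∆∆Ct means
higher expression in the experimental group. The sign convention was
fixed against the two published fly-tissue tables shipped as package
data (32 rows): recomputed fold changes match the printed ones at printed
precision, to within one unit in the last printed digit. Exact equality
for all rows is impossible because the printed ∆∆Ct column is itself
rounded to three decimals, which can shift the third decimal of
2^(−∆∆Ct); 25 of 32 rows agree exactly, the other 7 by one final-digit
unit. Per-gene significance uses the unpaired *t* on per-sample ∆Ct.
Amplification-efficiency-corrected (Pfaffl) and standard-curve methods
are out of scope.

## Stress-test OCR

Phases (basal / oligomycin / FCCP / rotenone+antimycin) are delimited by
the injection annotations — not by hard-coded measurement-interval
indices, since plate programs vary. Readouts per phase: basal and
non-mitochondrial use the phase mean, oligomycin the phase minimum,
FCCP the phase maximum ("the peak"); the choices are recorded in each
summary's metadata. After subtracting the non-mitochondrial floor:
basal = atp_linked + proton_leak and reserve = maximal − basal hold
exactly by construction, and any constant added to a trace leaves all
corrected summaries unchanged. A negative corrected basal is flagged
(`negative_basal_after_correction`), not raised — it happens in real
noisy wells. ECAR/glycolysis analysis and protein normalization are out
of scope.

## Lipidomics

Names follow `CLS xx:x/yy:y`. Duplicate features keep the reading with
the highest total abundance. Display-style normalization divides each
feature by the median of the young samples and log2-transforms.

The moderated *t* assumes feature variances drawn from a scaled inverse
chi-square prior (d₀, s₀²) estimated by method of moments on the log
residual variances (digamma/trigamma matching); posterior variances
s̃² = (d₀s₀² + d·s²)/(d₀ + d) feed t statistics with d + d₀ df. The two
limits are exposed and tested: d₀ = 0 recovers the ordinary two-sample
*t*, d₀ = ∞ a z-like statistic at the prior variance. The exact
hyperprior estimator used by upstream omics packages is not specified in
this pipeline's sources; the method-of-moments choice is recorded in the
result metadata (`attrs["prior"]`). BH-FDR is a step-up with enforced
monotonicity; differential significance requires adjusted p < 0.05 and
|log2 FC| > 1.

Enrichment (LSEA) ranks features by log2 fold change (ties broken by
name) and scores each class or total-chain-length set with the GSEA-style
weighted KS running sum: hits advance a |logFC|-weighted cumulative,
misses advance a uniform one, and the ES is the signed maximal gap. A set
containing every feature has no misses to contrast against and scores 0.
The null is random membership permutations of equal size;
p = (1 + #{|ES_perm| ≥ |ES|})/(1 + n_perm), BH-adjusted across tested
sets; sets below the minimum size (default 4) are reported untested.
Results are bit-reproducible given (seed, n_perm). Chain-length sets use
each distinct total carbon count as a candidate set, since no bucket
edges are prescribed.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); the single seed
fans out through fixed `SeedSequence` spawn keys, one per generator, so
adding a generator never perturbs another's draws.

- **Phantoms** are rasterized by voxel-center inclusion with closed-form
  volume, surface and extent (branched unions are flagged approximate:
  junction overlap is not subtracted).
- **Cohorts** default to the study scale — 3 animals × 175 mitochondria
  per age group — with log-normal per-mitochondrion heterogeneity
  (volume geometric mean 0.4 µm³, log-SD 0.8, typical of intermyofibrillar
  populations), a multiplicative per-animal random effect, and aged
  multipliers below 1 for size metrics (0.6–0.75) and above 1 for
  sphericity (1.15), matching the reported direction of aging effects.
  The per-animal effect SD defaults to 0.08: age-group differences in
  this design reach four-star significance with only three animals per
  group, which requires between-animal replicate variation well under
  10%. Metrics are generated independently per row; the generator does
  not reproduce the physical V–SA–Ψ coupling of a single object, so it
  validates the statistical pipeline, not the geometry estimators (the
  phantoms do that).
- **TEM scenes** place non-overlapping ellipses with stripe cristae;
  real micrograph texture, membrane contrast and segmentation error are
  not simulated.
- **qPCR plates** share a per-replicate loading offset between reference
  and target (what reference normalization removes) plus gene-specific
  cycle noise; amplification-efficiency differences are not modeled.
- **OCR traces** are plateau + Gaussian noise; injection transients and
  drift are not modeled.
- **Lipidomes** draw log-normal abundances with class-level log2 shifts
  in the aged group; correlated co-regulation within classes beyond the
  mean shift is not modeled.

Consequently, passing tests demonstrate estimator correctness on known
geometry and correct statistical behavior (power, calibration, exactness
of identities) under idealized noise — not robustness to segmentation
error, batch effects or instrument drift.

## Problem sizes and reproducibility

Simulation-based checks use 200 seeds for power properties, 500 for
recovery and null-calibration properties, and permutation counts of
10³–4×10⁴ in tests (the enrichment CLI defaults to 10⁵); these sizes give
Monte-Carlo standard errors well below the asserted margins. The
acceptance script (`scripts/acceptance.py --seed S --out f.json`)
recomputes every headline quantity from scratch in well under a minute on
a single CPU, deterministically in `S`.

## Known limitations

- The sectioning-axis step recorded in a sidecar is taken at face value;
  the pipeline does not attempt to reconcile conflicting acquisition
  metadata (e.g. nominal z-resolution vs physical section thickness).
- Whether published whole-cohort comparisons pooled mitochondria or used
  per-animal means is convention-dependent; both modes are provided and
  must be selected explicitly.
- Nanotunnel detection and network/branch topology beyond Feret length
  are not implemented.
- Circularity estimates carry a rasterization bias of order 10% on
  sharp-cornered axis-aligned shapes (see above); for the smooth blobs
  the metric is designed for, the estimator converges.
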