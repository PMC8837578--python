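# Methods

This note documents the models, conventions and numerical choices behind
`wmbottleneck`, and what the phantom-based validation does and does not
establish.

## Spherical-harmonic FOD representation

FOD volumes are stored as even-order real symmetric spherical harmonics.
The basis (`basis_convention = "real-sym-lm-scipy"`) is built from scipy's
complex harmonics `Y_l^m` (Condon–Shortley phase included), ordered by
ascending even degree `l = 0, 2, …, lmax` and, within a degree, ascending
order `m = −l … l`, with

```
m < 0:  √2 · Im(Y_l^|m|)      m = 0:  Y_l^0      m > 0:  √2 · Re(Y_l^m)
```

This basis is orthonormal; the convention string and `lmax` are written to
a JSON sidecar next to every FOD NIfTI so files are self-describing.  FOD
basis conventions differ between tools, and coefficients are meaningless
without a declared ordering/normalization — hence the explicit sidecar.

### Lobe synthesis (forward model)

Phantom FODs are mixtures of axially symmetric lobes with kernel
`K_κ(θ) = exp(κ(cos²θ − 1))`, κ = 50 by default (half-width ≈ 13°, sharp
enough that two lobes 40° apart are clearly bimodal at lmax = 8).  The SH
coefficients are obtained *exactly* through the Funk–Hecke theorem: the
kernel's Legendre transform `λ_l = 2π∫K(t)P_l(t)dt` is evaluated by
200-point Gauss–Legendre quadrature and the lobe's coefficients are
`λ_l · Y_lm(d)`.  An earlier least-squares projection over a discrete
sphere mesh was rejected: mesh anisotropy left an orientation-dependent
amplitude bias of ~2·10⁻⁴ between identical lobes at different
orientations, whereas the zonal projection is rotation-equivariant to
machine precision — which matters when tests assert symmetry between
equal-weight lobes.

## Fixel extraction

Peak search is discrete-then-refined:

* **mesh**: subdivided icosahedron, 2562 vertices (≈ 2.5° spacing),
  centrally symmetric, so antipodal deduplication is exact (canonical
  hemisphere: z ≥ 0, ties by y then x);
* **local maxima**: vertices whose amplitude is ≥ all one-ring neighbors
  and > 0, prefiltered at half the absolute threshold (refinement only
  raises amplitude, so no true peak is lost);
* **refinement**: 20 iterations of projected gradient ascent on the
  continuous SH surface, central-difference tangent-plane gradients
  (ε = 10⁻³), step 0.1 rad halved on non-improvement, batched over all
  candidate peaks of all voxels;
* **threshold**: the refined amplitude must reach the absolute peak
  threshold, default **0.1** — the standard choice for suppressing
  spurious FOD peaks.  The threshold is applied to the refined amplitude
  (the refined value is the better estimate of the true lobe height);
* **merging**: refined peaks closer than 5° collapse to the larger one;
  at most `max_fixels` (default 3) survive, descending amplitude.

Lobe segmentation assigns every positive-amplitude mesh vertex to a local
maximum by steepest ascent along mesh edges (pointer doubling, vectorized
per voxel block).  Basins whose maximum does not correspond to a retained
peak (within 15°, and at comparable amplitude — lmax-8 ringing puts tiny
local maxima everywhere, so direction alone is not evidence) are dropped.
A fixel's orientation is the amplitude-weighted mean of its member
directions sign-aligned to the peak — the mean orientation of the lobe,
not the raw argmax; the refined peak direction is kept as a secondary
field.  The lobe integral is the quadrature sum of member amplitudes over
per-vertex areas (one third of adjacent triangle areas, normalized to 4π);
uniform `4π/N` weights would leave a ~1% orientation-dependent bias
because icosphere vertex density is not uniform.

Degenerate voxels (all-zero or negative FOD, or no peak above threshold)
get zero fixels and are excluded from all denominators.

## Streamlines and voxel mapping

World coordinates are mm throughout; TCK files are native world-mm and TRK
voxel-scaled coordinates are converted through their header affine
(`nibabel.streamlines` handles both).  A point with continuous voxel
coordinate `v = A⁻¹p` belongs to voxel `floor(v)` — half-open boundaries
`[i, i+1)` per axis.  Streamlines are resampled at arc-length step
`0.25 ×` (smallest voxel edge) rather than exact segment–box clipping;
the path-length error is bounded by one step.  Per voxel, a streamline
contributes **one** visit (re-entries merge) whose direction is the
sign-aligned mean of its sample tangents — so a streamline is never
double-counted in a density map, matching the "count streamlines"
semantics of density-based assignment.

## Bundle assignment and counting

The 5%-of-maximum density threshold is applied per bundle against that
bundle's own maximum (each bundle's density map is an
independent measurement); a dataset-global maximum is available as an option.  The
comparison is inclusive (`count ≥ 0.05·max`, and `count > 0`).  Alignment
ties are broken toward the lowest flat fixel index for cross-platform
determinism.  `bundles_per_voxel` is the size of the union of bundle sets
over the voxel's fixels, so it always dominates the per-fixel maximum and
never exceeds the number of profiles — both asserted at classification
time, which would surface any counting bug as a hard error.

## Prevalence tables and bottleneck clusters

Histograms of bundle counts are reported for k = 1…6 and capped at "7+".
Denominators exclude zero-bundle elements; for the voxel table the all-WM
denominator is additionally reported (`voxel_fractions_all_wm`), since
both conventions are in use.  Empty denominators produce an explicit
empty-table marker, never NaN.

"Spatial clusters of coherent multi-bundle fixels" is operationalized as:
nodes = fixels with bundle count ≥ `min_bundles` (default 7); edges
between fixels in identical or 26-neighbor voxels whose orientations agree
within `angle_tol` (default 30°, antipodal); clusters = connected
components with voxel footprint ≥ `min_size` (default 5), sorted by
footprint.  All three knobs are configurable; the defaults are this
package's choice of a reasonable operational rule for a concept that is
usually presented visually.

## Phantom generator

Five analytic configurations on a 20³ grid of 1 mm voxels, 500
streamlines per bundle:

* **parallel** — two straight tubes 3 voxels apart (no interaction);
* **kissing** — two circular arcs (radius 12 mm) tangent at the grid
  center, curving apart;
* **overlap2 / overlap3** — two / three pathways converging into a shared
  straight 7-voxel corridor, then diverging to distinct endpoints;
* **sharp_crossing** — two straight lines crossing at a configurable
  angle (default 20°) at the grid center.

Streamlines are the centerline translated by a per-streamline Gaussian
offset (σ = 0.2 mm) in the plane perpendicular to the overall bundle
direction; translation preserves tangents, so centerline tangents are the
exact true orientations.  The ground truth is computed from the generated
streamlines themselves: a bundle occupies a voxel if at least 10% of its
streamlines traverse it (`min_presence_frac`).  Below that, a jitter tube
grazing a voxel face contributes a handful of streamlines whose presence
flips with the seed — partial-volume noise, not occupancy; at 10% every
voxel in these geometries is far from the decision boundary and truth
labels are seed-stable.  Per voxel, per-bundle mean directions are merged
greedily into orientation clusters when closer than `merge_angle`
(default 30°) — the generator's operationalization of "not resolvable by
the angular resolution".  The FOD is synthesized from the cluster
directions with weights proportional to per-cluster streamline counts,
normalized per voxel.  Region labels: *corridor* (some cluster holds ≥ 2
bundles), *crossing* (≥ 2 bundles, all clusters single-bundle),
*exclusive* (1 bundle), *background*.

Exact-recovery assertions run on region **cores**: region voxels not
face-adjacent (6-connectivity) to a differently-labeled occupied voxel.
The stripped ring is where partial-volume mixing is expected — that edge
behavior is the phenomenon under study, not a defect to assert away.
Face adjacency (rather than 26-connectivity) is used because mixing acts
across shared faces; corner contact contributes negligible volume, and
26-connectivity would empty the small crossing cores entirely.

A sub-resolution crossing (15° < merge angle) yields corridor truth:
one orientation cluster holding both bundles, hence a single fixel with
bundle count 2 — the bottleneck configuration — while a 90° crossing
yields two single-bundle fixels.  Both are verified end-to-end.

### What the phantoms do not emulate

No diffusion signal or noise model (FODs are synthesized, not estimated);
no fanning, curving-within-voxel, or axon-diameter effects; tube-shaped
bundles with stationary cross-section; single subject (population
averaging is out of scope).  Passing phantom recovery therefore shows the
*pipeline logic* (fixel segmentation, assignment, counting, clustering) is
correct under known geometry — it does not certify FOD estimation quality
or segmentation quality on real data, where prevalence numbers depend on
acquisition, reconstruction and the bundle atlas used.

## Determinism and problem sizes

Every stage is deterministic given inputs; the only randomness is the
phantom jitter, driven by an explicit seed.  Outputs (fixel directory,
profiles, report JSON with sorted keys) are byte-identical across
equally-seeded runs.  Validation problem sizes — 200 random FODs for the
peak oracle, a 5³ grid with 3 bundles for the exhaustive recount, 20³
phantoms with 500 streamlines per bundle for recovery — were chosen so
each check exercises the full code path while the complete suite runs on
a laptop-class single core in a couple of minutes.
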