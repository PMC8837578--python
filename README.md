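# wmbottleneck

Quantify **bottleneck regions** in white-matter fiber tractography.

The *crossing-fiber* problem — several differently oriented fiber
populations in one voxel — has dominated diffusion-MRI methods development
for two decades and is largely addressed by models that resolve multiple
orientations per voxel.  The *bottleneck* problem is harder: several
anatomically distinct bundles converge, temporarily share the **same**
orientation and trajectory through the same voxels, then diverge toward
different terminations.  No orientation model can disambiguate streamlines
inside such a corridor, so tractography produces false-positive (and
false-negative) connections there.  This package measures how prevalent
that configuration is, given

1. a 4D **FOD volume** (even-order real spherical-harmonic fiber
   orientation distributions, NIfTI + JSON sidecar),
2. one **streamline file per bundle** (TCK or TRK, world mm), and
3. a binary **white-matter mask** (NIfTI).

It is aimed at diffusion-MRI researchers studying tractography reliability,
and ships with a synthetic phantom generator so the whole pipeline can be
validated without any imaging data.

## Method

Per voxel, the FOD `f(u)` on the unit sphere is segmented into *fixels*
(discrete fiber elements): local maxima of `f` are found on a subdivided
icosahedron, refined by projected gradient ascent, kept if the refined
amplitude is at least an absolute threshold (default 0.1), and the surface
is partitioned into lobes by steepest-ascent watershed.  Each fixel carries
the amplitude-weighted mean orientation of its lobe.

Each bundle *B* is assigned to fixels via a **fixel-density map**: every
streamline increments, in each voxel it traverses, the fixel maximizing
`|t · d|` between its local tangent `t` and the fixel orientation `d`.
The map is thresholded at 5% of its own maximum to give a binary fixel
profile, projected to a binary voxel profile.  Counting profiles yields

* `bundles_per_fixel(f)` — number of bundles assigned to fixel `f`;
* `bundles_per_voxel(v)` — number of **distinct** bundles over the voxel's
  fixels (a bundle on two fixels of one voxel counts once).

Voxels and fixels are then classified on the
{single-fixel, multi-fixel} × {zero-, single-, multi-bundle} grid.  The
**single-fixel, multi-bundle** case is the bottleneck configuration, and
*bottleneck regions* are reported as connected clusters of
orientation-coherent fixels whose bundle count meets a threshold (default
7, with 26-neighbor voxel adjacency and a 30° angular tolerance).
Zero-bundle elements are excluded from every prevalence denominator.

## Worked example (synthetic phantom)

Three bundles funnel into a shared 7-voxel corridor, then fan out —
the canonical bottleneck:

```sh
bottleneck phantom --config overlap3 --out phantom --seed 1
cat > config.json <<'EOF'
{"fod": "phantom/fod.nii.gz",
 "wm_mask": "phantom/wm_mask.nii.gz",
 "bundles": ["phantom/bundle_B1.tck", "phantom/bundle_B2.tck", "phantom/bundle_B3.tck"],
 "min_bundles": 3, "min_cluster_voxels": 3}
EOF
bottleneck run --config config.json --out out
```

This prints the prevalence tables, including

```
"bundles_per_fixel": { "counts": { "1": 50, "2": 1, "3": 7, ... }, ... },
"multi_bundle_fixel_fraction": 0.13793103448275862,
"multi_bundle_voxel_fraction": 0.18518518518518517
```

— 7 fixels carry all 3 bundles (the corridor plus its entry), and about 14%
of bundle-occupied fixels are multi-bundle even though, by construction,
the three pathways are disjoint almost everywhere.  `out/clusters.tsv`
locates the bottleneck itself:

```
cluster	size_voxels	n_fixels	min_bundle_count	dir_x	dir_y	dir_z
0	7	7	3	0.000804	1.0	0.0
```

one 7-voxel cluster of 3-bundle fixels, oriented along the corridor axis
(+y).  Stage-wise commands (`bottleneck fixels | assign | count |
clusters`) expose the same pipeline step by step, and everything is
importable from Python (`wmbottleneck.run_pipeline`, see docstrings).

## Limitations

The phantoms use idealized tube-shaped bundles with perpendicular Gaussian
jitter and noise-free FODs synthesized from the known orientations; see
`docs/methods.md` for what that does and does not establish about real
data.  Population-template averaging, tractography itself, and FOD
estimation from diffusion-weighted images are out of scope: FODs, bundles
and masks are inputs.
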