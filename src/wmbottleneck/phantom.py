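"""Synthetic crossing-fiber phantoms with exhaustive ground truth.

Generates the canonical partial-volume bundle configurations on a small
voxel grid: two parallel pathways, kissing (tangent) pathways, two or three
pathways overlapping in a shared straight corridor before diverging, and
two straight pathways crossing at a configurable angle (sub-resolution
when the angle is below the merge threshold).  Each phantom provides

* one streamline :class:`~wmbottleneck.tract_io.Bundle` per pathway
  (centerline plus Gaussian perpendicular jitter, seeded),
* a matched FOD volume synthesized from the per-voxel true orientation
  clusters with weights proportional to streamline counts,
* a white-matter mask (streamline-traversed voxels dilated by one), and
* :class:`PhantomTruth`: per-voxel bundle sets, orientation clusters and
  region labels, so bundles-per-voxel and bundles-per-fixel have exact
  expected values in region cores.

Orientation clusters closer than ``merge_angle`` are merged into one lobe:
this operationalizes "not resolvable by the angular resolution", so a
sub-resolution crossing yields a single-fixel, two-bundle voxel — the
bottleneck configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .sh_field import SHImage, sh_basis_size, sh_from_lobes
from .tract_io import Bundle, map_streamline_to_voxels

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomConstructionError",
    "make_phantom",
    "truth_expected_counts",
    "core_mask",
    "CONFIGURATIONS",
    "LABELS",
]

CONFIGURATIONS = ("parallel", "kissing", "overlap2", "overlap3", "sharp_crossing")

# region labels
LABELS = {"background": 0, "exclusive": 1, "crossing": 2, "corridor": 3}


class PhantomConstructionError(RuntimeError):
    """Generated geometry violates a construction guarantee."""


@dataclass
class PhantomSpec:
    """Study conditions of one phantom realization."""

    configuration: str
    grid_shape: tuple = (20, 20, 20)
    voxel_size: float = 1.0
    n_streamlines: int = 500
    crossing_angle_deg: float = 20.0  # sharp_crossing only
    kappa: float = 50.0
    lmax: int = 8
    merge_angle_deg: float = 30.0
    jitter_sigma: float = 0.2  # mm, perpendicular to the centerline
    min_presence_frac: float = 0.10  # bundle occupies a voxel if this share
    # of its streamlines traverses it; below that, grazing contact at voxel
    # faces is partial-volume noise, not ground-truth occupancy (and the
    # Gaussian jitter makes such borderline voxels seed-dependent)
    seed: int = 0

    def __post_init__(self):
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(
                f"configuration must be one of {CONFIGURATIONS}, got {self.configuration!r}"
            )
        sh_basis_size(self.lmax)  # validates lmax

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        return a


@dataclass
class PhantomTruth:
    """Exhaustive per-voxel ground truth.

    ``bundle_sets[i,j,k]`` is a frozenset of bundle names present;
    ``clusters[i,j,k]`` is a list of ``(direction, member_names, count)``
    orientation clusters (pairwise separated by more than the merge angle);
    ``labels`` holds region codes per :data:`LABELS`.
    """

    spec: PhantomSpec
    bundle_sets: dict = field(repr=False)  # voxel -> frozenset of names
    clusters: dict = field(repr=False)  # voxel -> list of (dir, names, count)
    labels: np.ndarray = field(repr=False)  # (X, Y, Z) int8


def _centerlines(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Analytic bundle centerlines in world mm (voxel size 1 => voxel
    coordinates).  All curves keep a >= 1-voxel margin inside the grid."""
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = nx / 2 + 0.5, ny / 2 + 0.5, nz / 2 + 0.5  # near grid center
    y0, y1 = 2.0, ny - 2.0
    t = np.linspace(0.0, 1.0, 200)
    cfg = spec.configuration
    if cfg == "parallel":
        # two straight lines along y, 3 voxels apart in x
        xs = (cx - 2.0, cx + 1.0)
        return {
            f"B{i + 1}": np.stack(
                [np.full_like(t, x), y0 + (y1 - y0) * t, np.full_like(t, cz)], axis=1
            )
            for i, x in enumerate(xs)
        }
    if cfg == "kissing":
        # two circular arcs tangent at the grid center, curving apart in x
        radius, t_max = 12.0, 0.65
        th = np.linspace(-t_max, t_max, 200)
        arc1 = np.stack(
            [cx + radius * (1 - np.cos(th)), cy + radius * np.sin(th), np.full_like(th, cz)],
            axis=1,
        )
        arc2 = np.stack(
            [cx - radius * (1 - np.cos(th)), cy + radius * np.sin(th), np.full_like(th, cz)],
            axis=1,
        )
        return {"B1": arc1, "B2": arc2}
    if cfg in ("overlap2", "overlap3"):
        yc0, yc1 = cy - 3.5, cy + 3.5  # 7-voxel shared corridor along y
        n = 2 if cfg == "overlap2" else 3
        entry_x = [cx - 4.0, cx + 4.0, cx][:n]
        # distinct exits: rotate the entry order so start/end points differ
        exit_x = entry_x[1:] + entry_x[:1]
        out = {}
        for b in range(n):
            pieces = [
                np.stack(
                    [
                        entry_x[b] + (cx - entry_x[b]) * t,
                        y0 + (yc0 - y0) * t,
                        np.full_like(t, cz),
                    ],
                    axis=1,
                ),
                np.stack(
                    [np.full_like(t, cx), yc0 + (yc1 - yc0) * t, np.full_like(t, cz)],
                    axis=1,
                ),
                np.stack(
                    [
                        cx + (exit_x[b] - cx) * t,
                        yc1 + (y1 - yc1) * t,
                        np.full_like(t, cz),
                    ],
                    axis=1,
                ),
            ]
            out[f"B{b + 1}"] = np.concatenate([pieces[0], pieces[1][1:], pieces[2][1:]])
        return out
    # sharp_crossing: two straight lines through the center at +/- angle/2
    half = np.deg2rad(spec.crossing_angle_deg) / 2.0
    span = (y1 - y0) / 2.0
    s = np.linspace(-span, span, 200)
    d1 = np.array([np.sin(half), np.cos(half), 0.0])
    d2 = np.array([-np.sin(half), np.cos(half), 0.0])
    c = np.array([cx, cy, cz])
    return {"B1": c + s[:, None] * d1, "B2": c + s[:, None] * d2}


def _perpendicular_frame(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to the overall
    bundle direction (jitter offsets live in this plane)."""
    main = centerline[-1] - centerline[0]
    main = main / np.linalg.norm(main)
    ref = np.array([0.0, 0.0, 1.0]) if abs(main[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(main, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(main, e1)
    return e1, e2


def make_phantom(spec: PhantomSpec):
    """Generate one phantom realization.

    Returns ``(fod, bundles, wm_mask, truth)``; deterministic given the
    spec (the seed drives the only randomness, the perpendicular jitter).
    """
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine
    shape = spec.grid_shape
    centerlines = _centerlines(spec)
    bundles = []
    for name in sorted(centerlines):
        cl = centerlines[name]
        e1, e2 = _perpendicular_frame(cl)
        offsets = rng.normal(scale=spec.jitter_sigma, size=(spec.n_streamlines, 2))
        streamlines = [cl + o1 * e1 + o2 * e2 for o1, o2 in offsets]
        bundles.append(Bundle(name=name, streamlines=streamlines))
    # margin guarantee
    for b in bundles:
        pts = np.concatenate(b.streamlines)
        vox = pts / spec.voxel_size
        if np.any(vox < 1.0) or np.any(vox >= np.array(shape, dtype=float) - 1.0):
            raise PhantomConstructionError(
                f"bundle {b.name} leaves the 1-voxel grid margin"
            )
    truth = _build_truth(spec, bundles, affine, shape)
    fod = _fod_from_truth(spec, truth, affine, shape)
    visited = np.zeros(shape, dtype=bool)
    for v in truth.bundle_sets:
        visited[v] = True
    wm_mask = binary_dilation(visited, structure=np.ones((3, 3, 3), dtype=bool))
    return fod, bundles, wm_mask, truth


def _build_truth(spec, bundles, affine, shape) -> PhantomTruth:
    merge_cos = np.cos(np.deg2rad(spec.merge_angle_deg))
    # accumulate per voxel, per bundle: streamline count and mean direction
    acc: dict[tuple, dict[str, list]] = {}
    for bundle in bundles:
        for streamline in bundle.streamlines:
            for visit in map_streamline_to_voxels(streamline, affine):
                slot = acc.setdefault(visit.voxel, {}).setdefault(
                    bundle.name, [np.zeros(3), 0]
                )
                d = visit.direction
                slot[0] += d if float(slot[0] @ d) >= 0 else -d
                slot[1] += 1
    min_count = max(2, int(np.ceil(spec.min_presence_frac * len(bundles[0].streamlines))))
    bundle_sets: dict[tuple, frozenset] = {}
    clusters: dict[tuple, list] = {}
    labels = np.zeros(shape, dtype=np.int8)
    for voxel, per_bundle in acc.items():
        # stray grazes below the presence threshold are not occupancy
        per_bundle = {n: s for n, s in per_bundle.items() if s[1] >= min_count}
        if not per_bundle:
            continue
        names = sorted(per_bundle, key=lambda n: (-per_bundle[n][1], n))
        bundle_sets[voxel] = frozenset(names)
        vox_clusters: list[list] = []  # [direction_acc, names, count]
        for name in names:
            vec, count = per_bundle[name]
            d = vec / np.linalg.norm(vec)
            for cl in vox_clusters:
                rep = cl[0] / np.linalg.norm(cl[0])
                if abs(float(rep @ d)) >= merge_cos:
                    cl[0] += count * (d if float(rep @ d) >= 0 else -d)
                    cl[1].append(name)
                    cl[2] += count
                    break
            else:
                vox_clusters.append([count * d, [name], count])
        clusters[voxel] = [
            (c[0] / np.linalg.norm(c[0]), tuple(c[1]), int(c[2])) for c in vox_clusters
        ]
        if any(len(c[1]) >= 2 for c in vox_clusters):
            labels[voxel] = LABELS["corridor"]
        elif len(names) >= 2:
            labels[voxel] = LABELS["crossing"]
        else:
            labels[voxel] = LABELS["exclusive"]
    if spec.configuration in ("overlap2", "overlap3"):
        corridor_y = {v[1] for v in bundle_sets if labels[v] == LABELS["corridor"]}
        if len(corridor_y) < 3:
            raise PhantomConstructionError(
                "shared corridor shorter than 3 voxels after discretization"
            )
    return PhantomTruth(spec=spec, bundle_sets=bundle_sets, clusters=clusters, labels=labels)


def _fod_from_truth(spec, truth, affine, shape) -> SHImage:
    coeffs = np.zeros(shape + (sh_basis_size(spec.lmax),))
    for voxel, vox_clusters in truth.clusters.items():
        dirs = np.array([c[0] for c in vox_clusters])
        weights = np.array([c[2] for c in vox_clusters], dtype=float)
        weights /= weights.sum()
        coeffs[voxel] = sh_from_lobes(dirs, weights, kappa=spec.kappa, lmax=spec.lmax)
    return SHImage(coeffs=coeffs, affine=affine, lmax=spec.lmax)


def truth_expected_counts(truth: PhantomTruth) -> dict:
    """Ground-truth twins of bundles-per-voxel and bundles-per-fixel.

    Returns ``expected_bundles_per_voxel`` (integer volume) and
    ``expected_cluster_counts`` (voxel -> sorted tuple of per-orientation
    bundle counts), for exact comparison in region cores.
    """
    shape = truth.labels.shape
    per_voxel = np.zeros(shape, dtype=np.int64)
    per_cluster: dict[tuple, tuple] = {}
    for voxel, names in truth.bundle_sets.items():
        per_voxel[voxel] = len(names)
        per_cluster[voxel] = tuple(
            sorted(len(c[1]) for c in truth.clusters[voxel])
        )
    return {
        "expected_bundles_per_voxel": per_voxel,
        "expected_cluster_counts": per_cluster,
    }


def core_mask(truth: PhantomTruth, region: str) -> np.ndarray:
    """Voxels of a region away from inter-region boundaries.

    Excludes region voxels face-adjacent (6-connectivity) to a *different*
    occupied region (background does not disqualify), i.e. strips the
    1-voxel partial-volume ring where exact recovery is not expected.
    Face adjacency is used because partial-volume mixing acts across shared
    voxel faces; corner contact contributes negligible volume.
    """
    labels = truth.labels
    target = LABELS[region]
    mask = labels == target
    other = (labels != target) & (labels != LABELS["background"])
    other_near = binary_dilation(other)  # default structure: 6-connectivity
    return mask & ~other_near
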