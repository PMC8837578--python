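"""Voxel/fixel classification, prevalence statistics and bottleneck regions.

The six-way nomenclature crosses the number of FOD lobes in a voxel
(single- vs multi-fixel) with the number of segmented bundles traversing
the voxel or the fixel (zero-, single-, multi-bundle).  The bottleneck case
is the single-fixel, multi-bundle configuration: several bundles share one
orientation through the same voxels before diverging, which tractography
cannot disambiguate.  *Bottleneck regions* are spatial clusters of
orientation-coherent multi-bundle fixels.

Zero-bundle elements (fixels or voxels no segmented bundle traverses) are
flagged and excluded from every prevalence denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fixel_extract import ConsistencyError, FixelGrid, canonicalize_direction

__all__ = [
    "Classification",
    "BottleneckCluster",
    "BottleneckReport",
    "classify",
    "prevalence_tables",
    "single_fixel_voxel_histogram",
    "zero_and_single_bundle_maps",
    "find_bottleneck_regions",
    "DEFAULT_MIN_BUNDLES",
    "DEFAULT_ANGLE_TOL_DEG",
    "DEFAULT_MIN_CLUSTER_VOXELS",
    "HISTOGRAM_CAP",
]

DEFAULT_MIN_BUNDLES = 7
DEFAULT_ANGLE_TOL_DEG = 30.0
DEFAULT_MIN_CLUSTER_VOXELS = 5
HISTOGRAM_CAP = 7  # bundle-count histograms report 1..6 and "7+"


@dataclass
class Classification:
    """Per-voxel and per-fixel counts and class labels.

    Voxel classes combine ``{single-fixel, multi-fixel}`` with
    ``{zero-bundle, single-bundle, multi-bundle}``; fixel classes are
    ``{zero-, single-, multi-bundle}``.  Stored as counts; the labels are
    derived views.
    """

    fixel_count: np.ndarray  # (X, Y, Z) fixels per voxel
    voxel_bundle_count: np.ndarray  # (X, Y, Z)
    fixel_bundle_count: np.ndarray  # (F,)
    wm_mask: np.ndarray  # (X, Y, Z) bool
    fixels: FixelGrid = field(repr=False)

    def voxel_class(self, i: int, j: int, k: int) -> str:
        nfix = int(self.fixel_count[i, j, k])
        nbun = int(self.voxel_bundle_count[i, j, k])
        fix = "single-fixel" if nfix == 1 else "multi-fixel" if nfix > 1 else "zero-fixel"
        bun = "zero-bundle" if nbun == 0 else "single-bundle" if nbun == 1 else "multi-bundle"
        return f"{fix}/{bun}"

    def fixel_class(self, flat_index: int) -> str:
        n = int(self.fixel_bundle_count[flat_index])
        return "zero-bundle" if n == 0 else "single-bundle" if n == 1 else "multi-bundle"


def classify(
    fixels: FixelGrid,
    counts_fixel: np.ndarray,
    counts_voxel: np.ndarray,
    wm_mask: np.ndarray,
) -> Classification:
    """Assemble the six-way classification and check its structural
    invariants.

    Raises :class:`ConsistencyError` if any multi-bundle fixel sits in a
    voxel not classified multi-bundle, or a voxel's bundle count falls
    below the maximum bundle count of its fixels (the count-once union rule
    guarantees both).
    """
    wm_mask = np.asarray(wm_mask).astype(bool)
    counts_voxel = np.asarray(counts_voxel)
    counts_fixel = np.asarray(counts_fixel)
    if wm_mask.shape != fixels.shape or counts_voxel.shape != fixels.shape:
        raise ValueError("mask/count volumes must match the fixel grid shape")
    if counts_fixel.shape != (fixels.n_fixels,):
        raise ValueError("counts_fixel must have one entry per fixel")
    if fixels.n_fixels:
        vi = fixels.voxel_index
        voxel_count_at_fixel = counts_voxel[vi[:, 0], vi[:, 1], vi[:, 2]]
        if np.any((counts_fixel >= 2) & (voxel_count_at_fixel < 2)):
            raise ConsistencyError("multi-bundle fixel in a non-multi-bundle voxel")
        if np.any(voxel_count_at_fixel < counts_fixel):
            raise ConsistencyError("voxel bundle count below a member fixel's count")
    return Classification(
        fixel_count=fixels.counts,
        voxel_bundle_count=counts_voxel,
        fixel_bundle_count=counts_fixel,
        wm_mask=wm_mask,
        fixels=fixels,
    )


def _capped_histogram(values: np.ndarray) -> dict:
    """Histogram of positive integer counts with the top bin capped at 7+.

    Returns ``None``-marked empty table if there are no values.
    """
    values = values[values >= 1]
    n = int(values.size)
    bins = {str(k): int(np.sum(values == k)) for k in range(1, HISTOGRAM_CAP)}
    bins[f"{HISTOGRAM_CAP}+"] = int(np.sum(values >= HISTOGRAM_CAP))
    if n == 0:
        return {"counts": bins, "fractions": None, "n": 0, "empty": True}
    fractions = {k: v / n for k, v in bins.items()}
    multi = float(np.sum(values >= 2) / n)
    return {"counts": bins, "fractions": fractions, "n": n, "empty": False, "multi_fraction": multi}


def prevalence_tables(classification: Classification) -> dict:
    """Prevalence of bundle counts per fixel and per voxel, and of fixel
    counts per voxel, inside the white-matter mask.

    Denominators follow the zero-exclusion convention: fixels/voxels with
    zero bundles do not count.  The voxel table is additionally reported
    against the all-WM denominator (``voxel_fractions_all_wm``) since both
    conventions appear in practice.
    """
    mask = classification.wm_mask
    fixels = classification.fixels
    if fixels.n_fixels:
        vi = fixels.voxel_index
        in_mask = mask[vi[:, 0], vi[:, 1], vi[:, 2]]
        fixel_counts = classification.fixel_bundle_count[in_mask]
    else:
        fixel_counts = np.zeros(0, dtype=int)
    voxel_counts = classification.voxel_bundle_count[mask]
    fixel_table = _capped_histogram(fixel_counts)
    voxel_table = _capped_histogram(voxel_counts)
    n_wm = int(mask.sum())
    voxel_fracs_all = (
        None
        if n_wm == 0
        else {k: v / n_wm for k, v in voxel_table["counts"].items()}
    )
    fpv = classification.fixel_count[mask]
    fpv_table = {
        "counts": {
            "1": int(np.sum(fpv == 1)),
            "2": int(np.sum(fpv == 2)),
            "3+": int(np.sum(fpv >= 3)),
        }
    }
    n_fpv = int(np.sum(fpv >= 1))
    fpv_table["n"] = n_fpv
    fpv_table["empty"] = n_fpv == 0
    fpv_table["fractions"] = (
        None if n_fpv == 0 else {k: v / n_fpv for k, v in fpv_table["counts"].items()}
    )
    fpv_table["multi_fixel_fraction"] = (
        None if n_fpv == 0 else float(np.sum(fpv >= 2) / n_fpv)
    )
    return {
        "bundles_per_fixel": fixel_table,
        "bundles_per_voxel": voxel_table,
        "voxel_fractions_all_wm": voxel_fracs_all,
        "fixels_per_voxel": fpv_table,
        "multi_bundle_fixel_fraction": fixel_table.get("multi_fraction"),
        "multi_bundle_voxel_fraction": voxel_table.get("multi_fraction"),
    }


def single_fixel_voxel_histogram(classification: Classification) -> dict:
    """Bundle-count histogram restricted to single-fixel voxels.

    Voxels with exactly one FOD lobe are "traditionally single fiber"
    voxels; a bundle count above one there is the bottleneck configuration.
    Returns the capped histogram plus ``fraction_multi`` (share with more
    than one bundle).
    """
    mask = classification.wm_mask & (classification.fixel_count == 1)
    values = classification.voxel_bundle_count[mask]
    table = _capped_histogram(values)
    table["fraction_multi"] = table.get("multi_fraction")
    return table


def zero_and_single_bundle_maps(classification: Classification) -> tuple[np.ndarray, np.ndarray]:
    """Masks of fixels with exactly 0 and exactly 1 assigned bundle."""
    c = classification.fixel_bundle_count
    return c == 0, c == 1


@dataclass
class BottleneckCluster:
    """A connected set of orientation-coherent high-bundle-count fixels."""

    fixel_indices: np.ndarray  # flat indices
    voxel_footprint: np.ndarray  # (V, 3) unique voxel indices
    direction: np.ndarray  # representative orientation (canonical)
    min_bundle_count: int
    size_voxels: int


def find_bottleneck_regions(
    counts_fixel: np.ndarray,
    fixels: FixelGrid,
    min_bundles: int = DEFAULT_MIN_BUNDLES,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
    min_size: int = DEFAULT_MIN_CLUSTER_VOXELS,
) -> list[BottleneckCluster]:
    """Cluster fixels with >= ``min_bundles`` bundles into coherent regions.

    Nodes are such fixels; two nodes are linked when their voxels are
    identical or 26-neighbors and their orientations differ by at most
    ``angle_tol_deg`` (antipodally).  Connected components with a voxel
    footprint of at least ``min_size`` are returned, largest first.
    """
    if min_bundles < 2:
        raise ValueError("min_bundles must be >= 2")
    counts_fixel = np.asarray(counts_fixel)
    nodes = np.nonzero(counts_fixel >= min_bundles)[0]
    if nodes.size == 0:
        return []
    cos_tol = np.cos(np.deg2rad(angle_tol_deg))
    vi = fixels.voxel_index[nodes]
    dirs = fixels.directions[nodes]
    by_voxel: dict[tuple, list[int]] = {}
    for local, ijk in enumerate(vi):
        by_voxel.setdefault(tuple(ijk), []).append(local)
    parent = np.arange(nodes.size)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
    ]
    for (i, j, k), members in by_voxel.items():
        for di, dj, dk in offsets:
            other = by_voxel.get((i + di, j + dj, k + dk))
            if other is None:
                continue
            for a in members:
                for b in other:
                    if a < b and abs(float(dirs[a] @ dirs[b])) >= cos_tol:
                        union(a, b)
    roots = np.array([find(a) for a in range(nodes.size)])
    clusters = []
    for root in np.unique(roots):
        members = np.nonzero(roots == root)[0]
        footprint = np.unique(vi[members], axis=0)
        if footprint.shape[0] < min_size:
            continue
        mdirs = dirs[members]
        ref = mdirs[0]
        signs = np.where(mdirs @ ref >= 0, 1.0, -1.0)
        mean = (signs[:, None] * mdirs).sum(axis=0)
        mean /= max(np.linalg.norm(mean), 1e-12)
        clusters.append(
            BottleneckCluster(
                fixel_indices=nodes[members],
                voxel_footprint=footprint,
                direction=canonicalize_direction(mean),
                min_bundle_count=int(counts_fixel[nodes[members]].min()),
                size_voxels=int(footprint.shape[0]),
            )
        )
    clusters.sort(key=lambda c: (-c.size_voxels, int(c.fixel_indices.min())))
    return clusters


@dataclass
class BottleneckReport:
    """Full analysis summary: prevalence tables, classifications-derived
    fractions, single-fixel-voxel histogram, clusters and parameters."""

    tables: dict
    single_fixel_voxel: dict
    clusters: list
    parameters: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tables": self.tables,
            "single_fixel_voxel": self.single_fixel_voxel,
            "clusters": [
                {
                    "n_fixels": int(len(c.fixel_indices)),
                    "size_voxels": c.size_voxels,
                    "direction": [round(float(x), 6) for x in c.direction],
                    "min_bundle_count": c.min_bundle_count,
                }
                for c in self.clusters
            ],
            "parameters": self.parameters,
            "provenance": self.provenance,
        }

    def save(self, directory: str | Path) -> None:
        """Write ``report.json`` plus TSV prevalence and cluster tables."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        rows = []
        for table_name in ("bundles_per_fixel", "bundles_per_voxel", "fixels_per_voxel"):
            t = self.tables[table_name]
            for k, v in t["counts"].items():
                rows.append(
                    {
                        "table": table_name,
                        "bin": k,
                        "count": v,
                        "fraction": (t["fractions"] or {}).get(k, float("nan")),
                    }
                )
        pd.DataFrame(rows).to_csv(directory / "prevalence.tsv", sep="\t", index=False)
        cluster_rows = [
            {
                "cluster": idx,
                "size_voxels": c.size_voxels,
                "n_fixels": len(c.fixel_indices),
                "min_bundle_count": c.min_bundle_count,
                "dir_x": round(float(c.direction[0]), 6),
                "dir_y": round(float(c.direction[1]), 6),
                "dir_z": round(float(c.direction[2]), 6),
            }
            for idx, c in enumerate(self.clusters)
        ]
        pd.DataFrame(
            cluster_rows,
            columns=[
                "cluster",
                "size_voxels",
                "n_fixels",
                "min_bundle_count",
                "dir_x",
                "dir_y",
                "dir_z",
            ],
        ).to_csv(directory / "clusters.tsv", sep="\t", index=False)
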