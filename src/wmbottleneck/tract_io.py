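"""Streamline bundle I/O and streamline-to-voxel mapping.

A *bundle* is a named group of tractography streamlines (ordered polylines
in world mm) intended to represent one anatomical white-matter pathway.
This module reads and writes bundles (TCK/TRK via :mod:`nibabel.streamlines`),
maps each streamline onto a voxel grid with a per-voxel local direction
(the geometric substrate of bundle-to-fixel assignment), and filters bundles
by a box region of interest.

Coordinate conventions
----------------------
World coordinates are mm throughout.  Voxel indices are 0-based; a point
with continuous voxel coordinate ``v = affine^{-1} @ p`` belongs to voxel
``floor(v)`` (half-open boundaries ``[i, i+1)`` along each axis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Bundle",
    "VoxelVisit",
    "load_bundle",
    "write_bundle",
    "map_streamline_to_voxels",
    "filter_by_roi",
    "BundleFormatError",
]


class BundleFormatError(IOError):
    """Malformed or unreadable streamline file."""


@dataclass
class Bundle:
    """A named set of streamlines in world-mm coordinates."""

    name: str
    streamlines: list  # list of (P_i, 3) float arrays, P_i >= 2

    def __post_init__(self):
        cleaned = []
        for s in self.streamlines:
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError("each streamline must be an (P, 3) array")
            # drop zero-length segments (consecutive identical points)
            keep = np.ones(len(s), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(s, axis=0), axis=1) > 0
            cleaned.append(s[keep])
        self.streamlines = cleaned

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)


@dataclass
class VoxelVisit:
    """One streamline's traversal of one voxel (revisits merged)."""

    voxel: tuple  # (i, j, k)
    direction: np.ndarray  # unit 3-vector, sign-canonicalized to 1st tangent
    path_length: float  # mm


def load_bundle(path, name: str | None = None) -> Bundle:
    """Load a TCK or TRK streamline file as a :class:`Bundle`.

    Points are returned in world mm (TRK voxel-space coordinates are
    converted using its header affine).  Streamlines with fewer than two
    distinct points are dropped with a logged count.
    """
    try:
        tractogram_file = nib.streamlines.load(str(path), lazy_load=False)
    except Exception as exc:  # malformed header/magic, truncation
        raise BundleFormatError(f"cannot read streamline file {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tractogram_file.streamlines]
    good = [s for s in streamlines if len(s) >= 2]
    dropped = len(streamlines) - len(good)
    if dropped:
        logger.warning("%s: dropped %d streamline(s) with < 2 points", path, dropped)
    if name is None:
        name = str(path).rsplit("/", 1)[-1].split(".")[0]
    bundle = Bundle(name=name, streamlines=good)
    bundle.streamlines = [s for s in bundle.streamlines if len(s) >= 2]
    return bundle


def write_bundle(bundle: Bundle, path) -> None:
    """Write a bundle as TCK (world mm; the format's native space)."""
    tractogram = nib.streamlines.Tractogram(bundle.streamlines, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def _resample(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing ``step`` (keeps the
    first point; last sample is within one step of the endpoint)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(int(np.floor(total / step)) + 1, 2)
    t = np.minimum(np.arange(n) * step, total)
    out = np.empty((n, 3))
    for dim in range(3):
        out[:, dim] = np.interp(t, arc, points[:, dim])
    return out


def map_streamline_to_voxels(
    points: np.ndarray,
    affine: np.ndarray,
    step_frac: float = 0.25,
) -> list[VoxelVisit]:
    """Map one streamline onto the voxel grid.

    The streamline is resampled at arc-length step ``step_frac`` times the
    smallest voxel edge; each sample falls in the voxel ``floor(v)`` of its
    continuous voxel coordinate.  Per voxel, the local direction is the
    normalized sum of sample tangents with signs aligned to the first
    tangent seen in that voxel, and the path length is (number of samples)
    times the step.  A streamline contributes at most one visit per voxel
    (re-entries are merged).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ValueError("streamline needs >= 2 points of shape (P, 3)")
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)
    voxel_edges = np.linalg.norm(affine[:3, :3], axis=0)
    step = step_frac * float(voxel_edges.min())
    samples = _resample(points, step)
    tangents = np.gradient(samples, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms < 1e-15] = 1.0
    tangents = tangents / norms
    vox_coord = samples @ inv[:3, :3].T + inv[:3, 3]
    idx = np.floor(vox_coord).astype(np.int64)
    visits: dict[tuple, list] = {}
    order: list[tuple] = []
    for sample_idx in range(len(samples)):
        key = tuple(idx[sample_idx])
        if key not in visits:
            visits[key] = [tangents[sample_idx].copy(), 1, tangents[sample_idx]]
            order.append(key)
        else:
            acc, n, first = visits[key]
            t = tangents[sample_idx]
            acc += t if float(t @ first) >= 0 else -t
            visits[key][1] = n + 1
    out = []
    for key in order:
        acc, n, _first = visits[key]
        norm = np.linalg.norm(acc)
        direction = acc / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        out.append(VoxelVisit(voxel=key, direction=direction, path_length=n * step))
    return out


def filter_by_roi(
    bundle: Bundle,
    roi: tuple,
    affine: np.ndarray,
    step_frac: float = 0.25,
) -> Bundle:
    """Keep exactly the streamlines with at least one sample inside a voxel
    index box.

    ``roi`` is ``((i0, i1), (j0, j1), (k0, k1))`` with half-open upper
    bounds — e.g. a 2x2x2-voxel cube is ``((i, i+2), (j, j+2), (k, k+2))``.
    """
    lo = np.array([r[0] for r in roi], dtype=np.int64)
    hi = np.array([r[1] for r in roi], dtype=np.int64)
    if np.any(hi <= lo):
        raise ValueError("empty ROI box")
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    voxel_edges = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    step = step_frac * float(voxel_edges.min())
    kept = []
    for s in bundle.streamlines:
        samples = _resample(s, step)
        v = np.floor(samples @ inv[:3, :3].T + inv[:3, 3]).astype(np.int64)
        if np.any(np.all((v >= lo) & (v < hi), axis=1)):
            kept.append(s)
    return Bundle(name=bundle.name, streamlines=kept)
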