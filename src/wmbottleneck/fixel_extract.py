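"""Fixel extraction: segment each voxel's FOD into discrete fiber elements.

A *fixel* ("fiber bundle element") is one lobe of a voxel's fiber
orientation distribution, parameterized by the mean orientation of the lobe.
Extraction is discrete-then-refined: local maxima are found on a subdivided
icosahedron, refined by projected gradient ascent on the continuous SH
surface, thresholded at an absolute peak amplitude (default 0.1 to suppress
spurious peaks), and the FOD surface is segmented into lobes by
steepest-ascent watershed over the mesh.

Voxels whose FOD has a single surviving peak are *single-fixel voxels*;
voxels with more are *multi-fixel voxels* ("crossing fibers").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .sh_field import (
    SHImage,
    SphereMesh,
    eval_sh,
    lmax_from_ncoeffs,
    sh_basis,
)

__all__ = [
    "Fixel",
    "FixelGrid",
    "ConsistencyError",
    "canonicalize_direction",
    "find_peaks",
    "segment_lobes",
    "extract_fixels",
    "fixels_per_voxel_histogram",
    "DEFAULT_PEAK_THRESHOLD",
    "DEFAULT_MAX_FIXELS",
]

DEFAULT_PEAK_THRESHOLD = 0.1
DEFAULT_MAX_FIXELS = 3
_PEAK_MATCH_DEG = 15.0  # local-max <-> peak association tolerance
_PEAK_MERGE_DEG = 5.0  # refined peaks closer than this collapse to one


class ConsistencyError(ValueError):
    """Raised when inputs that must agree (e.g. peaks vs. mesh) do not."""


def canonicalize_direction(d: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Map a direction to the canonical hemisphere: z >= 0, ties broken by
    y >= 0 then x >= 0.  Antipodal pairs map to one representative."""
    d = np.asarray(d, dtype=float)
    flip = (d[..., 2] < -tol) | (
        (np.abs(d[..., 2]) <= tol)
        & ((d[..., 1] < -tol) | ((np.abs(d[..., 1]) <= tol) & (d[..., 0] < 0)))
    )
    return np.where(flip[..., None], -d, d)


@dataclass
class Fixel:
    """One FOD lobe.

    direction is the amplitude-weighted mean orientation of the lobe
    (canonical hemisphere); peak_direction is the refined location of the
    lobe's maximum; lobe_integral approximates the integral of the FOD over
    the lobe (both antipodal copies): sum of member amplitudes weighted by
    the mesh vertex quadrature areas.
    """

    direction: np.ndarray
    peak_amplitude: float
    lobe_integral: float
    peak_direction: np.ndarray | None = None


def _pad_neighbors(mesh: SphereMesh) -> np.ndarray:
    """Neighbor lists as a dense (N, max_degree) index array, self-padded."""
    max_deg = max(len(n) for n in mesh.neighbors)
    idx = np.tile(np.arange(mesh.n_vertices)[:, None], (1, max_deg))
    for i, nbr in enumerate(mesh.neighbors):
        idx[i, : len(nbr)] = nbr
    return idx


_NBR_CACHE: dict[int, np.ndarray] = {}


def _neighbors_of(mesh: SphereMesh) -> np.ndarray:
    key = id(mesh)
    if key not in _NBR_CACHE:
        _NBR_CACHE[key] = _pad_neighbors(mesh)
    return _NBR_CACHE[key]


def _tangent_basis(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit tangents per direction, orthogonal to it and each other."""
    ref = np.where(
        np.abs(dirs[:, 2:3]) < 0.9, np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]])
    )
    t1 = np.cross(dirs, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(dirs, t1)
    return t1, t2


def _amp_rows(dirs: np.ndarray, coeffs: np.ndarray, lmax: int) -> np.ndarray:
    """Row-wise SH amplitude: dirs (P,3) against per-row coeffs (P,C)."""
    return np.einsum("pc,pc->p", sh_basis(dirs, lmax), coeffs)


def refine_peaks(
    dirs: np.ndarray,
    coeffs: np.ndarray,
    n_iter: int = 20,
    step0: float = 0.1,
    eps: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Refine peak directions by projected gradient ascent on the SH surface.

    Batched: ``dirs`` is (P, 3) and ``coeffs`` (P, C) gives each row its own
    coefficient vector.  The spherical gradient is estimated by forward
    differences along a tangent basis; the step is halved whenever the
    candidate does not improve the amplitude.

    Returns the refined unit directions and their amplitudes.
    """
    dirs = np.array(dirs, dtype=float)
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    if coeffs.shape[0] == 1 and dirs.shape[0] > 1:
        coeffs = np.broadcast_to(coeffs, (dirs.shape[0], coeffs.shape[1])).copy()
    lmax = lmax_from_ncoeffs(coeffs.shape[1])
    amp = _amp_rows(dirs, coeffs, lmax)
    step = np.full(dirs.shape[0], step0)
    for _ in range(n_iter):
        t1, t2 = _tangent_basis(dirs)

        def _at(offset):
            d = dirs + offset
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            return d

        g1 = (
            _amp_rows(_at(eps * t1), coeffs, lmax)
            - _amp_rows(_at(-eps * t1), coeffs, lmax)
        ) / (2 * eps)
        g2 = (
            _amp_rows(_at(eps * t2), coeffs, lmax)
            - _amp_rows(_at(-eps * t2), coeffs, lmax)
        ) / (2 * eps)
        grad = g1[:, None] * t1 + g2[:, None] * t2
        gnorm = np.linalg.norm(grad, axis=1, keepdims=True)
        gnorm[gnorm < 1e-15] = 1.0
        cand = _at(step[:, None] * grad / gnorm)
        cand_amp = _amp_rows(cand, coeffs, lmax)
        better = cand_amp > amp
        dirs[better] = cand[better]
        amp[better] = cand_amp[better]
        step[~better] *= 0.5
    return dirs, amp


def _mesh_local_maxima(amplitudes: np.ndarray, mesh: SphereMesh) -> np.ndarray:
    """Vertex indices that are >= all mesh neighbors, canonical hemisphere
    representative only (amplitudes are antipodally symmetric)."""
    nbr = _neighbors_of(mesh)
    is_max = amplitudes >= amplitudes[nbr].max(axis=1)
    idx = np.nonzero(is_max & (amplitudes > 0))[0]
    d = mesh.directions[idx]
    keep = np.einsum("ij,ij->i", canonicalize_direction(d), d) > 0.999999
    return idx[keep]


def find_peaks(
    coeffs: np.ndarray,
    mesh: SphereMesh | None = None,
    abs_threshold: float = DEFAULT_PEAK_THRESHOLD,
    max_peaks: int = DEFAULT_MAX_FIXELS,
) -> list[tuple[np.ndarray, float]]:
    """Find FOD peaks: discrete mesh maxima, antipodally deduplicated,
    refined on the continuous surface, and kept if the refined amplitude is
    at least ``abs_threshold``.

    Returns a list of ``(direction, amplitude)`` in descending amplitude,
    truncated to ``max_peaks``.  Directions are canonical-hemisphere.
    """
    if abs_threshold <= 0:
        raise ValueError("abs_threshold must be > 0")
    if mesh is None:
        mesh = SphereMesh.icosphere(4)
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    coeffs = np.asarray(coeffs, dtype=float)
    amp = eval_sh(coeffs, mesh.directions)
    cand = _mesh_local_maxima(amp, mesh)
    # refinement only increases amplitude, so a loose prefilter is safe
    cand = cand[amp[cand] >= 0.5 * abs_threshold]
    if cand.size == 0:
        return []
    refined, ref_amp = refine_peaks(
        mesh.directions[cand], np.broadcast_to(coeffs, (cand.size, coeffs.size))
    )
    keep = ref_amp >= abs_threshold
    refined, ref_amp = refined[keep], ref_amp[keep]
    order = np.argsort(-ref_amp)
    peaks: list[tuple[np.ndarray, float]] = []
    cos_merge = np.cos(np.deg2rad(_PEAK_MERGE_DEG))
    for i in order:
        d = canonicalize_direction(refined[i])
        if any(abs(float(d @ p[0])) >= cos_merge for p in peaks):
            continue
        peaks.append((d, float(ref_amp[i])))
        if len(peaks) == max_peaks:
            break
    return peaks


def segment_lobes(
    coeffs: np.ndarray,
    peaks: list[tuple[np.ndarray, float]],
    mesh: SphereMesh | None = None,
) -> list[Fixel]:
    """Partition the FOD surface into lobes, one per peak.

    Every mesh vertex with positive amplitude climbs to its local maximum by
    steepest ascent along mesh edges; the basin is attributed to the nearest
    peak (antipodally, within a small angular tolerance — basins of
    sub-threshold maxima are discarded).  Each lobe yields one
    :class:`Fixel`: direction = amplitude-weighted mean of member directions
    sign-aligned to the peak; lobe_integral = quadrature sum of member
    amplitudes over the mesh vertex areas.
    """
    if mesh is None:
        mesh = SphereMesh.icosphere(4)
    if not peaks:
        return []
    amp = eval_sh(np.asarray(coeffs, dtype=float), mesh.directions)
    roots = _ascend_roots(amp[None, :], mesh)[0]
    return _lobes_from_roots(amp, roots, peaks, mesh)


def _ascend_roots(amp: np.ndarray, mesh: SphereMesh) -> np.ndarray:
    """Steepest-ascent root of every vertex, batched over rows of ``amp``.

    Each vertex points to its best-improving neighbor (itself if none);
    pointer-doubling converges to the local maximum of each basin.
    """
    nbr = _neighbors_of(mesh)  # (N, D)
    v, n = amp.shape
    nbr_amp = amp[:, nbr]  # (V, N, D)
    best = np.argmax(nbr_amp, axis=2)
    ptr = np.take_along_axis(nbr[None, :, :].repeat(v, axis=0), best[:, :, None], 2)[:, :, 0]
    improving = np.take_along_axis(amp, ptr, axis=1) > amp
    self_idx = np.broadcast_to(np.arange(n), (v, n))
    ptr = np.where(improving, ptr, self_idx)
    for _ in range(10):  # doubling: path length up to 2**10
        nxt = np.take_along_axis(ptr, ptr, axis=1)
        if np.array_equal(nxt, ptr):
            break
        ptr = nxt
    return ptr


def _lobes_from_roots(
    amp: np.ndarray,
    roots: np.ndarray,
    peaks: list[tuple[np.ndarray, float]],
    mesh: SphereMesh,
) -> list[Fixel]:
    cos_match = np.cos(np.deg2rad(_PEAK_MATCH_DEG))
    peak_dirs = np.array([p[0] for p in peaks])
    root_ids = np.unique(roots[amp > 0])
    if root_ids.size:
        align = np.abs(mesh.directions[root_ids] @ peak_dirs.T)  # (R, P)
        root_peak = np.where(align.max(axis=1) >= cos_match, align.argmax(axis=1), -1)
    else:
        root_peak = np.empty(0, dtype=int)
    for d, a in peaks:
        # a genuine peak has a nearby mesh-local maximum of comparable
        # amplitude (SH ringing produces tiny spurious maxima everywhere,
        # so direction alone is not evidence)
        near = np.abs(mesh.directions[root_ids] @ d) >= cos_match
        if not np.any(near & (amp[root_ids] >= 0.5 * a)):
            raise ConsistencyError(
                "peak is not associated with a mesh-local maximum of "
                "comparable amplitude"
            )
    cell = mesh.vertex_areas
    fixels: list[Fixel] = []
    member_peak = np.full(roots.shape, -1)
    lut = dict(zip(root_ids.tolist(), root_peak.tolist()))
    pos = amp > 0
    member_peak[pos] = [lut[r] for r in roots[pos]]
    for k, (pdir, pamp) in enumerate(peaks):
        sel = member_peak == k
        w = amp[sel]
        dirs = mesh.directions[sel]
        sign = np.where(dirs @ pdir >= 0, 1.0, -1.0)
        mean = (w[:, None] * sign[:, None] * dirs).sum(axis=0)
        norm = np.linalg.norm(mean)
        mean = pdir if norm < 1e-12 else mean / norm
        fixels.append(
            Fixel(
                direction=canonicalize_direction(mean),
                peak_amplitude=float(pamp),
                lobe_integral=float((w * cell[sel]).sum()),
                peak_direction=np.asarray(pdir, dtype=float),
            )
        )
    return fixels


@dataclass
class FixelGrid:
    """All fixels of a volume, with a flat global index.

    Fixels of voxel ``(i, j, k)`` occupy the contiguous flat range
    ``offsets[i,j,k] : offsets[i,j,k] + counts[i,j,k]`` in descending peak
    amplitude; voxels are laid out in C order.
    """

    shape: tuple
    affine: np.ndarray
    counts: np.ndarray  # (X, Y, Z) int
    offsets: np.ndarray  # (X, Y, Z) int
    directions: np.ndarray  # (F, 3)
    peak_amplitudes: np.ndarray  # (F,)
    lobe_integrals: np.ndarray  # (F,)
    peak_directions: np.ndarray | None = None
    voxel_index: np.ndarray = field(default=None, repr=False)  # (F, 3) int

    def __post_init__(self):
        if self.voxel_index is None and self.n_fixels:
            vi = np.zeros((self.n_fixels, 3), dtype=np.int64)
            for ijk in np.argwhere(self.counts > 0):
                o = self.offsets[tuple(ijk)]
                vi[o : o + self.counts[tuple(ijk)]] = ijk
            self.voxel_index = vi
        elif self.voxel_index is None:
            self.voxel_index = np.zeros((0, 3), dtype=np.int64)

    @property
    def n_fixels(self) -> int:
        return int(self.directions.shape[0])

    def fixels_of_voxel(self, i: int, j: int, k: int) -> np.ndarray:
        o, c = int(self.offsets[i, j, k]), int(self.counts[i, j, k])
        return np.arange(o, o + c)

    # ---- fixel directory format (MRtrix-compatible layout) ----
    def save(self, directory: str | Path, compress: bool = False) -> None:
        """Write ``index`` (X,Y,Z,2 = [count, offset]), ``directions``
        (F,1,3), ``peak_amp`` and ``integral`` (F,1,1) NIfTI files.
        Offsets are 0-based and contiguous."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ext = ".nii.gz" if compress else ".nii"
        index = np.stack([self.counts, self.offsets], axis=-1).astype(np.int32)
        eye = np.eye(4)
        nib.save(nib.Nifti1Image(index, self.affine), directory / f"index{ext}")
        nib.save(
            nib.Nifti1Image(
                self.directions.reshape(-1, 1, 3).astype(np.float32), eye
            ),
            directory / f"directions{ext}",
        )
        nib.save(
            nib.Nifti1Image(
                self.peak_amplitudes.reshape(-1, 1, 1).astype(np.float32), eye
            ),
            directory / f"peak_amp{ext}",
        )
        nib.save(
            nib.Nifti1Image(
                self.lobe_integrals.reshape(-1, 1, 1).astype(np.float32), eye
            ),
            directory / f"integral{ext}",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "FixelGrid":
        directory = Path(directory)

        def _read(stem):
            for ext in (".nii", ".nii.gz"):
                p = directory / f"{stem}{ext}"
                if p.exists():
                    return nib.load(p)
            raise FileNotFoundError(f"{stem}.nii[.gz] not found in {directory}")

        index_img = _read("index")
        index = np.asarray(index_img.dataobj)
        counts, offsets = index[..., 0], index[..., 1]
        return cls(
            shape=counts.shape,
            affine=index_img.affine,
            counts=counts.astype(np.int64),
            offsets=offsets.astype(np.int64),
            directions=np.asarray(_read("directions").dataobj, dtype=float).reshape(-1, 3),
            peak_amplitudes=np.asarray(_read("peak_amp").dataobj, dtype=float).ravel(),
            lobe_integrals=np.asarray(_read("integral").dataobj, dtype=float).ravel(),
        )


def extract_fixels(
    fod: SHImage,
    mask: np.ndarray,
    abs_threshold: float = DEFAULT_PEAK_THRESHOLD,
    max_fixels: int = DEFAULT_MAX_FIXELS,
    mesh: SphereMesh | None = None,
    chunk: int = 512,
) -> FixelGrid:
    """Segment every masked voxel's FOD into fixels.

    Deterministic given inputs.  Voxels whose FOD has no peak above the
    absolute threshold (including all-zero and negative-only FODs) get a
    fixel count of 0.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != fod.shape:
        raise ValueError(f"mask shape {mask.shape} != FOD grid {fod.shape}")
    if mesh is None:
        mesh = SphereMesh.icosphere(4)
    vox = np.argwhere(mask)
    counts = np.zeros(fod.shape, dtype=np.int64)
    per_voxel: dict[tuple, list[Fixel]] = {}
    for start in range(0, len(vox), chunk):
        block = vox[start : start + chunk]
        coeffs = fod.coeffs[block[:, 0], block[:, 1], block[:, 2]]
        amp = coeffs @ sh_basis(mesh.directions, fod.lmax).T  # (V, N)
        roots = _ascend_roots(amp, mesh)
        for r, ijk in enumerate(block):
            peaks = _peaks_from_grid(coeffs[r], amp[r], mesh, abs_threshold, max_fixels)
            if not peaks:
                continue
            fx = _lobes_from_roots(amp[r], roots[r], peaks, mesh)
            per_voxel[tuple(ijk)] = fx
            counts[tuple(ijk)] = len(fx)
    offsets = np.zeros_like(counts)
    flat_order = np.argwhere(np.ones(fod.shape, dtype=bool))  # C order
    dirs, pamps, integrals, pdirs = [], [], [], []
    off = 0
    for ijk in flat_order:
        key = tuple(ijk)
        offsets[key] = off
        for f in per_voxel.get(key, ()):  # descending amplitude already
            dirs.append(f.direction)
            pamps.append(f.peak_amplitude)
            integrals.append(f.lobe_integral)
            pdirs.append(f.peak_direction)
            off += 1
    return FixelGrid(
        shape=fod.shape,
        affine=fod.affine,
        counts=counts,
        offsets=offsets,
        directions=np.asarray(dirs, dtype=float).reshape(-1, 3),
        peak_amplitudes=np.asarray(pamps, dtype=float),
        lobe_integrals=np.asarray(integrals, dtype=float),
        peak_directions=np.asarray(pdirs, dtype=float).reshape(-1, 3),
    )


def _peaks_from_grid(coeffs, amp, mesh, abs_threshold, max_peaks):
    """find_peaks given precomputed mesh amplitudes (extraction fast path)."""
    cand = _mesh_local_maxima(amp, mesh)
    cand = cand[amp[cand] >= 0.5 * abs_threshold]
    if cand.size == 0:
        return []
    refined, ref_amp = refine_peaks(
        mesh.directions[cand], np.broadcast_to(coeffs, (cand.size, coeffs.size))
    )
    keep = ref_amp >= abs_threshold
    refined, ref_amp = refined[keep], ref_amp[keep]
    order = np.argsort(-ref_amp)
    cos_merge = np.cos(np.deg2rad(_PEAK_MERGE_DEG))
    peaks = []
    for i in order:
        d = canonicalize_direction(refined[i])
        if any(abs(float(d @ p[0])) >= cos_merge for p in peaks):
            continue
        peaks.append((d, float(ref_amp[i])))
        if len(peaks) == max_peaks:
            break
    return peaks


def fixels_per_voxel_histogram(fixels: FixelGrid, mask: np.ndarray) -> dict:
    """Histogram of fixel counts over masked voxels with >= 1 fixel.

    Returns ``{"counts": {"1": n1, "2": n2, "3+": n3}, "fractions": {...},
    "n_voxels": total}``; fractions sum to 1 (empty marker if no voxels).
    """
    mask = np.asarray(mask).astype(bool)
    c = fixels.counts[mask]
    c = c[c >= 1]
    n = int(c.size)
    counts = {
        "1": int(np.sum(c == 1)),
        "2": int(np.sum(c == 2)),
        "3+": int(np.sum(c >= 3)),
    }
    if n == 0:
        return {"counts": counts, "fractions": None, "n_voxels": 0, "empty": True}
    fractions = {k: v / n for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions, "n_voxels": n, "empty": False}
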