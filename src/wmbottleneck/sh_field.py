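"""Even-order real spherical-harmonic (SH) fields for fiber orientation
distributions (FODs).

An FOD is a nonnegative, antipodally symmetric function on the 2-sphere whose
lobes point along the local axon orientations of a voxel.  This module
provides the coefficient container (:class:`SHImage`), the discrete spherical
domain used for peak search and projection (:class:`SphereMesh`), evaluation
of SH series, and a forward model that synthesizes an FOD from a mixture of
axially symmetric lobes (used by the phantom generator and by peak-finding
oracles).

Basis convention
----------------
``BASIS_CONVENTION = "real-sym-lm-scipy"``: real, symmetric (even ``l`` only)
basis built from scipy's complex spherical harmonics ``Y_l^m`` (which include
the Condon–Shortley phase).  Coefficients are ordered by ascending even
degree ``l = 0, 2, ..., lmax`` and, within each degree, ascending order
``m = -l, ..., l``.  The real basis function for index ``(l, m)`` is::

    m < 0 :  sqrt(2) * Im( Y_l^{|m|} )
    m = 0 :  Y_l^0                      (real already)
    m > 0 :  sqrt(2) * Re( Y_l^{m} )

This basis is orthonormal over the sphere.  Files written by this package
record the convention string in a JSON sidecar next to the NIfTI volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.special import sph_harm_y

BASIS_CONVENTION = "real-sym-lm-scipy"

__all__ = [
    "BASIS_CONVENTION",
    "SHImage",
    "SphereMesh",
    "sh_basis_size",
    "sh_basis",
    "eval_sh",
    "sh_from_lobes",
    "lmax_from_ncoeffs",
]


def sh_basis_size(lmax: int) -> int:
    """Number of coefficients of the even-order real symmetric basis.

    Parameters
    ----------
    lmax : even, nonnegative integer
        Maximum SH degree.

    Returns
    -------
    int
        ``(lmax + 1) * (lmax + 2) // 2``.
    """
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be even and >= 0, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def lmax_from_ncoeffs(n: int) -> int:
    """Invert :func:`sh_basis_size`; raises if ``n`` is not a valid size."""
    lmax = 0
    while sh_basis_size(lmax) < n:
        lmax += 2
    if sh_basis_size(lmax) != n:
        raise ValueError(f"{n} is not a valid even-order SH basis size")
    return lmax


def _check_unit(directions: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    directions = np.asarray(directions, dtype=float)
    if directions.ndim == 1:
        directions = directions[None, :]
    if directions.shape[-1] != 3:
        raise ValueError("directions must have shape (M, 3)")
    norms = np.linalg.norm(directions, axis=-1)
    if not np.allclose(norms, 1.0, atol=tol):
        raise ValueError("directions must be unit vectors")
    return directions


def sh_basis(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Design matrix of the real symmetric SH basis.

    Parameters
    ----------
    directions : (M, 3) array of unit vectors
    lmax : even integer

    Returns
    -------
    (M, C) array where column ``j`` is basis function ``j`` evaluated at each
    direction, with the ordering documented in the module docstring.
    """
    directions = _check_unit(directions)
    n_coef = sh_basis_size(lmax)
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar angle
    phi = np.arctan2(y, x)
    out = np.empty((directions.shape[0], n_coef))
    j = 0
    for ell in range(0, lmax + 1, 2):
        # complex Y_l^m for m = 0..l; negative m via conjugation symmetry
        for m in range(-ell, ell + 1):
            ylm = sph_harm_y(ell, abs(m), theta, phi)
            if m < 0:
                out[:, j] = np.sqrt(2.0) * ylm.imag
            elif m == 0:
                out[:, j] = ylm.real
            else:
                out[:, j] = np.sqrt(2.0) * ylm.real
            j += 1
    return out


def eval_sh(coeffs: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Evaluate an SH series at unit directions.

    ``coeffs`` may be a single length-C vector or a stack ``(..., C)``; the
    result has shape ``(..., M)``.  Antipodal symmetry ``f(d) = f(-d)`` holds
    by construction (even degrees only).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = lmax_from_ncoeffs(coeffs.shape[-1])
    basis = sh_basis(directions, lmax)
    return coeffs @ basis.T


@dataclass
class SphereMesh:
    """Triangulated discrete sphere used for peak search and projection.

    Attributes
    ----------
    directions : (N, 3) unit vectors (icosphere vertices; antipodally
        complete — the icosphere is centrally symmetric).
    triangles : (T, 3) int vertex indices.
    neighbors : list of N int arrays, the one-ring of each vertex.
    """

    directions: np.ndarray
    triangles: np.ndarray
    neighbors: list = field(repr=False)
    vertex_areas: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.directions = _check_unit(self.directions, tol=1e-9)
        if self.vertex_areas is None:
            # one third of each adjacent flat-triangle area, rescaled so the
            # weights sum to the sphere area (a proper quadrature rule —
            # icosphere vertex density is not uniform)
            v, f = self.directions, self.triangles
            cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            face_area = 0.5 * np.linalg.norm(cross, axis=1)
            areas = np.zeros(len(v))
            np.add.at(areas, f.ravel(), np.repeat(face_area / 3.0, 3))
            self.vertex_areas = areas * (4.0 * np.pi / areas.sum())

    @property
    def n_vertices(self) -> int:
        return self.directions.shape[0]

    @classmethod
    def icosphere(cls, subdivisions: int = 4) -> "SphereMesh":
        return _icosphere_cached(subdivisions)


@lru_cache(maxsize=8)
def _icosphere_cached(subdivisions: int) -> SphereMesh:
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    nbrs: list[set] = [set() for _ in range(len(verts))]
    for a, b, c in faces:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    neighbors = [np.fromiter(sorted(s), dtype=np.int64) for s in nbrs]
    return SphereMesh(directions=verts, triangles=faces, neighbors=neighbors)


@lru_cache(maxsize=64)
def _zonal_coeffs(kappa: float, lmax: int, n_quad: int = 200) -> np.ndarray:
    """Funk–Hecke eigenvalues of the axial kernel, one per even degree.

    ``lambda_l = 2*pi * int_{-1}^{1} exp(kappa*(t^2 - 1)) P_l(t) dt`` by
    Gauss–Legendre quadrature; the SH coefficients of a kernel centered on
    ``d`` are then ``lambda_l * Y_lm(d)`` exactly, which keeps the synthesis
    rotation-equivariant (no mesh-discretization anisotropy).
    """
    from scipy.special import eval_legendre

    t, w = np.polynomial.legendre.leggauss(n_quad)
    k = np.exp(kappa * (t**2 - 1.0))
    return np.array(
        [2.0 * np.pi * np.sum(w * k * eval_legendre(ell, t)) for ell in range(0, lmax + 1, 2)]
    )


def sh_from_lobes(
    lobe_dirs: np.ndarray,
    weights: np.ndarray,
    kappa: float = 50.0,
    lmax: int = 8,
) -> np.ndarray:
    """Synthesize SH coefficients for a mixture of axially symmetric lobes.

    The lobe kernel is ``K_kappa(theta) = exp(kappa * (cos^2 theta - 1))``,
    sharply peaked along ``+/- lobe_dir`` and antipodally symmetric.  The
    mixture ``sum_k w_k K_kappa(angle to d_k)`` is projected onto the SH
    basis exactly via the Funk–Hecke theorem (zonal expansion rotated to
    each lobe direction), so the result is linear in ``weights`` and free of
    orientation bias.

    Parameters
    ----------
    lobe_dirs : (K, 3) unit vectors (K may be 0)
    weights : (K,) nonnegative reals
    kappa : concentration > 0; larger is sharper
    lmax : even SH degree of the output

    Returns
    -------
    (C,) coefficient vector.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    n_coef = sh_basis_size(lmax)
    lobe_dirs = np.asarray(lobe_dirs, dtype=float).reshape(-1, 3)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if lobe_dirs.shape[0] != weights.shape[0]:
        raise ValueError("lobe_dirs and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if lobe_dirs.shape[0] == 0 or np.all(weights == 0):
        return np.zeros(n_coef)
    lobe_dirs = _check_unit(lobe_dirs)
    lam = _zonal_coeffs(float(kappa), lmax)
    per_degree = np.repeat(lam, [2 * ell + 1 for ell in range(0, lmax + 1, 2)])
    basis_at_lobes = sh_basis(lobe_dirs, lmax)  # (K, C)
    return per_degree * (weights @ basis_at_lobes)


@dataclass
class SHImage:
    """4D grid of even-order real SH coefficients with a world affine.

    Attributes
    ----------
    coeffs : (X, Y, Z, C) float array of SH coefficients.
    affine : (4, 4) invertible voxel-index -> world-mm transform
        (voxel center of index ``(0,0,0)`` maps to ``affine @ (0,0,0,1)``).
    lmax : even SH degree consistent with C.
    basis_convention : identifier of the real-basis ordering/normalization.
    """

    coeffs: np.ndarray
    affine: np.ndarray
    lmax: int | None = None
    basis_convention: str = BASIS_CONVENTION

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4:
            raise ValueError("coeffs must be 4D (X, Y, Z, C)")
        inferred = lmax_from_ncoeffs(self.coeffs.shape[-1])
        if self.lmax is None:
            self.lmax = inferred
        elif self.lmax != inferred:
            raise ValueError(
                f"lmax={self.lmax} inconsistent with C={self.coeffs.shape[-1]}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple:
        return self.coeffs.shape[:3]

    def save(self, path: str | Path) -> None:
        """Write as NIfTI-1 4D volume plus a JSON sidecar recording the
        basis convention and lmax."""
        path = Path(path)
        nib.save(nib.Nifti1Image(self.coeffs.astype(np.float32), self.affine), path)
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
        sidecar = sidecar.parent / (sidecar.name + ".json")
        sidecar.write_text(
            json.dumps(
                {"basis_convention": self.basis_convention, "lmax": self.lmax},
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "SHImage":
        path = Path(path)
        img = nib.load(path)
        sidecar = path.with_suffix("").with_suffix("")
        sidecar = sidecar.parent / (sidecar.name + ".json")
        convention = BASIS_CONVENTION
        lmax = None
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            convention = meta.get("basis_convention", BASIS_CONVENTION)
            lmax = meta.get("lmax")
        return cls(
            coeffs=np.asarray(img.dataobj, dtype=float),
            affine=img.affine,
            lmax=lmax,
            basis_convention=convention,
        )
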