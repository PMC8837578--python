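"""Assign bundles to fixels and voxels via fixel-density maps.

For each bundle, a *fixel-density map* counts the streamlines most closely
aligned to each fixel (maximal ``|tangent . fixel direction|`` within the
voxel each streamline traverses).  The map is thresholded at a fraction of
its own maximum (default 5%) to produce a binary fixel profile, which is
projected to a binary voxel profile.  Counting profiles per fixel gives
bundles-per-fixel; bundles-per-voxel counts the union of bundles over a
voxel's fixels, so a bundle assigned to two fixels of one voxel still
counts once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .fixel_extract import FixelGrid
from .tract_io import Bundle, map_streamline_to_voxels

logger = logging.getLogger(__name__)

__all__ = [
    "FixelDensityMap",
    "BundleProfile",
    "fixel_density",
    "threshold_profile",
    "bundles_per_fixel",
    "bundles_per_voxel",
    "DEFAULT_DENSITY_FRAC",
]

DEFAULT_DENSITY_FRAC = 0.05


@dataclass
class FixelDensityMap:
    """Per-bundle streamline counts over the flat fixel index."""

    bundle_name: str
    counts: np.ndarray  # (F,) nonnegative int

    def save(self, fixel_directory, compress: bool = False) -> None:
        ext = ".nii.gz" if compress else ".nii"
        path = Path(fixel_directory) / f"density_{self.bundle_name}{ext}"
        nib.save(
            nib.Nifti1Image(self.counts.reshape(-1, 1, 1).astype(np.float32), np.eye(4)),
            path,
        )


@dataclass
class BundleProfile:
    """Binary fixel mask and derived binary voxel mask of one bundle."""

    bundle_name: str
    fixel_mask: np.ndarray  # (F,) bool
    voxel_mask: np.ndarray  # (X, Y, Z) bool
    threshold_frac: float

    def save(self, fixel_directory, compress: bool = False) -> None:
        ext = ".nii.gz" if compress else ".nii"
        directory = Path(fixel_directory)
        nib.save(
            nib.Nifti1Image(
                self.fixel_mask.reshape(-1, 1, 1).astype(np.uint8), np.eye(4)
            ),
            directory / f"profile_{self.bundle_name}{ext}",
        )
        meta = {
            "bundle": self.bundle_name,
            "threshold_frac": self.threshold_frac,
            "n_fixels": int(self.fixel_mask.sum()),
            "n_voxels": int(self.voxel_mask.sum()),
        }
        (directory / f"profile_{self.bundle_name}.json").write_text(
            json.dumps(meta, indent=2)
        )


def fixel_density(bundle: Bundle, fixels: FixelGrid, step_frac: float = 0.25) -> FixelDensityMap:
    """Count, per fixel, the streamlines most closely aligned with it.

    Each streamline visit (one per voxel) increments the voxel fixel that
    maximizes ``|visit direction . fixel direction|``; exact ties go to the
    lowest flat fixel index.  Visits in voxels with no fixels are dropped
    (logged).  A streamline increments a given fixel at most once.
    """
    counts = np.zeros(fixels.n_fixels, dtype=np.int64)
    shape = fixels.shape
    dropped = 0
    for streamline in bundle.streamlines:
        for visit in map_streamline_to_voxels(streamline, fixels.affine, step_frac):
            i, j, k = visit.voxel
            if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
                dropped += 1
                continue
            c = fixels.counts[i, j, k]
            if c == 0:
                dropped += 1
                continue
            o = fixels.offsets[i, j, k]
            align = np.abs(fixels.directions[o : o + c] @ visit.direction)
            counts[o + int(np.argmax(align))] += 1  # argmax: first max = lowest index
    if dropped:
        logger.info(
            "bundle %s: %d streamline visit(s) in zero-fixel voxels dropped",
            bundle.name,
            dropped,
        )
    return FixelDensityMap(bundle_name=bundle.name, counts=counts)


def threshold_profile(
    density: FixelDensityMap,
    fixels: FixelGrid,
    frac: float = DEFAULT_DENSITY_FRAC,
    global_max: float | None = None,
) -> BundleProfile:
    """Binarize a fixel-density map at ``frac`` of its maximum density.

    A fixel is kept iff ``count >= frac * max`` and ``count > 0``; the
    maximum is this bundle's own map maximum unless ``global_max`` is given
    (dataset-wide alternative).  The voxel mask marks voxels containing at
    least one kept fixel.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    counts = density.counts
    peak = float(counts.max()) if global_max is None else float(global_max)
    if peak <= 0:
        logger.warning("bundle %s: all-zero density map; empty profile", density.bundle_name)
        fixel_mask = np.zeros(counts.shape, dtype=bool)
    else:
        fixel_mask = (counts >= frac * peak) & (counts > 0)
    voxel_mask = np.zeros(fixels.shape, dtype=bool)
    if fixel_mask.any():
        vi = fixels.voxel_index[fixel_mask]
        voxel_mask[vi[:, 0], vi[:, 1], vi[:, 2]] = True
    return BundleProfile(
        bundle_name=density.bundle_name,
        fixel_mask=fixel_mask,
        voxel_mask=voxel_mask,
        threshold_frac=frac,
    )


def _check_shared_grid(profiles: list[BundleProfile]) -> None:
    if not profiles:
        return
    f = profiles[0].fixel_mask.shape
    v = profiles[0].voxel_mask.shape
    for p in profiles[1:]:
        if p.fixel_mask.shape != f or p.voxel_mask.shape != v:
            raise ValueError("profiles do not share one fixel grid")


def bundles_per_fixel(profiles: list[BundleProfile], n_fixels: int | None = None) -> np.ndarray:
    """Number of bundle profiles marking each fixel."""
    _check_shared_grid(profiles)
    if not profiles:
        return np.zeros(0 if n_fixels is None else n_fixels, dtype=np.int64)
    out = np.zeros(profiles[0].fixel_mask.shape, dtype=np.int64)
    for p in profiles:
        out += p.fixel_mask
    return out


def bundles_per_voxel(profiles: list[BundleProfile], shape: tuple | None = None) -> np.ndarray:
    """Number of distinct bundles per voxel (count-once union rule).

    A bundle assigned to several fixels of one voxel contributes one; this
    equals the count of profiles whose voxel mask is true.
    """
    _check_shared_grid(profiles)
    if not profiles:
        return np.zeros((0, 0, 0) if shape is None else shape, dtype=np.int64)
    out = np.zeros(profiles[0].voxel_mask.shape, dtype=np.int64)
    for p in profiles:
        out += p.voxel_mask
    return out
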