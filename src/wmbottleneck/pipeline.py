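"""End-to-end bottleneck quantification pipeline.

Chains the stages: fixel extraction from the FOD volume, per-bundle
fixel-density maps and binary profiles, bundle counting per fixel and per
voxel, six-way classification, prevalence tables, and bottleneck-region
clustering.  The single entry point :func:`run_pipeline` is what the CLI
``run`` command and the phantom validation drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .bottleneck_stats import (
    BottleneckReport,
    Classification,
    DEFAULT_ANGLE_TOL_DEG,
    DEFAULT_MIN_BUNDLES,
    DEFAULT_MIN_CLUSTER_VOXELS,
    classify,
    find_bottleneck_regions,
    prevalence_tables,
    single_fixel_voxel_histogram,
)
from .bundle_assignment import (
    DEFAULT_DENSITY_FRAC,
    bundles_per_fixel,
    bundles_per_voxel,
    fixel_density,
    threshold_profile,
)
from .fixel_extract import (
    DEFAULT_MAX_FIXELS,
    DEFAULT_PEAK_THRESHOLD,
    FixelGrid,
    extract_fixels,
)
from .sh_field import SHImage
from .tract_io import Bundle

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate and final products of one pipeline run."""

    fixels: FixelGrid
    densities: list
    profiles: list
    counts_fixel: np.ndarray
    counts_voxel: np.ndarray
    classification: Classification
    report: BottleneckReport
    parameters: dict = field(default_factory=dict)


def run_pipeline(
    fod: SHImage,
    bundles: list[Bundle],
    wm_mask: np.ndarray,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    max_fixels: int = DEFAULT_MAX_FIXELS,
    density_frac: float = DEFAULT_DENSITY_FRAC,
    min_bundles: int = DEFAULT_MIN_BUNDLES,
    angle_tol_deg: float = DEFAULT_ANGLE_TOL_DEG,
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
    fixels: FixelGrid | None = None,
) -> PipelineResult:
    """Run the full analysis on one dataset.

    ``fixels`` may be passed to reuse a precomputed extraction (the stage
    is deterministic, so results are identical either way).
    """
    wm_mask = np.asarray(wm_mask).astype(bool)
    if fixels is None:
        fixels = extract_fixels(
            fod, wm_mask, abs_threshold=peak_threshold, max_fixels=max_fixels
        )
    densities = [fixel_density(b, fixels) for b in bundles]
    profiles = [threshold_profile(d, fixels, frac=density_frac) for d in densities]
    counts_fixel = bundles_per_fixel(profiles, n_fixels=fixels.n_fixels)
    counts_voxel = bundles_per_voxel(profiles, shape=fixels.shape)
    classification = classify(fixels, counts_fixel, counts_voxel, wm_mask)
    tables = prevalence_tables(classification)
    sfv = single_fixel_voxel_histogram(classification)
    clusters = find_bottleneck_regions(
        counts_fixel,
        fixels,
        min_bundles=min_bundles,
        angle_tol_deg=angle_tol_deg,
        min_size=min_cluster_voxels,
    )
    parameters = {
        "peak_threshold": peak_threshold,
        "max_fixels": max_fixels,
        "density_frac": density_frac,
        "min_bundles": min_bundles,
        "angle_tol_deg": angle_tol_deg,
        "min_cluster_voxels": min_cluster_voxels,
        "n_bundles": len(bundles),
        "bundle_names": [b.name for b in bundles],
    }
    report = BottleneckReport(
        tables=tables,
        single_fixel_voxel=sfv,
        clusters=clusters,
        parameters=parameters,
        provenance={"tool": "wmbottleneck", "version": __version__},
    )
    return PipelineResult(
        fixels=fixels,
        densities=densities,
        profiles=profiles,
        counts_fixel=counts_fixel,
        counts_voxel=counts_voxel,
        classification=classification,
        report=report,
        parameters=parameters,
    )
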