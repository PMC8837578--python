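"""Shared fixtures: sphere meshes and cached phantom pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from wmbottleneck import PhantomSpec, make_phantom, run_pipeline
from wmbottleneck.sh_field import SphereMesh


@pytest.fixture(scope="session")
def search_mesh():
    return SphereMesh.icosphere(4)  # 2562 directions, peak-search default


@pytest.fixture(scope="session")
def dense_mesh():
    return SphereMesh.icosphere(5)  # 10242 directions, brute-force oracle


class _PhantomCache:
    """Generate each phantom configuration (and its pipeline run) once per
    session; every run uses the study defaults and seed 1."""

    def __init__(self):
        self._cache = {}

    def __call__(self, configuration: str, **kwargs):
        key = (configuration, tuple(sorted(kwargs.items())))
        if key not in self._cache:
            spec = PhantomSpec(configuration=configuration, seed=1, **kwargs)
            fod, bundles, wm_mask, truth = make_phantom(spec)
            result = run_pipeline(fod, bundles, wm_mask)
            self._cache[key] = dict(
                spec=spec,
                fod=fod,
                bundles=bundles,
                wm_mask=wm_mask,
                truth=truth,
                result=result,
            )
        return self._cache[key]


@pytest.fixture(scope="session")
def phantom_run():
    return _PhantomCache()


def brute_force_peaks(coeffs, mesh, threshold=0.0):
    """Independent grid search for FOD maxima: evaluate on a dense mesh,
    keep vertices that beat every one-ring neighbor, deduplicate
    antipodally.  No continuous refinement — pure enumeration."""
    from wmbottleneck.sh_field import eval_sh

    amp = eval_sh(np.asarray(coeffs, float), mesh.directions)
    out = []
    for v in range(mesh.n_vertices):
        if amp[v] <= threshold:
            continue
        if all(amp[v] >= amp[n] for n in mesh.neighbors[v]):
            d = mesh.directions[v]
            if not any(abs(float(d @ q)) > np.cos(np.deg2rad(5.0)) for q, _ in out):
                out.append((d, float(amp[v])))
    out.sort(key=lambda p: -p[1])
    return out
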