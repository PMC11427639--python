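"""Shared fixtures: phantoms, simulation grids and one noiseless study slice.

Expensive objects (1-2 mm voxelizations, the noiseless blur-only
Jaszczak quantification) are session-scoped so several property tests
can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import holoquant as hq


@pytest.fixture(scope="session")
def jz_spec() -> hq.PhantomSpec:
    return hq.jaszczak_phantom()


@pytest.fixture(scope="session")
def sim_grid() -> hq.VoxelGrid:
    return hq.VoxelGrid.centered(216 + 120, 4.8)


@pytest.fixture(scope="session")
def whole_sim(jz_spec, sim_grid) -> hq.VOIMask:
    return hq.voxelize_cylinder(
        jz_spec.body_diameter_mm, jz_spec.body_height_mm, grid=sim_grid, label="whole"
    )


@pytest.fixture(scope="session")
def jz_truth0(jz_spec, sim_grid) -> hq.ActivityVolume:
    return hq.ground_truth_map(jz_spec, sim_grid, 0.0)


@pytest.fixture(scope="session")
def noiseless_selfcal(jz_spec, sim_grid, whole_sim, jz_truth0):
    """Blur-only (no noise, no dead time) Jaszczak scan quantified by CF_self."""
    acq = hq.AcquisitionSpec(noise=False)
    counts = hq.simulate_acquisition(jz_truth0, acq, hq.DeadTimeModel.none())
    cf = hq.self_calibration_cf(counts, whole_sim, jz_truth0.total)
    return hq.quantify_with_cf(counts, cf, 0.0)


@pytest.fixture(scope="session")
def metrics_grid() -> hq.VoxelGrid:
    return hq.VoxelGrid.centered(226, 2.0)


@pytest.fixture(scope="session")
def metrics_vois(jz_spec, metrics_grid):
    return hq.build_jaszczak_vois(jz_spec, metrics_grid)


@pytest.fixture(scope="session")
def noiseless_acrcs(jz_spec, noiseless_selfcal, metrics_grid, metrics_vois):
    """Sphere and background ACRCs of the blur-only self-calibrated scan."""
    hi = hq.resample_nearest(
        noiseless_selfcal.as_activity_volume(), hq.AffineTransform.identity(), metrics_grid
    )
    qhi = hq.QuantifiedVolume(metrics_grid, hi.values, "self")
    out = {
        f"sphere_{i}": hq.acrc(qhi, metrics_vois[f"sphere_{i}"], jz_spec.concentration_spheres)
        for i in range(1, 7)
    }
    out["background"] = hq.acrc(
        qhi, metrics_vois["background"], jz_spec.concentration_background
    )
    return out
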