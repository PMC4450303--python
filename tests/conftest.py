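"""Shared fixtures: phantom geometry, projections and cached pipeline runs.

The expensive full-scale runs (120 angles, 64x64x64 volume, complete
AR-OSEM-AR pipelines) are session-scoped and shared across the
acceptance tests so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

import arspect as a


@pytest.fixture(scope="session")
def phantom_spec():
    return a.default_3dmac()


@pytest.fixture(scope="session")
def truth_volume(phantom_spec):
    """Full-scale rasterized phantom on the 64x64x64 acquisition grid."""
    return a.rasterize_phantom(phantom_spec, 64, 4.0, 64)


@pytest.fixture(scope="session")
def ideal_projections(truth_volume):
    """Noise-free 120-angle projections of the full-scale phantom."""
    return a.forward_project(truth_volume, a.DEFAULT_ACQUISITION)


@pytest.fixture(scope="session")
def small_truth(phantom_spec):
    """Coarse 32x32x32 rasterization (8 mm voxels) for fast pipeline tests."""
    return a.rasterize_phantom(phantom_spec, 32, 8.0, 32)


@pytest.fixture(scope="session")
def small_acq():
    return a.AcquisitionSpec(n_angles=40, detector_bins=32, bin_size=8.0)


@pytest.fixture(scope="session")
def small_projections(small_truth, small_acq):
    return a.forward_project(small_truth, small_acq)


@pytest.fixture(scope="session")
def low_count_runs(phantom_spec, truth_volume, ideal_projections):
    """Five seeded full-scale pipeline runs at the low count level.

    For each seed: the noisy projections, the AR-OSEM-AR volume, the
    unfiltered OSEM volume (for fixed-cutoff post-filtering) and the
    BW-FBP volume CoV-matched to the AR pipeline.  Shared by every
    acceptance test that needs the low-count comparison.
    """
    from dataclasses import replace

    u_roi = a.uniform_roi(truth_volume, phantom_spec)
    methods = a.standard_methods()
    runs = []
    for seed in (101, 102, 103, 104, 105):
        noisy = a.simulate_counts(ideal_projections, 50_000.0, seed)
        vol_ar = a.run_method(noisy, methods["AR-OSEM-AR"])
        cov_ar = a.cov_percent(a.roi_stats(vol_ar, u_roi))
        res = a.match_cov(noisy, "BW-FBP", cov_ar, u_roi)
        fbp_spec = methods["BW-FBP"]
        fbp_spec = replace(
            fbp_spec,
            recon=replace(
                fbp_spec.recon,
                butterworth_cutoff=res.cutoff,
                butterworth_stage="pre2d",
            ),
        )
        vol_fbp = a.run_method(noisy, fbp_spec)
        vol_osem = a.osem_reconstruct(noisy)
        runs.append(
            {
                "seed": seed,
                "noisy": noisy,
                "ar": vol_ar,
                "cov_ar": cov_ar,
                "fbp": vol_fbp,
                "fbp_cutoff": res.cutoff,
                "osem": vol_osem,
            }
        )
    return {"runs": runs, "uniform_roi": u_roi}
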