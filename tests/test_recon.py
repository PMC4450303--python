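"""Butterworth filtering, FBP and OSEM reconstruction."""

import numpy as np
import pytest

import arspect as a
from arspect.errors import ConfigurationError, InvalidInputError
from arspect.phantom import ActivityVolume
from arspect.projector import AcquisitionSpec, scale_counts
from arspect.recon import (
    ReconConfig,
    apply_butterworth,
    butterworth_gain,
    fbp_reconstruct,
    nyquist_cycles_per_cm,
    osem_reconstruct,
    poisson_loglik,
)


def _disk_volume(n=64, r_px=10.0, n_slices=3, value=1.0):
    c = (n - 1) / 2
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c)
    vox = np.where(np.hypot(yy, xx) <= r_px, value, 0.0)
    return ActivityVolume(np.stack([vox] * n_slices), 4.0)


class TestButterworthGain:
    def test_closed_form_points(self):
        assert butterworth_gain(0.0, 0.84, 2) == 1.0
        for order in (1, 2, 5):
            assert np.isclose(butterworth_gain(0.84, 0.84, order), 1 / np.sqrt(2))
        assert np.isclose(butterworth_gain(1.68, 0.84, 2), 1 / np.sqrt(17))

    def test_guards(self):
        with pytest.raises(ConfigurationError):
            butterworth_gain(0.5, 0.0, 2)
        with pytest.raises(InvalidInputError):
            butterworth_gain(-1.0, 0.5, 2)


class TestApplyButterworth:
    def test_constant_input_unchanged(self):
        img = np.full((8, 8), 3.0)
        np.testing.assert_allclose(apply_butterworth(img, 1.0, 2, 4.0), img, atol=1e-12)

    def test_identity_limit_far_above_nyquist(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16))
        out = apply_butterworth(
            img, 100 * nyquist_cycles_per_cm(4.0), 2, 4.0, high_cutoff="allow"
        )
        assert np.abs(out - img).max() < 1e-6

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        cutoff, order, d_cm = 0.7, 2, 0.4
        fy = np.fft.fftfreq(32, d=d_cm)
        fx = np.fft.fftfreq(32, d=d_cm)
        rad = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
        gain = 1.0 / np.sqrt(1.0 + (rad / cutoff) ** (2 * order))
        oracle = np.fft.ifft2(np.fft.fft2(img) * gain).real
        out = apply_butterworth(img, cutoff, order, 4.0)
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_energy_never_increases_and_cutoff_orders_variance(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0.0, 1.0, (32, 32))
        v = [np.var(apply_butterworth(img, c, 2, 4.0)) for c in (0.3, 0.6, 1.2)]
        assert v[0] < v[1] < v[2] <= np.var(img) + 1e-12

    def test_cutoff_above_nyquist_raises_by_default(self):
        with pytest.raises(ConfigurationError):
            apply_butterworth(np.ones((8, 8)), 2.0, 2, 4.0)


class TestFBP:
    def test_zero_sinogram_gives_zero_volume(self):
        vol = _disk_volume()
        proj = a.forward_project(vol, AcquisitionSpec(n_angles=30))
        zero = a.ProjectionSet(
            data=np.zeros_like(proj.data),
            angles=proj.angles,
            geometry=proj.geometry,
        )
        rec = fbp_reconstruct(zero)
        np.testing.assert_allclose(rec.voxels, 0.0, atol=1e-12)

    def test_uniform_disk_self_consistency(self):
        vol = _disk_volume(r_px=5.0)  # 40 mm disk at 4 mm pixels
        proj = a.forward_project(vol, AcquisitionSpec(n_angles=60))
        rec = fbp_reconstruct(proj)
        c = 31.5
        yy, xx = np.meshgrid(np.arange(64) - c, np.arange(64) - c)
        inner = np.hypot(yy, xx) <= 3.75  # concentric 30 mm ROI
        assert abs(rec.voxels[1][inner].mean() - 1.0) < 0.05

    def test_point_source_localization(self):
        vox = np.zeros((3, 64, 64))
        vox[1, 40, 22] = 1.0
        proj = a.forward_project(ActivityVolume(vox, 4.0), AcquisitionSpec(n_angles=90))
        rec = fbp_reconstruct(proj)
        assert np.unravel_index(np.argmax(rec.voxels), rec.voxels.shape) == (1, 40, 22)

    def test_linearity(self):
        vol = _disk_volume(r_px=8.0)
        acq = AcquisitionSpec(n_angles=20)
        p1 = a.forward_project(vol, acq)
        rng = np.random.default_rng(4)
        d2 = rng.random(p1.data.shape)
        p2 = a.ProjectionSet(data=d2, angles=p1.angles, geometry=acq)
        combo = a.ProjectionSet(
            data=2.0 * p1.data + 3.0 * d2, angles=p1.angles, geometry=acq
        )
        r = fbp_reconstruct(combo).voxels
        expected = 2.0 * fbp_reconstruct(p1).voxels + 3.0 * fbp_reconstruct(p2).voxels
        scale = np.abs(expected).max()
        assert np.abs(r - expected).max() / scale < 1e-6


class TestOSEM:
    def test_output_nonnegative_and_zero_data_gives_zero(self):
        vol = _disk_volume()
        proj = a.forward_project(vol, AcquisitionSpec(n_angles=16))
        noisy = a.simulate_counts(proj, 5_000.0, 3)
        rec = osem_reconstruct(noisy, ReconConfig(osem_subsets=4, osem_iterations=2))
        assert rec.voxels.min() >= 0.0
        zero = a.ProjectionSet(
            data=np.zeros_like(proj.data), angles=proj.angles, geometry=proj.geometry
        )
        rec0 = osem_reconstruct(zero, ReconConfig(osem_subsets=4, osem_iterations=1))
        np.testing.assert_allclose(rec0.voxels, 0.0, atol=1e-12)

    def test_noise_free_hot_cylinder_contrast_converges(
        self, phantom_spec, truth_volume, ideal_projections
    ):
        rec = osem_reconstruct(ideal_projections)
        u_roi = a.uniform_roi(truth_volume, phantom_spec)
        roi = a.cylinder_roi(rec, phantom_spec, 4.0, 60.0)
        ratio = a.roi_stats(rec, roi).mean / a.roi_stats(rec, u_roi).mean
        assert abs(ratio - 4.0) / 4.0 < 0.10

    def test_mlem_loglikelihood_is_monotone(self):
        vol = _disk_volume(r_px=8.0, value=2.0)
        proj = scale_counts(a.forward_project(vol, AcquisitionSpec(n_angles=24)), 20_000.0)
        lls = [
            poisson_loglik(
                proj,
                osem_reconstruct(proj, ReconConfig(osem_subsets=1, osem_iterations=k)),
            )
            for k in range(1, 11)
        ]
        assert np.all(np.diff(lls) > -1e-6)

    def test_count_preservation_after_first_iteration(self):
        vol = _disk_volume(r_px=8.0)
        proj = scale_counts(a.forward_project(vol, AcquisitionSpec(n_angles=24)), 20_000.0)
        rec = osem_reconstruct(proj, ReconConfig(osem_subsets=8, osem_iterations=1))
        expected = proj.data.sum() / proj.n_angles
        assert abs(rec.voxels.sum() - expected) / expected < 0.02

    def test_negative_projections_rejected(self):
        acq = AcquisitionSpec(n_angles=4, detector_bins=8)
        with pytest.raises(InvalidInputError):
            a.ProjectionSet(
                data=-np.ones((4, 2, 8)), angles=acq.angles, geometry=acq
            )
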