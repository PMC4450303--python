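"""AR model: block fits, decomposition, cascade and 3D filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import arspect as a
from arspect.armodel import (
    ARFilterSpec,
    DEFAULT_ERR_SPEC,
    DEFAULT_MAIN_SPEC,
    FULL3X3,
    ORTHO4,
    PredictionRegion,
    ar_cascade_denoise,
    ar_decompose,
    ar_denoise_3d,
    evaluate_grid,
    fit_block_ar,
)
from arspect.errors import ConfigurationError, InvalidInputError


def brute_force_fit(block, region):
    """Independent normal-equation oracle: explicit per-pixel design loops."""
    block = np.asarray(block, dtype=float)
    e = region.extent
    mean = block.mean()
    centred = block - mean
    padded = np.pad(centred, e, mode="edge")
    rows, ys = [], []
    for i in range(block.shape[0]):
        for j in range(block.shape[1]):
            rows.append(
                [padded[i + e + dr, j + e + dc] for dr, dc in region.offsets]
            )
            ys.append(centred[i, j])
    A = np.asarray(rows)
    y = np.asarray(ys)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid), mean


class TestFitBlockAR:
    def test_constant_block_is_perfectly_predicted(self):
        fit = fit_block_ar(np.full((5, 5), 7.0), ORTHO4)
        assert fit.residual_sse == 0.0
        assert fit.block_mean == 7.0
        # centred data are identically zero -> minimum-norm solution is 0
        np.testing.assert_allclose(fit.coefficients, 0.0)

    def test_checkerboard_matches_bruteforce_oracle(self):
        """The +-1 checkerboard under mean-centred edge-padded OLS.

        On the idealized system (every neighbour exactly -x, zero mean)
        the normal equations give coefficients -1/4 with zero residual;
        the finite 5x5 block has nonzero mean and replicated borders, so
        the fitted solution differs — the implementation must agree with
        the brute-force oracle on the actual system.
        """
        cb = (np.indices((5, 5)).sum(axis=0) % 2) * 2.0 - 1.0
        fit = fit_block_ar(cb, ORTHO4)
        coef, sse, _ = brute_force_fit(cb, ORTHO4)
        np.testing.assert_allclose(fit.coefficients, coef, atol=1e-10)
        assert np.isclose(fit.residual_sse, sse, atol=1e-10)
        # idealized periodic system: x = sum(w * (-x)) over 4 neighbours
        A_ideal = np.full((25, 4), -1.0) * cb.ravel()[:, None]
        w, *_ = np.linalg.lstsq(A_ideal, cb.ravel(), rcond=None)
        np.testing.assert_allclose(w, -0.25, atol=1e-12)

    @pytest.mark.parametrize("region", [ORTHO4, FULL3X3], ids=["ortho4", "full3x3"])
    def test_matches_bruteforce_on_random_blocks(self, region):
        rng = np.random.default_rng(7)
        for _ in range(100):
            size = rng.integers(4, 9)
            block = rng.normal(10.0, 3.0, (size, size))
            fit = fit_block_ar(block, region)
            coef, sse, mean = brute_force_fit(block, region)
            np.testing.assert_allclose(fit.coefficients, coef, atol=1e-8)
            assert np.isclose(fit.residual_sse, sse, atol=1e-6)
            assert np.isclose(fit.block_mean, mean)

    def test_rejects_nonfinite_and_small_blocks(self):
        with pytest.raises(InvalidInputError):
            fit_block_ar(np.array([[1.0, np.nan], [0.0, 1.0]]), ORTHO4)
        with pytest.raises(ConfigurationError):
            fit_block_ar(np.ones((2, 2)), FULL3X3)


class TestPredictionRegion:
    def test_named_constructors(self):
        assert set(ORTHO4.offsets) == {(-1, 0), (1, 0), (0, -1), (0, 1)}
        assert len(FULL3X3.offsets) == 8
        assert all(max(abs(r), abs(c)) == 1 for r, c in FULL3X3.offsets)

    def test_invariants(self):
        with pytest.raises(ConfigurationError):
            PredictionRegion(((0, 0), (1, 0)))
        with pytest.raises(ConfigurationError):
            PredictionRegion(((1, 0), (1, 0)))


class TestARFilterSpec:
    def test_stride_realizes_overlap(self):
        assert ARFilterSpec(ORTHO4, 5, 0.75).stride == 1
        assert ARFilterSpec(FULL3X3, 6, 0.75).stride == 2
        assert ARFilterSpec(ORTHO4, 5, 0.0).stride == 5

    def test_invariants(self):
        with pytest.raises(ConfigurationError):
            ARFilterSpec(ORTHO4, 1, 0.75)
        with pytest.raises(ConfigurationError):
            ARFilterSpec(ORTHO4, 5, 1.0)
        with pytest.raises(ConfigurationError):
            ARFilterSpec(FULL3X3, 3, 0.75)  # 9 <= 8 + 1


class TestDecompose:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_additivity_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(50.0, 10.0, (16, 16))
        dec = ar_decompose(img, DEFAULT_MAIN_SPEC)
        assert np.abs(img - (dec.predicted + dec.error)).max() == 0.0
        assert dec.predicted.shape == img.shape

    def test_constant_image_is_fixed_point(self):
        img = np.full((16, 16), 3.5)
        dec = ar_decompose(img, DEFAULT_MAIN_SPEC)
        np.testing.assert_allclose(dec.predicted, img, atol=1e-12)
        np.testing.assert_allclose(dec.error, 0.0, atol=1e-12)

    def test_acts_as_low_pass_on_poisson_noise(self):
        truth, noisy = a.make_test_slice(64, 3, seed=5)
        dec = ar_decompose(noisy, DEFAULT_MAIN_SPEC)
        assert a.mse(dec.predicted, truth) < a.mse(noisy, truth)

    def test_tiled_fit_agrees_with_single_block_fit(self):
        """With stride = image size the decomposition is one fit_block_ar."""
        rng = np.random.default_rng(3)
        img = rng.normal(20.0, 5.0, (6, 6))
        spec = ARFilterSpec(FULL3X3, 6, 0.0, 1)
        dec = ar_decompose(img, spec)
        fit = fit_block_ar(img, FULL3X3)
        from arspect.armodel import predict_block

        np.testing.assert_allclose(
            dec.predicted, predict_block(img, fit, FULL3X3), atol=1e-10
        )

    def test_rejects_image_smaller_than_block(self):
        with pytest.raises(ConfigurationError):
            ar_decompose(np.ones((4, 4)), DEFAULT_MAIN_SPEC)


class TestCascade:
    def test_zero_image_maps_to_zero(self):
        out = ar_cascade_denoise(np.zeros((16, 16)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_count_bookkeeping_within_ten_percent(self):
        truth, noisy = a.make_test_slice(64, 3, seed=2)
        out = ar_cascade_denoise(noisy)
        assert abs(out.sum() - noisy.sum()) <= 0.10 * noisy.sum()

    def test_cascade_beats_single_decomposition(self):
        truth, noisy = a.make_test_slice(64, 3, seed=9)
        cascade = ar_cascade_denoise(noisy)
        single = ar_decompose(noisy, DEFAULT_MAIN_SPEC).predicted
        assert a.mse(cascade, truth) < a.mse(single, truth)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_reduces_poisson_noise_on_every_seed(self, seed):
        truth, noisy = a.make_test_slice(64, 3, seed=seed)
        out = ar_cascade_denoise(noisy)
        assert a.mse(out, truth) < a.mse(noisy, truth)


class TestDenoise3D:
    def test_constant_volume_is_fixed_point(self):
        vol = np.full((8, 8, 8), 2.0)
        out = ar_denoise_3d(vol)
        np.testing.assert_allclose(out, 2.0, atol=1e-10)

    def test_equals_mean_of_three_orientations(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(30.0, 5.0, (8, 10, 12))
        out = ar_denoise_3d(vol)
        acc = np.zeros_like(vol)
        for axis in range(3):
            moved = np.moveaxis(vol, axis, 0)
            filt = np.stack([ar_cascade_denoise(s) for s in moved])
            acc += np.moveaxis(filt, 0, axis)
        np.testing.assert_allclose(out, acc / 3.0, atol=1e-12)

    def test_reduces_noise_on_phantom_volume(self, truth_volume):
        rng = np.random.default_rng(21)
        scale = 40.0  # counts-like level so Poisson noise is substantial
        noisy = rng.poisson(truth_volume.voxels * scale).astype(float)
        out = ar_denoise_3d(noisy)
        clean = truth_volume.voxels * scale
        assert a.mse(out, clean) < a.mse(noisy, clean)

    def test_rejects_too_small_volume(self):
        with pytest.raises(ConfigurationError):
            ar_denoise_3d(np.ones((4, 8, 8)))


class TestEvaluateGrid:
    def test_single_candidate_single_row(self):
        truth, noisy = a.make_test_slice(32, 2, seed=1)
        table = evaluate_grid(truth, noisy, [(DEFAULT_MAIN_SPEC, DEFAULT_ERR_SPEC)])
        assert len(table) == 1
        assert table.loc[0, "mse"] > 0

    def test_ranking_is_reproducible(self):
        candidates = [
            (DEFAULT_MAIN_SPEC, ARFilterSpec(FULL3X3, b, 0.75, 1)) for b in (5, 6, 7)
        ]
        for counts in (28_705.0, 54_469.0, 108_938.0):
            truth, noisy = a.make_test_slice(64, 3, seed=4, total_counts=counts)
            t1 = evaluate_grid(truth, noisy, candidates)
            t2 = evaluate_grid(truth, noisy, candidates)
            assert list(t1["err_block"]) == list(t2["err_block"])
            np.testing.assert_array_equal(t1["mse"].values, t2["mse"].values)
            assert t1["mse"].is_monotonic_increasing

    def test_rejects_mismatched_shapes(self):
        with pytest.raises(InvalidInputError):
            evaluate_grid(
                np.ones((16, 16)),
                np.ones((17, 17)),
                [(DEFAULT_MAIN_SPEC, DEFAULT_ERR_SPEC)],
            )
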