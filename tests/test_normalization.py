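import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from mfnorm import (
    EntropyParams,
    SeriesGrid,
    VolumeGrid,
    apply_warp,
    build_template,
    estimate_affine,
    estimate_warp,
    normalize_subject,
)
from mfnorm.normalization import (
    DctWarp,
    WarpConfig,
    dct_basis,
    displacement_field,
    identity_affine_params,
    warp_from_json,
    warp_to_json,
)

from conftest import make_blob_volume

SMALL_CONFIG = WarpConfig(basis_counts=(4, 4, 3))


def pull_back(vol: VolumeGrid, displacement: np.ndarray) -> VolumeGrid:
    """Deform a volume by sampling at x + u(x) (same model as the warp)."""
    coords = np.indices(vol.data.shape, dtype=float).reshape(3, -1)
    out = map_coordinates(
        vol.data, coords + displacement.reshape(3, -1), order=1, mode="constant"
    )
    return VolumeGrid(out.reshape(vol.data.shape), vol.affine)


def in_span_warp(amplitude: float, shape=(32, 32, 16), seed=0) -> DctWarp:
    rng = np.random.default_rng(seed)
    warp = DctWarp(
        affine_params=identity_affine_params(),
        basis_counts=(4, 4, 3),
        coefficients=rng.standard_normal((3, 48)),
        grid_shape=shape,
    )
    warp.coefficients[:, 0] = 0.0
    peak = np.abs(displacement_field(warp)).max()
    warp.coefficients *= amplitude / peak
    return warp


class TestDctBasis:
    def test_orthonormal(self):
        b = dct_basis(16, 5)
        np.testing.assert_allclose(b.T @ b, np.eye(5), atol=1e-12)

    def test_default_parameter_count_is_392(self):
        config = WarpConfig()
        assert int(np.prod(config.basis_counts)) == 392

    def test_coefficient_shape_validated(self):
        with pytest.raises(ValueError, match="coefficients"):
            DctWarp(identity_affine_params(), (2, 2, 2), np.zeros((3, 7)), (8, 8, 8))


class TestEstimateAffine:
    def test_identity_on_equal_images(self, blob_volume):
        params, _ = estimate_affine(blob_volume, blob_volume)
        np.testing.assert_allclose(params, identity_affine_params(), atol=1e-3)

    def test_translation_recovery(self, blob_volume):
        target = pull_back(
            blob_volume,
            np.broadcast_to(
                np.array([2.0, 0.0, 0.0])[:, None, None, None],
                (3,) + blob_volume.data.shape,
            ).copy(),
        )
        params, _ = estimate_affine(blob_volume, target)
        np.testing.assert_allclose(params[:3], [2.0, 0.0, 0.0], atol=0.1)

    def test_scale_recovery(self, blob_volume):
        shape = blob_volume.data.shape
        centre = (np.asarray(shape, dtype=float) - 1) / 2
        coords = np.indices(shape, dtype=float).reshape(3, -1)
        scaled = (coords - centre[:, None]) * 1.1 + centre[:, None]
        target = VolumeGrid(
            map_coordinates(blob_volume.data, scaled, order=1).reshape(shape),
            blob_volume.affine,
        )
        params, _ = estimate_affine(blob_volume, target)
        np.testing.assert_allclose(params[6:9], [1.1, 1.1, 1.1], rtol=0.01)

    def test_constant_image_rejected(self, blob_volume):
        flat = VolumeGrid(np.ones(blob_volume.data.shape))
        with pytest.raises(ValueError, match="constant"):
            estimate_affine(flat, blob_volume)


class TestEstimateWarp:
    def test_identity_coefficients_near_zero(self, blob_volume):
        warp = estimate_warp(blob_volume, blob_volume, SMALL_CONFIG)
        assert np.linalg.norm(warp.coefficients) < 1e-6 * np.linalg.norm(
            blob_volume.data
        )

    def test_in_span_recovery_reduces_ssd(self, blob_volume):
        true = in_span_warp(2.0, seed=3)
        target = pull_back(blob_volume, displacement_field(true))
        warp = estimate_warp(blob_volume, target, SMALL_CONFIG)
        # SSD after full warp vs after the affine stage alone
        affine_only = DctWarp(
            warp.affine_params, warp.basis_counts,
            np.zeros_like(warp.coefficients), warp.grid_shape,
        )
        ssd_affine = ((apply_warp(affine_only, blob_volume).data - target.data) ** 2).sum()
        ssd_warp = ((apply_warp(warp, blob_volume).data - target.data) ** 2).sum()
        assert ssd_warp <= 0.1 * ssd_affine
        # displacement recovered over the image support
        mask = blob_volume.data > 0.05 * blob_volume.data.max()
        err = displacement_field(warp) - displacement_field(true)
        assert np.sqrt((err[:, mask] ** 2).mean()) < 0.5

    def test_objective_monotone_nonincreasing(self, blob_volume):
        true = in_span_warp(2.0, seed=4)
        target = pull_back(blob_volume, displacement_field(true))
        warp = estimate_warp(blob_volume, target, SMALL_CONFIG)
        trace = np.asarray(warp.objective_trace)
        assert len(trace) >= 2
        assert (np.diff(trace) <= 1e-9).all()

    def test_deterministic(self, blob_volume):
        true = in_span_warp(1.5, seed=5)
        target = pull_back(blob_volume, displacement_field(true))
        w1 = estimate_warp(blob_volume, target, SMALL_CONFIG)
        w2 = estimate_warp(blob_volume, target, SMALL_CONFIG)
        np.testing.assert_array_equal(w1.coefficients, w2.coefficients)

    def test_grid_mismatch(self, blob_volume):
        other = VolumeGrid(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="grid"):
            estimate_warp(blob_volume, other, SMALL_CONFIG)


class TestApplyWarp:
    def test_identity_warp_nearest_exact(self, blob_volume):
        warp = DctWarp(
            identity_affine_params(), (2, 2, 2), np.zeros((3, 8)),
            blob_volume.data.shape,
        )
        out = apply_warp(warp, blob_volume, interpolation="nearest")
        np.testing.assert_array_equal(out.data, blob_volume.data)

    def test_intensity_linearity(self, blob_volume):
        warp = in_span_warp(1.0, seed=6)
        w_x = apply_warp(warp, blob_volume).data
        scaled = VolumeGrid(3.0 * blob_volume.data, blob_volume.affine)
        w_scaled = apply_warp(warp, scaled).data
        np.testing.assert_allclose(w_scaled, 3.0 * w_x, atol=1e-10)

    def test_series_timepoints_processed_independently(self, blob_volume):
        series = SeriesGrid(
            np.repeat(blob_volume.data[..., None], 5, axis=3), blob_volume.affine
        )
        warp = in_span_warp(1.0, seed=7)
        out = apply_warp(warp, series)
        for t in range(1, 5):
            np.testing.assert_array_equal(out.data[..., t], out.data[..., 0])

    def test_registration_improvement(self, blob_volume):
        true = in_span_warp(2.0, seed=8)
        target = pull_back(blob_volume, displacement_field(true))
        warp = estimate_warp(blob_volume, target, SMALL_CONFIG)
        applied = apply_warp(warp, blob_volume)

        def corr(a, b):
            return np.corrcoef(a.ravel(), b.ravel())[0, 1]

        assert corr(applied.data, target.data) > corr(blob_volume.data, target.data)

    def test_grid_mismatch(self, blob_volume):
        warp = in_span_warp(1.0)
        with pytest.raises(ValueError, match="grid"):
            apply_warp(warp, VolumeGrid(np.zeros((8, 8, 8))))


class TestNormalizeSubject:
    def test_identical_subject_keeps_series(self, blob_volume):
        template = build_template([blob_volume], EntropyParams(enabled=False))
        series = SeriesGrid(
            np.repeat(template.volume.data[..., None], 3, axis=3),
            blob_volume.affine,
        )
        warp, warped = normalize_subject(
            [blob_volume], template, series, SMALL_CONFIG, interpolation="nearest"
        )
        np.testing.assert_allclose(warped.data, series.data, atol=1e-6)

    def test_grid_mismatch_before_estimation(self, blob_volume):
        template = build_template([blob_volume])
        bad = VolumeGrid(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="grid"):
            normalize_subject([bad], template, None, SMALL_CONFIG)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        warp = in_span_warp(1.0, seed=9)
        path = warp_to_json(warp, tmp_path / "warp.json")
        back = warp_from_json(path)
        np.testing.assert_allclose(back.coefficients, warp.coefficients)
        np.testing.assert_allclose(back.affine_params, warp.affine_params)
        assert back.basis_counts == warp.basis_counts
        assert back.grid_shape == warp.grid_shape
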