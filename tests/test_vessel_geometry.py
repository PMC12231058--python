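"""Frangi vesselness, orientation estimation, and the ALPS-geometry report."""

import numpy as np
import pytest

from alpsim.io_formats import ROILabelMap, VolumeImage
from alpsim.synthetic_data import generate_vessel_volume
from alpsim.tensor_metrics import TensorField
from alpsim.vessel_geometry import (
    OrientationField,
    alps_assumption_report,
    angular_difference,
    downsample_orientations,
    frangi_vesselness,
)


def _otsu_cut(v):
    from skimage.filters import threshold_otsu

    return threshold_otsu(v[v > 0])


class TestFrangi:
    def test_dark_tube_orientation(self):
        vol, truth = generate_vessel_volume(
            shape=(30, 30, 30), tubes=[((15.0, 15.0, 15.0), (0, 0, 1.0), 2.0)]
        )
        v, field = frangi_vesselness(vol, scales_mm=(1.0, 2.0), polarity="dark")
        m = truth.mask & (v > _otsu_cut(v))
        ang = angular_difference(field, np.array([0, 0, 1.0]))[m]
        assert (ang < 5.0).mean() >= 0.95

    def test_skimage_frangi_agrees_on_response_location(self):
        """Independent cross-check: scikit-image's Frangi filter should light
        up the same voxels as the in-package response."""
        from skimage.filters import frangi as sk_frangi

        vol, truth = generate_vessel_volume(
            shape=(24, 24, 24), tubes=[((12.0, 12.0, 12.0), (0, 1.0, 0), 2.0)]
        )
        v, _ = frangi_vesselness(vol, scales_mm=(1.0, 2.0), polarity="dark")
        ref = sk_frangi(vol.data, sigmas=(1.0, 2.0), black_ridges=True)
        # parameterisations differ in detail, so compare where each filter
        # responds most strongly rather than absolute response values
        k = 200
        ours = set(np.argsort(v.ravel())[-k:])
        theirs = set(np.argsort(ref.ravel())[-k:])
        assert len(ours & theirs) / k > 0.5

    def test_uniform_volume_zero_response(self):
        vol = VolumeImage(np.full((16, 16, 16), 0.7))
        v, field = frangi_vesselness(vol, scales_mm=(1.0,))
        np.testing.assert_allclose(v, 0.0, atol=1e-12)
        assert not field.mask.any()

    def test_blob_suppressed_relative_to_tube(self):
        # matched contrast and radius; compare at the structure centers,
        # where the sphere is isotropic and the tube maximally tubular
        shape = (27, 27, 27)
        grid = np.stack(np.indices(shape, dtype=float), axis=-1)
        center = np.array([13.0, 13.0, 13.0])
        r_sphere = np.linalg.norm(grid - center, axis=-1)
        sphere = VolumeImage(1.0 - np.exp(-((r_sphere / 3.0) ** 4)))
        tube_vol, _ = generate_vessel_volume(
            shape=shape, tubes=[((13.0, 13.0, 13.0), (0, 0, 1.0), 3.0)]
        )
        v_sphere, _ = frangi_vesselness(sphere, scales_mm=(2.0, 3.0))
        v_tube, _ = frangi_vesselness(tube_vol, scales_mm=(2.0, 3.0))
        assert v_sphere[13, 13, 13] < 0.25 * v_tube[13, 13, 13]

    def test_small_scale_clamped_with_warning(self):
        vol = VolumeImage(np.zeros((8, 8, 8)), (2.0, 2.0, 2.0))
        with pytest.warns(UserWarning, match="clamp"):
            frangi_vesselness(vol, scales_mm=(0.1,))


class TestAngularDifference:
    def test_trivial_cases(self):
        shape = (2, 2, 2)
        x = OrientationField.constant([1.0, 0, 0], shape)
        y = OrientationField.constant([0, 1.0, 0], shape)
        diag = OrientationField.constant([1.0, 1.0, 0], shape)
        assert np.allclose(angular_difference(x, x), 0.0)
        assert np.allclose(angular_difference(x, y), 90.0)
        assert np.allclose(angular_difference(diag, np.array([1.0, 0, 0])), 45.0)

    def test_sign_and_joint_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        shape = (3, 3, 3)
        va = rng.standard_normal(shape + (3,))
        vb = rng.standard_normal(shape + (3,))
        va /= np.linalg.norm(va, axis=-1, keepdims=True)
        vb /= np.linalg.norm(vb, axis=-1, keepdims=True)
        mask = np.ones(shape, dtype=bool)
        a = angular_difference(OrientationField(va, mask), OrientationField(vb, mask))
        flip = rng.choice([-1.0, 1.0], size=shape + (1,))
        b = angular_difference(
            OrientationField(va * flip, mask), OrientationField(vb, mask)
        )
        np.testing.assert_allclose(a, b, atol=1e-9)
        R = Rotation.from_euler("xyz", [10, 70, -30], degrees=True).as_matrix()
        c = angular_difference(
            OrientationField(va @ R.T, mask), OrientationField(vb @ R.T, mask)
        )
        np.testing.assert_allclose(a, c, atol=1e-6)
        assert np.all((a >= 0) & (a <= 90))

    def test_empty_intersection_raises(self):
        shape = (2, 2, 2)
        a = OrientationField.constant([1.0, 0, 0], shape)
        b = OrientationField(a.vectors.copy(), np.zeros(shape, dtype=bool))
        with pytest.raises(ValueError):
            angular_difference(a, b)


class TestDownsampling:
    def test_constant_field_recovered_exactly(self):
        f = OrientationField.constant([0.6, 0.8, 0.0], (8, 8, 4))
        g = downsample_orientations(f, 2)
        assert g.vectors.shape == (4, 4, 2, 3)
        dot = np.abs(g.vectors @ np.array([0.6, 0.8, 0.0]))
        np.testing.assert_allclose(dot, 1.0, atol=1e-9)

    def test_sign_mixture_is_stable(self):
        # half the voxels sign-flipped: vector averaging would cancel, the
        # orientation tensor must not
        v = np.tile([0.0, 0.0, 1.0], (4, 4, 4, 1))
        v[::2] *= -1
        f = OrientationField(v, np.ones((4, 4, 4), dtype=bool))
        g = downsample_orientations(f, 2)
        dot = np.abs(g.vectors @ np.array([0.0, 0.0, 1.0]))
        np.testing.assert_allclose(dot, 1.0, atol=1e-9)


def _tensor_field_axis(shape, v1_axis, v2_axis):
    """Axis-aligned anisotropic tensors: lambda = (1.7, 0.5, 0.2) x 1e-3."""
    v1 = np.asarray(v1_axis, dtype=float)
    v2 = np.asarray(v2_axis, dtype=float)
    v3 = np.cross(v1, v2)
    evecs = np.stack([v1, v2, v3], axis=-1)
    D = evecs @ np.diag([1.7e-3, 0.5e-3, 0.2e-3]) @ evecs.T
    return TensorField(
        tensors=np.broadcast_to(D, shape + (3, 3)).copy(),
        evals=np.broadcast_to([1.7e-3, 0.5e-3, 0.2e-3], shape + (3,)).copy(),
        evecs=np.broadcast_to(evecs, shape + (3, 3)).copy(),
        s0=np.ones(shape),
        mask=np.ones(shape, dtype=bool),
        clamped=np.zeros(shape, dtype=bool),
    )


class TestALPSAssumptionReport:
    def _rois(self, shape):
        labels = np.ones(shape, dtype=int)
        return ROILabelMap(labels, {1: "scr"})

    def test_ideal_alps_geometry(self):
        shape = (6, 6, 6)
        vessels = OrientationField.constant([1.0, 0, 0], shape)  # along x
        tensors = _tensor_field_axis(shape, [0, 0, 1.0], [1.0, 0, 0])  # V1 z, V2 x
        table = alps_assumption_report(vessels, tensors, self._rois(shape))
        row = table.iloc[0]
        assert row["vessel_v1_median_deg"] == pytest.approx(90.0, abs=1e-9)
        assert row["vessel_v2_median_deg"] == pytest.approx(0.0, abs=1e-9)
        assert row["vessel_rl_median_deg"] == pytest.approx(0.0, abs=1e-9)
        assert row["vessel_rl_frac_lt10"] == 1.0
        assert row["vessel_v1_frac_gt80"] == 1.0

    def test_tilted_vessels(self):
        shape = (6, 6, 6)
        tilt = np.radians(30.0)
        axis = [np.cos(tilt), np.sin(tilt), 0.0]
        vessels = OrientationField.constant(axis, shape)
        tensors = _tensor_field_axis(shape, [0, 0, 1.0], [1.0, 0, 0])
        table = alps_assumption_report(vessels, tensors, self._rois(shape))
        assert table.iloc[0]["vessel_rl_median_deg"] == pytest.approx(30.0, abs=2.0)

    def test_vessel_fan_fraction(self, rng):
        # vessels fanned uniformly +-30 deg about x in the x-y plane: the
        # fraction within 10 deg of RL should match the planted 1/3
        shape = (12, 12, 12)
        n = int(np.prod(shape))
        ang = rng.uniform(-np.pi / 6, np.pi / 6, n)
        v = np.stack([np.cos(ang), np.sin(ang), np.zeros(n)], axis=-1).reshape(
            shape + (3,)
        )
        vessels = OrientationField(v, np.ones(shape, dtype=bool))
        tensors = _tensor_field_axis(shape, [0, 0, 1.0], [1.0, 0, 0])
        table = alps_assumption_report(vessels, tensors, self._rois(shape))
        assert table.iloc[0]["vessel_rl_frac_lt10"] == pytest.approx(1 / 3, abs=0.1)
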