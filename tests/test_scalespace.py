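"""Scale-space construction, smoothing kernels and detector volumes."""
import math

import numpy as np
import pytest

import hessianblob as hb
from hessianblob.scalespace import InvalidScaleError, ScaleList, smooth


def bessel_i_series(n: int, t: float, terms: int = 60) -> float:
    """Modified Bessel I_n(t) by its power series (independent oracle)."""
    total = 0.0
    for k in range(terms):
        total += (t / 2.0) ** (2 * k + n) / (
            math.factorial(k) * math.factorial(k + n)
        )
    return total


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

class TestKernel:
    def test_zero_scale_is_identity(self):
        assert np.array_equal(hb.discrete_gaussian_kernel(0.0), [1.0])

    @pytest.mark.parametrize("family", ["discrete", "sampled"])
    @pytest.mark.parametrize("t", [0.5, 2.0, 7.3, 40.0])
    def test_symmetric_nonnegative_normalized(self, t, family):
        k = hb.discrete_gaussian_kernel(t, tol=1e-8, family=family)
        assert len(k) % 2 == 1
        assert np.all(k >= 0)
        assert np.allclose(k, k[::-1])
        assert abs(k.sum() - 1.0) < 1e-12

    def test_discrete_center_weight_matches_bessel_series(self):
        # T(0; t) = exp(-t) I_0(t); at t=1 this is ~0.46576
        k = hb.discrete_gaussian_kernel(1.0, tol=1e-12)
        expected = math.exp(-1.0) * bessel_i_series(0, 1.0)
        assert k[len(k) // 2] == pytest.approx(expected, rel=1e-9)
        # a non-central weight too: T(2; 1) = exp(-1) I_2(1)
        assert k[len(k) // 2 + 2] == pytest.approx(
            math.exp(-1.0) * bessel_i_series(2, 1.0), rel=1e-9
        )

    def test_negative_scale_rejected(self):
        with pytest.raises(InvalidScaleError):
            hb.discrete_gaussian_kernel(-1.0)

    def test_tighter_tolerance_widens_support(self):
        loose = hb.discrete_gaussian_kernel(5.0, tol=1e-4)
        tight = hb.discrete_gaussian_kernel(5.0, tol=1e-12)
        assert len(tight) > len(loose)


# ---------------------------------------------------------------------------
# scale list
# ---------------------------------------------------------------------------

class TestScaleList:
    def test_geometric_sampling(self):
        sl = ScaleList.geometric(0.5, 1024.0, 4)
        v = sl.values
        assert v[0] == pytest.approx(0.5)
        assert v[-1] == pytest.approx(1024.0)
        ratios = v[1:] / v[:-1]
        assert np.max(np.abs(ratios / sl.ratio - 1)) < 1e-12
        # power-of-two multiples of t_min land exactly on the grid
        assert np.min(np.abs(v - 8.0)) < 1e-9

    def test_invalid_bounds_rejected(self):
        with pytest.raises(InvalidScaleError):
            ScaleList.geometric(0.0, 4.0, 4)
        with pytest.raises(InvalidScaleError):
            ScaleList.geometric(8.0, 4.0, 4)
        with pytest.raises(InvalidScaleError):
            ScaleList.geometric(0.5, 4.0, 0)

    def test_non_monotone_rejected(self):
        with pytest.raises(InvalidScaleError):
            ScaleList(values=np.array([1.0, 3.0, 2.0]), ratio=2.0)


# ---------------------------------------------------------------------------
# scale-space stack
# ---------------------------------------------------------------------------

class TestScaleSpace:
    def test_constant_image_stays_constant(self):
        img = hb.HeightImage(np.full((32, 32), 3.7), 1.0)
        ss = hb.build_scale_space(img, t_min=0.5, t_max=16.0)
        for layer in ss.layers:
            assert np.allclose(layer, 3.7, rtol=1e-12)

    def test_sum_preserved_and_variation_decreases(self):
        rng = np.random.default_rng(3)
        base = smooth(rng.normal(0, 1, (48, 48)), 2.0)  # smooth random field
        img = hb.HeightImage(base, 1.0)
        ss = hb.build_scale_space(img, t_min=0.5, t_max=16.0)
        total = img.heights.sum()
        tv_prev = np.inf
        for layer in ss.layers:
            assert layer.sum() == pytest.approx(total, rel=1e-9)
            tv = np.abs(np.diff(layer, axis=0)).sum() + np.abs(
                np.diff(layer, axis=1)
            ).sum()
            assert tv <= tv_prev * (1 + 1e-12)
            tv_prev = tv

    def test_impulse_reproduces_kernel(self):
        h = np.zeros((33, 33))
        h[16, 16] = 1.0
        out = smooth(h, 3.0)
        k = hb.discrete_gaussian_kernel(3.0)
        dense = np.outer(k, k)
        half = len(k) // 2
        got = out[16 - half : 16 + half + 1, 16 - half : 16 + half + 1]
        assert np.allclose(got, dense, atol=1e-12)

    def test_gaussian_bump_semigroup_closed_form(self):
        # smoothing a bump of scale t0 at scale t gives a bump of scale
        # t0 + t with center amplitude A t0 / (t0 + t)
        t0, A = 6.0, 2.0
        img, _ = hb.gaussian_blob_image((96, 96), 1.0, [(48.0, 48.0, A, t0)])
        # ~1% slack: the continuum semigroup is an approximation for a
        # bump sampled at t0 = 6 px^2 (discretization correction O(1/t0))
        for t in (2.0, 8.0, 16.0):
            out = smooth(img.heights, t)
            assert out[48, 48] == pytest.approx(A * t0 / (t0 + t), rel=2e-2)

    def test_two_stage_smoothing_equals_one_stage(self):
        rng = np.random.default_rng(11)
        h = smooth(rng.normal(0, 1, (64, 64)), 1.0)
        one = smooth(h, 6.0)
        two = smooth(smooth(h, 2.0), 4.0)
        scale = np.ptp(h)
        interior = (slice(16, -16), slice(16, -16))
        assert np.max(np.abs(one[interior] - two[interior])) < 1e-9 * scale

    def test_t_max_clamped_with_warning(self):
        img = hb.HeightImage(np.zeros((16, 16)), 1.0)
        with pytest.warns(UserWarning, match="clamp"):
            ss = hb.build_scale_space(img, t_min=0.5, t_max=1e6)
        assert ss.scale_list.values[-1] <= 16.0**2

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            hb.HeightImage(np.full((16, 16), np.nan), 1.0)
        with pytest.raises(ValueError):
            hb.build_scale_space(hb.HeightImage(np.zeros((4, 4)), 1.0))
        aniso = hb.HeightImage(np.zeros((16, 16)), 1.0, pixel_size_y=1.5)
        with pytest.raises(ValueError, match="anisotropic"):
            hb.build_scale_space(aniso)


# ---------------------------------------------------------------------------
# detector volumes and curvature
# ---------------------------------------------------------------------------

def _plane_image(shape, a=0.013, b=-0.007, c=1.2):
    R, C = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return hb.HeightImage(a * R + b * C + c, 1.0)


class TestDetectors:
    def test_planar_input_gives_zero_detectors(self):
        img = _plane_image((96, 96))
        ss = hb.build_scale_space(img, t_min=0.5, t_max=16.0)
        vol = hb.detector_volumes(ss)
        # interior = beyond the padding influence radius at the top scale
        # (mirror padding creases a tilted plane at the border)
        half = len(hb.discrete_gaussian_kernel(16.0)) // 2 + 3
        interior = (slice(None), slice(half, -half), slice(half, -half))
        scale = np.ptp(img.heights) ** 2
        assert np.max(np.abs(vol.detH[interior])) < 1e-9 * scale
        assert np.max(np.abs(vol.lap[interior])) < 1e-9 * scale

    def test_bump_center_response_matches_closed_form(self, single_bump_volume):
        # detH(t) at the center of a bump (t0, A) is A^2 t0^2 t^2/(t0+t)^4,
        # maximal at t = t0; the Laplacian detector is negative there
        img, gt, vol = single_bump_volume
        t0, A = 8.0, 3.0
        t = vol.scale_list.values
        resp = vol.detH[:, 64, 64]
        window = (t >= 1.0) & (t <= 64.0)
        pred = A**2 * t0**2 * t**2 / (t0 + t) ** 4
        assert np.allclose(resp[window], pred[window], rtol=4e-2)
        assert t[np.argmax(resp)] == pytest.approx(t0, rel=1e-6)
        assert vol.lap[np.argmax(resp), 64, 64] < 0

    def test_affine_perturbations_leave_detectors_unchanged(
        self, single_bump_volume
    ):
        img, _, vol = single_bump_volume
        dyn = np.ptp(img.heights)
        interior = (slice(None, 20), slice(30, -30), slice(30, -30))
        for kind in ("offset", "tilt"):
            pert = hb.perturb(img, kind, 2.0)
            vol2 = hb.detector_volumes(
                hb.build_scale_space(pert, t_max=vol.scale_list.values[-1])
            )
            assert np.max(
                np.abs(vol2.detH[interior] - vol.detH[interior])
            ) < 1e-9 * dyn**2
            assert np.max(
                np.abs(vol2.lap[interior] - vol.lap[interior])
            ) < 1e-9 * dyn**2

    def test_quarter_rotation_commutes_with_detectors(self):
        rng = np.random.default_rng(5)
        h = smooth(rng.normal(0, 1, (48, 48)), 2.0)
        vol = hb.detector_volumes(
            hb.build_scale_space(hb.HeightImage(h, 1.0), t_max=16.0)
        )
        vol_rot = hb.detector_volumes(
            hb.build_scale_space(hb.HeightImage(np.rot90(h), 1.0), t_max=16.0)
        )
        for k in range(vol.detH.shape[0]):
            assert np.allclose(
                vol_rot.detH[k], np.rot90(vol.detH[k]), rtol=1e-9, atol=1e-12
            )
            assert np.allclose(
                vol_rot.lap[k], np.rot90(vol.lap[k]), rtol=1e-9, atol=1e-12
            )


class TestGaussianCurvature:
    def test_planar_layer_has_zero_curvature(self):
        img = _plane_image((32, 32))
        K = hb.gaussian_curvature(hb.derivative_fields(img.heights))
        assert np.max(np.abs(K)) < 1e-12

    def test_sign_matches_hessian_determinant(self):
        rng = np.random.default_rng(8)
        layer = smooth(rng.normal(0, 1, (40, 40)), 1.5)
        f = hb.derivative_fields(layer)
        K = hb.gaussian_curvature(f)
        det = f.Lxx * f.Lyy - f.Lxy**2
        assert np.array_equal(np.sign(K), np.sign(det))

    def test_radial_gaussian_sign_change_at_sqrt_s(self):
        # layer exp(-r^2/2s): convex (K>0) for r < sqrt(s), saddle beyond
        s = 16.0
        R, C = np.mgrid[0:64, 0:64].astype(float)
        r2 = (R - 32.0) ** 2 + (C - 32.0) ** 2
        layer = 3.0 * np.exp(-r2 / (2 * s))
        K = hb.gaussian_curvature(hb.derivative_fields(layer))
        r = np.sqrt(r2)
        assert np.all(K[r < np.sqrt(s) - 0.8] > 0)
        band = (r > np.sqrt(s) + 0.8) & (r < 3 * np.sqrt(s))
        assert np.all(K[band] < 0)
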