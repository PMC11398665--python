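"""Sinogram acquisition, smoothing, FBP and recentering."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from strtomo.layout import GaussianSubunit, SubunitLayout
from strtomo.model import GanglionModel
from strtomo.stimuli import RickerStripeSpec, render_ricker_stripe
from strtomo.tomography import (
    Reconstruction,
    Sinogram,
    SmoothingParams,
    TomographyPlan,
    acquire_sinogram,
    fbp_reconstruct,
    recenter_sinogram,
    smooth_sinogram,
)


def single_subunit_model(cx, cy, smaj, smin, theta=0.0):
    return GanglionModel([SubunitLayout([GaussianSubunit(cx, cy, smaj, smin, theta)])])


class TestAcquire:
    def test_shape_and_rate_oracle(self):
        """Rate-mode sinogram equals per-combination model_rate calls."""
        m = single_subunit_model(18.0, 23.0, 2.5, 1.5, 0.4)
        plan = TomographyPlan()
        stripe = RickerStripeSpec()
        sino = acquire_sinogram(m, plan, stripe)
        assert sino.responses.shape == (36, 60)
        for i in [0, 17, 35]:
            for j in [0, 29, 59]:
                stim = render_ricker_stripe(
                    RickerStripeSpec(
                        w=stripe.w, s=stripe.s,
                        angle=float(plan.angles[i]),
                        offset=float(plan.positions[j]),
                    ),
                    40,
                )
                assert sino.responses[i, j] == pytest.approx(m.rate(stim), rel=1e-12)

    def test_circular_subunit_rows_identical(self):
        # rotational symmetry holds up to pixel-grid discretization of
        # the Gaussian filter and the clipped stripe profile (~3%)
        m = single_subunit_model(20.0, 20.0, 2.0, 2.0)
        sino = acquire_sinogram(m, TomographyPlan(), RickerStripeSpec())
        dev = np.abs(sino.responses - sino.responses[:1]).max()
        assert dev < 0.05 * sino.responses.max()

    def test_elliptical_center_response_angle_dependent(self):
        """A strong surround can silence an elongated subunit when the
        stripe crosses its minor axis."""
        m = single_subunit_model(20.0, 20.0, 4.0, 1.0, 0.0)  # major axis = x
        sino = acquire_sinogram(m, TomographyPlan(), RickerStripeSpec(w=5.0, s=5.0))
        center_col = sino.responses[:, 29:31].max(axis=1)
        horizontal = center_col[0]   # stripe parallel to major axis
        vertical = center_col[18]    # stripe across the major axis
        assert horizontal > 5 * max(vertical, 1e-9)

    def test_spikes_need_rng_and_average_repeats(self):
        m = single_subunit_model(20.0, 20.0, 2.0, 2.0)
        plan = TomographyPlan(response_mode="spikes", repeats=8)
        with pytest.raises(ValueError):
            acquire_sinogram(m, plan, RickerStripeSpec())
        sino = acquire_sinogram(
            m, plan, RickerStripeSpec(), rng=np.random.default_rng(0)
        )
        # averaged counts are multiples of 1/repeats
        assert np.allclose((sino.responses * 8) % 1, 0.0)

    def test_rotation_covariance(self):
        """Rotating the layout by one 5-degree angle step shifts the
        sinogram rows cyclically (with position flip across the seam)."""
        m1 = single_subunit_model(26.0, 20.0, 2.0, 1.4, 0.3)
        step = math.radians(5.0)
        c, s = math.cos(step), math.sin(step)
        dx, dy = 26.0 - 20.0, 0.0
        su = GaussianSubunit(
            20.0 + c * dx - s * dy, 20.0 + s * dx + c * dy, 2.0, 1.4,
            (0.3 + step) % math.pi,
        )
        m2 = GanglionModel([SubunitLayout([su])])
        plan, stripe = TomographyPlan(), RickerStripeSpec()
        s1 = acquire_sinogram(m1, plan, stripe).responses
        s2 = acquire_sinogram(m2, plan, stripe).responses
        expected = np.vstack([s1[-1:, ::-1], s1[:-1]])  # roll + seam flip
        assert np.abs(s2 - expected).max() < 0.05 * s1.max()


class TestSmoothing:
    def test_zero_sigma_identity(self):
        rng = np.random.default_rng(0)
        sino = Sinogram(rng.random((36, 60)), np.arange(0, 180, 5),
                        (np.arange(60) - 29.5) * 2 / 3)
        out = smooth_sinogram(sino, SmoothingParams(0.0, 0.0))
        assert np.array_equal(out.responses, sino.responses)

    def test_constant_preserved(self):
        sino = Sinogram(np.full((36, 60), 3.7), np.arange(0, 180, 5),
                        (np.arange(60) - 29.5) * 2 / 3)
        out = smooth_sinogram(sino, SmoothingParams(2.5, 5.0))
        assert np.allclose(out.responses, 3.7)

    def test_interior_impulse_gives_gaussian_kernel(self):
        resp = np.zeros((36, 60))
        resp[18, 30] = 1.0
        sino = Sinogram(resp, np.arange(0, 180, 5), (np.arange(60) - 29.5) * 2 / 3)
        out = smooth_sinogram(sino, SmoothingParams(2.5, 5.0), 40.0)
        # sigma_pos: 2.5% * 40 px = 1 px = 1.5 columns; sigma_ang: 1 row
        expected = np.zeros((36, 60))
        expected[18, 30] = 1.0
        expected = gaussian_filter(expected, sigma=(1.0, 1.5), mode="constant")
        assert np.allclose(out.responses, expected, atol=1e-12)

    def test_angle_seam_wraps_with_position_flip(self):
        resp = np.zeros((36, 60))
        resp[0, 10] = 1.0  # first angle row, off-center position
        sino = Sinogram(resp, np.arange(0, 180, 5), (np.arange(60) - 29.5) * 2 / 3)
        out = smooth_sinogram(sino, SmoothingParams(0.0, 5.0), 40.0)
        # mass leaking past angle 0 reappears at angle 175 at the
        # mirrored position 49
        assert out.responses[35, 49] > 0
        assert out.responses[35, 49] == pytest.approx(out.responses[1, 10], rel=1e-9)


class TestFBP:
    def test_zero_in_zero_out_and_single_angle_error(self):
        sino = Sinogram(np.zeros((36, 60)), np.arange(0, 180, 5),
                        (np.arange(60) - 29.5) * 2 / 3)
        rec = fbp_reconstruct(sino)
        assert np.allclose(rec.values, 0.0)
        assert rec.values.shape == (60, 60)
        with pytest.raises(ValueError):
            fbp_reconstruct(Sinogram(np.zeros((1, 60)), [0.0],
                                     (np.arange(60) - 29.5) * 2 / 3))

    def test_linearity(self):
        rng = np.random.default_rng(1)
        ang = np.arange(0, 180, 5)
        pos = (np.arange(60) - 29.5) * 2 / 3
        s1 = Sinogram(rng.random((36, 60)), ang, pos)
        s2 = Sinogram(rng.random((36, 60)), ang, pos)
        a, b = 2.5, -1.25
        combo = Sinogram(a * s1.responses + b * s2.responses, ang, pos)
        lhs = fbp_reconstruct(combo).values
        rhs = a * fbp_reconstruct(s1).values + b * fbp_reconstruct(s2).values
        assert np.abs(lhs - rhs).max() < 1e-9 * max(1.0, np.abs(rhs).max())

    def test_point_mass_localisation(self):
        """Sinogram of an analytic Radon point mass reconstructs with its
        global maximum within one pixel of the point."""
        ang = np.arange(0, 180, 5)
        pos = (np.arange(61) - 30.0) * 2 / 3
        x0, y0 = 4.0, -6.5  # offsets from the arena center
        resp = np.zeros((len(ang), len(pos)))
        for i, a in enumerate(np.radians(ang)):
            t0 = -x0 * math.sin(a) + y0 * math.cos(a)
            # triangular (linear-interp) point spread on the grid
            resp[i] = np.maximum(0.0, 1.0 - np.abs(pos - t0) / (2 / 3))
        rec = fbp_reconstruct(Sinogram(resp, ang, pos))
        r, c = np.unravel_index(np.argmax(rec.values), rec.values.shape)
        xx, yy = rec.pixel_coordinates()
        assert math.hypot(xx[r, c] - (20 + x0), yy[r, c] - (20 + y0)) <= 1.0

    def test_matches_skimage_iradon_on_smooth_phantoms(self):
        """FBP agrees with the established inverse-Radon reference to
        well under 2% relative RMS on the interior disk."""
        skimage = pytest.importorskip("skimage.transform")
        rng = np.random.default_rng(2)
        n = 61
        yy, xx = np.mgrid[0:n, 0:n]
        support = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= (n // 2 - 2) ** 2
        theta = np.arange(0.0, 180.0, 5.0)
        for _ in range(3):
            phantom = gaussian_filter(rng.random((n, n)), 4.0) * support
            sino_ref = skimage.radon(phantom, theta=theta)
            ref = skimage.iradon(sino_ref, theta=theta, filter_name="ramp",
                                 interpolation="linear", circle=True)
            mine = fbp_reconstruct(
                Sinogram(sino_ref.T, theta, (np.arange(n) - (n - 1) / 2.0)),
                arena_size=n,
            ).values.T
            inner = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= (0.4 * n) ** 2
            rms = np.sqrt(np.mean((mine[inner] - ref[inner]) ** 2))
            assert rms <= 0.02 * np.sqrt(np.mean(ref[inner] ** 2))


class TestRecenter:
    def test_requires_cyclic(self):
        sino = acquire_sinogram(
            single_subunit_model(20, 20, 2, 2), TomographyPlan(), RickerStripeSpec()
        )
        with pytest.raises(ValueError):
            recenter_sinogram(sino, (20.0, 20.0))

    def test_identity_at_arena_center_and_multiset_preserved(self):
        # synthetic cyclic sinogram on a grid whose central column is
        # offset zero: recentering on the arena center is the identity
        rng = np.random.default_rng(0)
        n = 61
        sino = Sinogram(
            rng.random((36, n)), np.arange(0, 180, 5),
            (np.arange(n) - n // 2) * 2 / 3, cyclic=True,
        )
        out = recenter_sinogram(sino, (20.0, 20.0))
        assert np.array_equal(out.responses, sino.responses)
        # row multisets preserved under any recentering
        off = recenter_sinogram(sino, (26.0, 14.0))
        for i in range(36):
            assert np.allclose(np.sort(off.responses[i]), np.sort(sino.responses[i]))

    def test_off_center_rf_realigns_row_maxima(self):
        """Periodic stripes on an off-center cell: after recentering,
        the row-wise response maxima cluster around the central column."""
        su = GaussianSubunit(27.0, 15.0, 2.0, 2.0, 0.0)
        m = GanglionModel([SubunitLayout([su])])
        plan = TomographyPlan(n_positions=60, position_step=2 / 3)
        sino = acquire_sinogram(m, plan, RickerStripeSpec(stripe_spacing=40.0))
        out = recenter_sinogram(sino, (27.0, 15.0))
        argmaxes = out.responses.argmax(axis=1)
        assert np.all(np.abs(argmaxes - 30) <= 2)


class TestReconstructionType:
    def test_rejects_non_square_and_non_finite(self):
        with pytest.raises(ValueError):
            Reconstruction(np.zeros((3, 4)), 1.0)
        bad = np.zeros((4, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            Reconstruction(bad, 1.0)
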