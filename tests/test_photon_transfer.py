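"""Photon transfer analysis: PTC construction, robust fit, flux conversion."""

import numpy as np
import pytest

from mpmqc.core import FrameSequence
from mpmqc.fixtures import SceneSpec, DetectorSpec, gen_poisson_movie
from mpmqc.photon_transfer import (
    PhotonTransferCurve, paired_moments, build_ptc, fit_sensitivity,
    cov_image, to_photon_flux, roi_photon_rate, weighted_roi_rate,
)


def make_movie(q=96.9, I0=100.0, lam_max=10.0, n_frames=200, size=64,
               seed=0, read_noise=2.0, **kwargs):
    rng = np.random.default_rng(1000 + seed)
    bm = rng.uniform(0.5, lam_max, (size, size))
    scene = SceneSpec(size, size, brightness_map=bm, **kwargs)
    det = DetectorSpec(q=q, I0=I0, read_noise_sd=read_noise)
    return gen_poisson_movie(scene, det, n_frames, seed=seed, clip=False), bm


class TestPairedMoments:
    def test_constant_movie(self):
        seq = FrameSequence(np.full((5, 10, 10), 7.0))
        M, D = paired_moments(seq, exclude_margin=0)
        assert np.all(M == 7.0) and np.all(D == 0.0)

    def test_single_pair_arithmetic(self):
        seq = FrameSequence(np.stack([np.full((3, 3), 10.0),
                                      np.full((3, 3), 14.0)]))
        M, D = paired_moments(seq, exclude_margin=0)
        assert np.all(M == 12.0) and np.all(D == 8.0)

    def test_margin_excluded(self):
        seq = FrameSequence(np.zeros((3, 256, 256)))
        M, _ = paired_moments(seq, exclude_margin=4)
        assert M.shape == (2, 248, 248)

    def test_rounding_is_half_up(self):
        seq = FrameSequence(np.stack([np.full((1, 1), 10.0),
                                      np.full((1, 1), 11.0)]))
        M, _ = paired_moments(seq, exclude_margin=0)
        assert M[0, 0, 0] == 11.0

    def test_errors(self):
        with pytest.raises(ValueError, match="2 frames"):
            paired_moments(FrameSequence(np.zeros((1, 4, 4)).reshape(1, 4, 4)
                                         + np.zeros((1, 4, 4))))
        with pytest.raises(ValueError, match="entire image"):
            paired_moments(FrameSequence(np.zeros((3, 8, 8))), exclude_margin=4)


class TestBuildPTC:
    def test_direct_enumeration(self):
        M = np.array([5.0, 5.0, 7.0])
        D = np.array([2.0, 4.0, 6.0])
        ptc = build_ptc(M, D)
        np.testing.assert_array_equal(ptc.I, [5.0, 7.0])
        np.testing.assert_array_equal(ptc.C, [2, 1])
        np.testing.assert_array_equal(ptc.V, [3.0, 6.0])

    def test_mass_conservation(self):
        mov, _ = make_movie(n_frames=20, size=40)
        M, D = paired_moments(mov, exclude_margin=4)
        ptc = build_ptc(M, D)
        assert ptc.n_samples == 19 * 32 * 32

    def test_slope_matches_generator(self):
        mov, _ = make_movie(q=50.0, I0=0.0, n_frames=300, size=64,
                            read_noise=0.0)
        M, D = paired_moments(mov, exclude_margin=0)
        ptc = build_ptc(M, D)
        # count-weighted least squares, independent of the Huber fit path
        w = ptc.C >= 50
        slope = np.polyfit(ptc.I[w], ptc.V[w], 1, w=np.sqrt(ptc.C[w]))[0]
        assert slope == pytest.approx(50.0, rel=0.02)

    def test_empty_refused(self):
        with pytest.raises(ValueError, match="empty"):
            build_ptc(np.array([]), np.array([]))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PhotonTransferCurve(I=[2.0, 1.0], C=[1, 1], V=[0.0, 0.0])


class TestFitSensitivity:
    def test_exact_line(self):
        I = np.arange(11.0, 101.0)
        ptc = PhotonTransferCurve(I=I, C=np.full(len(I), 200),
                                  V=2.0 * (I - 10.0))
        fit = fit_sensitivity(ptc)
        assert fit.q == pytest.approx(2.0, abs=1e-8)
        assert fit.I0 == pytest.approx(10.0, abs=1e-6)

    def test_recovers_generator_parameters(self):
        mov, _ = make_movie(q=96.9, I0=100.0, n_frames=500, size=128)
        M, D = paired_moments(mov, exclude_margin=4)
        fit = fit_sensitivity(build_ptc(M, D))
        assert fit.q == pytest.approx(96.9, rel=0.03)
        assert fit.I0 == pytest.approx(100.0, abs=2.0)

    def test_robust_to_inflated_top_levels(self):
        """Activity-like variance inflation shifts the Huber fit < 5%."""
        I = np.arange(20.0, 220.0)
        V = 3.0 * (I - 15.0)
        C = np.round(1e5 * np.exp(-(I - 20) / 40)).astype(int) + 100
        clean = fit_sensitivity(PhotonTransferCurve(I=I, C=C, V=V))
        V2 = V.copy()
        V2[-10:] *= 10.0  # top levels inflated by dynamic signals
        dirty = fit_sensitivity(PhotonTransferCurve(I=I, C=C, V=V2))
        assert abs(dirty.q / clean.q - 1) < 0.05
        # ordinary least squares must shift more than the robust fit
        w = C.astype(float)

        def wols(Vv):
            A = np.vstack([I, np.ones_like(I)]).T * np.sqrt(w)[:, None]
            coef, *_ = np.linalg.lstsq(A, Vv * np.sqrt(w), rcond=None)
            return coef[0]

        ols_shift = abs(wols(V2) / wols(V) - 1)
        assert ols_shift > abs(dirty.q / clean.q - 1)

    def test_degenerate_single_level_refused(self):
        ptc = build_ptc(np.full(500, 5.0), np.full(500, 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            fit_sensitivity(ptc)

    def test_negative_slope_flagged_not_raised(self):
        I = np.arange(10.0, 60.0)
        ptc = PhotonTransferCurve(I=I, C=np.full(len(I), 200),
                                  V=100.0 - 1.5 * (I - 10.0))
        fit = fit_sensitivity(ptc)
        assert not fit.valid and fit.q <= 0


class TestCovImage:
    def test_pure_poisson_median_near_unity(self):
        mov, _ = make_movie(q=40.0, I0=50.0, n_frames=500, size=64, seed=5)
        M, D = paired_moments(mov, exclude_margin=4)
        fit = fit_sensitivity(build_ptc(M, D))
        cov = cov_image(mov, fit, exclude_margin=4)
        assert 0.95 <= np.nanmedian(cov) <= 1.05

    def test_activity_region_elevated(self):
        # frame-to-frame rate fluctuations add variance beyond shot noise;
        # paired differences cancel only signals slower than the frame rate
        size, n_frames = 48, 400
        mask = np.zeros((size, size), bool)
        mask[10:20, 10:20] = True
        rng = np.random.default_rng(9)
        trace = rng.uniform(0.5, 2.0, n_frames)
        mov, _ = make_movie(q=50.0, I0=20.0, size=size, n_frames=n_frames,
                            seed=6, activity_traces=[(mask, trace)])
        M, D = paired_moments(mov, exclude_margin=0)
        fit = fit_sensitivity(build_ptc(M, D))
        cov = cov_image(mov, fit)
        assert np.nanmedian(cov[mask]) > 1.1 * np.nanmedian(cov[~mask])

    def test_low_gain_columns_depressed(self):
        """Scan-speed compensation bands show ratios < 1."""
        size = 48
        gain_profile = np.ones(size)
        gain_profile[:6] = 0.5
        gain_profile[-6:] = 0.5
        mov, _ = make_movie(q=60.0, I0=30.0, size=size, n_frames=400, seed=7,
                            margin_gain_profile=gain_profile)
        M, D = paired_moments(mov, exclude_margin=0)
        fit = fit_sensitivity(build_ptc(M, D))
        cov = cov_image(mov, fit)
        edge = np.nanmedian(cov[:, :6])
        center = np.nanmedian(cov[:, 10:-10])
        assert edge < 0.8 * center

    def test_invalid_fit_refused(self):
        mov, _ = make_movie(n_frames=10, size=16)
        from mpmqc.photon_transfer import SensitivityFit
        bad = SensitivityFit(q=-1.0, I0=np.nan, n_levels_used=0,
                             robust_loss_scale=0.0, valid=False)
        with pytest.raises(ValueError, match="invalid"):
            cov_image(mov, bad)


class TestPhotonFlux:
    def make_fit(self, q=96.9, I0=109.0):
        from mpmqc.photon_transfer import SensitivityFit
        return SensitivityFit(q=q, I0=I0, n_levels_used=10,
                              robust_loss_scale=1.0)

    def test_offset_maps_to_zero(self):
        seq = FrameSequence(np.full((2, 4, 4), 109.0))
        flux = to_photon_flux(seq, self.make_fit())
        assert np.all(flux.data == 0.0)

    def test_worked_value_three_photons(self):
        # grayscale 400 with q=96.9, I0~109 -> ~3 photons/px/frame
        seq = FrameSequence(np.full((2, 4, 4), 400.0))
        flux = to_photon_flux(seq, self.make_fit())
        assert flux.data[0, 0, 0] == pytest.approx(3.0, abs=0.01)

    def test_round_trip_identity(self):
        fit = self.make_fit(q=50.0, I0=20.0)
        raw = np.arange(24, dtype=float).reshape(2, 3, 4) * 10 + 20
        flux = to_photon_flux(FrameSequence(raw), fit)
        np.testing.assert_allclose(flux.data * fit.q + fit.I0, raw)

    def test_physical_units_require_metadata(self):
        seq = FrameSequence(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError, match="metadata"):
            to_photon_flux(seq, self.make_fit(), units="per_um2_s")

    def test_per_um2_s_scaling(self):
        seq = FrameSequence(np.full((2, 4, 4), 400.0), dx=0.5, dy=0.5, dt=0.125)
        flux = to_photon_flux(seq, self.make_fit(), units="per_um2_s")
        assert flux.data[0, 0, 0] == pytest.approx(3.0 / (0.5 * 0.5 * 0.125),
                                                   abs=0.1)

    def test_negative_values_retained(self):
        seq = FrameSequence(np.full((2, 4, 4), 100.0))
        flux = to_photon_flux(seq, self.make_fit())  # below I0=109
        assert np.all(flux.data < 0)


class TestROIRates:
    def uniform_flux(self, value=3.0, shape=(10, 8, 8), dt=0.125):
        from mpmqc.photon_transfer import PhotonFluxMovie
        return PhotonFluxMovie(np.full(shape, value),
                               units_tag="per_pixel_frame", dt=dt)

    def test_uniform_rate_arithmetic(self):
        flux = self.uniform_flux()
        roi = np.zeros((8, 8), bool)
        roi.flat[:20] = True
        tr = roi_photon_rate(flux, roi)
        np.testing.assert_allclose(tr.trace, 3.0 * 20 / 0.125)  # 480 photons/s

    def test_rate_inverse_in_dt(self):
        flux = self.uniform_flux()
        roi = np.ones((8, 8), bool)
        a = roi_photon_rate(flux, roi, dt=0.125)
        b = roi_photon_rate(flux, roi, dt=0.25)
        np.testing.assert_allclose(a.trace, 2 * b.trace)

    def test_empty_roi_refused(self):
        with pytest.raises(ValueError, match="empty"):
            roi_photon_rate(self.uniform_flux(), np.zeros((8, 8), bool))

    def test_uniform_weights_gamma_one(self):
        flux = self.uniform_flux()
        roi = np.zeros((8, 8), bool)
        roi.flat[:20] = True
        tr = weighted_roi_rate(flux, roi, np.ones(20))
        assert tr.gamma == pytest.approx(1.0)
        np.testing.assert_allclose(tr.trace,
                                   roi_photon_rate(flux, roi).trace)

    def test_uniform_image_optimal_equals_simple(self):
        flux = self.uniform_flux(value=5.0)
        roi = np.zeros((8, 8), bool)
        roi.flat[:16] = True
        rng = np.random.default_rng(0)
        h = rng.uniform(0.5, 2.0, 16)
        opt = weighted_roi_rate(flux, roi, h, normalization="optimal")
        simple = weighted_roi_rate(flux, roi, h, normalization="simple")
        assert opt.gamma == pytest.approx(simple.gamma)

    def test_gamma_matches_hand_computation(self):
        from mpmqc.photon_transfer import PhotonFluxMovie
        data = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (3, 1, 1))
        flux = PhotonFluxMovie(data, units_tag="per_pixel_frame", dt=1.0)
        roi = np.ones((2, 2), bool)
        h = np.array([1.0, 0.5, 2.0, 1.0])
        xbar = data[0].ravel()
        simple = weighted_roi_rate(flux, roi, h, normalization="simple")
        opt = weighted_roi_rate(flux, roi, h, normalization="optimal")
        assert simple.gamma == pytest.approx(h.sum() / (h**2).sum())
        assert opt.gamma == pytest.approx(
            (h * xbar).sum() / (h**2 * xbar).sum())

    def test_normalization_ordering_follows_weight_brightness_correlation(self):
        """gamma_simple >= gamma_optimal iff weights correlate with brightness.

        Direct consequence of the closed forms: the pairwise decomposition
        of gamma_opt - gamma_simple has the sign of -(h_i - h_j)(X_i - X_j).
        On a uniform image the two normalizations coincide.
        """
        from mpmqc.photon_transfer import PhotonFluxMovie
        data = np.tile(np.linspace(1.0, 10.0, 16).reshape(4, 4), (5, 1, 1))
        flux = PhotonFluxMovie(data, units_tag="per_pixel_frame", dt=0.1)
        roi = np.ones((4, 4), bool)
        h_pos = data[0].ravel()           # brightness-proportional weights
        h_neg = 1.0 / data[0].ravel()     # anti-correlated weights
        for h, cmp in ((h_pos, np.greater_equal), (h_neg, np.less_equal)):
            opt = weighted_roi_rate(flux, roi, h, normalization="optimal")
            simple = weighted_roi_rate(flux, roi, h, normalization="simple")
            assert cmp(simple.gamma, opt.gamma)
            assert cmp(simple.trace.mean(), opt.trace.mean())

    def test_all_zero_weights_refused(self):
        with pytest.raises(ValueError, match="not all zero"):
            weighted_roi_rate(self.uniform_flux(), np.ones((8, 8), bool),
                              np.zeros(64))
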