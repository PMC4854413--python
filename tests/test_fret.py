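"""Leading-edge FRET pipeline: wavelets, segmentation, ROIs, ratios."""

import numpy as np
import pytest
from scipy import ndimage

from rholoop.fret import (
    CellMask,
    ChannelStack,
    CrescentROI,
    FretConfig,
    FretError,
    atrous_bandpass,
    atrous_decompose,
    fourier_translate,
    leading_edge_ratio,
    quantify_stack,
    register_channels,
    ring_and_crescents,
    segment_cell,
)
from rholoop.synth import SyntheticCellParams, gen_fret_stack


def _disc(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestAtrousBandpass:
    def test_constant_image_gives_zero_details(self):
        out = atrous_bandpass(np.full((300, 300), 1234.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 4000, (280, 290))
        details, residual = atrous_decompose(img, 8)
        assert np.allclose(np.sum(details, axis=0) + residual, img, atol=1e-8)

    def test_impulse_matches_direct_convolution_oracle(self):
        # band 2..3 of an impulse == smoothing at scale 1 minus cumulative
        # smoothing through scale 3, computed with explicit 2-D kernels
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        k = np.array([1.0, 2.0, 1.0]) / 4.0

        def kernel2d(dilation):
            k1 = np.zeros(2 * dilation + 1)
            k1[[0, dilation, -1]] = k
            return np.outer(k1, k1)

        c = img
        smooths = []
        for scale in (1, 2, 3):
            c = ndimage.convolve(c, kernel2d(2 ** (scale - 1)), mode="mirror")
            smooths.append(c)
        expected = smooths[0] - smooths[2]
        assert np.allclose(atrous_bandpass(img, (2, 3)), expected, atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(FretError, match="smaller"):
            atrous_bandpass(np.zeros((64, 64)), (2, 8))


class TestRegistration:
    def test_identical_channels_give_zero_shift(self):
        rng = np.random.default_rng(2)
        frame = ndimage.gaussian_filter(rng.uniform(0, 1000, (128, 128)), 3)
        stack = ChannelStack(*(frame[None].copy() for _ in range(3)))
        _, shifts = register_channels(stack)
        assert np.allclose(shifts, 0.0)

    def test_known_shift_recovered_to_a_hundredth_pixel(self):
        p = SyntheticCellParams(
            ratio_front=1.5, ratio_back=1.5, noise=1.0, n_frames=1,
            channel_shift=(3.25, -1.5), background=500.0, seed=4,
        )
        stack, _ = gen_fret_stack(p)
        _, shifts = register_channels(stack)
        assert np.allclose(shifts, [-3.25, 1.5], atol=0.01)

    def test_constant_channel_warns_and_returns_zero_shift(self):
        stack = ChannelStack(
            np.full((1, 64, 64), 7.0),
            np.full((1, 64, 64), 7.0),
            np.random.default_rng(0).uniform(0, 10, (1, 64, 64)),
        )
        with pytest.warns(UserWarning, match="constant"):
            _, shifts = register_channels(stack)
        assert np.allclose(shifts, 0.0)

    def test_pure_noise_channels_flag_low_confidence(self):
        rng = np.random.default_rng(3)
        stack = ChannelStack(
            rng.normal(100, 10, (1, 64, 64)),
            rng.normal(100, 10, (1, 64, 64)),
            rng.normal(100, 10, (1, 64, 64)),
        )
        with pytest.warns(UserWarning, match="low-confidence"):
            register_channels(stack)


class TestSegmentCell:
    def test_keeps_only_the_largest_object(self):
        img = np.zeros((100, 100))
        big = _disc(img.shape, (40, 40), 13)     # ~500 px
        small = _disc(img.shape, (80, 80), 5)    # ~80 px
        img[big] = 5000.0
        img[small] = 5000.0
        mask = segment_cell(img).mask
        assert (mask & big).sum() == big.sum()
        assert not (mask & small).any()

    def test_all_below_threshold_raises(self):
        with pytest.raises(FretError, match="threshold"):
            segment_cell(np.full((50, 50), 1999.0))

    def test_diagonal_touching_pixels_merge(self):
        img = np.zeros((20, 20))
        img[5, 5] = img[6, 6] = img[7, 7] = 5000.0
        img[15, 15] = img[15, 16] = 5000.0
        mask = segment_cell(img).mask
        assert mask.sum() == 3  # the diagonal chain is one 8-connected object


class TestRingAndCrescents:
    def test_disc_gives_annulus_of_requested_width(self):
        mask = _disc((260, 260), (130, 130), 100)
        roi = ring_and_crescents(CellMask(mask, 0), width=40, front_hint=1)
        assert roi.ring.sum() == pytest.approx(
            np.pi * (100 ** 2 - 60 ** 2), rel=0.02
        )
        assert not (roi.ring & ~mask).any()  # ring subset of the mask
        dist = ndimage.distance_transform_edt(mask)
        assert dist[roi.ring].max() <= 41.0

    def test_disc_crescents_have_equal_area(self):
        mask = _disc((260, 260), (130, 130), 100)
        roi = ring_and_crescents(CellMask(mask, 0), width=40, front_hint=1)
        assert roi.front.sum() == pytest.approx(roi.back.sum(), rel=0.02)
        assert (roi.front & ~roi.ring).sum() == 0
        assert roi.front.sum() <= roi.ring.sum()

    def test_thin_mask_erodes_to_nothing(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[20:90, 20:90] = True  # 70-px square < 2 * 40
        with pytest.raises(FretError, match="thinner"):
            ring_and_crescents(CellMask(mask, 0), width=40, front_hint=0)

    def test_horizontal_ellipse_quarters_along_x(self):
        yy, xx = np.mgrid[0:240, 0:300]
        mask = ((xx - 150) / 130) ** 2 + ((yy - 120) / 90) ** 2 <= 1
        roi = ring_and_crescents(CellMask(mask, 0), width=30, front_hint=1)
        assert roi.long_axis == 1
        # the high-end crescent lives at large x
        assert np.flatnonzero(roi.front.any(axis=0)).min() > 150

    def test_front_tracked_by_overlap_on_later_frames(self):
        p = SyntheticCellParams(n_frames=3, noise=0.0)
        stack, truth = gen_fret_stack(p)
        tc, masks, _ = quantify_stack(
            stack, FretConfig(front_hint=truth.front_hint, register=False)
        )
        for roi, center in zip(tc.rois, truth.centers):
            cols = np.flatnonzero(roi.front.any(axis=0))
            assert cols.min() > center[0]  # front stays on the leading side


class TestLeadingEdgeRatio:
    @staticmethod
    def _uniform_stack(ratio=2.0, level=1000.0, shape=(320, 320)):
        p = SyntheticCellParams(
            ratio_front=ratio, ratio_back=ratio, donor_level=level,
            noise=0.0, n_frames=2, shape=shape,
        )
        return gen_fret_stack(p)

    def test_uniform_field_is_blur_invariant(self):
        stack, truth = self._uniform_stack()
        tc, _, _ = quantify_stack(stack, FretConfig(front_hint=truth.front_hint,
                                                    register=False))
        assert tc.summary == pytest.approx(2.0, abs=1e-6)
        assert np.allclose(tc.back_mean, 2.0, atol=1e-6)

    def test_invariant_to_common_rescaling(self):
        stack, truth = gen_fret_stack(
            SyntheticCellParams(noise=0.0, n_frames=1)
        )
        cfg = FretConfig(front_hint=truth.front_hint, register=False)
        tc1, _, _ = quantify_stack(stack, cfg)
        scaled = ChannelStack(
            stack.donor_donor * 3.0, stack.fret * 3.0,
            stack.acceptor_direct,
        )
        tc2, _, _ = quantify_stack(scaled, cfg)
        assert tc2.summary == pytest.approx(tc1.summary, abs=1e-12)

    def test_front_and_back_ratios_recovered(self):
        p = SyntheticCellParams(ratio_front=1.8, ratio_back=1.1, noise=0.0,
                                n_frames=2)
        stack, truth = gen_fret_stack(p)
        tc, _, _ = quantify_stack(stack, FretConfig(front_hint=truth.front_hint,
                                                    register=False))
        assert tc.summary == pytest.approx(1.8, abs=0.05)
        assert np.nanmean(tc.back_mean) == pytest.approx(1.1, abs=0.05)

    def test_zero_denominator_pixels_excluded(self):
        stack, truth = self._uniform_stack()
        donor = stack.donor_donor.astype(float)
        fret = stack.fret.astype(float)
        # zero the outer part of the leading-edge crescent in both channels:
        # those pixels must simply drop out of the mean
        donor[:, :, 240:] = 0.0
        fret[:, :, 240:] = 0.0
        hacked = ChannelStack(donor, fret, stack.acceptor_direct)
        masks = [segment_cell(atrous_bandpass(hacked.acceptor_direct[t]))
                 for t in range(2)]
        rois = []
        prev = None
        for t, m in enumerate(masks):
            roi = ring_and_crescents(m, 40, front_hint=truth.front_hint
                                     if prev is None else None,
                                     previous_front=prev)
            prev = roi.front
            rois.append(roi)
        tc = leading_edge_ratio(hacked, rois)
        assert (tc.n_pixels > 0).all()
        assert tc.n_pixels[0] < rois[0].front.sum()
        assert tc.summary == pytest.approx(2.0, abs=1e-6)

    def test_fully_zero_denominator_yields_flagged_nan(self):
        stack, truth = self._uniform_stack()
        donor = np.zeros_like(stack.donor_donor, dtype=float)
        hacked = ChannelStack(donor, stack.fret.astype(float),
                              stack.acceptor_direct)
        mask = segment_cell(atrous_bandpass(hacked.acceptor_direct[0]))
        roi = ring_and_crescents(mask, 40, front_hint=truth.front_hint)
        with pytest.warns(UserWarning, match="zero-denominator"):
            tc = leading_edge_ratio(
                ChannelStack(donor[:1], hacked.fret[:1],
                             hacked.acceptor_direct[:1]),
                [roi],
            )
        assert np.isnan(tc.front_mean[0]) and tc.n_pixels[0] == 0

    def test_blur_precedes_division(self):
        # on a gradient image the two orders measurably differ; the pipeline
        # must match the blur-then-divide oracle
        stack, truth = gen_fret_stack(
            SyntheticCellParams(ratio_front=1.8, ratio_back=1.1, noise=0.0,
                                n_frames=1)
        )
        mask = segment_cell(atrous_bandpass(stack.acceptor_direct[0]))
        roi = ring_and_crescents(mask, 40, front_hint=truth.front_hint)
        # oracle A: specified order
        num = ndimage.gaussian_filter(stack.fret[0].astype(float), 1.0)
        den = ndimage.gaussian_filter(stack.donor_donor[0].astype(float), 1.0)
        sel = roi.ring & (den != 0)
        specified = float(np.mean(num[sel] / den[sel]))
        # oracle B: swapped order (divide raw, then blur the ratio image)
        raw_den = stack.donor_donor[0].astype(float)
        raw_ratio = np.divide(stack.fret[0].astype(float), raw_den,
                              out=np.zeros_like(raw_den), where=raw_den != 0)
        swapped = float(np.mean(ndimage.gaussian_filter(raw_ratio, 1.0)[sel]))
        assert specified != pytest.approx(swapped, abs=1e-4)
        roi_full = CrescentROI(roi.ring, roi.ring, roi.ring, roi.long_axis,
                               roi.selected_front)
        tc = leading_edge_ratio(
            ChannelStack(stack.donor_donor[:1], stack.fret[:1],
                         stack.acceptor_direct[:1]),
            [roi_full],
        )
        assert tc.front_mean[0] == pytest.approx(specified, abs=1e-9)
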