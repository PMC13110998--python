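import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eitvent.breaths import Breath, global_signal, segment_breaths
from eitvent.io_formats import LungMasks, SequenceMeta
from eitvent.metrics import (BreathMetrics, aggregate_phase, breath_scalars,
                             cov, functional_image, roi_split, run_rates)
from eitvent.synthetic import (BreathGroundTruth, weight_map_centroids,
                               weight_map_for_targets)

from conftest import render


@pytest.fixture()
def mirror_masks():
    """Masks symmetric about the midline on a small grid."""
    right = np.zeros((9, 10), bool)
    left = np.zeros((9, 10), bool)
    right[2:7, 1:4] = True
    left[2:7, 6:9] = True
    return LungMasks(right_mask=right, left_mask=left, midline_col=5)


class TestFunctionalImage:
    def test_map_is_amplitude_times_weight_map(self, masks):
        w = weight_map_for_targets(masks, 48.0, 46.0, 52.0)
        b = [BreathGroundTruth(onset_s=1.0 + 5 * i, ti_s=2.0, te_s=3.0,
                               amplitude=0.8, eeli=27.0) for i in range(3)]
        seq, _ = render(b, masks, weight_map=w, duration_s=18.0)
        sig = global_signal(seq, masks)
        breath = segment_breaths(sig, 20.0)[0]
        img = functional_image(seq, breath)
        np.testing.assert_allclose(img.pixels[masks.union],
                                   0.8 * w[masks.union], rtol=1e-4, atol=1e-6)

    def test_zero_amplitude_gives_zero_map(self, masks):
        seq, _ = render([], masks, duration_s=5.0)
        img = functional_image(seq, Breath(onset=0, peak=10, end=20))
        assert not img.pixels.any()

    def test_negative_excursion_clamped_and_counted(self, masks):
        seq, _ = render([], masks, duration_s=5.0)
        seq.frames = seq.frames.astype(np.float64)
        seq.frames[10, 0, 0] = -0.2  # non-lung pixel dips at end-inspiration
        img = functional_image(seq, Breath(onset=0, peak=10, end=20))
        assert img.pixels[0, 0] == 0.0
        assert img.n_clamped == 1


class TestCoV:
    def test_symmetric_map_centres_at_50(self, mirror_masks):
        m = np.zeros((9, 10))
        m[mirror_masks.union] = 1.0
        assert cov(m, mirror_masks, "rl") == pytest.approx(50.0)

    def test_most_ventral_row_anchors_at_0(self, mirror_masks):
        m = np.zeros((9, 10))
        m[2, 1:4] = 1.0  # all signal in the most ventral lung row
        assert cov(m, mirror_masks, "vd") == pytest.approx(0.0)
        m2 = np.zeros((9, 10))
        m2[6, 6:9] = 1.0  # most dorsal row
        assert cov(m2, mirror_masks, "vd") == pytest.approx(100.0)

    def test_two_pixel_weighted_mean(self):
        right = np.zeros((3, 8), bool)
        left = np.zeros((3, 8), bool)
        right[1, 1] = True   # rightmost lung pixel -> 0%
        left[1, 6] = True    # leftmost lung pixel -> 100%
        masks = LungMasks(right_mask=right, left_mask=left, midline_col=4)
        m = np.zeros((3, 8))
        m[1, 1] = 3.0
        m[1, 6] = 1.0
        assert cov(m, masks, "rl") == pytest.approx(25.0)

    def test_all_zero_map_rejected(self, mirror_masks):
        with pytest.raises(ValueError, match="no ventilation signal"):
            cov(np.zeros((9, 10)), mirror_masks, "rl")

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        right = np.zeros((6, 8), bool)
        left = np.zeros((6, 8), bool)
        right[1:5, 1:4] = True
        left[1:5, 5:7] = True
        masks = LungMasks(right_mask=right, left_mask=left, midline_col=4)
        rng = np.random.default_rng(0)
        m = np.where(masks.union, rng.random((6, 8)), 0.0)
        assert cov(scale * m, masks, "rl") == pytest.approx(
            cov(m, masks, "rl"), abs=1e-9)

    def test_translation_shifts_by_one_column_step(self):
        right = np.zeros((5, 12), bool)
        left = np.zeros((5, 12), bool)
        right[1:4, 1:5] = True
        left[1:4, 7:11] = True
        masks = LungMasks(right_mask=right, left_mask=left, midline_col=6)
        m = np.zeros((5, 12))
        m[2, 2] = 1.0
        step = 100.0 / (10 - 1)  # lung columns span indices 1..10
        assert (cov(np.roll(m, 1, axis=1), masks, "rl")
                - cov(m, masks, "rl")) == pytest.approx(step)


class TestRoiSplit:
    def test_mirrored_map_splits_evenly(self, mirror_masks):
        m = np.zeros((9, 10))
        m[mirror_masks.union] = 2.0
        assert roi_split(m, mirror_masks) == pytest.approx((50.0, 50.0))

    def test_all_right_mass(self, mirror_masks):
        m = np.zeros((9, 10))
        m[mirror_masks.right_mask] = 1.0
        assert roi_split(m, mirror_masks) == pytest.approx((100.0, 0.0))

    def test_three_to_one_split(self, mirror_masks):
        m = np.zeros((9, 10))
        m[mirror_masks.right_mask] = 3.0
        m[mirror_masks.left_mask] = 1.0
        assert roi_split(m, mirror_masks) == pytest.approx((75.0, 25.0))

    def test_sum_is_exactly_100(self, mirror_masks):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = np.where(mirror_masks.union, rng.random((9, 10)), 0.0)
            r, l = roi_split(m, mirror_masks)
            assert r + l == 100.0


class TestBreathScalars:
    def test_injected_values_recovered(self, masks):
        b = [BreathGroundTruth(onset_s=1.0 + 5 * i, ti_s=2.0, te_s=3.0,
                               amplitude=1.0, eeli=27.0) for i in range(3)]
        seq, _ = render(b, masks, duration_s=18.0)
        sig = global_signal(seq, masks)
        breath = segment_breaths(sig, 20.0)[0]
        tiv, ti, eeli = breath_scalars(sig, breath, 20.0)
        assert tiv == pytest.approx(1.0, rel=1e-4)
        assert ti == pytest.approx(2.0, abs=0.1)
        assert eeli == pytest.approx(27.0, rel=1e-5)

    def test_scaling_signal_scales_tiv_eeli_not_ti(self):
        sig = 27.0 + np.concatenate([np.linspace(0, 1, 20),
                                     np.linspace(1, 0, 20)])
        b = Breath(onset=0, peak=19, end=39)
        tiv1, ti1, eeli1 = breath_scalars(sig, b, 10.0)
        tiv2, ti2, eeli2 = breath_scalars(3.0 * sig, b, 10.0)
        assert tiv2 == pytest.approx(3.0 * tiv1)
        assert eeli2 == pytest.approx(3.0 * eeli1)
        assert ti2 == ti1

    def test_half_hz_raised_cosine_train(self, masks):
        b = [BreathGroundTruth(onset_s=0.5 + 2 * i, ti_s=1.0, te_s=1.0,
                               amplitude=1.0, eeli=27.0) for i in range(10)]
        seq, _ = render(b, masks, duration_s=22.0)
        sig = global_signal(seq, masks)
        for breath in segment_breaths(sig, 20.0):
            tiv, ti, _ = breath_scalars(sig, breath, 20.0)
            assert tiv == pytest.approx(1.0, rel=1e-3)
            assert ti == pytest.approx(1.0, abs=0.1)

    def test_non_positive_tiv_rejected(self):
        sig = np.linspace(5, 0, 50)
        with pytest.raises(ValueError, match="non-positive TIV"):
            breath_scalars(sig, Breath(onset=0, peak=10, end=20), 10.0)


class TestRates:
    def test_uniform_five_second_breaths(self):
        run = [Breath(onset=100 * i, peak=100 * i + 30, end=100 * (i + 1))
               for i in range(6)]
        rate, _ = run_rates(run, 20.0, np.ones(6))
        assert rate == pytest.approx(12.0)

    def test_miv_is_rate_times_mean_tiv(self):
        run = [Breath(onset=120 * i, peak=120 * i + 30, end=120 * (i + 1))
               for i in range(6)]
        rate, miv = run_rates(run, 20.0, np.full(6, 0.5))
        assert miv == pytest.approx(rate * 0.5)

    def test_alternating_durations_average_out(self):
        onsets = np.cumsum([0, 80, 120, 80, 120, 80])  # 4 s / 6 s at 20 Hz
        run = [Breath(onset=int(o), peak=int(o) + 30, end=int(o) + d)
               for o, d in zip(onsets, [80, 120, 80, 120, 80, 120])]
        rate, _ = run_rates(run, 20.0, np.ones(6))
        assert rate == pytest.approx(12.0)


class TestAggregation:
    def _metrics(self, tiv):
        return BreathMetrics(tiv=tiv, ti=2.0, eeli=27.0, cov_rl=50.0,
                             cov_vd=46.0, roi_r=52.0, roi_l=48.0)

    def test_identical_breaths_aggregate_to_themselves(self):
        meta = SequenceMeta(animal="A1", session=1, phase="Stand_pre",
                            duration_s=60.0)
        obs = aggregate_phase([self._metrics(1.0)] * 6, 12.0, 12.0, meta)
        assert obs.tiv == 1.0 and obs.n_breaths == 6

    def test_mean_of_arithmetic_progression(self):
        meta = SequenceMeta(animal="A1", session=1, phase="Stand_pre",
                            duration_s=60.0)
        per = [self._metrics(t) for t in np.arange(0.5, 1.05, 0.1)]
        obs = aggregate_phase(per, 12.0, 9.0, meta)
        assert obs.tiv == pytest.approx(0.75)
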