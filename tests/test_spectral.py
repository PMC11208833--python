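import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnohrv.preprocess import Tachogram
from somnohrv.spectral import (
    BandDefinition,
    band_power,
    frame_series,
    lf_hf_ratio,
    night_summary,
    window_psd,
)

from conftest import make_tone_tachogram

BANDS = BandDefinition()


class TestWindowPsd:
    def test_constant_tachogram_has_no_band_power(self):
        tach = make_tone_tachogram([], duration_s=300.0)
        for f, pxx, ok in window_psd(tach):
            assert ok
            assert band_power(f, pxx, (0.05, 0.40)) < 1e-9

    def test_pure_tone_total_power_matches_parseval(self):
        a = 30.0
        tach = make_tone_tachogram([(0.10, a)], duration_s=60.0)
        f, pxx, ok = window_psd(tach)[0]
        assert ok
        assert band_power(f, pxx, (0.0, 2.0)) == pytest.approx(a * a / 2.0, rel=0.05)

    def test_white_noise_band_power_matches_sample_variance(self):
        """Mean integrated 0-2 Hz power over 100 windows estimates sigma^2."""
        sigma = 25.0
        tach = make_tone_tachogram([], duration_s=6000.0, noise_sd=sigma, seed=4)
        windows = window_psd(tach)
        assert len(windows) == 100
        total = [band_power(f, pxx, (0.0, 2.0)) for f, pxx, ok in windows]
        assert np.mean(total) == pytest.approx(sigma**2, rel=0.10)

    def test_invalid_window_reported(self):
        tach = make_tone_tachogram([(0.10, 20.0)], duration_s=120.0)
        tach.valid_mask[240:340] = False  # 100/240 masked in second window
        psds = window_psd(tach)
        assert psds[0][2] and not psds[1][2]

    def test_window_longer_than_recording_yields_nothing(self):
        tach = make_tone_tachogram([], duration_s=30.0)
        assert window_psd(tach, window_s=60.0) == []


class TestBandPower:
    def test_zero_psd_integrates_to_zero(self):
        f = np.linspace(0.0, 2.0, 121)
        assert band_power(f, np.zeros_like(f), (0.05, 0.15)) == 0.0

    def test_hf_tone_lands_in_hf_band(self):
        tach = make_tone_tachogram([(0.25, 20.0)], duration_s=60.0)
        f, pxx, _ = window_psd(tach)[0]
        hf = band_power(f, pxx, BANDS.hf)
        both = band_power(f, pxx, (0.05, 0.40))
        assert hf / both >= 0.95

    def test_equal_tones_give_unit_ratio(self):
        tach = make_tone_tachogram([(0.10, 20.0), (0.25, 20.0)], duration_s=600.0)
        lf = hf = 0.0
        for f, pxx, _ in window_psd(tach):
            lf += band_power(f, pxx, BANDS.lf)
            hf += band_power(f, pxx, BANDS.hf)
        assert lf / hf == pytest.approx(1.0, rel=0.10)

    def test_boundary_bin_never_double_counted(self):
        tach = make_tone_tachogram([(0.15, 20.0)], duration_s=60.0)
        f, pxx, _ = window_psd(tach)[0]
        lf = band_power(f, pxx, BANDS.lf)
        hf = band_power(f, pxx, BANDS.hf)
        total = band_power(f, pxx, (BANDS.lf_lo, BANDS.hf_hi))
        assert lf + hf <= total + 1e-9

    def test_inverted_band_raises(self):
        f = np.linspace(0.0, 2.0, 121)
        with pytest.raises(ValueError):
            band_power(f, np.zeros_like(f), (0.4, 0.1))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        a_lf=st.floats(5.0, 50.0),
        a_hf=st.floats(5.0, 50.0),
        c=st.floats(0.2, 5.0),
    )
    def test_scale_equivariance(self, a_lf, a_hf, c):
        """Scaling fluctuations by c scales powers by c^2; LF/HF unchanged."""
        t1 = make_tone_tachogram([(0.10, a_lf), (0.25, a_hf)], duration_s=60.0)
        t2 = make_tone_tachogram([(0.10, c * a_lf), (0.25, c * a_hf)], duration_s=60.0)
        f1, p1, _ = window_psd(t1)[0]
        f2, p2, _ = window_psd(t2)[0]
        lf1, hf1 = band_power(f1, p1, BANDS.lf), band_power(f1, p1, BANDS.hf)
        lf2, hf2 = band_power(f2, p2, BANDS.lf), band_power(f2, p2, BANDS.hf)
        assert lf2 == pytest.approx(c * c * lf1, rel=1e-6)
        assert hf2 == pytest.approx(c * c * hf1, rel=1e-6)
        assert lf2 / hf2 == pytest.approx(lf1 / hf1, rel=1e-6)

    def test_parseval_band_partition(self):
        """Band powers over a partition of [0, Nyquist] sum to the windowed variance."""
        tach = make_tone_tachogram(
            [(0.10, 25.0), (0.25, 10.0)], duration_s=60.0, noise_sd=15.0, seed=2
        )
        f, pxx, _ = window_psd(tach)[0]
        edges = [0.0, 0.05, 0.15, 0.40, 1.0, 2.0]
        total = sum(
            band_power(f, pxx, (lo, hi)) for lo, hi in zip(edges[:-1], edges[1:])
        )
        assert total == pytest.approx(band_power(f, pxx, (0.0, 2.0)), rel=1e-9)


class TestRatioAndFrames:
    def test_ratio_arithmetic(self):
        assert lf_hf_ratio(4.0, 4.0) == (1.0, True)
        assert lf_hf_ratio(2.0, 1.0) == (2.0, True)

    def test_vanishing_hf_marks_frame_invalid(self):
        ratio, ok = lf_hf_ratio(1.0, 0.0)
        assert not ok and math.isnan(ratio)
        ratio, ok = lf_hf_ratio(0.0, 0.0)
        assert not ok

    def test_one_frame_per_minute(self):
        tach = make_tone_tachogram([(0.10, 20.0)], duration_s=600.0)
        frames = frame_series(tach)
        assert len(frames) == 10
        assert [fr.window_start_min for fr in frames] == list(range(10))
        for fr in frames:
            assert fr.lf_amp == pytest.approx(math.sqrt(fr.lf_power))
            assert fr.hf_amp == pytest.approx(math.sqrt(fr.hf_power))

    def test_masked_window_yields_invalid_frame(self):
        tach = make_tone_tachogram([(0.10, 20.0), (0.25, 20.0)], duration_s=180.0)
        tach.valid_mask[240:480] = False
        frames = frame_series(tach)
        assert [fr.valid for fr in frames] == [True, False, True]

    def test_pure_lf_tone_frame_invalid_by_hf_floor(self):
        # no HF power at all -> the ratio is undefined, frame marked invalid
        tach = make_tone_tachogram([(0.10, 20.0)], duration_s=60.0)
        fr = frame_series(tach)[0]
        assert not fr.valid and math.isnan(fr.lf_hf)

    def test_stagewise_ratio_recovered_on_synthetic_night(self, short_night):
        """Median in-stage LF/HF tracks the configured stage power ratio."""
        from somnohrv.pipeline import process_night

        night = short_night
        res = process_night(night.rri, night.accel)
        truth = night.stages.labels
        prof = night.profile
        got = {}
        for stage in ("S", "PS_DEEP"):
            vals = [
                fr.lf_hf
                for fr in res.frames
                if fr.valid and fr.window_start_min < truth.size
                and truth[fr.window_start_min] == stage
            ]
            got[stage] = float(np.median(vals))
        # configured tone-power ratio, ignoring the broadband noise floor:
        # S is strongly sympathetic-dominant, deep strongly vagal-dominant
        assert got["S"] > 1.5
        assert got["PS_DEEP"] < 0.5
        assert got["S"] > 10 * got["PS_DEEP"]


class TestNightSummary:
    def _frames(self, n=5, lf=9.0, hf=4.0):
        from somnohrv.spectral import SpectralFrame

        return [
            SpectralFrame(i, lf, hf, math.sqrt(lf), math.sqrt(hf), lf / hf, True)
            for i in range(n)
        ]

    def test_identical_frames_mean_is_that_frame(self):
        frames = self._frames(5)
        labels = np.array(["S"] * 5, dtype=object)
        s = night_summary(frames, labels)
        assert s.lf_amp == pytest.approx(3.0)
        assert s.hf_amp == pytest.approx(2.0)
        assert s.lf_hf == pytest.approx(2.25)
        assert s.n_frames == 5

    def test_only_sleep_frames_counted(self):
        frames = self._frames(6)
        frames[0].valid = False
        labels = np.array(["WAKE", "S", "S", "WAKE", "S", "PS_DEEP"], dtype=object)
        s = night_summary(frames, labels)
        assert s.n_frames == 4
        assert set(s.per_stage) == {"S", "PS_DEEP"}
        assert s.per_stage["S"]["n_frames"] == 3

    def test_no_valid_sleep_frames_raises(self):
        frames = self._frames(3)
        labels = np.array(["WAKE"] * 3, dtype=object)
        with pytest.raises(ValueError, match="no valid sleep frames"):
            night_summary(frames, labels)
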