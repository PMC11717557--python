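"""Framewise displacement, respiratory filtering, and censoring rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scrubaudit as sa
from scrubaudit.motion import censor_from_fd

from conftest import brute_force_keep


def _trace(params, subject="s1", run=1, tr=0.8):
    return sa.MotionTrace(subject_id=subject, run_index=run, params=params, tr_seconds=tr)


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        fd = sa.compute_fd(_trace(np.zeros((100, 6))))
        assert fd.fd.shape == (100,)
        assert np.all(fd.fd == 0)

    def test_translation_step_appears_once_at_step_frame(self):
        p = np.zeros((50, 6))
        p[10:, 0] = 0.5  # 0.5 mm step in trans_x between frames 9 and 10
        fd = sa.compute_fd(_trace(p))
        assert fd.fd[10] == pytest.approx(0.5)
        assert np.all(np.delete(fd.fd, 10) == 0)

    def test_rotation_step_converts_via_head_radius_arc(self):
        p = np.zeros((20, 6))
        p[7:, 4] = 0.02  # rot_y step of 0.02 rad; 50 mm * 0.02 = 1.0 mm
        fd = sa.compute_fd(_trace(p), head_radius_mm=50.0)
        assert fd.fd[7] == pytest.approx(1.0)

    def test_first_frame_is_zero_by_convention(self):
        rng = np.random.default_rng(0)
        fd = sa.compute_fd(_trace(rng.normal(size=(30, 6))))
        assert fd.fd[0] == 0.0

    def test_fd_equals_translation_plus_scaled_rotation_sum(self):
        rng = np.random.default_rng(1)
        p = rng.normal(scale=0.05, size=(60, 6))
        fd = sa.compute_fd(_trace(p), head_radius_mm=35.0).fd
        d = np.abs(np.diff(p, axis=0))
        expect = d[:, :3].sum(axis=1) + 35.0 * d[:, 3:].sum(axis=1)
        np.testing.assert_allclose(fd[1:], expect, rtol=1e-12)

    def test_nonfinite_parameter_reports_frame(self):
        p = np.zeros((20, 6))
        p[13, 2] = np.nan
        with pytest.raises(ValueError, match="frame 13"):
            sa.compute_fd(_trace(p))

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError, match="n_frames, 6"):
            _trace(np.zeros((20, 5)))


class TestRespiratoryFilter:
    tr = 0.8

    def _sine(self, freq, n=375):
        t = np.arange(n) * self.tr
        return np.cos(2 * np.pi * freq * t)

    def test_dc_series_unchanged(self):
        p = np.full((200, 6), 0.7)
        out = sa.filter_respiratory(_trace(p), sa.CensorConfig(threshold_mm=0.2))
        np.testing.assert_allclose(out.params, p, atol=1e-9)

    def test_respiratory_band_attenuated_to_under_ten_percent(self):
        p = np.zeros((375, 6))
        p[:, 1] = self._sine(0.35)
        out = sa.filter_respiratory(_trace(p), sa.CensorConfig(threshold_mm=0.2))
        core = out.params[10:-10, 1]
        assert np.max(np.abs(core)) <= 0.10

    def test_slow_signal_preserved_within_five_percent(self):
        p = np.zeros((375, 6))
        p[:, 0] = self._sine(0.05)
        out = sa.filter_respiratory(_trace(p), sa.CensorConfig(threshold_mm=0.2))
        core = out.params[10:-10, 0]
        ref = self._sine(0.05)[10:-10]
        assert np.max(np.abs(core - ref)) <= 0.05

    def test_filter_is_idempotent_outside_the_transition_band(self):
        cfg = sa.CensorConfig(threshold_mm=0.2)
        # passband content is untouched by a second application
        p = np.zeros((375, 6))
        p[:, 0] = self._sine(0.05)
        once = sa.filter_respiratory(_trace(p), cfg).params
        twice = sa.filter_respiratory(_trace(once), cfg).params
        rel = np.linalg.norm(twice - once) / np.linalg.norm(once)
        assert rel < 0.01
        # broadband input: the second pass only re-attenuates the transition
        # band; the overall change stays within the documented bound
        rng = np.random.default_rng(2)
        p = rng.normal(size=(375, 6))
        once = sa.filter_respiratory(_trace(p), cfg).params
        twice = sa.filter_respiratory(_trace(once), cfg).params
        rel = np.linalg.norm(twice - once) / np.linalg.norm(once)
        assert rel < 0.12

    def test_fd_series_target_clips_negative_values(self):
        fd = sa.FDSeries("s", 1, np.abs(np.random.default_rng(3).normal(size=375)))
        out = sa.filter_fd_series(fd, 0.8, sa.CensorConfig(threshold_mm=0.2))
        assert out.filtered
        assert np.all(out.fd >= 0)
        assert out.fd[0] == 0.0

    def test_stopband_above_nyquist_rejected(self):
        p = np.zeros((375, 6))
        cfg = sa.CensorConfig(threshold_mm=0.2, respiratory_stopband_hz=(0.31, 0.43))
        with pytest.raises(ValueError, match="Nyquist"):
            sa.filter_respiratory(_trace(p, tr=2.0), cfg)

    def test_short_series_rejected(self):
        p = np.zeros((10, 6))
        with pytest.raises(ValueError, match="warm-up"):
            sa.filter_respiratory(_trace(p), sa.CensorConfig(threshold_mm=0.2))


class TestCensorMask:
    def _mask(self, fd, thr=0.2, min_island=5, boundaries=True):
        cfg = sa.CensorConfig(
            threshold_mm=thr, min_island=min_island, censor_boundary_islands=boundaries
        )
        return sa.build_censor_mask(sa.FDSeries("s", 1, np.asarray(fd, float)), cfg)

    def test_no_exceedance_keeps_everything(self):
        mask = self._mask(np.full(500, 0.1))
        assert mask.n_retained == 500

    def test_five_frame_island_between_spikes_is_censored(self):
        fd = np.full(30, 0.05)
        fd[10] = fd[16] = 0.5  # 5 kept frames at 11..15
        mask = self._mask(fd)
        assert not mask.keep[10:17].any()
        assert mask.keep.sum() == 30 - 7

    def test_six_frame_island_survives(self):
        fd = np.full(30, 0.05)
        fd[10] = fd[17] = 0.5  # 6 kept frames at 11..16
        mask = self._mask(fd)
        assert mask.keep[11:17].all()
        assert (~mask.keep).sum() == 2

    def test_fd_exactly_at_threshold_is_kept(self):
        fd = np.full(100, 0.2)
        mask = self._mask(fd, thr=0.2)
        assert mask.n_retained == 100

    def test_boundary_island_convention_switch(self):
        fd = np.full(40, 0.05)
        fd[4] = 0.5  # 4 kept frames before the first spike
        censored = self._mask(fd, boundaries=True)
        kept = self._mask(fd, boundaries=False)
        assert not censored.keep[:4].any()
        assert kept.keep[:4].all()

    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(
        fd=st.lists(st.floats(0, 0.6, allow_nan=False), min_size=1, max_size=200),
        thr=st.sampled_from([0.1, 0.2, 0.3, 0.4, 0.5]),
        min_island=st.integers(0, 8),
        boundaries=st.booleans(),
    )
    def test_matches_segment_enumeration_oracle(self, fd, thr, min_island, boundaries):
        cfg = sa.CensorConfig(
            threshold_mm=thr,
            min_island=min_island,
            censor_boundary_islands=boundaries,
        )
        got = censor_from_fd(np.asarray(fd), cfg)
        want = brute_force_keep(fd, thr, min_island, boundaries)
        np.testing.assert_array_equal(got, want)

    def test_threshold_monotonicity_of_censored_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            fd = rng.gamma(2.0, 0.08, size=rng.integers(20, 200))
            prev = None
            for thr in (0.1, 0.2, 0.3, 0.4, 0.5):  # strict to liberal
                keep = censor_from_fd(fd, sa.CensorConfig(threshold_mm=thr))
                if prev is not None:
                    # loosening the threshold can only retain more frames:
                    # the stricter censored set contains the looser one
                    assert set(np.flatnonzero(prev)) <= set(np.flatnonzero(keep))
                prev = keep


class TestExclusionRule:
    def _mask_with(self, retained, total=1500, thr=0.2):
        keep = np.zeros(total, dtype=bool)
        keep[:retained] = True
        return sa.CensorMask("s", 1, keep, thr)

    def test_374_retained_is_excluded_375_is_included(self):
        cfg = sa.CensorConfig(threshold_mm=0.2)
        assert sa.flag_motion_exclusion([self._mask_with(374)], cfg) is True
        assert sa.flag_motion_exclusion([self._mask_with(375)], cfg) is False

    def test_uncensored_full_acquisition_is_included(self):
        cfg = sa.CensorConfig(threshold_mm=0.2)
        masks = [
            sa.CensorMask("s", r, np.ones(375, dtype=bool), 0.2) for r in range(1, 5)
        ]
        assert sa.flag_motion_exclusion(masks, cfg) is False

    def test_retention_sums_across_runs(self):
        cfg = sa.CensorConfig(threshold_mm=0.2)
        masks = [self._mask_with(100, total=375), self._mask_with(275, total=375)]
        assert sa.flag_motion_exclusion(masks, cfg) is False  # 375 total

    def test_mixed_thresholds_rejected(self):
        cfg = sa.CensorConfig(threshold_mm=0.2)
        masks = [self._mask_with(400, thr=0.2), self._mask_with(400, thr=0.3)]
        with pytest.raises(ValueError, match="mix"):
            sa.flag_motion_exclusion(masks, cfg)

    def test_five_minute_minimum_at_this_tr_is_375_frames(self):
        assert sa.min_frames_for_duration(5.0, 0.8) == 375

    def test_invalid_censor_config_names_field(self):
        with pytest.raises(ValueError, match="threshold_mm"):
            sa.CensorConfig(threshold_mm=0.0)
        with pytest.raises(ValueError, match="filter_target"):
            sa.CensorConfig(threshold_mm=0.2, filter_target="volumes")
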