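"""Segmentation, normalization and cohort round-trip behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsepair.signals import (FS, NormalizationStats, Recording,
                               apply_norm, fit_norm_stats, invert_norm,
                               read_cohort, segment_recording, write_cohort)


def make_rec(T, pid="p0", **kw):
    x = np.arange(2 * T, dtype=float).reshape(T, 2)
    return Recording(pid, f"{pid}_r0", x, **kw)


class TestSegmentation:
    @pytest.mark.parametrize("T,expected", [
        (4800, 7),   # 60 s at 80 Hz with 10 s windows / 2 s overlap
        (800, 1),    # exactly one window
        (799, 0),    # sub-window input yields nothing, no error
        (1440, 2),   # 800 + one stride
        (1439, 1),
    ])
    def test_segment_counts(self, T, expected):
        segs = segment_recording(make_rec(T))
        assert len(segs) == expected
        assert all(s.samples.shape == (800, 2) for s in segs)
        assert [s.index for s in segs] == list(range(expected))

    def test_consecutive_segments_share_overlap(self):
        rec = make_rec(4800)
        segs = segment_recording(rec)
        stride, overlap = 640, 160
        for a, b in zip(segs, segs[1:]):
            np.testing.assert_array_equal(a.samples[stride:], b.samples[:overlap])

    def test_covered_prefix_reconstructs_recording(self):
        rec = make_rec(4800)
        segs = segment_recording(rec, window_s=10, overlap_s=0)
        rebuilt = np.concatenate([s.samples for s in segs])
        np.testing.assert_array_equal(rebuilt, rec.samples[: len(rebuilt)])

    @given(T=st.integers(0, 3000), window=st.integers(1, 20),
           overlap=st.integers(0, 19))
    @settings(max_examples=200, deadline=None)
    def test_count_matches_sliding_window_oracle(self, T, window, overlap):
        """Brute-force enumeration of window start positions."""
        if overlap >= window:
            return
        rec = make_rec(T) if T else Recording("p", "r", np.empty((0, 2)))
        segs = segment_recording(rec, window_s=window, overlap_s=overlap)
        win, stride = window * FS, (window - overlap) * FS
        starts = [s for s in range(0, T - win + 1, stride)]
        assert len(segs) == len(starts)
        for s, start in zip(segs, starts):
            np.testing.assert_array_equal(s.samples, rec.samples[start:start + win])

    def test_window_not_exceeding_overlap_rejected(self):
        with pytest.raises(ValueError):
            segment_recording(make_rec(4800), window_s=2, overlap_s=2)


class TestNormalization:
    def test_two_point_stats(self):
        x = np.tile([[1.0, 5.0], [3.0, 5.0]], (10, 1))
        stats = fit_norm_stats([Recording("p", "r", x)])
        assert stats.mean_red == 2.0
        assert stats.sd_red == 1.0  # population convention

    def test_constant_channel_clamped_with_warning(self):
        x = np.ones((100, 2))
        with pytest.warns(UserWarning, match="variance"):
            stats = fit_norm_stats([Recording("p", "r", x)])
        assert stats.sd_red == pytest.approx(1e-8)

    def test_self_normalization_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        recs = [Recording(f"p{i}", f"r{i}", rng.normal(2, 3, (200, 2)))
                for i in range(50)]
        stats = fit_norm_stats(recs)
        normed = np.concatenate([apply_norm(r, stats).samples for r in recs])
        assert np.abs(normed.mean(axis=0)).max() < 1e-6
        assert np.abs(normed.std(axis=0) - 1).max() < 1e-6

    def test_centering_and_identity(self):
        x = np.full((50, 2), 7.0)
        rec = Recording("p", "r", x)
        stats = NormalizationStats(7.0, 2.0, 1.0, 1.0)
        assert np.all(apply_norm(rec, stats).samples[:, 0] == 0)
        ident = NormalizationStats(0.0, 1.0, 0.0, 1.0)
        np.testing.assert_array_equal(apply_norm(rec, ident).samples, x)

    def test_affine_round_trip(self, rng):
        rec = Recording("p", "r", rng.normal(size=(100, 2)))
        stats = NormalizationStats(1.2, 0.7, -3.0, 2.5)
        back = invert_norm(apply_norm(rec, stats), stats)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            fit_norm_stats([])


class TestCohortIO:
    def test_round_trip(self, tmp_path, small_cohort):
        _, _, recordings = small_cohort
        manifest = write_cohort(tmp_path, recordings[:4],
                                splits={recordings[0].patient_id: "test"})
        back = read_cohort(manifest)
        assert len(back) == 4
        for orig, rt in zip(recordings[:4], back):
            assert rt.patient_id == orig.patient_id
            assert rt.recording_id == orig.recording_id
            assert rt.phase == orig.phase
            assert rt.label == orig.label
            np.testing.assert_allclose(rt.samples, orig.samples, atol=1e-6)
        assert back[0].meta["split"] == "test"

    def test_missing_recording_file_named_in_error(self, tmp_path, small_cohort):
        _, _, recordings = small_cohort
        manifest = write_cohort(tmp_path, recordings[:2])
        (tmp_path / recordings[1].recording_id).with_suffix(".csv").unlink()
        with pytest.raises(FileNotFoundError, match=recordings[1].recording_id):
            read_cohort(manifest)

    def test_wrong_sampling_rate_rejected(self, tmp_path, small_cohort):
        import json
        _, _, recordings = small_cohort
        manifest = write_cohort(tmp_path, recordings[:1])
        sidecar = (tmp_path / recordings[0].recording_id).with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        meta["fs"] = 100
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="[sS]ampling rate"):
            read_cohort(manifest)

    def test_recording_rejects_wrong_rate_and_shape(self):
        with pytest.raises(ValueError, match="80"):
            Recording("p", "r", np.zeros((10, 2)), fs=100)
        with pytest.raises(ValueError, match="red, ir"):
            Recording("p", "r", np.zeros((10, 3)))
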