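"""Pressure-video container, file I/O and the preprocessing pipeline."""

import numpy as np
import pytest

from copsense.pressure_video import (
    PressureVideo,
    StanceVideo,
    crop_white_border,
    downsample,
    preprocess_recording,
    read_video,
    select_representatives,
    split_stance_phases,
    write_video,
)


class TestContainer:
    def test_rejects_negative_pressure(self):
        with pytest.raises(ValueError, match="negative"):
            PressureVideo(np.array([[[0.0, -1.0]]]))

    def test_rejects_empty_and_bad_rate(self):
        with pytest.raises(ValueError, match="no frames"):
            PressureVideo(np.zeros((0, 2, 2)))
        with pytest.raises(ValueError, match="frame_rate"):
            PressureVideo(np.zeros((1, 2, 2)), frame_rate=0.0)

    def test_stance_video_rejects_empty_frame(self):
        frames = np.ones((3, 2, 2))
        frames[1] = 0.0
        with pytest.raises(ValueError, match="all-zero frame at index 1"):
            StanceVideo(frames)


class TestFileIO:
    def test_roundtrip_identity_zero_video(self, tmp_path):
        v = PressureVideo(np.zeros((1, 2, 2)))
        path = tmp_path / "v.ppv"
        write_video(v, path)
        assert read_video(path) == v

    def test_roundtrip_random_videos_bitwise(self, tmp_path, rng):
        for i in range(5):
            frames = rng.uniform(0, 300, size=(3, 20, 7))
            v = PressureVideo(frames, frame_rate=100.0)
            path = tmp_path / f"v{i}.ppv"
            write_video(v, path)
            back = read_video(path)
            assert np.array_equal(back.frames, v.frames)
            assert back.frame_rate == v.frame_rate

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.ppv"
        path.write_text("")
        with pytest.raises(ValueError, match="no frames"):
            read_video(path)

    def test_malformed_frame_names_index(self, tmp_path):
        path = tmp_path / "bad.ppv"
        path.write_text("ppv 2 2 100.0\n\n1 2\n3 4\n\n1 2 3\n4 5\n")
        with pytest.raises(ValueError, match="frame 1"):
            read_video(path)

    def test_negative_value_names_frame(self, tmp_path):
        path = tmp_path / "neg.ppv"
        path.write_text("ppv 1 2 100.0\n\n1 2\n\n-1 2\n")
        with pytest.raises(ValueError, match="frame 1"):
            read_video(path)

    def test_csv_directory(self, tmp_path):
        d = tmp_path / "frames"
        d.mkdir()
        (d / "f0.csv").write_text("1.5,0\n0,2\n")
        (d / "f1.csv").write_text("0,0\n0,1\n")
        v = read_video(d)
        assert v.n_frames == 2
        assert v.frames[0, 0, 0] == 1.5


class TestSplitStancePhases:
    def test_all_zero_gives_empty_list(self):
        assert split_stance_phases(PressureVideo(np.zeros((10, 2, 2)))) == []

    def test_runs_of_nonzero_frames(self):
        # frame totals [0, 5, 7, 0, 0, 3, 0] -> segments of lengths 2 and 1
        totals = [0, 5, 7, 0, 0, 3, 0]
        frames = np.array([[[t]] for t in totals], dtype=float)
        segs = split_stance_phases(PressureVideo(frames))
        assert [s.n_frames for s in segs] == [2, 1]
        assert [s.segment_index for s in segs] == [0, 1]
        # nonzero frames preserved verbatim, in order
        recon = np.concatenate([s.frames for s in segs])
        assert np.array_equal(recon[:, 0, 0], [5, 7, 3])

    def test_single_nonzero_frame(self):
        frames = np.zeros((1, 2, 2))
        frames[0, 0, 0] = 1.0
        segs = split_stance_phases(PressureVideo(frames))
        assert len(segs) == 1 and segs[0].n_frames == 1


def _segments(n):
    out = []
    for i in range(n):
        frames = np.full((2, 2, 2), float(i + 1))
        out.append(StanceVideo(frames, segment_index=i))
    return out


class TestSelectRepresentatives:
    def test_ten_segments_five_groups(self):
        chosen = select_representatives(_segments(10), 5, rng_seed=0)
        assert len(chosen) == 5
        # one per contiguous group of 2
        for g, seg in enumerate(chosen):
            assert seg.segment_index in (2 * g, 2 * g + 1)

    def test_identity_when_counts_match(self):
        chosen = select_representatives(_segments(5), 5, rng_seed=3)
        assert [s.segment_index for s in chosen] == [0, 1, 2, 3, 4]

    def test_remainder_goes_to_earliest_groups_and_reproducible(self):
        segs = _segments(12)
        a = select_representatives(segs, 5, rng_seed=42)
        b = select_representatives(segs, 5, rng_seed=42)
        assert [s.segment_index for s in a] == [s.segment_index for s in b]
        # group sizes [3, 3, 2, 2, 2]
        bounds = [(0, 3), (3, 6), (6, 8), (8, 10), (10, 12)]
        for (lo, hi), seg in zip(bounds, a):
            assert lo <= seg.segment_index < hi

    def test_too_few_segments(self):
        with pytest.raises(ValueError, match="at least 5"):
            select_representatives(_segments(4), 5, rng_seed=0)


class TestCropWhiteBorder:
    def test_bounding_box(self):
        frames = np.zeros((2, 4, 4))
        frames[:, 1:3, 1:3] = 1.0
        out = crop_white_border(PressureVideo(frames))
        assert out.shape == (2, 2)
        assert np.all(out.frames == 1.0)

    def test_identity_when_borders_touched(self, rng):
        frames = rng.uniform(0.1, 1.0, size=(2, 3, 3))
        v = PressureVideo(frames)
        assert np.array_equal(crop_white_border(v).frames, frames)

    def test_union_over_frames(self):
        # frame A nonzero at row 0, frame B at row 3: all 4 rows kept
        frames = np.zeros((2, 4, 2))
        frames[0, 0, 0] = 1.0
        frames[1, 3, 1] = 1.0
        out = crop_white_border(PressureVideo(frames))
        assert out.height == 4 and out.width == 2

    def test_interior_zero_rows_kept(self):
        frames = np.zeros((1, 5, 1))
        frames[0, [0, 4], 0] = 1.0
        assert crop_white_border(PressureVideo(frames)).height == 5

    def test_idempotent(self, rng):
        frames = np.zeros((3, 8, 6))
        frames[:, 2:5, 1:4] = rng.uniform(0, 1, size=(3, 3, 3))
        once = crop_white_border(PressureVideo(frames))
        twice = crop_white_border(once)
        assert np.array_equal(once.frames, twice.frames)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="nothing to crop"):
            crop_white_border(PressureVideo(np.zeros((2, 2, 2))))


class TestDownsample:
    def test_identity_at_target_shape(self, rng):
        v = PressureVideo(rng.uniform(0, 1, size=(2, 20, 7)))
        assert downsample(v, (20, 7)) is v

    def test_uniform_field_is_fixed_point(self):
        v = PressureVideo(np.full((2, 9, 5), 3.7))
        out = downsample(v, (4, 2))
        assert np.allclose(out.frames, 3.7)

    def test_hand_computed_area_weighted_mean(self):
        v = PressureVideo(np.array([[[1.0, 2.0], [3.0, 4.0]]]))
        out = downsample(v, (1, 1))
        assert out.frames.shape == (1, 1, 1)
        assert out.frames[0, 0, 0] == pytest.approx(2.5, abs=1e-12)

    @pytest.mark.parametrize("src,tgt", [((60, 21), (20, 7)), ((13, 11), (20, 7)), ((5, 3), (2, 2))])
    def test_force_conserved_noninteger_ratios(self, rng, src, tgt):
        v = PressureVideo(rng.uniform(0, 100, size=(3, *src)), cell_area=2.0)
        out = downsample(v, tgt)
        f_in = v.frames.sum(axis=(1, 2)) * v.cell_area
        f_out = out.frames.sum(axis=(1, 2)) * out.cell_area
        assert np.allclose(f_out, f_in, rtol=1e-9)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            downsample(PressureVideo(np.ones((1, 2, 2))), (0, 1))


class TestPipeline:
    def test_full_pipeline_produces_stance_clips(self, rng):
        # a recording at native resolution (long axis first: 60x21),
        # 12 stance bursts separated by zero-pressure swing frames
        frames = []
        for burst in range(12):
            for _ in range(4):
                f = np.zeros((60, 21))
                f[10 + burst : 40 + burst, 5:16] = rng.uniform(1, 10, size=(30, 11))
                frames.append(f)
            frames.append(np.zeros((60, 21)))
        video = PressureVideo(np.array(frames))
        clips = preprocess_recording(video, n_groups=5, target=(20, 7), rng_seed=9)
        assert len(clips) == 5
        for c in clips:
            assert c.shape == (20, 7)
            assert np.all(c.frame_totals() > 0)
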