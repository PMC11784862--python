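import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efnet.avi import read_avi, write_avi
from efnet.data_io import (
    GrayVideo,
    VideoRecord,
    compute_ef,
    denormalize_frames,
    normalize_frames,
    read_manifest,
    read_video,
    write_dataset,
)

# Table-style cohort IDs used by the upstream dataset
COHORT_IDS = [
    "0X100E3B8D3280BEC5",
    "0X100E491B3CD58DE2",
    "0X100F044876B98F90",
    "0X1002E8FBACD08477",
    "0X1005D03EED19C65B",
]


def _record(video_id, ef=55.0, edv=100.0, n_frames=12, ed=0, es=5, split="TRAIN", **kw):
    esv = kw.pop("esv", edv * (1 - ef / 100.0))
    return VideoRecord(
        video_id=video_id, ef=ef, edv=edv, esv=esv, fps=50.0,
        n_frames=n_frames, ed_frame=ed, es_frame=es, split=split, **kw
    )


def _video(n_frames=12, size=16, seed=0):
    rng = np.random.default_rng(seed)
    return GrayVideo(rng.integers(0, 256, (n_frames, size, size)).astype(np.uint8))


class TestAviRoundTrip:
    def test_grayscale_stack_is_bit_exact(self, tmp_path, rng):
        frames = rng.integers(0, 256, (3, 112, 112)).astype(np.uint8)
        path = tmp_path / "clip.avi"
        write_avi(path, frames, fps=50.9)
        back, fps = read_avi(path)
        assert back.shape == (3, 112, 112)
        np.testing.assert_array_equal(back, frames)
        assert fps == pytest.approx(50.9, abs=1e-3)

    def test_odd_width_row_padding(self, tmp_path, rng):
        frames = rng.integers(0, 256, (2, 9, 11)).astype(np.uint8)
        path = tmp_path / "odd.avi"
        write_avi(path, frames)
        back, _ = read_avi(path)
        np.testing.assert_array_equal(back, frames)

    def test_equal_rgb_channels_keep_their_luma(self, tmp_path):
        frames = np.full((1, 8, 8), 200, dtype=np.uint8)
        path = tmp_path / "flat.avi"
        write_avi(path, frames)
        video = read_video(path)
        assert video.pixels.dtype == np.uint8
        assert (video.pixels == 200).all()

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_video(tmp_path / "nope.avi")

    def test_zero_frames_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_avi(tmp_path / "e.avi", np.zeros((0, 4, 4), dtype=np.uint8))


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        clip = normalize_frames(np.array([[[0.0, 127.5, 255.0]]]))
        np.testing.assert_allclose(clip.ravel(), [-1.0, 0.0, 1.0])
        assert clip.shape == (1, 1, 1, 3)

    @given(st.integers(min_value=0, max_value=255))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_is_identity(self, value):
        pixels = np.full((1, 2, 2), value, dtype=np.uint8)
        back = denormalize_frames(normalize_frames(pixels))
        np.testing.assert_allclose(back, value, atol=1e-4)

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            normalize_frames(np.zeros((1, 2, 2)), std=0.0)


class TestComputeEf:
    def test_cohort_mean_volumes(self):
        assert compute_ef(91.0, 43.3) == pytest.approx(52.417582, abs=1e-4)

    @pytest.mark.parametrize("esv,expected", [(0.0, 100.0), (80.0, 0.0)])
    def test_degenerate_volumes(self, esv, expected):
        assert compute_ef(80.0, esv) == pytest.approx(expected)

    def test_invalid_edv(self):
        with pytest.raises(ValueError):
            compute_ef(0.0, 0.0)

    @given(
        st.floats(min_value=50.0, max_value=250.0),
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.001, max_value=0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_esv(self, edv, frac, step):
        esv = edv * frac
        esv2 = min(edv, esv + step * edv)
        if esv2 > esv:
            assert compute_ef(edv, esv2) < compute_ef(edv, esv)


class TestManifest:
    def test_write_then_read_round_trips(self, tmp_path):
        splits = ["TRAIN", "TRAIN", "VAL", "TEST", "TRAIN"]
        records = [
            _record(vid, ef=50.0 + i, split=split)
            for i, (vid, split) in enumerate(zip(COHORT_IDS, splits))
        ]
        videos = [_video(seed=i) for i in range(5)]
        fl, tr = write_dataset(records, videos, tmp_path)
        back = read_manifest(fl, tr)
        assert [r.video_id for r in back] == COHORT_IDS
        for orig, got in zip(records, back):
            assert got.ef == pytest.approx(orig.ef, abs=1e-4)
            assert (got.ed_frame, got.es_frame) == (orig.ed_frame, orig.es_frame)
            assert got.split == orig.split

    def test_video_pixels_round_trip(self, tmp_path):
        video = _video(seed=7)
        rec = _record("vid0")
        write_dataset([rec], [video], tmp_path)
        back = read_video(tmp_path / "Videos" / "vid0.avi")
        np.testing.assert_array_equal(back.pixels, video.pixels)

    def test_empty_manifest(self, tmp_path):
        fl, tr = write_dataset([], [], tmp_path)
        assert read_manifest(fl, tr) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        (tmp_path / "FileList.csv").write_text("FileName,EF\na,50\n")
        (tmp_path / "T.csv").write_text("FileName,ED_Frame,ES_Frame\na,0,5\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_manifest(tmp_path / "FileList.csv", tmp_path / "T.csv")

    def test_esv_above_edv_names_offender(self, tmp_path):
        (tmp_path / "FileList.csv").write_text(
            "FileName,EF,ESV,EDV,FPS,NumberOfFrames,Split\n"
            "badvid,50.0,120.0,100.0,50,12,TRAIN\n"
        )
        (tmp_path / "T.csv").write_text("FileName,ED_Frame,ES_Frame\nbadvid,0,5\n")
        with pytest.raises(ValueError, match="badvid"):
            read_manifest(tmp_path / "FileList.csv", tmp_path / "T.csv")

    def test_ef_outside_range_rejected(self, tmp_path):
        (tmp_path / "FileList.csv").write_text(
            "FileName,EF,ESV,EDV,FPS,NumberOfFrames,Split\n"
            "hot,140.0,10.0,100.0,50,12,TRAIN\n"
        )
        (tmp_path / "T.csv").write_text("FileName,ED_Frame,ES_Frame\nhot,0,5\n")
        with pytest.raises(ValueError, match="hot"):
            read_manifest(tmp_path / "FileList.csv", tmp_path / "T.csv")

    def test_unannotated_rows_dropped_with_warning(self, tmp_path, caplog):
        records = [_record("a"), _record("b")]
        videos = [_video(seed=0), _video(seed=1)]
        fl, tr = write_dataset(records, videos, tmp_path)
        frame = pd.read_csv(tr)
        frame = frame[frame.FileName != "b"]
        frame.to_csv(tr, index=False)
        with caplog.at_level("WARNING"):
            back = read_manifest(fl, tr)
        assert [r.video_id for r in back] == ["a"]
        assert any("b" in message for message in caplog.messages)


class TestVideoRecordInvariants:
    def test_ef_volume_consistency_enforced(self):
        rec = _record("x", ef=70.0, edv=100.0, esv=50.0)  # volumes imply 50%
        with pytest.raises(ValueError, match="inconsistent"):
            rec.validate()

    def test_frame_indices_bounded(self):
        rec = _record("x", n_frames=4, ed=0, es=9)
        with pytest.raises(ValueError, match="es_frame"):
            rec.validate()

    def test_ed_es_must_differ(self):
        rec = _record("x", ed=3, es=3)
        with pytest.raises(ValueError, match="coincide"):
            rec.validate()
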