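"""Series container, I/O round trips, normalization contract, region selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import faceflow as ff
from faceflow.errors import (
    MalformedInputError,
    ParameterError,
    SchemaError,
    VocabularyError,
)


class TestSeriesInvariants:
    def test_zero_confidence_requires_zero_coords(self, scheme):
        coords = np.ones((3, scheme.n_landmarks, 2))
        conf = np.array([1.0, 0.0, 1.0])
        with pytest.raises(MalformedInputError, match="frame 1"):
            ff.LandmarkSeries("v", "a", 25.0, coords, conf)

    def test_confidence_bounds(self, scheme):
        coords = np.zeros((2, scheme.n_landmarks, 2))
        with pytest.raises(MalformedInputError):
            ff.LandmarkSeries("v", "a", 25.0, coords, np.array([0.5, 1.5]))

    def test_label_vocabulary(self, scheme):
        coords = np.zeros((1, scheme.n_landmarks, 2))
        with pytest.raises(VocabularyError):
            ff.LandmarkSeries("v", "a", 25.0, coords, np.zeros(1), label="happy")


class TestSeriesIO:
    def test_round_trip_exact(self, small_series, scheme, tmp_path):
        path = tmp_path / "s.csv"
        ff.write_series(small_series, path)
        back = ff.read_series(path, scheme)
        np.testing.assert_array_equal(back.coords, small_series.coords)
        np.testing.assert_array_equal(back.confidence, small_series.confidence)
        assert back.video_id == small_series.video_id
        assert back.animal_id == small_series.animal_id
        assert back.fps == small_series.fps
        assert back.label == small_series.label

    def test_write_read_write_byte_identical(self, small_series, scheme, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ff.write_series(small_series, p1)
        ff.write_series(ff.read_series(p1, scheme), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_generated_series_round_trip(self, scheme, tmp_path):
        template = ff.canonical_face(scheme, seed=7)
        cfg = ff.SimulationConfig(T=100, missing_rate=0.05, seed=7)
        series, _ = ff.simulate_series(cfg, template, scheme,
                                       rng=np.random.default_rng(7))
        path = tmp_path / "gen.csv"
        ff.write_series(series, path)
        back = ff.read_series(path, scheme)
        np.testing.assert_array_equal(back.coords, series.coords)

    def test_single_frame_round_trip(self, scheme, tmp_path):
        coords = np.random.default_rng(0).normal(size=(1, scheme.n_landmarks, 2))
        s = ff.LandmarkSeries("one", "a", 25.0, coords, np.ones(1))
        ff.write_series(s, tmp_path / "one.csv")
        back = ff.read_series(tmp_path / "one.csv", scheme)
        np.testing.assert_array_equal(back.coords, s.coords)

    def test_wrong_column_count_is_schema_error(self, scheme, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,conf,x1,y1\n0,1.0,1.0,2.0\n")
        with pytest.raises(SchemaError):
            ff.read_series(path, scheme)

    def test_noncontiguous_frames_named(self, small_series, scheme, tmp_path):
        path = tmp_path / "s.csv"
        ff.write_series(small_series, path)
        lines = path.read_text().splitlines()
        del lines[2]  # drop frame 1
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MalformedInputError, match="1"):
            ff.read_series(path, scheme)

    def test_zero_conf_nonzero_coords_rejected(self, scheme, tmp_path):
        n = scheme.n_landmarks
        row = ["0", "0.0"] + ["1.0", "2.0"] * n
        header = "frame,conf," + ",".join(
            f"x{j},y{j}" for j in range(1, n + 1)
        )
        path = tmp_path / "z.csv"
        path.write_text(header + "\n" + ",".join(row) + "\n")
        with pytest.raises(MalformedInputError):
            ff.read_series(path, scheme)


class TestNormalize:
    def test_contract_iod_one_centroid_zero(self, small_series, scheme):
        ns = ff.normalize_series(small_series, scheme)
        a, b = scheme.iod_pair
        for t in range(ns.n_frames):
            if ns.empty_frames[t]:
                assert not ns.coords[t].any()
                continue
            frame = ns.coords[t]
            assert np.linalg.norm(frame[a] - frame[b]) == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.norm(frame.mean(axis=0)) <= 1e-9

    def test_hand_computed_example(self, scheme):
        # iod endpoints at (0,0) and (10,0); put every other landmark at (5,0)
        # so the centroid is (5,0); after normalization the endpoints must sit
        # at (-0.5,0) and (+0.5,0).
        a, b = scheme.iod_pair
        coords = np.zeros((1, scheme.n_landmarks, 2))
        coords[0, :, 0] = 5.0
        coords[0, a] = [0.0, 0.0]
        coords[0, b] = [10.0, 0.0]
        s = ff.LandmarkSeries("v", "x", 25.0, coords, np.ones(1))
        ns = ff.normalize_series(s, scheme)
        np.testing.assert_allclose(ns.coords[0, a], [-0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(ns.coords[0, b], [0.5, 0.0], atol=1e-12)

    def test_idempotent(self, small_series, scheme):
        once = ff.normalize_series(small_series, scheme)
        twice = ff.normalize_series(once, scheme)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)

    def test_degenerate_iod_demoted_to_empty(self, scheme):
        coords = np.random.default_rng(3).normal(size=(2, scheme.n_landmarks, 2))
        a, b = scheme.iod_pair
        coords[1, b] = coords[1, a]  # IOD zero in frame 1
        s = ff.LandmarkSeries("v", "x", 25.0, coords, np.ones(2))
        ns = ff.normalize_series(s, scheme)
        assert ns.empty_frames[1]
        assert not ns.coords[1].any()
        assert not ns.empty_frames[0]

    def test_empty_frame_conserved(self, small_series, scheme):
        ns = ff.normalize_series(small_series, scheme)
        np.testing.assert_array_equal(ns.empty_frames, small_series.empty_frames)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_normalization_contract_random_series(self, seed, scheme):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=30.0, size=(4, scheme.n_landmarks, 2)) + 100.0
        s = ff.LandmarkSeries("v", "x", 25.0, coords, np.ones(4))
        ns = ff.normalize_series(s, scheme)
        a, b = scheme.iod_pair
        for t in range(4):
            if ns.empty_frames[t]:
                continue
            d = np.linalg.norm(ns.coords[t, a] - ns.coords[t, b])
            assert d == pytest.approx(1.0, abs=1e-9)


class TestSelectRegion:
    def test_series_reduction(self, normalized_series, scheme):
        reduced = ff.select_region(normalized_series, "eyes", scheme)
        assert reduced.coords.shape[1] == len(scheme.region_indices("eyes"))

    def test_window_column_count(self, scheme, rng):
        win = rng.normal(size=(5, 2 * scheme.n_landmarks))
        out = ff.select_region(win, "ears", scheme)
        assert out.shape == (5, 2 * len(scheme.region_indices("ears")))

    def test_idempotent_on_window(self, scheme, rng):
        win = rng.normal(size=(5, 2 * scheme.n_landmarks))
        once = ff.select_region(win, "eyes", scheme)
        np.testing.assert_array_equal(ff.select_region(once, "eyes", scheme), once)

    def test_unknown_region(self, normalized_series, scheme):
        with pytest.raises(VocabularyError):
            ff.select_region(normalized_series, "tail", scheme)

    def test_empty_frames_stay_empty(self, normalized_series, scheme):
        reduced = ff.select_region(normalized_series, "nose_mouth", scheme)
        np.testing.assert_array_equal(
            reduced.empty_frames, normalized_series.empty_frames
        )


class TestEvents:
    def test_seconds_conversion_five_frame_section(self):
        assert ff.seconds_to_frames(0.4, 0.6, 25.0) == (10, 14)

    @pytest.mark.parametrize(
        "start_s,end_s,fps,expected",
        [
            (0.0, 0.2, 25.0, (0, 4)),
            (1.0, 1.2, 25.0, (25, 29)),
            (0.4, 0.6, 25.0, (10, 14)),
        ],
    )
    def test_seconds_conversion_sections(self, start_s, end_s, fps, expected):
        assert ff.seconds_to_frames(start_s, end_s, fps) == expected

    def test_read_frame_based(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "variable,category,start_frame,end_frame\n"
            "Blink (AU145),UpperFaceAU,10,14\n"
        )
        events = ff.read_events(path)
        assert events[0].start_frame == 10 and events[0].end_frame == 14

    def test_read_seconds_based_matches_frames(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "variable,category,start_s,end_s\nBlink (AU145),UpperFaceAU,0.4,0.6\n"
        )
        (event,) = ff.read_events(path, fps=25.0)
        assert (event.start_frame, event.end_frame) == (10, 14)

    def test_reversed_interval_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "variable,category,start_s,end_s\nBlink (AU145),UpperFaceAU,0.6,0.4\n"
        )
        with pytest.raises(MalformedInputError):
            ff.read_events(path, fps=25.0)

    def test_unknown_category_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "variable,category,start_frame,end_frame\nBlink (AU145),BodyMove,0,4\n"
        )
        with pytest.raises(VocabularyError):
            ff.read_events(path)

    def test_write_read_round_trip(self, tmp_path):
        events = [
            ff.EventAnnotation(0, 4, "Blink (AU145)", "UpperFaceAU"),
            ff.EventAnnotation(10, 14, "Nose Lick (AD137)", "ActionDescriptor"),
        ]
        ff.write_events(events, tmp_path / "e.csv")
        assert ff.read_events(tmp_path / "e.csv") == events

    def test_seconds_requires_fps(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "variable,category,start_s,end_s\nBlink (AU145),UpperFaceAU,0.4,0.6\n"
        )
        with pytest.raises(ParameterError):
            ff.read_events(path)
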