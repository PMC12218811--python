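"""Post-processing unit oracles and the scoring chain's structural behaviour."""

import numpy as np
import pytest

import faceflow as ff
from faceflow.errors import DataLeakError, ParameterError
from faceflow.events import ScoreTrack, _runs


def _track(agg, scored=None, variable="Blink (AU145)"):
    agg = np.asarray(agg, dtype=float)
    scored = np.ones(len(agg), dtype=bool) if scored is None else np.asarray(scored)
    return ScoreTrack(
        channel_errors=agg[:, None],
        scored=scored,
        thresholds=np.array([1.0]),
        aggregate=agg.copy(),
        variable=variable,
    )


class TestSmoothing:
    def _err_track(self, values, scored=None):
        values = np.asarray(values, dtype=float)
        scored = np.ones(len(values), dtype=bool) if scored is None \
            else np.asarray(scored)
        return ScoreTrack(channel_errors=values[:, None], scored=scored)

    def test_recursion_hand_case(self):
        t = ff.smooth_scores(self._err_track([0.0, 1.0, 0.0]), alpha=0.5)
        np.testing.assert_allclose(t.channel_errors[:, 0], [0.0, 0.5, 0.25])

    def test_constant_fixed_point(self):
        t = ff.smooth_scores(self._err_track([3.0] * 6), alpha=0.3)
        np.testing.assert_allclose(t.channel_errors[:, 0], 3.0)

    def test_alpha_one_identity(self):
        vals = [0.1, 0.9, 0.4, 0.7]
        t = ff.smooth_scores(self._err_track(vals), alpha=1.0)
        np.testing.assert_allclose(t.channel_errors[:, 0], vals)

    def test_gap_resets_recursion(self):
        scored = np.array([True, True, False, True, True])
        t = ff.smooth_scores(self._err_track([0.0, 1.0, 0.0, 0.0, 1.0], scored),
                             alpha=0.5)
        # second segment starts fresh at frame 3
        assert t.channel_errors[3, 0] == 0.0
        assert t.channel_errors[4, 0] == 0.5

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError):
            ff.smooth_scores(self._err_track([1.0]), alpha=0.0)


class TestThresholds:
    def test_hand_case_population_sd(self):
        thr = ff.compute_thresholds(np.array([[0.0], [2.0]]), sigma_k=3.0)
        assert thr[0] == pytest.approx(4.0)

    def test_constant_channel_floor(self):
        thr = ff.compute_thresholds(np.full((10, 1), 0.7), sigma_k=3.0)
        assert thr[0] == pytest.approx(0.7 + 1e-8)

    def test_monotone_in_sigma(self):
        errs = np.random.default_rng(0).random((50, 4))
        t2 = ff.compute_thresholds(errs, 2.0)
        t3 = ff.compute_thresholds(errs, 3.0)
        assert np.all(t3 >= t2)

    def test_flag_count_monotone_in_sigma(self):
        rng = np.random.default_rng(1)
        errs = rng.random((100, 3))
        track = ScoreTrack(channel_errors=errs, scored=np.ones(100, dtype=bool))
        counts = []
        for k in (1.0, 2.0, 3.0):
            thr = ff.compute_thresholds(errs, k)
            counts.append(int(ff.apply_thresholds(track, thr).flags().sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            ff.compute_thresholds(np.array([[1.0]]), 3.0)


class TestMaskEdges:
    def test_margin_zero_identity(self):
        t = _track([0.5, -0.2, 0.8])
        out = ff.mask_edges(t, 0)
        np.testing.assert_array_equal(out.aggregate, t.aggregate)

    def test_margin_covers_whole_segment(self):
        t = _track([0.5, 0.9, 0.8])
        out = ff.mask_edges(t, 5)
        np.testing.assert_allclose(out.aggregate, 0.5)

    def test_edge_spike_suppressed_center_survives(self):
        agg = np.full(20, -0.5)
        agg[1] = 3.0
        agg[10] = 3.0
        out = ff.mask_edges(_track(agg), 2)
        assert out.aggregate[1] == -0.5  # edge spike gone
        assert out.aggregate[10] == 3.0  # central spike kept

    def test_each_scored_segment_masked(self):
        scored = np.array([True] * 5 + [False] * 2 + [True] * 5)
        agg = np.where(scored, 1.0, 0.0)
        agg[0] = agg[4] = agg[7] = agg[11] = 5.0
        out = ff.mask_edges(_track(agg, scored), 1)
        assert out.aggregate[0] == out.aggregate[4] == 1.0
        assert out.aggregate[7] == out.aggregate[11] == 1.0


class TestSequences:
    def test_run_length_hand_case(self):
        t = _track([-1.0, 0.5, 0.5, -1.0, 0.5])
        seqs = ff.detect_sequences(t, ff.DetectorConfig(prune_p=0.0))
        assert [(q.start_frame, q.end_frame) for q in seqs] == [(1, 2), (4, 4)]

    def test_no_flags_empty(self):
        seqs = ff.detect_sequences(_track([-1.0, -0.5]), ff.DetectorConfig())
        assert seqs == []

    def test_flags_reconstruct_from_sequences(self, rng):
        for _ in range(30):
            flags = rng.random(50) > 0.6
            agg = np.where(flags, 1.0, -1.0)
            seqs = ff.detect_sequences(_track(agg), ff.DetectorConfig(prune_p=0.0))
            rebuilt = np.zeros(50, dtype=bool)
            for q in seqs:
                rebuilt[q.start_frame : q.end_frame + 1] = True
            np.testing.assert_array_equal(rebuilt, flags)

    def test_peak_is_max_inside_run(self):
        t = _track([-1.0, 0.2, 0.9, 0.4, -1.0])
        (q,) = ff.detect_sequences(t, ff.DetectorConfig(prune_p=0.0))
        assert q.peak_score == pytest.approx(0.9)


class TestPruning:
    def _seqs(self, peaks):
        return [ff.AnomalySequence(10 * i, 10 * i + 4, peak_score=p)
                for i, p in enumerate(peaks)]

    def test_hand_case_keeps_two(self):
        kept = ff.prune_sequences(self._seqs([1.0, 0.5, 0.48]), prune_p=0.13)
        assert [q.peak_score for q in kept] == [1.0, 0.5]

    def test_single_sequence_kept(self):
        kept = ff.prune_sequences(self._seqs([0.2]), prune_p=0.13)
        assert len(kept) == 1

    def test_p_zero_keeps_all(self):
        kept = ff.prune_sequences(self._seqs([1.0, 0.9, 0.1]), prune_p=0.0)
        assert len(kept) == 3

    def test_highest_peak_always_survives(self, rng):
        for _ in range(20):
            peaks = rng.random(rng.integers(1, 10)).tolist()
            kept = ff.prune_sequences(self._seqs(peaks), prune_p=0.13)
            assert max(peaks) in [q.peak_score for q in kept]

    def test_flat_plateau_survives_before_sharp_drop(self):
        # several similar peaks followed by a sharp drop to the noise floor:
        # the plateau must survive, the floor must go
        kept = ff.prune_sequences(self._seqs([2.0, 1.9, 1.85, 0.2, 0.19]),
                                  prune_p=0.13)
        assert [q.peak_score for q in kept] == [2.0, 1.9, 1.85, 0.2]

    def test_positional_order_restored(self):
        seqs = self._seqs([0.5, 1.0, 0.48])
        kept = ff.prune_sequences(seqs, prune_p=0.13)
        assert [q.start_frame for q in kept] == sorted(q.start_frame for q in kept)


@pytest.fixture(scope="module")
def tiny_detector(scheme):
    cfg = ff.DetectorConfig.fast("Blink (AU145)", seed=0, epochs=8, L=15)
    tpl = ff.canonical_face(scheme, seed=50)
    sim = ff.SimulationConfig(T=120, seed=5, missing_rate=0.0)
    series, _ = ff.simulate_series(sim, tpl, scheme,
                                   rng=np.random.default_rng(5))
    series = ff.normalize_series(series, scheme)
    ws = ff.normal_windows_for_variable([series], {}, cfg, scheme)
    det = ff.train_autoencoder(ws, cfg)
    return det, series


class TestScoringChain:
    def test_reconstruction_shape(self, tiny_detector):
        det, series = tiny_detector
        ws = ff.slide_windows(series, det.config.window_spec(
            ff.default_scheme()), ff.default_scheme())
        recon = det.reconstruct(ws.windows[:3])
        assert recon.shape == ws.windows[:3].shape

    def test_window_error_matches_brute_force(self, tiny_detector):
        det, series = tiny_detector
        scheme = ff.default_scheme()
        ws = ff.slide_windows(series, det.config.window_spec(scheme), scheme)
        win = ws.windows[:5]
        recon = det.reconstruct(win)
        expected = np.array([
            [np.mean(np.abs(win[i, :, c] - recon[i, :, c]))
             for c in range(win.shape[2])]
            for i in range(len(win))
        ])
        np.testing.assert_allclose(det.window_errors(win), expected, atol=1e-12)

    def test_training_series_mostly_subthreshold(self, tiny_detector, scheme):
        det, series = tiny_detector
        track = ff.score_series(det, series, scheme)
        track = ff.smooth_scores(track, det.config.ewma_alpha)
        track = ff.apply_thresholds(track, det.thresholds)
        agg = track.aggregate[track.scored]
        assert np.mean(agg < 0) >= 0.95

    def test_all_empty_series_empty_track(self, tiny_detector, scheme):
        det, _ = tiny_detector
        coords = np.zeros((30, scheme.n_landmarks, 2))
        empty = ff.LandmarkSeries("e", "a", 25.0, coords, np.zeros(30),
                                  normalized=True)
        track = ff.score_series(det, empty, scheme)
        assert not track.scored.any()

    def test_chain_deterministic_post_training(self, tiny_detector, scheme):
        det, series = tiny_detector
        s1, _ = ff.detect_events({det.config.variable: det}, series, scheme)
        s2, _ = ff.detect_events({det.config.variable: det}, series, scheme)
        assert s1 == s2

    def test_missing_model_rejected(self, tiny_detector, scheme):
        det, series = tiny_detector
        with pytest.raises(ParameterError):
            ff.detect_events({det.config.variable: det}, series, scheme,
                             variables=["Nose Lick (AD137)"])

    def test_data_leak_guard(self, tiny_detector, scheme):
        det, series = tiny_detector
        cfg = det.config
        ws = ff.slide_windows(series, cfg.window_spec(scheme), scheme)
        leak = [ff.EventAnnotation(5, 9, cfg.variable, "UpperFaceAU")]
        with pytest.raises(DataLeakError):
            ff.train_autoencoder(ws, cfg, truth=leak)


class TestEvaluateVariables:
    def test_rare_variables_excluded(self, tiny_detector, scheme):
        det, series = tiny_detector
        var = det.config.variable
        truth = {series.video_id: [
            ff.EventAnnotation(5 * k, 5 * k + 4, var, "UpperFaceAU")
            for k in range(5)  # only 5 occurrences
        ]}
        out = ff.evaluate_variables({var: det}, [series], truth, scheme,
                                    min_occurrences=20)
        assert out == {}
        out = ff.evaluate_variables({var: det}, [series], truth, scheme,
                                    min_occurrences=5)
        assert set(out) == {var}
        assert out[var].tp + out[var].fn == 5


class TestIntensity:
    def test_single_track_is_own_normalization(self):
        t = _track([0.0, 1.0, 3.0, 2.0])
        out = ff.aggregate_intensity({"v": t})
        np.testing.assert_allclose(out, [0.0, 1 / 3, 1.0, 2 / 3])

    def test_degenerate_second_track_ignored(self):
        t1 = _track([0.0, 1.0, 2.0])
        t2 = _track([0.5, 0.5, 0.5])  # constant: min-max degenerate, stays 0
        out = ff.aggregate_intensity({"a": t1, "b": t2})
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_codomain(self, rng):
        tracks = {
            f"v{k}": _track(rng.normal(size=40)) for k in range(3)
        }
        out = ff.aggregate_intensity(tracks)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)

    def test_runs_helper(self):
        assert _runs(np.array([0, 1, 1, 0, 1], dtype=bool)) == [(1, 2), (4, 4)]
        assert _runs(np.zeros(4, dtype=bool)) == []
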