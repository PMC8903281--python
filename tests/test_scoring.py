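"""Perception and production scoring against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batkit import make_beat_grid
from batkit.scoring import (
    PerceptionResponse,
    TapTrial,
    aggregate_participant,
    asynchrony_score,
    cdev_score,
    cov_score,
    match_taps_to_beats,
    percent_correct,
    score_taps_frame,
    score_trial,
    validate_trial,
)


def trial(taps, pid="p", ex="g120", rep=1):
    return TapTrial(pid, ex, rep, np.asarray(taps, dtype=float))


def brute_force_nearest(taps, beats):
    """O(n*m) oracle: scan every beat for each tap, earlier beat wins ties."""
    out = []
    for t in taps:
        dists = [abs(t - b) for b in beats]
        out.append(int(np.argmin(dists)))  # argmin returns the first minimum
    return np.array(out)


class TestPercentCorrect:
    def resp(self, judgment, truth):
        return PerceptionResponse("p", 0, judgment, truth)

    def test_all_correct_and_fractions(self):
        perfect = [self.resp(True, True)] * 17
        assert percent_correct(perfect) == 100.0
        mixed = [self.resp(True, True)] * 12 + [self.resp(False, True)] * 5
        assert percent_correct(mixed) == pytest.approx(100 * 12 / 17)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_correct([])


class TestNearestBeatMatching:
    def test_simple_and_tie_cases(self):
        assert match_taps_to_beats([0.1], [0.0, 0.5]).tolist() == [0]
        # exactly halfway: earlier beat wins
        assert match_taps_to_beats([0.25], [0.0, 0.5]).tolist() == [0]
        assert match_taps_to_beats([0.26], [0.0, 0.5]).tolist() == [1]

    def test_taps_outside_span_match_terminal_beats(self):
        idx = match_taps_to_beats([-1.0, 99.0], [0.0, 0.5, 1.0])
        assert idx.tolist() == [0, 2]

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            beats = np.sort(rng.uniform(0, 10, size=rng.integers(2, 21)))
            beats = np.unique(beats)
            taps = np.sort(rng.uniform(-1, 11, size=rng.integers(1, 51)))
            np.testing.assert_array_equal(
                match_taps_to_beats(taps, beats), brute_force_nearest(taps, beats)
            )

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            match_taps_to_beats([], [0.0, 1.0])


class TestAsynchrony:
    def test_perfect_taps_score_zero(self, grid_120bpm):
        assert asynchrony_score(trial(grid_120bpm.beat_onsets), grid_120bpm) == 0.0

    def test_constant_offset(self, grid_120bpm):
        taps = grid_120bpm.beat_onsets + 0.05
        assert asynchrony_score(trial(taps), grid_120bpm) == pytest.approx(0.1)

    def test_hand_computed_example(self):
        grid = make_beat_grid(120, 3, 0.0)  # beats 0, 0.5, 1.0
        t = trial([0.1, 0.48, 1.02])
        # |0.1-0| + |0.48-0.5| + |1.02-1.0| = 0.14; /3/0.5
        assert asynchrony_score(t, grid) == pytest.approx(0.14 / 3 / 0.5)

    def test_normalized_asynchrony_bounded_by_half_within_span(self, rng, grid_120bpm):
        lo, hi = grid_120bpm.beat_onsets[0], grid_120bpm.beat_onsets[-1]
        taps = np.sort(rng.uniform(lo, hi, size=50))
        idx = match_taps_to_beats(taps, grid_120bpm.beat_onsets)
        per_tap = np.abs(taps - grid_120bpm.beat_onsets[idx]) / grid_120bpm.mean_ibi
        assert np.all(per_tap <= 0.5 + 1e-12)


class TestCdev:
    def test_matching_tempo_scores_zero(self, grid_120bpm):
        assert cdev_score(trial(grid_120bpm.beat_onsets), grid_120bpm) == 0.0

    def test_constant_period_error(self, grid_120bpm):
        taps = np.arange(10) * 0.5 * 1.02
        assert cdev_score(trial(taps), grid_120bpm) == pytest.approx(0.02)

    def test_per_interval_vs_aggregate_variants(self, grid_120bpm):
        taps = np.array([0.0, 0.45, 1.0])  # IRIs 0.45, 0.55; mean IBI 0.5
        t = trial(taps)
        assert cdev_score(t, grid_120bpm) == pytest.approx((0.05 + 0.05) / 2 / 0.5)
        # fast and slow intervals cancel in the aggregate reading
        assert cdev_score(t, grid_120bpm, variant="aggregate") == pytest.approx(0.0)

    def test_too_few_taps_is_missing(self, grid_120bpm):
        assert np.isnan(cdev_score(trial([1.0]), grid_120bpm))


class TestCov:
    def test_constant_iris_score_zero(self):
        assert cov_score(trial([0.0, 0.5, 1.0, 1.5])) == 0.0

    def test_sample_sd_convention(self):
        t = trial([0.0, 0.4, 1.0])  # IRIs 0.4, 0.6: sample SD 0.1414..., mean 0.5
        assert cov_score(t) == pytest.approx(np.std([0.4, 0.6], ddof=1) / 0.5)

    def test_too_few_taps_is_missing(self):
        assert np.isnan(cov_score(trial([0.0, 0.5])))


class TestScaleInvariance:
    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_all_scores_invariant_under_joint_time_rescaling(self, scale):
        rng = np.random.default_rng(7)
        grid = make_beat_grid(110, 12, 0.2)
        taps = np.sort(grid.beat_onsets + rng.normal(0, 0.05, grid.n_beats))
        scaled_grid = make_beat_grid(110 / scale, 12, 0.2 * scale)
        t, ts = trial(taps), trial(taps * scale)
        assert asynchrony_score(ts, scaled_grid) == pytest.approx(
            asynchrony_score(t, grid), rel=1e-9
        )
        assert cdev_score(ts, scaled_grid) == pytest.approx(
            cdev_score(t, grid), rel=1e-9
        )
        assert cov_score(ts) == pytest.approx(cov_score(t), rel=1e-9)


class TestValidateTrial:
    def test_boundaries_and_reasons(self, grid_120bpm):
        assert validate_trial(trial([1.0]), grid_120bpm).reason == "too_few_taps"
        assert validate_trial(trial([1, 2, 3, 4.0]), grid_120bpm).valid  # inclusive
        v = validate_trial(
            trial([0.1, 0.2, 0.3, 0.4]), grid_120bpm, listen_window=5.0
        )
        assert v.reason == "no_taps_after_listen_window"

    def test_invalid_trial_scores_missing_not_zero(self, grid_120bpm):
        scores = score_trial(trial([1.0]), grid_120bpm)
        assert np.isnan(scores["asynchrony"]) and np.isnan(scores["cov"])


class TestAggregateParticipant:
    def make_resp(self, n_correct, n_total):
        return [
            PerceptionResponse("p", i, i < n_correct, True) for i in range(n_total)
        ]

    def test_two_stage_averaging_weights_excerpts_equally(self):
        ga = make_beat_grid(120, 10, 0.0, excerpt_id="A")
        gb = make_beat_grid(120, 10, 0.0, excerpt_id="B")
        # constant tap offsets of {0.1, 0.3} IBI on A and {0.2, 0.2} IBI on B
        trials = [
            (trial(ga.beat_onsets + 0.10 * 0.5, ex="A", rep=1), ga),
            (trial(ga.beat_onsets + 0.30 * 0.5, ex="A", rep=2), ga),
            (trial(gb.beat_onsets + 0.20 * 0.5, ex="B", rep=1), gb),
            (trial(gb.beat_onsets + 0.20 * 0.5, ex="B", rep=2), gb),
        ]
        scores = aggregate_participant("p", trials, self.make_resp(10, 17))
        assert scores.asynchrony == pytest.approx(0.2)
        assert scores.n_valid_trials == 4

    def test_lone_valid_repetition_represents_its_excerpt(self):
        ga = make_beat_grid(120, 10, 0.0, excerpt_id="A")
        trials = [
            (trial(ga.beat_onsets + 0.05, ex="A", rep=1), ga),
            (trial([1.0], ex="A", rep=2), ga),  # invalid: too few taps
        ]
        scores = aggregate_participant("p", trials, self.make_resp(17, 17))
        assert scores.asynchrony == pytest.approx(0.1)
        assert scores.n_valid_trials == 1

    def test_participant_without_valid_trials_is_excluded(self, grid_120bpm):
        with pytest.raises(ValueError, match="excluded"):
            aggregate_participant(
                "p", [(trial([1.0]), grid_120bpm)], self.make_resp(17, 17)
            )


class TestVectorizedScoring:
    def test_frame_scoring_matches_per_trial_scoring(self, rng):
        grids = {
            f"e{i}": make_beat_grid(90 + 15 * i, 12, 0.3, excerpt_id=f"e{i}")
            for i in range(3)
        }
        rows = []
        expected = {}
        for pid in ("a", "b"):
            for ex, grid in grids.items():
                for rep in (1, 2):
                    taps = np.sort(
                        grid.beat_onsets + rng.normal(0, 0.06, grid.n_beats)
                    )
                    t = TapTrial(pid, ex, rep, taps)
                    expected[(pid, ex, rep)] = score_trial(t, grid)
                    rows += [
                        {
                            "participant_id": pid,
                            "excerpt_id": ex,
                            "repetition": rep,
                            "tap_onset_s": x,
                        }
                        for x in taps
                    ]
        scored = score_taps_frame(pd.DataFrame(rows), grids)
        for _, r in scored.iterrows():
            exp = expected[(r["participant_id"], r["excerpt_id"], r["repetition"])]
            for col in ("asynchrony", "cdev", "cov"):
                assert r[col] == pytest.approx(exp[col], rel=1e-9)

    def test_input_order_independence(self, rng, grid_120bpm):
        taps = np.sort(grid_120bpm.beat_onsets + rng.normal(0, 0.05, 21))
        rows = pd.DataFrame(
            {
                "participant_id": "p",
                "excerpt_id": "g120",
                "repetition": 1,
                "tap_onset_s": taps,
            }
        )
        shuffled = rows.sample(frac=1.0, random_state=3)
        a = score_taps_frame(rows, {"g120": grid_120bpm})
        b = score_taps_frame(shuffled, {"g120": grid_120bpm})
        pd.testing.assert_frame_equal(a, b)
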