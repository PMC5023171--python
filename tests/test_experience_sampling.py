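"""Cursor mapping, pre-rating windows and the three concordance analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from spontaffect import decoding, experience_sampling as es, synthetic_data as syn
from spontaffect.datatypes import EMOTIONS, ScoreMatrix

LAYOUT = es.DEFAULT_LAYOUT


def trial(mean_scores, reported, event_id=0):
    return es.TrialWindow(event_id, 0, 5, np.asarray(mean_scores, float), reported)


class TestCursorMapping:
    def test_center_reads_neutral(self):
        reading = es.map_cursor_to_label(0.0, 0.0)
        assert EMOTIONS[reading.label] == "neutral"

    def test_relief_sector_ring3_reads_content(self):
        # relief occupies sector 0; aim at its center, middle of ring 3
        theta = math.radians(0.5 * LAYOUT.sector_width_deg)
        r = LAYOUT.neutral_radius + 2.5 * LAYOUT.ring_width
        reading = es.map_cursor_to_label(r * math.cos(theta), r * math.sin(theta))
        assert EMOTIONS[reading.label] == "content"
        assert reading.intensity == 3
        assert not reading.flagged

    def test_sector_boundary_flagged_lower_sector(self):
        theta = math.radians(LAYOUT.sector_width_deg)  # exact boundary 0|1
        r = LAYOUT.neutral_radius + 1.5 * LAYOUT.ring_width
        reading = es.map_cursor_to_label(r * math.cos(theta), r * math.sin(theta))
        assert reading.flagged
        assert EMOTIONS[reading.label] == "content"  # relief, the lower sector

    def test_off_vocabulary_term_dropped(self):
        sector = LAYOUT.terms.index("love")
        theta = math.radians((sector + 0.5) * LAYOUT.sector_width_deg)
        r = LAYOUT.neutral_radius + 0.5 * LAYOUT.ring_width
        reading = es.map_cursor_to_label(r * math.cos(theta), r * math.sin(theta))
        assert reading.label is None and reading.flagged

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="bounds"):
            es.map_cursor_to_label(2.0, 2.0)

    @pytest.mark.parametrize("category", EMOTIONS)
    @pytest.mark.parametrize("intensity", [1, 2, 3, 4])
    def test_placement_round_trip(self, category, intensity, rng):
        x, y = es.cursor_position(category, intensity, rng)
        reading = es.map_cursor_to_label(x, y)
        assert EMOTIONS[reading.label] == category
        if category != "neutral":
            assert reading.intensity == intensity


class TestWindowScores:
    def _scores(self, T=100, tr=2.0):
        return ScoreMatrix(np.tile(np.arange(7, dtype=float), (T, 1)), tr_seconds=tr)

    def test_default_window_is_five_volumes(self):
        sm = self._scores()
        events = pd.DataFrame({"time_s": [40.0], "label": ["fear"]})
        (tw,) = es.window_scores(sm, events)
        assert tw.stop - tw.start == 5
        assert tw.stop == 20  # rating onset volume, exclusive

    def test_constant_scores_window_mean(self):
        sm = self._scores()
        events = pd.DataFrame({"time_s": [60.0], "label": ["sad"]})
        (tw,) = es.window_scores(sm, events)
        assert np.allclose(tw.mean_scores, np.arange(7))

    def test_longer_window_uses_more_volumes(self):
        sm = self._scores()
        events = pd.DataFrame({"time_s": [60.0], "label": ["sad"]})
        (tw,) = es.window_scores(sm, events, window_s=20.0)
        assert tw.stop - tw.start == 10

    def test_early_event_dropped_with_warning(self):
        sm = self._scores()
        events = pd.DataFrame({"time_s": [4.0, 60.0], "label": ["sad", "fear"]})
        with pytest.warns(UserWarning):
            trials = es.window_scores(sm, events)
        assert len(trials) == 1


class TestCongruenceContrast:
    def test_perfect_decoder_one_hot(self):
        trials_by_subject = []
        for _ in range(6):
            trials = []
            for reported in range(7):
                onehot = np.zeros(7)
                onehot[reported] = 1.0
                trials.append(trial(onehot, reported))
            trials_by_subject.append(trials)
        res = es.congruence_contrast(trials_by_subject)
        assert np.allclose(res.congruent_means, 1.0)
        assert np.allclose(res.incongruent_means, 0.0)
        assert res.congruent_test.z > 0

    def test_weighted_decomposition_identity(self, rng):
        trials = [trial(rng.standard_normal(7), int(rng.integers(7))) for _ in range(20)]
        res = es.congruence_contrast([trials, trials, trials])
        for c, i in zip(res.congruent_means, res.incongruent_means):
            grand = np.mean([t.mean_scores.mean() for t in trials])
            assert (c + 6 * i) / 7 == pytest.approx(grand)

    def test_empty_subject_excluded(self, rng):
        trials = [trial(rng.standard_normal(7), 2) for _ in range(5)]
        with pytest.warns(UserWarning):
            res = es.congruence_contrast([trials, [], trials])
        assert res.n_excluded == 1
        assert res.congruent_means.size == 2


class TestTrialwiseAccuracy:
    def test_uniform_marginals_chance_is_one_seventh(self, rng):
        trials = []
        for reported in range(7):
            for decoded in range(7):
                onehot = np.zeros(7)
                onehot[decoded] = 1.0
                trials.append(trial(onehot, reported))
        res = es.trialwise_accuracy(trials)
        assert res.chance == pytest.approx(1 / 7)
        assert res.accuracy == pytest.approx(1 / 7)

    def test_degenerate_single_category(self):
        onehot = np.zeros(7)
        onehot[3] = 1.0
        res = es.trialwise_accuracy([trial(onehot, 3)] * 10)
        assert res.accuracy == 1.0 and res.chance == 1.0 and res.pvalue == 1.0

    def test_hand_marginal_product(self):
        # reports half cat0/half cat1; decoder likewise → chance 0.5
        trials = []
        for reported, decoded in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            onehot = np.zeros(7)
            onehot[decoded] = 1.0
            trials.append(trial(onehot, reported))
        res = es.trialwise_accuracy(trials)
        assert res.chance == pytest.approx(0.5)
        assert res.confusion[0, 1] == 1

    def test_accuracy_monotone_in_congruence(self, small_weights):
        accs = []
        for congruence in (0.2, 0.5, 0.8):
            hits = total = 0
            for rep in range(3):
                ts, events = syn.generate_experience_sampling(
                    small_weights, n_events=30, congruence=congruence,
                    seed=900 + rep, amplitude=10.0,
                )
                sm, _, _ = decoding.decode_subject(ts, small_weights)
                trials = es.window_scores(sm, events)
                hits += sum(t.decoded == t.reported for t in trials)
                total += len(trials)
            accs.append(hits / total)
        assert accs[0] < accs[1] < accs[2]


class TestFrequencyCorrelation:
    def test_perfect_agreement_clipped(self, rng):
        trials_by_subject = []
        for _ in range(5):
            trials = []
            for reported in [0, 0, 1, 2, 2, 2, 5]:
                onehot = np.zeros(7)
                onehot[reported] = 1.0
                trials.append(trial(onehot, reported))
            trials_by_subject.append(trials)
        res = es.frequency_correlation(trials_by_subject)
        assert np.allclose(res.per_subject_r, 1.0)
        assert res.n_clipped == 5
        assert res.mean_r == pytest.approx(1.0, abs=1e-6)

    def test_independent_labels_near_zero(self, rng):
        means = []
        for rep in range(10):
            trials_by_subject = []
            for _ in range(12):
                trials = []
                for _ in range(40):
                    onehot = np.zeros(7)
                    onehot[int(rng.integers(7))] = 1.0
                    trials.append(trial(onehot, int(rng.integers(7))))
                trials_by_subject.append(trials)
            means.append(es.frequency_correlation(trials_by_subject).mean_r)
        assert abs(np.mean(means)) < 0.1

    def test_too_few_subjects_rejected(self, rng):
        trials = [trial(rng.standard_normal(7), 1), trial(rng.standard_normal(7), 2)]
        with pytest.raises(ValueError):
            es.frequency_correlation([trials])
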