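"""Generator contracts: supports, chains, noise structure, determinism."""

import numpy as np
import pytest

from spontaffect import decoding, synthetic_data as syn
from spontaffect.datatypes import EMOTIONS, N_EMOTIONS, HiddenStateSequence


def lag1_autocorr(x):
    x = x - x.mean(axis=0)
    num = (x[:-1] * x[1:]).sum(axis=0)
    den = (x * x).sum(axis=0)
    return num / den


class TestWeightMaps:
    def test_disjoint_supports(self):
        wms = syn.generate_weight_maps(n_voxels=100, sparsity=0.1, overlap=0.0, seed=1)
        supports = [set(np.flatnonzero(row)) for row in wms.coefficients]
        assert all(len(s) == 10 for s in supports)
        for i in range(N_EMOTIONS):
            for j in range(i + 1, N_EMOTIONS):
                assert not supports[i] & supports[j]

    def test_full_overlap_dense(self):
        wms = syn.generate_weight_maps(n_voxels=7, sparsity=1.0, overlap=1.0, seed=2)
        assert np.all(wms.coefficients != 0)
        norms = wms.norms()
        assert np.allclose(norms, norms[0], atol=1e-10)

    def test_partial_overlap_fraction(self):
        wms = syn.generate_weight_maps(n_voxels=200, sparsity=0.1, overlap=0.5, seed=3)
        supports = [set(np.flatnonzero(row)) for row in wms.coefficients]
        m = len(supports[0])
        for i in range(N_EMOTIONS):
            for j in range(i + 1, N_EMOTIONS):
                assert abs(len(supports[i] & supports[j]) / m - 0.5) <= 1.0 / m

    def test_equal_norms(self):
        wms = syn.generate_weight_maps(n_voxels=500, sparsity=0.1, overlap=0.2, seed=4)
        norms = wms.norms()
        assert np.all(np.abs(norms - norms[0]) < 1e-10)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            syn.generate_weight_maps(n_voxels=0)
        with pytest.raises(ValueError):
            syn.generate_weight_maps(n_voxels=100, sparsity=0.0)
        with pytest.raises(ValueError):
            syn.generate_weight_maps(n_voxels=10, sparsity=1.0, overlap=0.0)


class TestStateSequence:
    def test_absorbing_chain_stays_put(self):
        seq = syn.generate_state_sequence(50, np.eye(7), seed=1, start=3)
        assert np.all(seq.states == 3)

    def test_uniform_chain_occupancy(self):
        seq = syn.generate_state_sequence(70_000, syn.uniform_transition(), seed=2)
        props = np.bincount(seq.states, minlength=7) / len(seq)
        assert np.all(np.abs(props - 1 / 7) < 0.005)

    def test_determinism(self):
        a = syn.generate_state_sequence(500, syn.dwell_transition(4), seed=7)
        b = syn.generate_state_sequence(500, syn.dwell_transition(4), seed=7)
        assert np.array_equal(a.states, b.states)

    def test_non_stochastic_matrix_rejected(self):
        bad = np.full((7, 7), 0.2)
        with pytest.raises(ValueError):
            syn.generate_state_sequence(10, bad)

    def test_dwell_transition_lengthens_runs(self):
        sticky = syn.generate_state_sequence(5000, syn.dwell_transition(10), seed=3)
        loose = syn.generate_state_sequence(5000, syn.dwell_transition(1), seed=3)
        runs = lambda s: np.mean(np.diff(np.flatnonzero(np.diff(s.states) != 0)))
        assert runs(sticky) > runs(loose)


class TestSubjectTimeseries:
    def test_white_noise_has_no_memory(self, flat_weights):
        states = HiddenStateSequence(np.zeros(500, dtype=int))
        ts = syn.generate_subject_timeseries(
            flat_weights, states, amplitude=0.0, ar_phi=0.0, noise_sd=1.0, seed=5
        )
        r = lag1_autocorr(ts.data)
        assert abs(r.mean()) < 0.05

    def test_noiseless_limit_reproduces_maps(self, flat_weights):
        states = syn.generate_state_sequence(40, seed=6)
        ts = syn.generate_subject_timeseries(
            flat_weights, states, amplitude=1.0, ar_phi=0.0, noise_sd=0.0, seed=7
        )
        expected = flat_weights.coefficients[states.states]
        assert np.allclose(ts.data, expected)

    def test_ar1_autocorrelation_recovered(self, flat_weights):
        states = HiddenStateSequence(np.zeros(2000, dtype=int))
        ts = syn.generate_subject_timeseries(
            flat_weights, states, amplitude=0.0, ar_phi=0.5, noise_sd=1.0, seed=8
        )
        assert abs(lag1_autocorr(ts.data).mean() - 0.5) < 0.05

    def test_invalid_ar_phi(self, flat_weights):
        states = HiddenStateSequence(np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            syn.generate_subject_timeseries(flat_weights, states, ar_phi=1.0)


class TestCohort:
    def test_determinism(self, small_weights):
        a = syn.generate_cohort(3, beta=0.002, seed=9, T=32, weights=small_weights)
        b = syn.generate_cohort(3, beta=0.002, seed=9, T=32, weights=small_weights)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a[0], b[0]))
        assert a[1].equals(b[1])

    def test_occupancy_probs_exactly_logit_linear(self):
        from scipy.special import logit

        beta = np.zeros(7)
        beta[5] = 0.003
        for c in (0.0, 20.0, 60.0):
            p = syn._occupancy_probs(beta, c)
            assert np.isclose(logit(p[5]), logit(1 / 7) + 0.003 * c)
            assert np.isclose(p.sum(), 1.0)
            assert np.allclose(p[:5], p[6])  # untilted states share equally

    def test_planted_beta_tilts_decoded_occupancy(self, small_weights):
        cohort, cov = syn.generate_cohort(
            80, beta=0.02, seed=10, T=128, weights=small_weights
        )
        sad = EMOTIONS.index("sad")
        props = np.array(
            [decoding.decode_subject(ts, small_weights)[2].proportions[sad] for ts in cohort]
        )
        c = cov["cesd"].to_numpy()
        lo, hi = props[c < np.median(c)].mean(), props[c >= np.median(c)].mean()
        assert hi > lo

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            syn.generate_cohort(1)


class TestExperienceSampling:
    def test_inter_event_gaps_at_least_isi(self, small_weights):
        _, events = syn.generate_experience_sampling(
            small_weights, n_events=10, congruence=0.5, seed=11
        )
        gaps = np.diff(events["time_s"].to_numpy())
        assert np.all(gaps >= 30.0)
        assert events["time_s"].iloc[0] >= 30.0

    def test_full_congruence_matches_hidden_state(self, small_weights):
        # amplitude ≫ noise so decoded labels reveal the hidden state
        from spontaffect import experience_sampling as es

        ts, events = syn.generate_experience_sampling(
            small_weights, n_events=15, congruence=1.0, seed=12,
            amplitude=50.0, noise_sd=1.0,
        )
        sm, _, _ = decoding.decode_subject(ts, small_weights)
        trials = es.window_scores(sm, events)
        assert len(trials) == 15
        assert all(t.decoded == t.reported for t in trials)

    def test_events_have_valid_labels_and_intensity(self, small_weights):
        _, events = syn.generate_experience_sampling(
            small_weights, n_events=25, congruence=0.3, seed=13
        )
        assert set(events["label"]) <= set(EMOTIONS)
        assert events["intensity"].between(1, 4).all()


class TestNetworkMasks:
    def test_disjoint_and_within_brain_mask(self, default_weights):
        grid = default_weights.grid
        masks = syn.generate_network_masks(grid, 7, seed=14)
        assert len(masks) == 7
        union = np.zeros(grid.shape, dtype=int)
        for m in masks:
            union += m.astype(int)
            assert np.all(grid.mask[m])  # inside the brain mask
        assert union.max() == 1  # pairwise disjoint

    def test_determinism(self, default_weights):
        a = syn.generate_network_masks(default_weights.grid, 3, seed=15)
        b = syn.generate_network_masks(default_weights.grid, 3, seed=15)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_oversized_request_rejected(self, default_weights):
        with pytest.raises(ValueError):
            syn.generate_network_masks(
                default_weights.grid, 7, voxels_per_network=10_000
            )
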