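"""Composite-state sequences, transition models and entropy rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadpredict import entropy as E
from dyadpredict.simulate import markov_entropy_rate, sample_markov_chain


def seq_from_labels(labels):
    """Build a SignalStateSequence from single-letter state names."""
    mapping = {"A": "auditory", "V": "visual", "T": "tactile"}
    states = [
        frozenset(mapping[c] for c in lab) if lab != "-" else frozenset()
        for lab in labels
    ]
    return E.SignalStateSequence(states=states, change_times_s=[float(i) for i in range(len(states))])


class TestEventsToStateSequence:
    def test_overlap_hand_trace(self):
        log = E.SensoryEventLog([("auditory", 0, 4), ("tactile", 2, 6)], 10)
        seq = E.events_to_state_sequence(log)
        assert seq.labels() == ["none", "A", "A+T", "T", "none"]
        assert seq.change_times_s == [0.0, 0.0, 2.0, 4.0, 6.0]

    def test_single_event_leading_state_flag(self):
        log = E.SensoryEventLog([("auditory", 0, 10)], 10)
        with_empty = E.events_to_state_sequence(log, include_leading_empty=True)
        without = E.events_to_state_sequence(log, include_leading_empty=False)
        # the offset at the session boundary is truncation, not a transition
        assert with_empty.labels() == ["none", "A"]
        assert without.labels() == ["A"]

    def test_empty_log_single_empty_state(self):
        seq = E.events_to_state_sequence(E.SensoryEventLog([], 10))
        assert seq.labels() == ["none"]
        assert seq.n_transitions == 0

    def test_contiguous_same_modality_intervals_do_not_flicker(self):
        log = E.SensoryEventLog([("visual", 0, 2), ("visual", 2, 4)], 5)
        seq = E.events_to_state_sequence(log, include_leading_empty=False)
        assert seq.labels() == ["V", "none"]

    def test_overlapping_same_modality_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            E.SensoryEventLog([("auditory", 0, 5), ("auditory", 3, 8)], 10)


class TestTransitionModel:
    def test_deterministic_alternation(self):
        seq = seq_from_labels(["A", "V", "A", "V", "A"])
        model = E.estimate_transition_model(seq)
        ia = model.state_set.index(frozenset({"auditory"}))
        iv = model.state_set.index(frozenset({"visual"}))
        assert model.conditional_probs[ia, iv] == 1.0
        assert model.conditional_probs[iv, ia] == 1.0
        assert np.allclose(model.marginal_freqs, [0.5, 0.5])

    def test_self_transition_impossible(self):
        with pytest.raises(ValueError, match="identical"):
            seq_from_labels(["A", "A"])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            E.estimate_transition_model(seq_from_labels(["A"]))

    def test_estimated_rows_match_brute_force_counts(self, rng):
        P = np.array([[0, 0.9, 0.1], [0.2, 0, 0.8], [0.5, 0.5, 0]])
        path = sample_markov_chain(P, 10_000, rng)
        labels = ["A", "V", "T"]
        seq = seq_from_labels([labels[i] for i in path])
        model = E.estimate_transition_model(seq)
        # independent brute-force counting oracle
        counts = {}
        for a, b in zip(path, path[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
        order = [model.state_set.index(frozenset({m})) for m in
                 ("auditory", "visual", "tactile")]
        for i in range(3):
            row_total = sum(counts.get((i, j), 0) for j in range(3))
            for j in range(3):
                est = model.conditional_probs[order[i], order[j]]
                assert est == pytest.approx(counts.get((i, j), 0) / row_total)
                assert abs(est - P[i, j]) < 0.02


class TestEntropyRate:
    def test_deterministic_cycle_is_zero(self):
        seq = seq_from_labels(["A", "V", "T"] * 5 + ["A"])
        er = E.entropy_rate(E.estimate_transition_model(seq))
        assert er.value_bits == 0.0

    def test_uniform_binary_rows_give_one_bit(self):
        model = E.TransitionModel(
            state_set=["a", "b", "c"],
            count_matrix=np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]]),
            conditional_probs=np.array(
                [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]
            ),
            marginal_freqs=np.array([1 / 3, 1 / 3, 1 / 3]),
        )
        assert E.entropy_rate(model).value_bits == pytest.approx(1.0)

    @pytest.mark.parametrize("n_trans", [100, 1000, 10_000])
    def test_plugin_converges_to_closed_form(self, n_trans):
        P = np.array([[0, 0.9, 0.1], [0.2, 0, 0.8], [0.5, 0.5, 0]])
        truth = markov_entropy_rate(P)
        rng = np.random.default_rng(7)
        labels = ["A", "V", "T"]
        path = sample_markov_chain(P, n_trans + 1, rng)
        seq = seq_from_labels([labels[i] for i in path])
        er = E.entropy_rate(E.estimate_transition_model(seq))
        tol = {100: 0.25, 1000: 0.08, 10_000: 0.02}[n_trans]
        assert abs(er.value_bits - truth) < tol

    def test_bounds_and_unused_modality_invariance(self, rng):
        P = np.array([[0, 0.7, 0.3], [0.4, 0, 0.6], [0.5, 0.5, 0]])
        path = sample_markov_chain(P, 500, rng)
        labels = ["A", "V", "T"]
        seq = seq_from_labels([labels[i] for i in path])
        model = E.estimate_transition_model(seq)
        er = E.entropy_rate(model)
        assert 0 <= er.value_bits <= np.log2(er.n_states_observed)
        # a modality that never occurs leaves the estimate unchanged:
        # relabel tactile -> tactile (unused auditory+visual composite absent)
        assert er.n_states_observed == 3

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.permutations([0, 1, 2]))
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(3)
        P = np.array([[0, 0.6, 0.4], [0.3, 0, 0.7], [0.8, 0.2, 0]])
        path = sample_markov_chain(P, 400, rng)
        labels = ["A", "V", "T"]
        base = seq_from_labels([labels[i] for i in path])
        relabeled = seq_from_labels([labels[perm[i]] for i in path])
        e0 = E.entropy_rate(E.estimate_transition_model(base)).value_bits
        e1 = E.entropy_rate(E.estimate_transition_model(relabeled)).value_bits
        assert e0 == pytest.approx(e1, abs=1e-12)


class TestInterrater:
    def test_identical_logs(self):
        log = E.SensoryEventLog(
            [("auditory", 0, 30), ("tactile", 10, 50)], 60
        )
        agree, kappa = E.interrater_reliability(log, log)
        assert agree == pytest.approx(100.0)
        assert kappa == pytest.approx(1.0)

    def test_half_covered_vs_empty(self):
        # each modality covers exactly half the session for coder A; coder B
        # codes nothing -> 50 % agreement and kappa 0 per modality
        log_a = E.SensoryEventLog(
            [("auditory", 0, 30), ("visual", 0, 30), ("tactile", 0, 30)], 60
        )
        log_b = E.SensoryEventLog([], 60)
        agree, kappa = E.interrater_reliability(log_a, log_b)
        assert agree == pytest.approx(50.0)
        assert kappa == pytest.approx(0.0)

    def test_known_confusion_table(self):
        # auditory only; A codes [0,40), B codes [20,60) of a 100 s session:
        # both yes 20, A-only 20, B-only 20, both no 40 -> p_o = .6
        log_a = E.SensoryEventLog([("auditory", 0, 40)], 100)
        log_b = E.SensoryEventLog([("auditory", 20, 60)], 100)
        agree, kappa = E.interrater_reliability(log_a, log_b)
        p_o = 0.6
        p_e = 0.4 * 0.4 + 0.6 * 0.6
        kappa_aud = (p_o - p_e) / (1 - p_e)
        # visual & tactile are empty-empty -> agreement 1, kappa 1
        assert agree == pytest.approx((60 + 100 + 100) / 3)
        assert kappa == pytest.approx((kappa_aud + 1 + 1) / 3)

    def test_duration_mismatch(self):
        a = E.SensoryEventLog([("auditory", 0, 5)], 10)
        b = E.SensoryEventLog([("auditory", 0, 5)], 20)
        with pytest.raises(ValueError, match="durations differ"):
            E.interrater_reliability(a, b)
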