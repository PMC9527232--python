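"""Sequence building, Markov property test, transition MLE and row tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oculochain.markov import (
    StateSequence,
    build_sequences,
    compare_probabilities,
    fit_transition_matrix,
    row_uniformity_test,
    screen_markov_subjects,
    verify_markov_property,
)
from oculochain.trials import TrialTable
from conftest import table_from_states


def chain(rng, P, length, labels="evf"):
    cum = np.cumsum(P, axis=1)
    s = np.empty(length, dtype=np.intp)
    s[0] = rng.integers(0, len(labels))
    u = rng.random(length)
    for t in range(1, length):
        s[t] = np.searchsorted(cum[s[t - 1]], u[t], side="right")
    return [labels[i] for i in s]


class TestBuildSequences:
    def test_one_sequence_per_subject_condition_block(self):
        t = table_from_states("eevvfev")
        seqs = build_sequences(t, "three")
        assert len(seqs) == 1 and seqs[0].states == list("eevvfev")

    def test_subjects_never_concatenated(self):
        a = table_from_states("ev", subject_id="a")
        b = table_from_states("ve", subject_id="b")
        t = TrialTable(pd.concat([a.data, b.data], ignore_index=True))
        seqs = build_sequences(t, "three")
        assert sorted(len(s) for s in seqs) == [2, 2]

    def test_four_state_requires_state4(self):
        t = table_from_states("ev")
        t.data["state4"] = np.nan
        with pytest.raises(ValueError, match="state4"):
            build_sequences(t, "four")


class TestTransitionMatrix:
    def test_worked_sequence(self):
        """The worked seven-trial sequence e-e-v-v-f-e-v by hand: six
        transitions, row e = (1/3, 2/3, 0), v->v = v->f = 1/2, f->e = 1."""
        tm = fit_transition_matrix([StateSequence("s", "implicit", 0, list("eevvfev"))])
        assert tm.states == ("e", "v", "f")
        np.testing.assert_allclose(tm.probs[0], [1 / 3, 2 / 3, 0.0])
        np.testing.assert_allclose(tm.probs[1], [0.0, 0.5, 0.5])
        np.testing.assert_allclose(tm.probs[2], [1.0, 0.0, 0.0])

    def test_unvisited_rows_are_nan(self):
        tm = fit_transition_matrix([StateSequence("s", "implicit", 0, list("vvv"))])
        assert tm.probs[1, 1] == 1.0
        assert np.isnan(tm.probs[0]).all() and np.isnan(tm.probs[2]).all()
        assert np.isnan(tm.ci_low[0]).all()

    def test_no_cross_sequence_transitions(self):
        seqs = [
            StateSequence("a", "implicit", 0, list("ev")),
            StateSequence("b", "implicit", 0, list("ve")),
        ]
        tm = fit_transition_matrix(seqs)
        assert tm.counts[0, 1] == 1 and tm.counts[1, 0] == 1
        assert tm.counts[1, 1] == 0

    def test_matches_brute_force_oracle_fuzzed(self, rng):
        """Exact equality with nested-loop pair counting on random sets."""
        labels3 = ["e", "v", "f"]
        labels4 = ["first", "second", "v", "f"]
        for trial in range(300):
            labels = labels3 if trial % 2 else labels4
            k = len(labels)
            seqs = [
                StateSequence(f"s{i}", "implicit", 0,
                              [labels[j] for j in rng.integers(0, k, rng.integers(1, 30))])
                for i in range(rng.integers(1, 6))
            ]
            tm = fit_transition_matrix(seqs, states=tuple(labels))
            counts = np.zeros((k, k), dtype=int)
            for s in seqs:
                for a, b in zip(s.states[:-1], s.states[1:]):
                    counts[labels.index(a), labels.index(b)] += 1
            assert np.array_equal(tm.counts, counts)
            for i in range(k):
                if counts[i].sum():
                    np.testing.assert_allclose(tm.probs[i], counts[i] / counts[i].sum())
                else:
                    assert np.isnan(tm.probs[i]).all()

    def test_wald_ci_contains_estimate_and_alphabet_sizes(self, rng):
        seq = StateSequence("s", "implicit", 0, chain(rng, np.full((3, 3), 1 / 3), 500))
        tm = fit_transition_matrix([seq], ci_level=0.99)
        ok = ~np.isnan(tm.probs)
        assert np.all(tm.ci_low[ok] <= tm.probs[ok]) and np.all(tm.probs[ok] <= tm.ci_high[ok])
        assert tm.probs.size == 9  # 3-state: 9 possible transitions
        seq4 = StateSequence(
            "s", "explicit", 0,
            chain(rng, np.full((4, 4), 0.25), 500, labels=["first", "second", "v", "f"]),
        )
        assert fit_transition_matrix([seq4]).probs.size == 16  # 4-state: 16


class TestMarkovProperty:
    def test_iid_sequence_passes(self, rng):
        seq = StateSequence("s", "implicit", 0, chain(rng, np.full((3, 3), 1 / 3), 10000))
        res = verify_markov_property(seq, alpha=0.05)
        assert res.passed and res.p_value > 0.05

    def test_second_order_chain_rejected(self, rng):
        # next state is 'e' with probability 0.9 iff the previous two states
        # are equal - a strictly second-order dependence
        s = ["e", "v"]
        for _ in range(10000):
            if s[-1] == s[-2]:
                nxt = "e" if rng.random() < 0.9 else ("v" if rng.random() < 0.5 else "f")
            else:
                nxt = "evf"[rng.integers(0, 3)]
            s.append(nxt)
        res = verify_markov_property(StateSequence("s", "implicit", 0, s), alpha=0.05)
        assert not res.passed

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError, match="too short"):
            verify_markov_property(StateSequence("s", "implicit", 0, list("evfevfevfe")))

    def test_screen_excludes_non_markov_subject(self, rng):
        good = table_from_states(chain(rng, np.full((3, 3), 1 / 3), 600), subject_id="good")
        s = ["e", "v"]
        for _ in range(600):
            if s[-1] == s[-2]:
                s.append("e" if rng.random() < 0.95 else "v")
            else:
                s.append("evf"[rng.integers(0, 3)])
        bad = table_from_states(s, subject_id="bad")
        t = TrialTable(pd.concat([good.data, bad.data], ignore_index=True))
        kept, results = screen_markov_subjects(t, alpha=0.05)
        assert "good" in kept and "bad" not in kept
        assert not results["bad"].passed


class TestRowAndPairTests:
    def test_uniform_row(self):
        chi2, df, p = row_uniformity_test([10, 10, 10])
        assert chi2 == 0.0 and df == 2 and p == 1.0

    def test_closed_form_example(self):
        # (30,10,20): expected 20 each, chi2 = (100+100+0)/20 = 10
        chi2, df, p = row_uniformity_test([30, 10, 20])
        assert chi2 == pytest.approx(10.0)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(10.0, 2), rel=1e-12)
        assert p == pytest.approx(0.00674, abs=5e-5)

    def test_zero_row_errors(self):
        with pytest.raises(ValueError):
            row_uniformity_test([0, 0, 0])

    def test_compare_probabilities_examples(self):
        same = compare_probabilities(0.5, 100, 0.5, 100, alpha=0.01)
        assert not same.significant and same.ci_low < 0 < same.ci_high
        big = compare_probabilities(0.9, 200, 0.1, 200, alpha=0.01, m_comparisons=1)
        assert big.significant
        assert big.se == pytest.approx(0.03)
        assert big.ci_low == pytest.approx(0.7227, abs=5e-4)
        assert big.ci_high == pytest.approx(0.8773, abs=5e-4)

    def test_bonferroni_level(self):
        res = compare_probabilities(0.5, 100, 0.4, 100, alpha=0.01, m_comparisons=3)
        assert res.level == pytest.approx(1 - 0.01 / 3)

    def test_compare_probabilities_input_errors(self):
        with pytest.raises(ValueError):
            compare_probabilities(1.2, 10, 0.5, 10)
        with pytest.raises(ValueError):
            compare_probabilities(0.5, 0, 0.5, 10)
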