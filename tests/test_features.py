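from fractions import Fraction as F

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musevol import (
    IntervalSequence,
    bigram_frequencies,
    extract_features,
    interval_sequence,
    nondiatonic_frequency,
    nondiatonic_set,
    nondiatonic_set_bruteforce,
    rare_rhythm_frequency,
    tritone_frequency,
)
from musevol.features import NoteEvent, unigram_frequencies
from musevol.errors import InvalidParameterError, UndefinedFrequencyError

intervals_strategy = st.lists(st.integers(min_value=1, max_value=11), min_size=2, max_size=60)


class TestIntervalSequence:
    def test_hand_traced_example(self):
        """(60,64,67,67,72,66,60): pitch classes (0,4,7,7,0,6,0), diffs
        (4,3,0,5,6,6), zeros dropped."""
        seq = interval_sequence([60, 64, 67, 67, 72, 66, 60])
        assert seq.intervals == (4, 3, 5, 6, 6)

    def test_constant_pitches_give_empty_sequence(self):
        assert interval_sequence([64, 64, 64]).intervals == ()

    def test_octave_transition_dropped(self):
        assert interval_sequence([60, 72]).intervals == ()

    def test_single_pitch_gives_empty_sequence(self):
        assert interval_sequence([60]).intervals == ()

    @given(pitches=st.lists(st.integers(min_value=0, max_value=127), min_size=2, max_size=50),
           shift=st.integers(min_value=-24, max_value=24))
    @settings(max_examples=100, derandomize=True)
    def test_transposition_invariance(self, pitches, shift):
        shifted = [p + shift for p in pitches]
        assert interval_sequence(pitches).intervals == interval_sequence(shifted).intervals

    @given(intervals=intervals_strategy, note=st.integers(min_value=1, max_value=20))
    @settings(max_examples=100, derandomize=True)
    def test_octave_displacement_invariance(self, intervals, note):
        """Displacing a note by an octave leaves the sequence unchanged
        when no zero intervals are created (guaranteed here because the
        planted intervals are nonzero mod 12 and +-12 = 0 mod 12)."""
        pitches = [40]
        for iv in intervals:
            pitches.append(pitches[-1] + iv)
        idx = note % len(pitches)
        displaced = list(pitches)
        displaced[idx] += 12
        assert interval_sequence(pitches).intervals == interval_sequence(displaced).intervals


class TestUnigramFeatures:
    def test_tritone_frequency_hand_count(self):
        assert tritone_frequency(IntervalSequence((4, 3, 5, 6, 6))) == pytest.approx(0.4)

    def test_no_tritones(self):
        assert tritone_frequency(IntervalSequence((1, 2, 3))) == 0.0

    def test_all_tritones(self):
        assert tritone_frequency(IntervalSequence((6, 6, 6))) == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(UndefinedFrequencyError):
            tritone_frequency(IntervalSequence(()))

    @given(intervals=intervals_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_unigram_frequencies_sum_to_one(self, intervals):
        seq = IntervalSequence(tuple(intervals))
        freqs = unigram_frequencies(seq)
        assert freqs.sum() == pytest.approx(1.0)
        assert freqs[5] == pytest.approx(tritone_frequency(seq))


class TestNondiatonicSet:
    def test_bruteforce_matches_published_constant(self):
        assert nondiatonic_set_bruteforce() == nondiatonic_set()

    def test_twenty_forbidden_and_101_realizable(self):
        c = nondiatonic_set()
        assert len(c) == 20
        assert 11 * 11 - len(c) == 101

    def test_known_members(self):
        assert (1, 1) in nondiatonic_set()
        assert (2, 2) not in nondiatonic_set()  # e.g. C -> D -> E

    def test_hand_counted_frequencies(self):
        assert nondiatonic_frequency(IntervalSequence((4, 3, 5, 6, 6))) == 0.0
        # (1,1) twice among 3 intervals; denominator is |x|, not |x|-1
        assert nondiatonic_frequency(IntervalSequence((1, 1, 1))) == pytest.approx(2 / 3)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(UndefinedFrequencyError):
            nondiatonic_frequency(IntervalSequence((6,)))


class TestBigrams:
    def test_hand_counted_bigram_vector(self):
        bg = bigram_frequencies(IntervalSequence((4, 3, 5, 6, 6)))
        assert bg.shape == (11, 11)
        assert bg[5, 5] == pytest.approx(0.2)  # (6,6)
        assert bg[3, 2] == pytest.approx(0.2)  # (4,3)
        assert np.count_nonzero(bg) == 4
        assert bg.sum() == pytest.approx(0.8)

    @given(intervals=intervals_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_bigram_sum_identity(self, intervals):
        seq = IntervalSequence(tuple(intervals))
        bg = bigram_frequencies(seq)
        assert bg.sum() == pytest.approx((len(seq) - 1) / len(seq))

    @given(intervals=intervals_strategy)
    @settings(max_examples=50, derandomize=True)
    def test_nondiatonic_is_bigram_mass_on_forbidden_pairs(self, intervals):
        seq = IntervalSequence(tuple(intervals))
        bg = bigram_frequencies(seq)
        mass = sum(bg[i - 1, j - 1] for i, j in nondiatonic_set())
        assert mass == pytest.approx(nondiatonic_frequency(seq))


class TestRareRhythms:
    def test_all_ratios_allowed(self):
        assert rare_rhythm_frequency([F(1), F(1), F(1, 2), F(1, 2), F(3, 4)]) == 0.0

    def test_hand_counted_rare_pair(self):
        # ratios (1/5, 1): 1/5 is rare -> 1 of 2 bigrams
        assert rare_rhythm_frequency([F(1), F(1, 5), F(1, 5)]) == pytest.approx(0.5)

    def test_unit_ratio_allowed(self):
        assert rare_rhythm_frequency([F(1), F(1)]) == 0.0

    def test_exact_rational_membership(self):
        # 0.6666... as a float would be misclassified; 2/3 is allowed
        assert rare_rhythm_frequency([F(3, 2), F(1)]) == 0.0
        assert rare_rhythm_frequency([F(8, 5), F(1)]) == 1.0

    def test_values_denominator_option(self):
        assert rare_rhythm_frequency([F(1), F(1, 5), F(1, 5)], denominator="values") == pytest.approx(1 / 3)

    def test_short_and_invalid_inputs(self):
        with pytest.raises(UndefinedFrequencyError):
            rare_rhythm_frequency([F(1)])
        with pytest.raises(InvalidParameterError):
            rare_rhythm_frequency([F(1), F(-1)])


class TestExtractFeatures:
    def _events(self, pitches, values=None):
        values = values or [None] * len(pitches)
        return [NoteEvent(F(i), p, v) for i, (p, v) in enumerate(zip(pitches, values))]

    def test_full_feature_row(self):
        events = self._events([60, 64, 67, 67, 72, 66, 60])
        f = extract_features(events, "trace", "tester", 1750.0, include_bigrams=True)
        assert f.n_notes == 7
        assert f.n_intervals == 5
        assert f.tritone_freq == pytest.approx(0.4)
        assert f.nondiatonic_freq == 0.0
        assert f.short is True  # < 100 notes
        assert f.bigram.sum() == pytest.approx(0.8)

    def test_hundred_note_piece_not_flagged_short(self):
        events = self._events([60 + (i % 2) for i in range(100)])
        f = extract_features(events, "long", "tester", 1800.0)
        assert f.short is False

    def test_rhythm_features_from_note_values(self):
        events = self._events([60, 62, 64], [F(1), F(1, 5), F(1, 5)])
        f = extract_features(events, "r", "tester", 1900.0)
        assert f.rare_rhythm_freq == pytest.approx(0.5)
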