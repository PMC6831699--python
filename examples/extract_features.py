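"""Feature extraction from a symbolic piece, traced by hand.

Builds a 7-note fixture, reduces it to pitch-class intervals, and
prints the tritone and non-diatonic-motion frequencies plus the bigram
mass.  The pitch line 60,64,67,67,72,66,60 reduces to intervals
(4,3,5,6,6): the repeated 67 and the octave 60->72 drop out as zero
intervals.
"""

import tempfile

from musevol import (
    NoteFixturePlan,
    bigram_frequencies,
    extract_features,
    interval_sequence,
    make_note_fixtures,
    nondiatonic_set,
    nondiatonic_set_bruteforce,
    read_piece,
)

pitches = [60, 64, 67, 67, 72, 66, 60]
seq = interval_sequence(pitches)
print(f"pitches  {pitches}")
print(f"intervals {seq.intervals}  (zeros from the repeat and the octave dropped)")

with tempfile.TemporaryDirectory() as tmp:
    (path,) = make_note_fixtures([NoteFixturePlan("trace", pitches=pitches)], tmp)
    feats = extract_features(read_piece(path), "trace", "example", 1750.0)

print(f"tritone frequency      {feats.tritone_freq:.2f}   (2 tritones among 5 intervals)")
print(f"non-diatonic frequency {feats.nondiatonic_freq:.2f}   (no pair lies in the forbidden set)")
print(f"bigram mass            {bigram_frequencies(seq).sum():.2f}   (= (|x|-1)/|x| for |x|=5)")
print(f"forbidden bigrams      {len(nondiatonic_set())} of 121; brute-force derivation agrees: "
      f"{nondiatonic_set_bruteforce() == nondiatonic_set()}")
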