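"""Symbolic-music feature extraction.

Pieces are reduced to sequences of pitch-class intervals: pitches are
taken mod 12, successive differences are taken mod 12, and zero
intervals (repeated pitches and octave transitions) are dropped, since
they dilute the features of interest.  Melodic and harmonic intervals
are not distinguished.  With zeros excluded there are 11 unigram types
and 121 = 11^2 bigram types.

The extracted per-piece features are

* tritone frequency   #{n | x_n = 6} / |x|
* non-diatonic motion frequency  #{n | (x_n, x_{n+1}) in C} / |x|,
  where C is the 20-element set of interval bigrams that cannot be
  realised by three-note transitions on a diatonic scale
* the full 121-vector of bigram frequencies (count / |x|, so the
  entries sum to (|x|-1)/|x|)
* rare-rhythm frequency: adjacent note-value pairs whose duration
  ratio is outside the 11 simple ratios
  {1, 1/2, 2, 2/3, 3/2, 1/3, 3, 1/4, 4, 1/6, 6}, tested in exact
  rational arithmetic.

Input formats: Standard MIDI File, a plain tab-separated note-list
(onset, MIDI pitch, optional note value as a rational string), and
MusicXML restricted to monophonic note-value extraction.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

from . import smf
from .errors import EmptyPieceError, FormatError, InvalidParameterError, UndefinedFrequencyError

__all__ = [
    "NoteEvent",
    "IntervalSequence",
    "PieceFeatures",
    "read_piece",
    "read_note_list",
    "read_musicxml_note_values",
    "interval_sequence",
    "tritone_frequency",
    "unigram_frequencies",
    "nondiatonic_set",
    "nondiatonic_set_bruteforce",
    "nondiatonic_frequency",
    "bigram_frequencies",
    "rare_rhythm_frequency",
    "extract_features",
    "features_frame",
    "SHORT_PIECE_THRESHOLD",
]

#: Pieces with fewer notes than this are flagged short and excluded at
#: the corpus level.
SHORT_PIECE_THRESHOLD = 100

#: Duration ratios between adjacent note values considered ordinary;
#: anything else counts as a rare rhythm.
ALLOWED_RHYTHM_RATIOS = frozenset(
    Fraction(n, d) for n, d in [(1, 1), (1, 2), (2, 1), (2, 3), (3, 2), (1, 3), (3, 1), (1, 4), (4, 1), (1, 6), (6, 1)]
)

#: Pitch classes of the diatonic (white-key) scale.
DIATONIC_SCALE = (0, 2, 4, 5, 7, 9, 11)

#: Interval bigrams unrealisable on a diatonic scale (see
#: :func:`nondiatonic_set_bruteforce` for the independent derivation).
_NONDIATONIC = frozenset(
    [
        (1, 1), (1, 3), (1, 8), (1, 10), (2, 11), (3, 1), (3, 8), (4, 4), (4, 9), (4, 11),
        (8, 1), (8, 3), (8, 8), (9, 4), (9, 11), (10, 1), (11, 2), (11, 4), (11, 9), (11, 11),
    ]
)


@dataclass(frozen=True)
class NoteEvent:
    """A note: onset (quarter-note units), MIDI pitch, optional notated
    duration in quarter-note units."""

    onset: Fraction
    pitch: int
    note_value: Optional[Fraction] = None

    def __post_init__(self) -> None:
        if not (0 <= self.pitch <= 127):
            raise InvalidParameterError(f"pitch {self.pitch} outside MIDI range 0-127")
        if self.note_value is not None and self.note_value <= 0:
            raise InvalidParameterError(f"note value must be positive, got {self.note_value}")


@dataclass(frozen=True)
class IntervalSequence:
    """A piece as an ordered sequence of nonzero pitch-class intervals."""

    intervals: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(i < 1 or i > 11 for i in self.intervals):
            raise InvalidParameterError("intervals must lie in 1..11")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class PieceFeatures:
    """Per-piece event counts and frequencies."""

    piece_id: str
    composer: str
    year: float
    n_notes: int
    n_intervals: int
    tritone_freq: Optional[float]
    nondiatonic_freq: Optional[float]
    rare_rhythm_freq: Optional[float] = None
    bigram: Optional[np.ndarray] = field(default=None, repr=False)  # shape (11, 11)
    short: bool = False


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_note_list(path) -> list[NoteEvent]:
    """Read the plain note-list format: one event per line, tab- (or
    whitespace-) separated onset, MIDI pitch, optional note value; each
    rational written like ``3/2`` or ``1``.  ``#`` starts a comment."""
    events = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(parts)}")
            try:
                onset = Fraction(parts[0])
                pitch = int(parts[1])
                value = Fraction(parts[2]) if len(parts) == 3 else None
            except (ValueError, ZeroDivisionError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            events.append(NoteEvent(onset, pitch, value))
    if not events:
        raise EmptyPieceError(f"{path}: no note events")
    events.sort(key=lambda e: (e.onset, e.pitch))
    return events


def read_musicxml_note_values(path) -> list[Fraction]:
    """Extract the monophonic note-value sequence (quarter-note units)
    from a MusicXML file.  Rests and grace notes are skipped; chords
    beyond the first note are ignored."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    root = tree.getroot()
    values: list[Fraction] = []
    divisions = None
    for elem in root.iter():
        if elem.tag == "divisions":
            divisions = int(elem.text)
        elif elem.tag == "note":
            if elem.find("rest") is not None or elem.find("grace") is not None:
                continue
            if elem.find("chord") is not None:
                continue
            dur = elem.find("duration")
            if dur is None:
                continue
            if divisions is None:
                raise FormatError(f"{path}: <duration> before <divisions>")
            values.append(Fraction(int(dur.text), divisions))
    if not values:
        raise EmptyPieceError(f"{path}: no notes with durations")
    return values


def read_piece(path, fmt: Optional[str] = None, *, note_value_grid: Optional[Sequence[Fraction]] = None) -> list[NoteEvent]:
    """Read a piece as ordered note events.

    ``fmt`` is ``"midi"`` or ``"notelist"``; inferred from the file
    extension when omitted (.mid/.midi vs anything else).  Events are
    ordered by onset with ties broken by track index (MIDI) then
    ascending pitch, so simultaneous notes contribute harmonic
    intervals in a deterministic order.  For MIDI input, note values
    are not notated; pass ``note_value_grid`` to approximate them by
    quantising inter-onset intervals to the nearest grid value.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "midi" if ext in (".mid", ".midi") else "notelist"
    if fmt == "notelist":
        return read_note_list(path)
    if fmt != "midi":
        raise FormatError(f"unknown format {fmt!r}")
    notes = smf.read_midi_notes(path)
    events = [NoteEvent(onset, pitch) for onset, pitch, _track, _ch in notes]
    if note_value_grid:
        grid = sorted(Fraction(g) for g in note_value_grid)
        onsets = [e.onset for e in events]
        out = []
        for i, e in enumerate(events):
            ioi = next((o - e.onset for o in onsets[i + 1 :] if o > e.onset), None)
            if ioi is None:
                value = grid[-1] if not out else out[-1].note_value
            else:
                value = min(grid, key=lambda g: abs(g - ioi))
            out.append(NoteEvent(e.onset, e.pitch, value))
        events = out
    return events


# ---------------------------------------------------------------------------
# feature extractors
# ---------------------------------------------------------------------------

def interval_sequence(pitches: Iterable[int]) -> IntervalSequence:
    """Pitch-class interval sequence of a pitch stream.

    Pitches are reduced mod 12, adjacent differences taken mod 12
    (values 0..11), and zeros removed after differencing.  Fewer than
    two pitches give an empty sequence.
    """
    p = [int(x) % 12 for x in pitches]
    diffs = [(p[i + 1] - p[i]) % 12 for i in range(len(p) - 1)]
    return IntervalSequence(tuple(d for d in diffs if d != 0))


def tritone_frequency(seq: IntervalSequence) -> float:
    """Frequency of the tritone interval: #{n | x_n = 6} / |x|."""
    if len(seq) < 1:
        raise UndefinedFrequencyError("tritone frequency undefined for empty sequence")
    return sum(1 for x in seq if x == 6) / len(seq)


def unigram_frequencies(seq: IntervalSequence) -> np.ndarray:
    """Frequencies of the 11 interval unigrams (index 0 holds interval
    1, ..., index 10 holds interval 11); sums to 1."""
    if len(seq) < 1:
        raise UndefinedFrequencyError("unigram frequencies undefined for empty sequence")
    counts = np.zeros(11)
    for x in seq:
        counts[x - 1] += 1
    return counts / len(seq)


def nondiatonic_set() -> frozenset[tuple[int, int]]:
    """The 20 interval bigrams unrealisable on a diatonic scale."""
    return _NONDIATONIC


def nondiatonic_set_bruteforce() -> frozenset[tuple[int, int]]:
    """Independent derivation of the non-diatonic set.

    Enumerates all three-note walks p -> q -> r on the diatonic
    pitch-class set with nonzero mod-12 steps, collects the realisable
    interval bigrams, and returns the complement within {1..11}^2.
    Transposition invariance of intervals makes one scale sufficient.
    """
    realizable = set()
    for p in DIATONIC_SCALE:
        for q in DIATONIC_SCALE:
            d1 = (q - p) % 12
            if d1 == 0:
                continue
            for r in DIATONIC_SCALE:
                d2 = (r - q) % 12
                if d2 == 0:
                    continue
                realizable.add((d1, d2))
    return frozenset((i, j) for i in range(1, 12) for j in range(1, 12)) - realizable


def nondiatonic_frequency(seq: IntervalSequence) -> float:
    """Frequency of non-diatonic motions: #{n | (x_n, x_{n+1}) in C} / |x|.

    The denominator is |x| (not the bigram count |x| - 1), matching the
    definition used for all interval-bigram frequencies here.
    """
    if len(seq) < 2:
        raise UndefinedFrequencyError("non-diatonic frequency needs at least 2 intervals")
    xs = seq.intervals
    hits = sum(1 for pair in zip(xs, xs[1:]) if pair in _NONDIATONIC)
    return hits / len(seq)


def bigram_frequencies(seq: IntervalSequence) -> np.ndarray:
    """The 121-vector of interval-bigram frequencies as an (11, 11)
    array, entry [i-1, j-1] = count of (i, j) / |x|; entries sum to
    (|x| - 1) / |x|."""
    if len(seq) < 2:
        raise UndefinedFrequencyError("bigram frequencies need at least 2 intervals")
    xs = seq.intervals
    counts = np.zeros((11, 11))
    for i, j in zip(xs, xs[1:]):
        counts[i - 1, j - 1] += 1
    return counts / len(seq)


def rare_rhythm_frequency(values: Sequence[Fraction], *, denominator: str = "bigrams") -> float:
    """Frequency of rare rhythms among adjacent note-value pairs.

    The ratio value[n+1] / value[n] is computed in exact rational
    arithmetic and tested against the 11 allowed simple ratios.
    ``denominator`` selects the normalisation: ``"bigrams"`` divides by
    the number of pairs |v| - 1 (default), ``"values"`` by |v|.
    """
    vals = [Fraction(v) for v in values]
    if len(vals) < 2:
        raise UndefinedFrequencyError("rare-rhythm frequency needs at least 2 note values")
    if any(v <= 0 for v in vals):
        raise InvalidParameterError("note values must be positive")
    if denominator not in ("bigrams", "values"):
        raise InvalidParameterError(f"unknown denominator {denominator!r}")
    rare = sum(1 for u, v in zip(vals, vals[1:]) if v / u not in ALLOWED_RHYTHM_RATIOS)
    return rare / (len(vals) - 1 if denominator == "bigrams" else len(vals))


# ---------------------------------------------------------------------------
# per-piece aggregation
# ---------------------------------------------------------------------------

def extract_features(
    events: Sequence[NoteEvent],
    piece_id: str,
    composer: str = "",
    year: float = float("nan"),
    *,
    include_bigrams: bool = False,
) -> PieceFeatures:
    """Compute all per-piece features from an ordered event sequence.

    Frequencies that are undefined for too-short interval sequences are
    reported as None rather than raising; the <100-note exclusion is
    only flagged here (``short``) and applied by the corpus layer.
    """
    pitches = [e.pitch for e in events]
    seq = interval_sequence(pitches)
    values = [e.note_value for e in events if e.note_value is not None]
    feats = PieceFeatures(
        piece_id=piece_id,
        composer=composer,
        year=year,
        n_notes=len(events),
        n_intervals=len(seq),
        tritone_freq=tritone_frequency(seq) if len(seq) >= 1 else None,
        nondiatonic_freq=nondiatonic_frequency(seq) if len(seq) >= 2 else None,
        rare_rhythm_freq=rare_rhythm_frequency(values) if len(values) >= 2 else None,
        bigram=bigram_frequencies(seq) if include_bigrams and len(seq) >= 2 else None,
        short=len(events) < SHORT_PIECE_THRESHOLD,
    )
    return feats


def features_frame(features: Iterable[PieceFeatures], *, include_bigrams: bool = False):
    """Tabulate per-piece features as a DataFrame (one row per piece)."""
    import pandas as pd

    rows = []
    for f in features:
        row = {
            "piece_id": f.piece_id,
            "composer": f.composer,
            "year": f.year,
            "n_notes": f.n_notes,
            "n_intervals": f.n_intervals,
            "tritone_freq": f.tritone_freq,
            "nondiatonic_freq": f.nondiatonic_freq,
            "rare_rhythm_freq": f.rare_rhythm_freq,
            "short": f.short,
        }
        if include_bigrams and f.bigram is not None:
            for i in range(11):
                for j in range(11):
                    row[f"bigram_{i + 1}_{j + 1}"] = f.bigram[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
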