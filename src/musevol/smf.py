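"""Minimal Standard MIDI File (format 0/1) reader and writer.

Only what symbolic feature extraction needs: note-on events with their
onset times in quarter-note units.  Meta events and sysex are skipped;
running status is honoured; SMPTE time division is rejected.  The
writer emits a single-track format-0 file with fixed tempo and
velocity, sufficient to round-trip pitch sequences through the reader.
"""

from __future__ import annotations

import struct
from fractions import Fraction
from typing import BinaryIO, Optional

from .errors import EmptyPieceError, FormatError

__all__ = ["read_midi_notes", "write_midi"]

PERCUSSION_CHANNEL = 9  # general MIDI drums; no pitch-class meaning


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    for _ in range(4):
        if pos >= len(data):
            raise FormatError(f"truncated variable-length quantity at byte {pos}")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos
    raise FormatError(f"variable-length quantity too long at byte {pos}")


def read_midi_notes(path, *, include_percussion: bool = False):
    """Parse an SMF file into note-on records.

    Returns a list of ``(onset, pitch, track_index, channel)`` tuples
    with onsets as :class:`fractions.Fraction` in quarter-note units,
    sorted by onset with ties broken by track index then ascending
    pitch.  Channel-10 (percussion) events are excluded by default.

    Raises
    ------
    FormatError
        On a malformed header/track or SMPTE time division.
    EmptyPieceError
        If the file parses but contains no note events.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 14 or data[:4] != b"MThd":
        raise FormatError(f"{path}: not a Standard MIDI File (missing MThd)")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if hlen < 6:
        raise FormatError(f"{path}: bad header length {hlen}")
    if division & 0x8000:
        raise FormatError(f"{path}: SMPTE time division unsupported")
    if division == 0:
        raise FormatError(f"{path}: zero ticks per quarter note")
    pos = 8 + hlen
    notes = []
    for track_idx in range(ntrks):
        if pos + 8 > len(data):
            raise FormatError(f"{path}: truncated at track {track_idx} (byte {pos})")
        if data[pos : pos + 4] != b"MTrk":
            raise FormatError(f"{path}: expected MTrk at byte {pos}")
        tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        tpos, tend = pos + 8, pos + 8 + tlen
        if tend > len(data):
            raise FormatError(f"{path}: track {track_idx} overruns file")
        ticks = 0
        status: Optional[int] = None
        while tpos < tend:
            delta, tpos = _read_varlen(data, tpos)
            ticks += delta
            byte = data[tpos]
            if byte >= 0x80:
                status = byte
                tpos += 1
            elif status is None:
                raise FormatError(f"{path}: running status without status byte at {tpos}")
            if status == 0xFF:  # meta
                tpos += 1  # meta type
                length, tpos = _read_varlen(data, tpos)
                tpos += length
                continue
            if status in (0xF0, 0xF7):  # sysex
                length, tpos = _read_varlen(data, tpos)
                tpos += length
                continue
            kind = status & 0xF0
            channel = status & 0x0F
            ndata = 1 if kind in (0xC0, 0xD0) else 2
            args = data[tpos : tpos + ndata]
            tpos += ndata
            if kind == 0x90 and len(args) == 2 and args[1] > 0:
                if include_percussion or channel != PERCUSSION_CHANNEL:
                    notes.append((Fraction(ticks, division), int(args[0]), track_idx, channel))
        pos = tend
    if not notes:
        raise EmptyPieceError(f"{path}: no note events")
    notes.sort(key=lambda n: (n[0], n[2], n[1]))
    return notes


def _varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def write_midi(path, events, *, division: int = 480, velocity: int = 64) -> None:
    """Write ``(onset, pitch, duration)`` triples (quarter-note units,
    onset/duration Fraction or float) as a format-0 SMF file."""
    msgs = []  # (ticks, order, bytes)
    for onset, pitch, duration in events:
        on = int(round(Fraction(onset) * division))
        off = on + max(1, int(round(Fraction(duration) * division)))
        msgs.append((on, 1, bytes((0x90, pitch, velocity))))
        msgs.append((off, 0, bytes((0x80, pitch, 0))))
    msgs.sort(key=lambda m: (m[0], m[1]))
    body = bytearray()
    prev = 0
    for ticks, _, payload in msgs:
        body += _varlen(ticks - prev) + payload
        prev = ticks
    body += _varlen(0) + bytes((0xFF, 0x2F, 0x00))  # end of track
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, division))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
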