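"""Minimal Standard MIDI File (format 0/1) reader and writer.

Only what monophonic melody stimuli need: note-on/note-off events with
absolute timing, a single tempo, and track selection.  Running status,
variable-length deltas, meta and sysex events are handled; everything
except notes and the first set-tempo event is skipped.
"""

from __future__ import annotations

import struct
from pathlib import Path

from .melody import Melody, NoteEvent, _check_monophonic

__all__ = ["read_midi_events", "read_midi_melody", "write_midi"]


def _read_varlen(data: bytes, i: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[i]
        i += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, i


def _encode_varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def read_midi_events(path: str | Path):
    """Parse an SMF into ``(tracks, division, tempo_us)``.

    Each track is a list of ``(tick, kind, pitch, velocity)`` with kind in
    {"on", "off"}; ``tempo_us`` is the first set-tempo value found or None.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File (missing MThd)")
    hlen = struct.unpack(">I", data[4:8])[0]
    fmt, ntrk, division = struct.unpack(">HHH", data[8:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division is not supported")
    if fmt not in (0, 1):
        raise ValueError(f"unsupported SMF format {fmt}")
    i = 8 + hlen
    tracks = []
    tempo_us = None
    for _ in range(ntrk):
        if data[i : i + 4] != b"MTrk":
            raise ValueError("malformed SMF: expected MTrk chunk")
        tlen = struct.unpack(">I", data[i + 4 : i + 8])[0]
        j, end = i + 8, i + 8 + tlen
        tick = 0
        status = 0
        events = []
        while j < end:
            delta, j = _read_varlen(data, j)
            tick += delta
            b = data[j]
            if b >= 0x80:
                status = b
                j += 1
            if status == 0xFF:  # meta
                mtype = data[j]
                mlen, j2 = _read_varlen(data, j + 1)
                if mtype == 0x51 and tempo_us is None:
                    payload = data[j2 : j2 + mlen]
                    tempo_us = int.from_bytes(payload, "big")
                j = j2 + mlen
            elif status in (0xF0, 0xF7):  # sysex
                slen, j2 = _read_varlen(data, j)
                j = j2 + slen
            else:
                hi = status & 0xF0
                n_data = 1 if hi in (0xC0, 0xD0) else 2
                d = data[j : j + n_data]
                j += n_data
                if hi == 0x90 and d[1] > 0:
                    events.append((tick, "on", d[0], d[1]))
                elif hi == 0x80 or (hi == 0x90 and d[1] == 0):
                    events.append((tick, "off", d[0], 0))
        tracks.append(events)
        i = end
    return tracks, division, tempo_us


def read_midi_melody(
    path: str | Path,
    tempo_bpm: float = 100.0,
    bar_duration: float = 2.4,
    voice: int = 0,
    overlap_policy: str = "error",
    melody_id: str | None = None,
) -> Melody:
    """Read one voice (track) of an SMF as a monophonic :class:`Melody`.

    An embedded set-tempo event, if present, overrides ``tempo_bpm`` for the
    tick-to-second conversion.
    """
    tracks, division, tempo_us = read_midi_events(path)
    note_tracks = [t for t in tracks if any(k == "on" for _, k, _, _ in t)]
    if not note_tracks:
        raise ValueError("MIDI file contains no notes")
    if voice >= len(note_tracks):
        raise ValueError(
            f"voice {voice} requested but file has {len(note_tracks)} note tracks"
        )
    events = note_tracks[voice]
    if tempo_us is None:
        tempo_us = round(60_000_000 / tempo_bpm)
    sec_per_tick = tempo_us / 1e6 / division
    notes: list[NoteEvent] = []
    open_notes: dict[int, int] = {}
    for tick, kind, pitch, _vel in events:
        if kind == "on":
            if pitch in open_notes:
                raise ValueError(f"overlapping note-on for pitch {pitch}")
            open_notes[pitch] = tick
        else:
            start = open_notes.pop(pitch, None)
            if start is not None and tick > start:
                notes.append(
                    NoteEvent(start * sec_per_tick, (tick - start) * sec_per_tick, pitch)
                )
    notes = _check_monophonic(sorted(notes, key=lambda n: n.onset), overlap_policy)
    mid = melody_id if melody_id is not None else Path(path).stem
    return Melody(
        id=mid,
        notes=notes,
        tempo_bpm=60e6 / tempo_us,
        bar_duration=bar_duration,
    )


def write_midi(melody: Melody, path: str | Path, division: int = 480) -> None:
    """Write a melody as a single-track (format 0) SMF."""
    tempo_us = round(60_000_000 / melody.tempo_bpm)
    tick_per_sec = division * 1e6 / tempo_us
    events = []  # (tick, order, bytes) — offs sort before ons at equal tick
    for n in melody.notes:
        on = round(n.onset * tick_per_sec)
        off = round(n.offset * tick_per_sec)
        events.append((on, 1, bytes([0x90, n.pitch, 64])))
        events.append((off, 0, bytes([0x80, n.pitch, 0])))
    events.sort(key=lambda e: (e[0], e[1]))
    body = b"\x00" + bytes([0xFF, 0x51, 0x03]) + tempo_us.to_bytes(3, "big")
    last = 0
    for tick, _, msg in events:
        body += _encode_varlen(tick - last) + msg
        last = tick
    body += b"\x00" + bytes([0xFF, 0x2F, 0x00])  # end of track
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, division)
    track = b"MTrk" + struct.pack(">I", len(body)) + body
    Path(path).write_bytes(header + track)
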