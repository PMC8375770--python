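"""Melody representation, bar grid, and stimulus-feature extraction.

A melody is a monophonic sequence of note events laid out on a bar grid
(default 100 bpm, 4 beats per bar, i.e. one bar every 2.4 s).  Stimulus
features — sound envelope, held pitch series and a note-onset gate — are
sampled at the EEG analysis rate so they can be used both to drive the
forward simulator and to score decoded melodies.

Time is continuous seconds internally.  Sampling uses nearest-sample
rounding for note onsets and half-open intervals [onset, offset) for the
envelope and pitch gates, so a note boundary is never counted twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NoteEvent",
    "Melody",
    "StimulusFeatures",
    "load_melody",
    "extract_features",
    "melody_from_csv",
    "melody_to_csv",
]

_EPS = 1e-9


@dataclass(frozen=True)
class NoteEvent:
    """A single monophonic note: onset and duration in seconds, MIDI pitch."""

    onset: float
    duration: float
    pitch: int

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"note onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"note duration must be > 0, got {self.duration}")
        if not (0 <= int(self.pitch) <= 127):
            raise ValueError(f"pitch must be a MIDI note number 0-127, got {self.pitch}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class Melody:
    """An ordered, non-overlapping note sequence on a bar grid."""

    id: str
    notes: list[NoteEvent]
    tempo_bpm: float = 100.0
    bar_duration: float = 2.4
    n_bars: int = 0

    def __post_init__(self) -> None:
        self.notes = sorted(self.notes, key=lambda n: n.onset)
        _check_monophonic(self.notes, policy="error")
        if self.n_bars <= 0:
            last = max((n.offset for n in self.notes), default=0.0)
            self.n_bars = max(1, math.ceil(last / self.bar_duration - _EPS))
        for n in self.notes:
            if n.onset >= self.n_bars * self.bar_duration - _EPS:
                raise ValueError(
                    f"note at {n.onset:.3f}s lies outside the {self.n_bars}-bar grid"
                )

    @property
    def duration(self) -> float:
        return self.n_bars * self.bar_duration


@dataclass
class StimulusFeatures:
    """Envelope, held-pitch series and onset gate sampled at ``rate`` Hz."""

    rate: float
    envelope: np.ndarray
    pitch_series: np.ndarray
    onset_gate: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.envelope)
        if len(self.pitch_series) != n or len(self.onset_gate) != n:
            raise ValueError("feature series must have identical length")
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")

    def __len__(self) -> int:
        return len(self.envelope)


def _check_monophonic(notes: list[NoteEvent], policy: str = "error") -> list[NoteEvent]:
    """Validate or repair note overlaps.

    policy="error" rejects overlapping notes; policy="truncate" shortens the
    earlier note to end where the next one starts.
    """
    out: list[NoteEvent] = []
    for n in notes:
        if out and out[-1].offset > n.onset + _EPS:
            if policy == "truncate":
                prev = out.pop()
                new_dur = n.onset - prev.onset
                if new_dur > _EPS:
                    out.append(NoteEvent(prev.onset, new_dur, prev.pitch))
            else:
                raise ValueError(
                    f"not monophonic: note at {out[-1].onset:.3f}s (offset "
                    f"{out[-1].offset:.3f}s) overlaps note at {n.onset:.3f}s"
                )
        out.append(n)
    return out


def melody_from_csv(
    path: str | Path,
    melody_id: str | None = None,
    tempo_bpm: float = 100.0,
    bar_duration: float = 2.4,
    overlap_policy: str = "error",
) -> Melody:
    """Read a note-list CSV with header ``onset_s,duration_s,pitch``."""
    df = pd.read_csv(path)
    required = {"onset_s", "duration_s", "pitch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"note CSV missing columns: {sorted(missing)}")
    notes = [
        NoteEvent(float(r.onset_s), float(r.duration_s), int(r.pitch))
        for r in df.itertuples()
    ]
    notes = _check_monophonic(sorted(notes, key=lambda n: n.onset), overlap_policy)
    mid = melody_id if melody_id is not None else Path(path).stem
    return Melody(id=mid, notes=notes, tempo_bpm=tempo_bpm, bar_duration=bar_duration)


def melody_to_csv(melody: Melody, path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset_s": [n.onset for n in melody.notes],
            "duration_s": [n.duration for n in melody.notes],
            "pitch": [n.pitch for n in melody.notes],
        }
    ).to_csv(path, index=False)


def load_melody(
    path: str | Path,
    tempo_bpm: float = 100.0,
    bar_duration: float = 2.4,
    voice: int = 0,
    overlap_policy: str = "error",
    melody_id: str | None = None,
) -> Melody:
    """Load a melody from a Standard MIDI File (.mid/.midi) or a note CSV.

    For multi-track MIDI files only the track selected by ``voice`` is kept
    (track indexing skips trackless meta-only tracks' note content naturally:
    a track with no notes simply yields no events).
    """
    p = Path(path)
    if p.suffix.lower() in {".mid", ".midi"}:
        from .midi import read_midi_melody

        return read_midi_melody(
            p,
            tempo_bpm=tempo_bpm,
            bar_duration=bar_duration,
            voice=voice,
            overlap_policy=overlap_policy,
            melody_id=melody_id,
        )
    return melody_from_csv(
        p,
        melody_id=melody_id,
        tempo_bpm=tempo_bpm,
        bar_duration=bar_duration,
        overlap_policy=overlap_policy,
    )


def extract_features(
    melody: Melody,
    rate: float,
    attack: float = 0.010,
    decay_tau: float | None = 0.5,
    rest_value: float = 0.0,
) -> StimulusFeatures:
    """Sample envelope, pitch series and onset gate at ``rate`` Hz.

    The envelope is built per note as a gate of amplitude 1 (all notes share
    the same loudness) with a linear attack of ``attack`` seconds and an
    exponential decay of time constant ``decay_tau`` seconds after the attack;
    ``decay_tau=None`` disables the decay.  The pitch series holds the MIDI
    pitch over each note's half-open interval and ``rest_value`` elsewhere.
    The onset gate is 1 at the sample nearest each note onset.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    n = math.ceil(melody.duration * rate - _EPS)
    t = np.arange(n) / rate
    envelope = np.zeros(n)
    pitch_series = np.full(n, float(rest_value))
    onset_gate = np.zeros(n)
    for note in melody.notes:
        sel = (t >= note.onset - _EPS) & (t < note.offset - _EPS)
        if not sel.any():
            idx = min(int(round(note.onset * rate)), n - 1)
            sel = np.zeros(n, bool)
            sel[idx] = True
        tt = t[sel] - note.onset
        amp = np.ones(tt.shape)
        if attack > 0:
            amp = np.clip(tt / attack, 0.0, 1.0)
        if decay_tau is not None and np.isfinite(decay_tau):
            amp = amp * np.exp(-np.maximum(tt - attack, 0.0) / decay_tau)
        envelope[sel] = np.maximum(envelope[sel], amp)
        pitch_series[sel] = float(note.pitch)
        gi = min(int(round(note.onset * rate)), n - 1)
        onset_gate[gi] += 1.0
    return StimulusFeatures(
        rate=rate, envelope=envelope, pitch_series=pitch_series, onset_gate=onset_gate
    )


def melody_window(melody: Melody, start_bar: int, n_bars: int) -> list[NoteEvent]:
    """Notes whose onset falls inside bars [start_bar, start_bar + n_bars),
    re-referenced to the window start."""
    t0 = start_bar * melody.bar_duration
    t1 = (start_bar + n_bars) * melody.bar_duration
    return [
        NoteEvent(n.onset - t0, n.duration, n.pitch)
        for n in melody.notes
        if t0 - _EPS <= n.onset < t1 - _EPS
    ]
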