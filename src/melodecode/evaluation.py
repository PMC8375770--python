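"""Decoding-quality metrics: note-onset accuracy, pitch correlation, the
pitch-shuffle baseline and permutation chance levels.

Melody windows are quantised to a beat grid (0.6 s at 100 bpm by default):
each grid position is labelled note-onset-present or absent, and carries the
pitch of the note starting there.  Note-onset accuracy is the fraction of
grid positions where presence matches between decoded and actual melody;
pitch correlation is the Spearman rank correlation of pitch values at the
positions where both melodies have a note (undefined, and excluded from
aggregates, with fewer than 3 matches or constant pitches).

The pitch-shuffle baseline permutes melody identities among reference
segments with identical onset timing: both decoders are blind to pitch
labels, so this is applied as an identity remap to the decoding records.
The chance level is the 95th percentile of scores obtained by shuffling
predicted identities across test segments.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .melody import Melody, melody_window

__all__ = [
    "quantize_window",
    "note_onset_accuracy",
    "onset_accuracy_from_grids",
    "pitch_correlation",
    "timing_signature",
    "timing_partition",
    "score_records",
    "pitch_shuffle_baseline",
    "permutation_chance",
]

MIN_MATCHED_NOTES = 3


def quantize_window(
    melody: Melody, start_bar: int, n_bars: int, grid: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Presence mask and pitch values of a bar window on the beat grid.

    Returns ``(presence, pitch)`` arrays of length round(window / grid);
    pitch is NaN at silent positions.  A note maps to the grid position
    nearest its onset (within half a grid step by construction).
    """
    if grid <= 0:
        raise ValueError(f"grid must be positive, got {grid}")
    duration = n_bars * melody.bar_duration
    n_pos = int(round(duration / grid))
    presence = np.zeros(n_pos, bool)
    pitch = np.full(n_pos, np.nan)
    for note in melody_window(melody, start_bar, n_bars):
        pos = int(round(note.onset / grid))
        if 0 <= pos < n_pos:
            presence[pos] = True
            pitch[pos] = note.pitch
    return presence, pitch


def onset_accuracy_from_grids(pred: np.ndarray, actual: np.ndarray) -> float:
    """Fraction of grid positions with matching note-vs-silence labels."""
    if len(pred) != len(actual):
        raise ValueError("grids must have equal length")
    return float(np.mean(pred == actual))


def note_onset_accuracy(
    predicted_onsets: list[float] | np.ndarray,
    actual_onsets: list[float] | np.ndarray,
    duration: float,
    grid: float = 0.6,
) -> float:
    """Note-onset accuracy from raw onset times within ``[0, duration)``."""
    if grid <= 0:
        raise ValueError(f"grid must be positive, got {grid}")
    n_pos = int(round(duration / grid))

    def to_grid(onsets):
        g = np.zeros(n_pos, bool)
        for o in onsets:
            p = int(round(o / grid))
            if 0 <= p < n_pos:
                g[p] = True
        return g

    return onset_accuracy_from_grids(to_grid(predicted_onsets), to_grid(actual_onsets))


def pitch_correlation(
    pred_presence: np.ndarray,
    pred_pitch: np.ndarray,
    act_presence: np.ndarray,
    act_pitch: np.ndarray,
) -> tuple[float, int]:
    """Spearman ρ of pitch values at positions where both melodies have a
    note.  Returns ``(nan, n_matched)`` when fewer than 3 notes match or
    either matched pitch list is constant."""
    both = pred_presence & act_presence
    n = int(both.sum())
    if n < MIN_MATCHED_NOTES:
        return float("nan"), n
    a = act_pitch[both]
    p = pred_pitch[both]
    if np.ptp(a) == 0 or np.ptp(p) == 0:
        return float("nan"), n
    return _spearman(a, p), n


def _average_ranks(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="stable")
    ranks = np.empty(len(a))
    sa = a[order]
    i = 0
    while i < len(a):
        j = i
        while j < len(a) and sa[j] == sa[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1)
        i = j
    return ranks


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman ρ as Pearson correlation of tie-averaged ranks (the short
    pitch lists here make scipy's generic implementation needless overhead;
    equivalence is asserted against it in the tests)."""
    ra = _average_ranks(a) - (len(a) - 1) / 2
    rb = _average_ranks(b) - (len(b) - 1) / 2
    denom = math.sqrt(float(np.dot(ra, ra) * np.dot(rb, rb)))
    if denom == 0:
        return float("nan")
    return float(np.dot(ra, rb) / denom)


def timing_signature(melody: Melody, start_bar: int, n_bars: int,
                     grid: float = 0.6) -> tuple[bool, ...]:
    """Grid-quantised onset pattern of a window — the key of the timing
    partition used by the pitch-shuffle baseline."""
    presence, _ = quantize_window(melody, start_bar, n_bars, grid)
    return tuple(presence.tolist())


def timing_partition(
    identities: list[tuple[str, int]],
    melodies: dict[str, Melody],
    n_bars: int,
    grid: float = 0.6,
) -> dict[tuple[bool, ...], list[tuple[str, int]]]:
    """Group window identities by their timing signature."""
    classes: dict[tuple[bool, ...], list[tuple[str, int]]] = {}
    for mel_id, start in identities:
        sig = timing_signature(melodies[mel_id], start, n_bars, grid)
        classes.setdefault(sig, []).append((mel_id, start))
    return classes


class _WindowCache:
    """Memoised grid quantisation of (melody, start_bar, n_bars) windows."""

    def __init__(self, melodies: dict[str, Melody], grid: float):
        self.melodies = melodies
        self.grid = grid
        self._cache: dict[tuple[str, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def get(self, mel_id: str, start_bar: int, n_bars: int):
        key = (mel_id, start_bar, n_bars)
        if key not in self._cache:
            self._cache[key] = quantize_window(
                self.melodies[mel_id], start_bar, n_bars, self.grid
            )
        return self._cache[key]

    def score(self, pred_id, true_id, n_bars):
        pp, ppi = self.get(pred_id[0], pred_id[1], n_bars)
        ap, api = self.get(true_id[0], true_id[1], n_bars)
        acc = onset_accuracy_from_grids(pp, ap)
        rho, n = pitch_correlation(pp, ppi, ap, api)
        return acc, rho, n


def _score_one(pred_id, true_id, melodies, n_bars, grid):
    pp, ppi = quantize_window(melodies[pred_id[0]], pred_id[1], n_bars, grid)
    ap, api = quantize_window(melodies[true_id[0]], true_id[1], n_bars, grid)
    acc = onset_accuracy_from_grids(pp, ap)
    rho, n = pitch_correlation(pp, ppi, ap, api)
    return acc, rho, n


def score_records(
    records: pd.DataFrame,
    melodies: dict[str, Melody],
    grid: float = 0.6,
) -> pd.DataFrame:
    """Per-segment note-onset accuracy and pitch ρ for decoding records
    (columns pred_melody/pred_start_bar vs true_melody/true_start_bar)."""
    out = records.copy()
    cache = _WindowCache(melodies, grid)
    accs, rhos, ns = [], [], []
    for r in records.itertuples():
        acc, rho, n = cache.score(
            (r.pred_melody, r.pred_start_bar),
            (r.true_melody, r.true_start_bar),
            int(r.bars),
        )
        accs.append(acc)
        rhos.append(rho)
        ns.append(n)
    out["onset_accuracy"] = accs
    out["pitch_rho"] = rhos
    out["n_matched"] = ns
    return out


def aggregate_scores(scored: pd.DataFrame) -> dict:
    """Mean onset accuracy and mean defined pitch ρ over segments."""
    rho = scored["pitch_rho"].to_numpy(float)
    defined = np.isfinite(rho)
    return {
        "onset_accuracy": float(scored["onset_accuracy"].mean()),
        "pitch_rho": float(rho[defined].mean()) if defined.any() else float("nan"),
        "n_segments": int(len(scored)),
        "n_undefined": int((~defined).sum()),
    }


def pitch_shuffle_baseline(
    records: pd.DataFrame,
    reference_identities: list[tuple[str, int]],
    melodies: dict[str, Melody],
    n_bars: int,
    rng: np.random.Generator,
    n_shuffles: int = 100,
    grid: float = 0.6,
) -> float:
    """Mean pitch ρ after permuting melody identities within each
    identical-timing class of the reference set.

    Decoding is blind to pitch labels, so permuting identities before
    decoding equals remapping predicted identities afterwards; singleton
    timing classes are fixed points, so with all-unique timing the baseline
    equals the unshuffled pitch score.
    """
    classes = timing_partition(
        sorted(set(reference_identities)), melodies, n_bars, grid
    )
    cache = _WindowCache(melodies, grid)
    preds = list(zip(records["pred_melody"], records["pred_start_bar"]))
    trues = list(zip(records["true_melody"], records["true_start_bar"]))
    vals = []
    for _ in range(n_shuffles):
        mapping: dict[tuple[str, int], tuple[str, int]] = {}
        for members in classes.values():
            perm = rng.permutation(len(members))
            for a, b in zip(members, perm):
                mapping[a] = members[b]
        rhos = []
        for pred, true in zip(preds, trues):
            _, rho, _ = cache.score(mapping.get(pred, pred), true, n_bars)
            if math.isfinite(rho):
                rhos.append(rho)
        if rhos:
            vals.append(float(np.mean(rhos)))
    return float(np.mean(vals)) if vals else float("nan")


def permutation_chance(
    records: pd.DataFrame,
    melodies: dict[str, Melody],
    rng: np.random.Generator,
    n_shuffles: int = 100,
    grid: float = 0.6,
    percentile: float = 95.0,
) -> dict:
    """Permutation null: shuffle predicted identities across test segments.

    Returns the observed aggregates, the null distributions of both metrics,
    and their 95th-percentile chance levels; a score is significant when the
    observed value exceeds the chance level.
    """
    if n_shuffles < 20:
        warnings.warn("fewer than 20 shuffles: percentile estimate is unstable")
    scored = score_records(records, melodies, grid)
    observed = aggregate_scores(scored)
    preds = list(zip(records["pred_melody"], records["pred_start_bar"]))
    trues = list(zip(records["true_melody"], records["true_start_bar"]))
    bars = records["bars"].to_numpy(int)
    cache = _WindowCache(melodies, grid)
    null_acc, null_rho = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(preds))
        accs, rhos = [], []
        for i, j in enumerate(perm):
            acc, rho, _ = cache.score(preds[j], trues[i], int(bars[i]))
            accs.append(acc)
            if math.isfinite(rho):
                rhos.append(rho)
        null_acc.append(float(np.mean(accs)))
        null_rho.append(float(np.mean(rhos)) if rhos else float("nan"))
    null_acc = np.array(null_acc)
    null_rho = np.array(null_rho)
    chance_acc = float(np.percentile(null_acc, percentile))
    rho_ok = np.isfinite(null_rho)
    chance_rho = (
        float(np.percentile(null_rho[rho_ok], percentile)) if rho_ok.any() else float("nan")
    )
    return {
        "observed": observed,
        "null_onset": null_acc,
        "null_pitch": null_rho,
        "chance_onset": chance_acc,
        "chance_pitch": chance_rho,
        "significant_onset": bool(observed["onset_accuracy"] > chance_acc),
        "significant_pitch": bool(
            math.isfinite(observed["pitch_rho"])
            and math.isfinite(chance_rho)
            and observed["pitch_rho"] > chance_rho
        ),
    }
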