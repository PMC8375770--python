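"""Maximum-correlation melody decoding (maxCorr).

The classifier assigns a test EEG segment the identity of the reference EEG
segment with the most similar signal: Pearson correlation is computed per JD
component, and the per-component correlations are averaged with a weighting
vector proportional to each component's RMS over the whole experiment.
Segments are bar-aligned windows of 1, 2, 4 or 8 bars; test sets tile trials
with step = window length, while the reference set is augmented with step 1.
Under leave-one-out cross-validation each test segment is matched against
every reference segment except those cut from its own trial (which share raw
samples with it and would match by identity rather than by neural
repetition); the reference set is optionally resampled to a fixed size so
that window lengths with fewer segments are not favoured by a smaller
candidate pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EEGTrial

__all__ = [
    "Segment",
    "bar_slice",
    "window_samples",
    "trial_bar_count",
    "build_segments",
    "resample_reference",
    "weighted_segment_correlation",
    "classify_segment",
    "maxcorr_loo_decode",
]

log = logging.getLogger(__name__)

_TIE_TOL = 1e-12


def bar_slice(start_bar: int, n_bars: int, bar_duration: float, rate: float) -> tuple[int, int]:
    """Sample boundaries of a bar-aligned window (nearest-sample rounding, so
    consecutive step-1 windows partition the trial exactly)."""
    i0 = int(round(start_bar * bar_duration * rate))
    i1 = int(round((start_bar + n_bars) * bar_duration * rate))
    return i0, i1


def window_samples(n_bars: int, bar_duration: float, rate: float) -> int:
    """Guaranteed common sample count of every ``n_bars`` window (bar
    boundaries round to the nearest sample, so lengths vary by one)."""
    return int(np.floor(n_bars * bar_duration * rate + 1e-9))


def trial_bar_count(n_samples: int, bar_duration: float, rate: float) -> int:
    """Largest k with round(k · bar · rate) ≤ n_samples — bar boundaries
    round to the nearest sample, so a trial a fraction of a sample short of
    k bars still counts as k bars."""
    k = int(np.floor(n_samples / (bar_duration * rate) + 0.5))
    while k > 0 and int(round(k * bar_duration * rate)) > n_samples:
        k -= 1
    return k


@dataclass(eq=False)
class Segment:
    """A bar-aligned window of one trial in component space."""

    subject: str
    condition: str
    trial_index: int
    melody_id: str
    repetition: int
    start_bar: int
    n_bars: int
    data: np.ndarray  # time × components

    @property
    def identity(self) -> tuple[str, int]:
        return (self.melody_id, self.start_bar)


def build_segments(
    trials: list[EEGTrial],
    n_bars: int,
    step_bars: int,
    bar_duration: float = 2.4,
) -> list[Segment]:
    """Moving-window segmentation of every trial.

    Windows start at bars 0, step, 2·step, … while they fit inside the trial;
    a trial shorter than one window contributes nothing (warned).
    """
    if n_bars < 1 or step_bars < 1:
        raise ValueError("n_bars and step_bars must be >= 1")
    segments = []
    for idx, trial in enumerate(trials):
        trial_bars = trial_bar_count(trial.n_samples, bar_duration, trial.rate)
        if trial_bars < n_bars:
            warnings.warn(
                f"trial {idx} ({trial_bars} bars) shorter than the {n_bars}-bar "
                "window; skipped"
            )
            continue
        for start in range(0, trial_bars - n_bars + 1, step_bars):
            i0, i1 = bar_slice(start, n_bars, bar_duration, trial.rate)
            segments.append(
                Segment(
                    subject=trial.subject,
                    condition=trial.condition,
                    trial_index=idx,
                    melody_id=trial.melody_id,
                    repetition=trial.repetition,
                    start_bar=start,
                    n_bars=n_bars,
                    data=trial.data[i0:i1],
                )
            )
    return segments


def resample_reference(
    reference: list[Segment], size: int = 96, rng: np.random.Generator | None = None
) -> list[Segment]:
    """Uniform subsample (without replacement) of the reference set to a fixed
    size; smaller sets pass through unchanged."""
    if size <= 0:
        raise ValueError(f"reference size must be positive, got {size}")
    if len(reference) <= size:
        if len(reference) < size:
            log.debug("reference set of %d <= target %d; left unchanged",
                      len(reference), size)
        return list(reference)
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.choice(len(reference), size=size, replace=False)
    return [reference[i] for i in idx]


def _standardise(data: np.ndarray, length: int) -> np.ndarray:
    """Per-component z-score of the first ``length`` samples; zero-variance
    components map to zero (their correlation contribution is 0)."""
    x = data[:length].astype(float)
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = np.inf
    return x / sd


def weighted_segment_correlation(a: Segment, b: Segment, w_rms: np.ndarray) -> float:
    """Σ_j w[j] · pearson(a[:, j], b[:, j]) with the weights summing to 1."""
    if abs(len(a.data) - len(b.data)) > 1:
        raise ValueError(
            f"segment length mismatch: {len(a.data)} vs {len(b.data)}"
        )
    if a.data.shape[1] != b.data.shape[1]:
        raise ValueError("segment component counts differ")
    if len(w_rms) != a.data.shape[1]:
        raise ValueError("weighting vector length must equal component count")
    L = min(len(a.data), len(b.data))
    za = _standardise(a.data, L)
    zb = _standardise(b.data, L)
    corr = np.einsum("tj,tj->j", za, zb) / L
    return float(np.dot(w_rms, corr))


def _identity_key(seg: Segment) -> tuple[str, int]:
    return (seg.melody_id, seg.start_bar)


def classify_segment(
    test: Segment,
    reference: list[Segment],
    w_rms: np.ndarray,
) -> tuple[str, int, float, bool]:
    """Identity of the reference segment with the highest weighted
    correlation; exact ties break to the lexicographically smallest
    (melody_id, start_bar) and are flagged."""
    if not reference:
        raise ValueError("reference set is empty")
    scores = np.array(
        [weighted_segment_correlation(test, r, w_rms) for r in reference]
    )
    best = float(scores.max())
    tied = np.flatnonzero(scores >= best - _TIE_TOL)
    tie = len(tied) > 1
    winner = min(tied, key=lambda i: _identity_key(reference[i]))
    mel, start = _identity_key(reference[winner])
    return mel, start, best, tie


def maxcorr_loo_decode(
    trials: list[EEGTrial],
    n_bars: int,
    w_rms: np.ndarray,
    reference_size: int = 96,
    rng: np.random.Generator | None = None,
    bar_duration: float = 2.4,
    leakage_guard: bool = True,
) -> pd.DataFrame:
    """Leave-one-out maxCorr decoding of one subject/condition at one window
    length.  Returns one record per test segment.

    Test segments tile each trial with step = ``n_bars``; the reference pool
    is the step-1 segmentation of all trials.  With the leakage guard on
    (default) every segment from the test segment's own trial is excluded
    from its reference set, because step-1 segments of the same trial share
    raw samples with the test segment.
    """
    if rng is None:
        rng = np.random.default_rng()
    rate = trials[0].rate
    test_segments = build_segments(trials, n_bars, n_bars, bar_duration)
    ref_segments = build_segments(trials, n_bars, 1, bar_duration)
    if not test_segments:
        return pd.DataFrame()
    L = window_samples(n_bars, bar_duration, rate)
    Z_ref = np.stack([_standardise(s.data, L) for s in ref_segments])
    Z_test = np.stack([_standardise(s.data, L) for s in test_segments])
    # weighted score matrix: tests × references
    Zw = Z_test * np.asarray(w_rms)[None, None, :]
    scores_all = np.einsum("stj,rtj->sr", Zw, Z_ref) / L
    ref_trials = np.array([s.trial_index for s in ref_segments])
    ref_keys = [_identity_key(s) for s in ref_segments]
    records = []
    for si, test in enumerate(test_segments):
        if leakage_guard:
            allowed = np.flatnonzero(ref_trials != test.trial_index)
        else:
            allowed = np.flatnonzero(
                ~(
                    (ref_trials == test.trial_index)
                    & np.array([s.start_bar == test.start_bar for s in ref_segments])
                )
            )
        if allowed.size == 0:
            raise ValueError("reference set empty after exclusions")
        if allowed.size > reference_size:
            allowed = allowed[
                rng.choice(allowed.size, size=reference_size, replace=False)
            ]
        sc = scores_all[si, allowed]
        best = float(sc.max())
        tied = allowed[np.flatnonzero(sc >= best - _TIE_TOL)]
        tie = len(tied) > 1
        winner = min(tied, key=lambda i: ref_keys[i])
        mel, start = ref_keys[winner]
        records.append(
            {
                "subject": test.subject,
                "condition": test.condition,
                "bars": n_bars,
                "trial": test.trial_index,
                "start_bar": test.start_bar,
                "true_melody": test.melody_id,
                "true_start_bar": test.start_bar,
                "pred_melody": mel,
                "pred_start_bar": start,
                "score": best,
                "tie": tie,
            }
        )
    return pd.DataFrame.from_records(records)
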