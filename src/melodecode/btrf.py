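"""Backward temporal response function (bTRF) envelope decoding.

A backward TRF is a regularised lagged linear map from multichannel EEG to
the univariate sound envelope: the stimulus at time t is predicted from EEG
samples at t+τ for lags τ in a 0–350 ms window.  Reconstruction quality is
assessed with leave-one-trial-out cross-validation; melody segments are then
classified by the Pearson correlation between the reconstructed envelope and
each candidate stimulus envelope (bTRF_env).

Ridge regularisation follows the common TRF-toolbox convention: columns are
standardised and λ is scaled by the mean diagonal of the covariance, with an
optional inner cross-validated grid search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EEGTrial
from .melody import StimulusFeatures

__all__ = [
    "BackwardTRF",
    "lag_expand",
    "fit_backward_trf",
    "reconstruct_envelope",
    "classify_by_envelope",
    "btrf_crossval_decode",
]

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-3, 7))


@dataclass
class BackwardTRF:
    weights: np.ndarray  # (channels · lags,)
    lag_window: tuple[float, float]
    ridge_lambda: float
    rate: float
    n_channels: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float

    @property
    def n_lags(self) -> int:
        t0, t1 = self.lag_window
        return int(round((t1 - t0) * self.rate)) + 1


def lag_expand(data: np.ndarray, lag_window: tuple[float, float], rate: float) -> np.ndarray:
    """Design matrix of lagged EEG, time × (channels · lags).

    Backward convention: row t holds data[t+τ] for each lag τ; out-of-range
    samples are zero.  Columns are channel-major (channel c, lag k at column
    c·L + k).
    """
    t0 = int(round(lag_window[0] * rate))
    L = int(round((lag_window[1] - lag_window[0]) * rate)) + 1
    T, C = data.shape
    out = np.zeros((T, C * L))
    for k in range(L):
        tau = t0 + k
        if tau >= 0:
            if tau < T:
                out[: T - tau, k::L] = data[tau:]
        else:
            out[-tau:, k::L] = data[: T + tau]
    return out


def _ridge_solve(A_eigh, b: np.ndarray, lam: float, mean_diag: float) -> np.ndarray:
    d, Q = A_eigh
    denom = d + lam * mean_diag
    inv = np.where(d > 1e-10 * d.max(), 1.0 / np.where(denom > 0, denom, 1.0), 0.0)
    if lam > 0:
        inv = 1.0 / denom
    return Q @ (inv * (Q.T @ b))


def fit_backward_trf(
    trials: list[np.ndarray],
    envelopes: list[np.ndarray],
    lam: float | None = None,
    lag_window: tuple[float, float] = (0.0, 0.35),
    rate: float = 64.0,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> BackwardTRF:
    """Fit the ridge decoder on concatenated training trials.

    ``lam=None`` selects λ from ``lambda_grid`` by inner leave-one-trial-out
    reconstruction correlation; λ=0 falls back to the pseudo-inverse
    least-squares solution.
    """
    if lam is not None and lam < 0:
        raise ValueError(f"ridge lambda must be >= 0, got {lam}")
    if len(trials) != len(envelopes):
        raise ValueError("trial and envelope counts differ")
    for x, y in zip(trials, envelopes):
        if len(x) != len(y):
            raise ValueError("trial and envelope lengths differ")
    Xs = [lag_expand(x, lag_window, rate) for x in trials]
    X = np.vstack(Xs)
    y = np.concatenate(envelopes)
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean = float(y.mean())
    Z = (X - x_mean) / x_std
    yc = y - y_mean
    if lam is None:
        lam = _select_lambda(Xs, envelopes, x_mean, x_std, y_mean, lambda_grid)
    A = Z.T @ Z
    b = Z.T @ yc
    eigh = np.linalg.eigh((A + A.T) / 2)
    w = _ridge_solve(eigh, b, lam, float(np.mean(np.diag(A))))
    return BackwardTRF(
        weights=w,
        lag_window=lag_window,
        ridge_lambda=float(lam),
        rate=rate,
        n_channels=trials[0].shape[1],
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
    )


def _select_lambda(Xs, envelopes, x_mean, x_std, y_mean, grid) -> float:
    """Inner leave-one-trial-out λ selection by reconstruction correlation."""
    if len(Xs) < 2:
        return float(grid[len(grid) // 2])
    Zs = [(X - x_mean) / x_std for X in Xs]
    ys = [e - y_mean for e in envelopes]
    As = [Z.T @ Z for Z in Zs]
    bs = [Z.T @ yc for Z, yc in zip(Zs, ys)]
    A_tot = np.sum(As, axis=0)
    b_tot = np.sum(bs, axis=0)
    scores = np.zeros(len(grid))
    for i, (Z, yc) in enumerate(zip(Zs, ys)):
        A = A_tot - As[i]
        eigh = np.linalg.eigh((A + A.T) / 2)
        md = float(np.mean(np.diag(A)))
        for g, lam in enumerate(grid):
            w = _ridge_solve(eigh, b_tot - bs[i], lam, md)
            pred = Z @ w
            if pred.std() > 0 and yc.std() > 0:
                scores[g] += float(np.corrcoef(pred, yc)[0, 1])
    return float(grid[int(np.argmax(scores))])


def reconstruct_envelope(trf: BackwardTRF, data: np.ndarray) -> np.ndarray:
    """Apply the decoder to a trial's EEG, returning the envelope estimate."""
    if data.shape[1] != trf.n_channels:
        raise ValueError(
            f"channel mismatch: data has {data.shape[1]}, decoder expects "
            f"{trf.n_channels}"
        )
    Z = (lag_expand(data, trf.lag_window, trf.rate) - trf.x_mean) / trf.x_std
    return Z @ trf.weights + trf.y_mean


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def classify_by_envelope(
    reconstruction: np.ndarray,
    candidates: list[np.ndarray],
    tie_tol: float = 1e-12,
) -> tuple[int, bool]:
    """Index of the candidate envelope most correlated with the
    reconstruction; ties break to the lowest index and are flagged."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate envelopes")
    scores = np.array([_pearson(reconstruction, c) for c in candidates])
    best = int(np.argmax(scores))
    tie = bool((np.abs(scores - scores[best]) < tie_tol).sum() > 1)
    if tie:
        best = int(np.flatnonzero(np.abs(scores - scores[best]) < tie_tol)[0])
    return best, tie


def btrf_crossval_decode(
    trials: list[EEGTrial],
    features: dict[str, StimulusFeatures],
    n_bars_window: int | tuple[int, ...] | list[int],
    bar_duration: float = 2.4,
    lam: float | None = None,
    lag_window: tuple[float, float] = (0.0, 0.35),
) -> pd.DataFrame:
    """Leave-one-trial-out envelope decoding with bar-segment classification.

    For each left-out trial the decoder is fitted on all remaining trials
    (which include other repetitions of the same melody), the envelope is
    reconstructed, and each bar-aligned window (step = window length) is
    classified against the inventory of all distinct bar-aligned stimulus
    envelope windows at step 1.  ``n_bars_window`` may be a sequence of
    window lengths, classified from the same per-trial reconstructions.
    Returns one record per test segment.
    """
    from .maxcorr import bar_slice, trial_bar_count, window_samples

    if len(trials) < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    windows = ([n_bars_window] if isinstance(n_bars_window, int)
               else list(n_bars_window))
    rate = trials[0].rate
    inventories = {}
    for w in windows:
        L = window_samples(w, bar_duration, rate)
        cand_ids: list[tuple[str, int]] = []
        cand_envs: list[np.ndarray] = []
        for mel_id in sorted(features):
            env = features[mel_id].envelope
            n_bars = trial_bar_count(len(env), bar_duration, rate)
            for start in range(0, n_bars - w + 1):
                i0, _ = bar_slice(start, w, bar_duration, rate)
                cand_ids.append((mel_id, start))
                cand_envs.append(env[i0 : i0 + L])
        if not cand_ids:
            warnings.warn(f"stimulus shorter than a {w}-bar window; skipped")
            continue
        inventories[w] = (L, cand_ids, cand_envs)
    records = []
    for i, test in enumerate(trials):
        train = [t for j, t in enumerate(trials) if j != i]
        trf = fit_backward_trf(
            [t.data for t in train],
            [features[t.melody_id].envelope[: t.n_samples] for t in train],
            lam=lam,
            lag_window=lag_window,
            rate=rate,
        )
        recon = reconstruct_envelope(trf, test.data)
        n_bars = trial_bar_count(test.n_samples, bar_duration, rate)
        for w, (L, cand_ids, cand_envs) in inventories.items():
            for start in range(0, n_bars - w + 1, w):
                i0, _ = bar_slice(start, w, bar_duration, rate)
                seg = recon[i0 : i0 + L]
                best, tie = classify_by_envelope(seg, cand_envs)
                records.append(
                    {
                        "subject": test.subject,
                        "condition": test.condition,
                        "bars": w,
                        "trial": i,
                        "start_bar": start,
                        "true_melody": test.melody_id,
                        "true_start_bar": start,
                        "pred_melody": cand_ids[best][0],
                        "pred_start_bar": cand_ids[best][1],
                        "score": _pearson(seg, cand_envs[best]),
                        "tie": tie,
                    }
                )
    return pd.DataFrame.from_records(records)
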