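"""EEG preprocessing: zero-phase band-pass, resampling, bad-channel
interpolation and average re-referencing.

Filtering uses separate order-2 Butterworth high-pass and low-pass stages
applied forward-backward, so the effective magnitude response is the squared
single-pass response and the phase shift is zero.  Trials are padded by
reflection (2 s by default) before filtering.  Bad channels are detected on
the concatenated session by comparing each channel's variance with the mean
variance of its k nearest spatial neighbours, and replaced by spherical
spline estimates (Perrin-style, stiffness m=4, regularisation 1e-5).
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.spatial.distance import cdist

from .containers import EEGTrial, TrialSet

__all__ = [
    "PreprocessConfig",
    "bandpass_zero_phase",
    "downsample",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "rereference_average",
    "preprocess_trialset",
    "spline_interpolation_matrix",
    "standard_layout_64",
    "frontal_channel_mask",
    "load_layout_csv",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    band: tuple[float, float] = (0.1, 30.0)
    filter_order: int = 2
    target_rate: float = 64.0
    bad_channel_factor: float = 3.0
    k_neighbors: int = 6
    spline_order: int = 4
    spline_reg: float = 1e-5
    max_bad_fraction: float = 0.25
    reference: str = "average"
    pad_seconds: float = 2.0
    interpolate: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi < self.target_rate / 2:
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist "
                f"({self.target_rate / 2} Hz)"
            )


def _sos_pair(band: tuple[float, float], order: int, rate: float):
    lo, hi = band
    nyq = rate / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz at rate {rate}")
    hp = signal.butter(order, lo / nyq, btype="high", output="sos")
    lp = signal.butter(order, hi / nyq, btype="low", output="sos")
    return hp, lp


def bandpass_zero_phase(
    trial: EEGTrial,
    band: tuple[float, float],
    order: int = 2,
    pad_seconds: float = 2.0,
) -> EEGTrial:
    """Forward-backward Butterworth band-pass (separate HP and LP stages)."""
    hp, lp = _sos_pair(band, order, trial.rate)
    padlen = int(round(pad_seconds * trial.rate))
    if trial.n_samples <= padlen:
        raise ValueError(
            f"trial too short for zero-phase filtering: {trial.n_samples} samples, "
            f"minimum {padlen + 1} at {trial.rate} Hz"
        )
    x = signal.sosfiltfilt(hp, trial.data, axis=0, padlen=padlen)
    x = signal.sosfiltfilt(lp, x, axis=0, padlen=padlen)
    return trial.copy_with(x)


def downsample(trial: EEGTrial, target_rate: float) -> EEGTrial:
    """Polyphase resampling to ``target_rate`` (anti-alias filter built in)."""
    if target_rate > trial.rate:
        raise ValueError(f"target rate {target_rate} exceeds trial rate {trial.rate}")
    if target_rate == trial.rate:
        return trial.copy_with(trial.data.copy())
    frac = Fraction(target_rate / trial.rate).limit_denominator(10_000)
    x = signal.resample_poly(trial.data, frac.numerator, frac.denominator, axis=0)
    out = trial.copy_with(x)
    out.rate = target_rate
    return out


def detect_bad_channels(
    data_by_channel_var: np.ndarray,
    positions: np.ndarray,
    factor: float = 3.0,
    k_neighbors: int = 6,
) -> list[int]:
    """Channels whose variance exceeds ``factor`` × the mean variance of their
    k nearest spatial neighbours."""
    var = np.asarray(data_by_channel_var, float)
    d = cdist(positions, positions)
    np.fill_diagonal(d, np.inf)
    bads = []
    for c in range(len(var)):
        nn = np.argsort(d[c])[:k_neighbors]
        if var[c] > factor * var[nn].mean():
            bads.append(c)
    return bads


def _legendre_gram(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin spline kernel g(cos) = (1/4π) Σ_n (2n+1)/(n(n+1))^m P_n(cos)."""
    n = np.arange(1, n_terms + 1)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** m / (4 * np.pi)
    return np.polynomial.legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs)


def spline_interpolation_matrix(
    pos_good: np.ndarray,
    pos_bad: np.ndarray,
    m: int = 4,
    reg: float = 1e-5,
) -> np.ndarray:
    """Matrix mapping good-channel data to spherical-spline estimates at the
    bad-channel positions (rows: bad channels, columns: good channels)."""
    pg = pos_good / np.linalg.norm(pos_good, axis=1, keepdims=True)
    pb = pos_bad / np.linalg.norm(pos_bad, axis=1, keepdims=True)
    k = len(pg)
    G = _legendre_gram(pg @ pg.T, m=m)
    Gb = _legendre_gram(pb @ pg.T, m=m)
    C = np.zeros((k + 1, k + 1))
    C[:k, :k] = G + reg * np.eye(k)
    C[:k, k] = 1.0
    C[k, :k] = 1.0
    Cinv = np.linalg.pinv(C)
    # spline coefficients = Cinv[:, :k] @ f; estimate = [Gb, 1] @ coeffs
    return np.hstack([Gb, np.ones((len(pb), 1))]) @ Cinv[:, :k]


def interpolate_bad_channels(
    trialset: TrialSet,
    positions: np.ndarray | None = None,
    factor: float = 3.0,
    k_neighbors: int = 6,
    spline_order: int = 4,
    spline_reg: float = 1e-5,
    max_bad_fraction: float = 0.25,
) -> tuple[TrialSet, list[int]]:
    """Detect bad channels on the concatenated session and replace them by
    spherical-spline estimates in every trial.

    Returns the repaired trial set and the list of bad channel indices; with
    no bad channels the input trials are returned unchanged.
    """
    if positions is None:
        positions = trialset.positions
    if positions is None:
        raise ValueError("channel positions are required for interpolation")
    concat = np.vstack([t.data for t in trialset.trials])
    var = concat.var(axis=0)
    bads = detect_bad_channels(var, positions, factor, k_neighbors)
    if not bads:
        return trialset, []
    n = len(trialset.channel_names)
    if len(bads) > max_bad_fraction * n:
        raise RuntimeError(
            f"{len(bads)}/{n} channels flagged bad "
            f"(limit {max_bad_fraction:.0%}); aborting — check the recording"
        )
    good = [c for c in range(n) if c not in bads]
    W = spline_interpolation_matrix(
        positions[good], positions[bads], m=spline_order, reg=spline_reg
    )

    def repair(data: np.ndarray) -> np.ndarray:
        out = data.copy()
        out[:, bads] = data[:, good] @ W.T
        return out

    return trialset.map_data(repair), bads


def rereference_average(trial: EEGTrial) -> EEGTrial:
    """Subtract the per-sample mean across channels."""
    if trial.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return trial.copy_with(trial.data - trial.data.mean(axis=1, keepdims=True))


def preprocess_trialset(trialset: TrialSet, config: PreprocessConfig) -> TrialSet:
    """Full per-session pipeline: band-pass → downsample → interpolate bad
    channels → average reference.  Trial count and metadata are preserved."""
    trials = [
        bandpass_zero_phase(t, config.band, config.filter_order, config.pad_seconds)
        for t in trialset.trials
    ]
    trials = [downsample(t, config.target_rate) for t in trials]
    out = TrialSet(trials, config.target_rate, list(trialset.channel_names),
                   trialset.positions)
    if config.interpolate and out.positions is not None:
        out, bads = interpolate_bad_channels(
            out,
            factor=config.bad_channel_factor,
            k_neighbors=config.k_neighbors,
            spline_order=config.spline_order,
            spline_reg=config.spline_reg,
            max_bad_fraction=config.max_bad_fraction,
        )
        if bads:
            log.info("interpolated bad channels: %s",
                     [out.channel_names[b] for b in bads])
    if config.reference == "average":
        out = TrialSet([rereference_average(t) for t in out.trials], out.rate,
                       out.channel_names, out.positions)
    return out


@functools.lru_cache(maxsize=1)
def standard_layout_64() -> tuple[list[str], np.ndarray]:
    """BioSemi 64-channel labels and unit-sphere positions (x right,
    y anterior, z up), from the standard montage."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    labels = list(pos)
    xyz = np.array([pos[ch] for ch in labels])
    xyz -= xyz.mean(axis=0)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return labels, xyz


def load_layout_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a channel layout CSV with header ``label,x,y,z`` (unit sphere)."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("label", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"layout CSV missing column {col!r}")
    xyz = df[["x", "y", "z"]].to_numpy(float)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return df["label"].astype(str).tolist(), xyz


def frontal_channel_mask(positions: np.ndarray, y_threshold: float = 0.6) -> np.ndarray:
    """Boolean mask of anterior (frontal) channels on the unit sphere."""
    return positions[:, 1] > y_threshold
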