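"""Multiway canonical correlation analysis (MCCA).

Given N subjects' time-aligned data matrices Y_i (T × J_i, trials sorted
into a common stimulus order), MCCA finds per-subject transforms W_i such
that the summed transformed data  Y = Σ_i Y_i W_i  concentrates the
activity shared across subjects in its leading columns (summary
components).  The construction used here is per-dataset PCA whitening
(rank-truncated) followed by PCA of the concatenated whitened data; the
summary components are then mutually orthogonal and ordered by shared
variance.  The leading components form a "virtual subject" whose SNR
exceeds any individual subject when a genuinely shared response exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EEGTrial, TrialSet

__all__ = ["MCCAModel", "fit_mcca", "summary_components", "virtual_subject",
           "fit_mcca_cohort"]

log = logging.getLogger(__name__)

_RANK_TOL = 1e-9


@dataclass
class MCCAModel:
    transforms: list[np.ndarray]  # per subject: J_i × n_sc
    means: list[np.ndarray]  # per subject column means removed before fitting
    n_sc: int
    sc_power: np.ndarray  # shared-variance spectrum, non-increasing


def _whitener(X: np.ndarray) -> np.ndarray:
    C = X.T @ X / len(X)
    d, U = np.linalg.eigh(C)
    keep = d > _RANK_TOL * d.max()
    return U[:, keep] / np.sqrt(d[keep])


def _break_degeneracy(d, U, centred, whiteners, tol: float = 1e-8):
    """Resolve tied shared-variance eigenvalues deterministically.

    Whitening flattens per-dataset variance, so perfectly shared directions
    (e.g. identical datasets) produce exactly degenerate eigenvalues and the
    eigenbasis within each tie group is arbitrary.  Each group is rotated to
    sort its components by original-data variance (the metric Σ_i W0ᵀ C_i² W0,
    which ranks whitened directions by the raw variance they carry), keeping
    results reproducible and making SC1 the dominant-variance shared signal.
    """
    blocks = []
    for x, w in zip(centred, whiteners):
        cw = (x.T @ x / len(x)) @ w
        blocks.append(cw.T @ cw)
    offs = np.cumsum([0] + [b.shape[0] for b in blocks])
    B = np.zeros((offs[-1], offs[-1]))
    for i, b in enumerate(blocks):
        B[offs[i] : offs[i + 1], offs[i] : offs[i + 1]] = b
    scale = max(d.max(), 1.0)
    i = 0
    while i < len(d):
        j = i + 1
        while j < len(d) and abs(d[j] - d[i]) <= tol * scale:
            j += 1
        if j - i > 1:
            Vg = U[:, i:j]
            w, R = np.linalg.eigh(Vg.T @ B @ Vg)
            U[:, i:j] = Vg @ R[:, np.argsort(w)[::-1]]
        i = j
    return U


def fit_mcca(datasets: list[np.ndarray], n_sc: int = 64) -> MCCAModel:
    """Fit MCCA on N ≥ 2 equal-length (T × J_i) datasets."""
    if len(datasets) < 2:
        raise ValueError("MCCA needs at least 2 datasets")
    T = len(datasets[0])
    if any(len(d) != T for d in datasets):
        raise ValueError(
            "datasets have unequal length; sort trials into a common stimulus "
            "order and crop to equal duration before fitting"
        )
    means = [d.mean(axis=0, keepdims=True) for d in datasets]
    centred = [d - m for d, m in zip(datasets, means)]
    whiteners = [_whitener(x) for x in centred]
    Z = np.hstack([x @ w for x, w in zip(centred, whiteners)])
    C = Z.T @ Z / len(Z)
    d, U = np.linalg.eigh(C)
    order = np.argsort(d)[::-1]
    d, U = d[order], U[:, order]
    U = _break_degeneracy(d, U, centred, whiteners)
    rank = int((d > _RANK_TOL * d.max()).sum())
    if n_sc > rank:
        log.warning("n_sc=%d exceeds achievable rank %d; truncating", n_sc, rank)
        n_sc = rank
    U = U[:, :n_sc]
    transforms = []
    offset = 0
    for w in whiteners:
        k = w.shape[1]
        transforms.append(w @ U[offset : offset + k])
        offset += k
    return MCCAModel(transforms=transforms, means=means, n_sc=n_sc,
                     sc_power=d[:n_sc])


def summary_components(model: MCCAModel, datasets: list[np.ndarray]) -> np.ndarray:
    """Y = Σ_i Y_i W_i, the T × n_sc summary-component matrix."""
    if len(datasets) != len(model.transforms):
        raise ValueError("dataset count does not match fitted model")
    Y = None
    for x, m, w in zip(datasets, model.means, model.transforms):
        contrib = (x - m) @ w
        Y = contrib if Y is None else Y + contrib
    return Y


def _sorted_common_slots(trialsets: dict[str, TrialSet], condition: str):
    """Common (melody, repetition) slots across subjects, with the per-slot
    minimum trial length."""
    per_subject = {}
    for sid, ts in trialsets.items():
        sub = ts.select(condition=condition)
        per_subject[sid] = {(t.melody_id, t.repetition): t for t in sub.trials}
    keys = None
    for slots in per_subject.values():
        keys = set(slots) if keys is None else keys & set(slots)
    keys = sorted(keys)
    if not keys:
        raise ValueError(f"no common trials across subjects for {condition!r}")
    lengths = [min(per_subject[s][k].n_samples for s in per_subject) for k in keys]
    return per_subject, keys, lengths


def virtual_subject(
    model: MCCAModel,
    datasets: list[np.ndarray],
    boundaries: list[tuple[str, int, int]],
    rate: float,
    condition: str,
) -> TrialSet:
    """Re-segment the summary matrix into trials.

    ``boundaries`` lists (melody_id, repetition, n_samples) in concatenation
    order; the segment lengths must partition the summary matrix exactly.
    """
    Y = summary_components(model, datasets)
    total = sum(n for _, _, n in boundaries)
    if total != len(Y):
        raise ValueError(
            f"trial boundaries cover {total} samples but summary matrix has {len(Y)}"
        )
    trials = []
    start = 0
    for melody_id, rep, n in boundaries:
        trials.append(
            EEGTrial(
                data=Y[start : start + n],
                rate=rate,
                subject="mcca-virtual",
                condition=condition,
                melody_id=melody_id,
                repetition=rep,
            )
        )
        start += n
    names = [f"sc{j:02d}" for j in range(Y.shape[1])]
    return TrialSet(trials, rate, names, None)


def fit_mcca_cohort(
    trialsets: dict[str, TrialSet],
    condition: str,
    n_sc: int = 64,
) -> tuple[MCCAModel, TrialSet]:
    """Sort every subject's trials into the common stimulus order, fit MCCA
    on the concatenated data, and return the virtual-subject trial set."""
    per_subject, keys, lengths = _sorted_common_slots(trialsets, condition)
    datasets = []
    for sid in sorted(per_subject):
        chunks = [per_subject[sid][k].data[:n] for k, n in zip(keys, lengths)]
        datasets.append(np.vstack(chunks))
    rate = next(iter(trialsets.values())).rate
    model = fit_mcca(datasets, n_sc=n_sc)
    boundaries = [(mel, rep, n) for (mel, rep), n in zip(keys, lengths)]
    vs = virtual_subject(model, datasets, boundaries, rate, condition)
    return model, vs
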