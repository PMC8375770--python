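"""Joint decorrelation: reliability-maximising component extraction.

Repetitions of the same melody share their stimulus-driven response, so a
linear component that is reliable across repetitions can be found by the
generalized symmetric eigenproblem  C_bias v = λ C_total v,  where C_total
is the covariance of all trials and C_bias the covariance of the
per-stimulus trial averages.  After whitening with rank truncation the
eigenvalues λ measure trial-to-trial reliability and lie in [0, 1]: the
first component is the most repeatable linear combination of channels.

Component selection keeps the smallest leading set capturing a configured
fraction (default 50%) of the reliable (trial-averaged) variance, i.e. of
the normalised eigenvalue spectrum; whitened components all carry unit
variance under the total covariance, so the raw-variance spectrum is flat
and carries no ranking information.  Ocular artifact components are
rejected automatically when their forward-model weight mass concentrates
on frontal channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EEGTrial, TrialSet
from .preprocess import frontal_channel_mask

__all__ = [
    "JDModel",
    "fit_jd",
    "select_components",
    "reject_artifact_components",
    "compute_weighting_vector",
    "project",
]

log = logging.getLogger(__name__)

_RANK_TOL = 1e-9


@dataclass
class JDModel:
    unmixing: np.ndarray  # channels × components, reliability-ordered
    forward: np.ndarray  # components × channels (pseudo-inverse topographies)
    eigenvalues: np.ndarray  # reliability λ per component, non-increasing
    component_variance: np.ndarray  # normalised λ spectrum, sums to 1
    M: int
    rejected: list[int] = field(default_factory=list)
    w_rms: np.ndarray | None = None
    channel_names: list[str] | None = None
    positions: np.ndarray | None = None

    @property
    def kept_components(self) -> list[int]:
        return [j for j in range(self.M) if j not in set(self.rejected)]


def _demean(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def fit_jd(trialset: TrialSet, variance_fraction: float = 0.5) -> JDModel:
    """Fit JD on one subject/condition's trials, grouped by melody.

    Stimuli with a single repetition contribute to the total covariance
    only; at least one stimulus must be repeated.
    """
    groups: dict[str, list[EEGTrial]] = {}
    for t in trialset.trials:
        groups.setdefault(t.melody_id, []).append(t)
    if not any(len(g) >= 2 for g in groups.values()):
        raise ValueError("no repetitions: every stimulus occurs once")
    X_all = np.vstack([_demean(t.data) for t in trialset.trials])
    C_tot = X_all.T @ X_all / len(X_all)
    d, U = np.linalg.eigh(C_tot)
    keep = d > _RANK_TOL * d.max()
    W0 = U[:, keep] / np.sqrt(d[keep])  # whitener, channels × rank
    means = []
    for mel, trials in sorted(groups.items()):
        if len(trials) < 2:
            continue
        tmin = min(t.n_samples for t in trials)
        avg = np.mean([_demean(t.data)[:tmin] for t in trials], axis=0)
        means.append(avg)
    Xb = np.vstack(means)
    C_bias = Xb.T @ Xb / len(Xb)
    Cb_w = W0.T @ C_bias @ W0
    lam, E = np.linalg.eigh((Cb_w + Cb_w.T) / 2)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = W0 @ E[:, order]
    forward = np.linalg.pinv(V)
    # sign convention: largest-|.| topography weight positive
    for j in range(V.shape[1]):
        s = np.sign(forward[j, np.argmax(np.abs(forward[j]))])
        if s < 0:
            V[:, j] *= -1
            forward[j] *= -1
    comp_var = lam.clip(min=0.0)
    total = comp_var.sum()
    comp_var = comp_var / total if total > 0 else comp_var
    model = JDModel(
        unmixing=V,
        forward=forward,
        eigenvalues=lam,
        component_variance=comp_var,
        M=V.shape[1],
        channel_names=list(trialset.channel_names),
        positions=trialset.positions,
    )
    model.M = select_components(model, variance_fraction)
    return model


def select_components(model: JDModel, variance_fraction: float = 0.5) -> int:
    """Smallest leading component count whose cumulative variance share
    reaches ``variance_fraction``."""
    cum = np.cumsum(model.component_variance)
    idx = np.searchsorted(cum, variance_fraction - 1e-12)
    return int(min(idx + 1, len(cum)))


def reject_artifact_components(
    model: JDModel,
    positions: np.ndarray | None = None,
    mass_threshold: float = 0.6,
    z_threshold: float = 3.0,
    y_threshold: float = 0.6,
) -> JDModel:
    """Flag components whose forward topography concentrates frontally.

    A component is rejected when more than ``mass_threshold`` of its absolute
    topography mass lies on frontal channels and the frontal-vs-rest mean
    absolute weight z-score exceeds ``z_threshold`` — the signature of eye
    blinks and eye movements.  With no frontal channels in the layout no
    component is rejected and a warning is logged.
    """
    pos = positions if positions is not None else model.positions
    if pos is None:
        raise ValueError("channel positions required for artifact rejection")
    frontal = frontal_channel_mask(pos, y_threshold)
    if not frontal.any():
        log.warning("no frontal channels in layout; skipping artifact rejection")
        return replace(model, rejected=[])
    rejected = []
    for j in range(model.M):
        a = np.abs(model.forward[j])
        frac = a[frontal].sum() / a.sum() if a.sum() > 0 else 0.0
        rest = a[~frontal]
        z = (a[frontal].mean() - rest.mean()) / rest.std() if rest.std() > 0 else np.inf
        if frac > mass_threshold and z > z_threshold:
            rejected.append(j)
    return replace(model, rejected=rejected)


def compute_weighting_vector(component_trials: list[np.ndarray]) -> np.ndarray:
    """RMS of each component over the concatenated experiment, normalised to
    sum to 1.  Zero-variance components get weight 0."""
    concat = np.vstack(component_trials)
    rms = np.sqrt(np.mean(concat**2, axis=0))
    total = rms.sum()
    return rms / total if total > 0 else rms


def project(trial: EEGTrial, model: JDModel) -> EEGTrial:
    """Map a trial into the selected, non-rejected component space."""
    if trial.n_channels != model.unmixing.shape[0]:
        raise ValueError(
            f"channel mismatch: trial has {trial.n_channels}, model expects "
            f"{model.unmixing.shape[0]}"
        )
    V = model.unmixing[:, model.kept_components]
    return trial.copy_with(_demean(trial.data) @ V)


def fit_subject_condition(
    trialset: TrialSet,
    condition: str,
    variance_fraction: float = 0.5,
    reject_artifacts: bool = True,
) -> tuple[JDModel, list[EEGTrial]]:
    """Convenience: fit JD on one condition, reject artifact components,
    project all trials and attach the RMS weighting vector."""
    sub = trialset.select(condition=condition)
    model = fit_jd(sub, variance_fraction)
    if reject_artifacts and sub.positions is not None:
        model = reject_artifact_components(model)
    projected = [project(t, model) for t in sub.trials]
    model.w_rms = compute_weighting_vector([t.data for t in projected])
    return model, projected
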