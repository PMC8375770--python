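"""In-memory containers for multichannel EEG trials."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["EEGTrial", "TrialSet"]


@dataclass
class EEGTrial:
    """One trial: time × channel matrix plus experiment metadata."""

    data: np.ndarray
    rate: float
    subject: str
    condition: str
    melody_id: str
    repetition: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("trial data must be a 2-D time × channel matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "EEGTrial":
        return replace(self, data=data)


@dataclass
class TrialSet:
    """A collection of trials sharing a channel set and sampling rate."""

    trials: list[EEGTrial]
    rate: float
    channel_names: list[str]
    positions: np.ndarray | None = None  # (channels, 3) unit-sphere coords

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def select(self, condition: str | None = None, melody_id: str | None = None) -> "TrialSet":
        kept = [
            t
            for t in self.trials
            if (condition is None or t.condition == condition)
            and (melody_id is None or t.melody_id == melody_id)
        ]
        return TrialSet(kept, self.rate, list(self.channel_names), self.positions)

    def sorted_trials(self) -> list[EEGTrial]:
        """Trials in the canonical (condition, melody, repetition) order."""
        return sorted(
            self.trials, key=lambda t: (t.condition, t.melody_id, t.repetition)
        )

    def map_data(self, fn) -> "TrialSet":
        out = [t.copy_with(fn(t.data)) for t in self.trials]
        return TrialSet(out, self.rate, list(self.channel_names), self.positions)
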