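"""Synthetic chorale-like melodies and forward-model EEG cohorts.

The generator emulates the structure of the melody-decoding experiment:
a small set of monophonic melodies on a 100 bpm bar grid (one bar every
2.4 s), each repeated several times per condition for every subject, with
EEG generated directly at the 64 Hz analysis rate.

The forward model convolves the stimulus envelope with a temporal response
kernel confined to 0–350 ms, and (optionally) a sub-1-Hz low-passed pitch
contour with a second kernel, mixes both into channels through random
unit-norm topographies, and adds spatially mixed pink (1/f) noise scaled
to a target stimulus-to-noise power ratio.  The stimulus-driven part is
deterministic per (subject, melody), so repetitions of the same melody
share it exactly; only the noise differs between repetitions.

``shared_fraction`` splits the stimulus-driven variance between a source
time-course common to all subjects (routed through subject-specific channel
mixing) and subject-private kernels, which is the structure multiway CCA
assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EEGTrial, TrialSet
from .melody import Melody, NoteEvent, StimulusFeatures, extract_features

__all__ = [
    "SimulationConfig",
    "Cohort",
    "generate_melody",
    "generate_timing_unique_melody",
    "simulate_trial",
    "simulate_cohort",
    "default_kernel",
]

_MAJOR = {0, 2, 4, 5, 7, 9, 11}


@dataclass
class SimulationConfig:
    n_subjects: int = 21
    n_melodies: int = 4
    n_repetitions: int = 11  # per condition
    n_bars: int = 14
    n_channels: int = 64
    rate: float = 64.0
    snr_db: float = 0.0  # stimulus-driven vs noise power; +inf disables noise
    env_gain: float = 1.0
    pitch_gain: float = 1.0
    kernel_envelope: np.ndarray | None = None
    kernel_pitch: np.ndarray | None = None
    shared_fraction: float = 0.5
    tempo_bpm: float = 100.0
    beats_per_bar: int = 4
    pitch_range: tuple[int, int] = (60, 81)
    step_bias: float = 0.7
    half_note_prob: float = 0.3
    blink_gain: float = 0.0  # frontal artifact source amplitude, off by default
    conditions: tuple[str, ...] = ("listening", "imagery")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_melodies", "n_repetitions", "n_bars", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")

    @property
    def bar_duration(self) -> float:
        return 60.0 / self.tempo_bpm * self.beats_per_bar


def default_kernel(rate: float, t_max: float = 0.35, peak: float = 0.10,
                   trough: float = 0.22, trough_gain: float = 0.6) -> np.ndarray:
    """Difference-of-gammas impulse response on lags [0, t_max], unit energy.

    Peaks near 100 ms with an opposite-sign deflection near 220 ms, a shape
    consistent with auditory evoked responses inside a 0–350 ms lag window.
    """
    t = np.arange(0, t_max + 0.5 / rate, 1.0 / rate)

    def gamma_bump(centre: float, shape: float = 3.0) -> np.ndarray:
        scale = centre / (shape - 1)
        g = (t / scale) ** (shape - 1) * np.exp(-t / scale)
        return g / g.max()

    k = gamma_bump(peak) - trough_gain * gamma_bump(trough, shape=4.0)
    return k / np.linalg.norm(k)


def _major_scale(pitch_range: tuple[int, int]) -> list[int]:
    lo, hi = pitch_range
    scale = [p for p in range(lo, hi + 1) if p % 12 in _MAJOR]
    if not scale:
        raise ValueError(f"no scale tones in pitch range {pitch_range}")
    return scale


def _random_walk_pitches(rng, n: int, scale: list[int], step_bias: float) -> list[int]:
    idx = len(scale) // 2
    out = [scale[idx]]
    for _ in range(n - 1):
        if rng.random() < step_bias:
            step = 1 if rng.random() < 0.5 else -1
        else:
            step = int(rng.integers(2, 5)) * (1 if rng.random() < 0.5 else -1)
        idx += step
        if idx < 0:
            idx = -idx
        if idx >= len(scale):
            idx = 2 * (len(scale) - 1) - idx
        idx = int(np.clip(idx, 0, len(scale) - 1))
        out.append(scale[idx])
    return out


def generate_melody(
    rng: np.random.Generator,
    n_bars: int = 14,
    tempo_bpm: float = 100.0,
    beats_per_bar: int = 4,
    pitch_range: tuple[int, int] = (60, 81),
    step_bias: float = 0.7,
    half_note_prob: float = 0.3,
    melody_id: str = "melody",
) -> Melody:
    """Chorale-like random melody: quarter/half notes on the beat grid with a
    stepwise random walk on the major scale (``step_bias`` = probability of a
    ±1 scale-step interval)."""
    if n_bars < 1:
        raise ValueError("n_bars must be >= 1")
    scale = _major_scale(pitch_range)
    beat_s = 60.0 / tempo_bpm
    total_beats = n_bars * beats_per_bar
    onsets_beats: list[int] = []
    durs_beats: list[int] = []
    beat = 0
    while beat < total_beats:
        rem_in_bar = beats_per_bar - beat % beats_per_bar
        dur = 2 if (rem_in_bar >= 2 and rng.random() < half_note_prob) else 1
        onsets_beats.append(beat)
        durs_beats.append(dur)
        beat += dur
    pitches = _random_walk_pitches(rng, len(onsets_beats), scale, step_bias)
    notes = [
        NoteEvent(b * beat_s, d * beat_s, p)
        for b, d, p in zip(onsets_beats, durs_beats, pitches)
    ]
    return Melody(
        id=melody_id,
        notes=notes,
        tempo_bpm=tempo_bpm,
        bar_duration=beat_s * beats_per_bar,
        n_bars=n_bars,
    )


def generate_timing_unique_melody(
    rng: np.random.Generator,
    n_bars: int = 8,
    tempo_bpm: float = 100.0,
    beats_per_bar: int = 4,
    pitch_range: tuple[int, int] = (60, 81),
    melody_id: str = "melody",
) -> Melody:
    """A melody whose bars carry pairwise-distinct onset patterns.

    The 4-beat bar admits exactly 8 onset patterns that start on the downbeat
    (the subsets of {0,1,2,3} containing 0); assigning each bar a different
    one makes every bar-aligned window of the melody uniquely identifiable
    from note timing alone.  Requires ``n_bars`` <= 8.
    """
    patterns = [s for s in _subsets_with_zero(beats_per_bar)]
    if n_bars > len(patterns):
        raise ValueError(
            f"at most {len(patterns)} bars can have unique timing, got {n_bars}"
        )
    rng.shuffle(patterns)
    patterns = patterns[:n_bars]
    scale = _major_scale(pitch_range)
    beat_s = 60.0 / tempo_bpm
    notes: list[NoteEvent] = []
    n_notes = sum(len(p) for p in patterns)
    pitches = iter(_random_walk_pitches(rng, n_notes, scale, step_bias=1.0))
    for bar, pat in enumerate(patterns):
        pat = sorted(pat)
        for i, b in enumerate(pat):
            nxt = pat[i + 1] if i + 1 < len(pat) else beats_per_bar
            notes.append(
                NoteEvent((bar * beats_per_bar + b) * beat_s, (nxt - b) * beat_s,
                          next(pitches))
            )
    return Melody(
        id=melody_id,
        notes=notes,
        tempo_bpm=tempo_bpm,
        bar_duration=beat_s * beats_per_bar,
        n_bars=n_bars,
    )


def _subsets_with_zero(n: int) -> list[list[int]]:
    rest = list(range(1, n))
    out = []
    for mask in range(1 << len(rest)):
        out.append([0] + [rest[i] for i in range(len(rest)) if mask >> i & 1])
    return out


@dataclass
class SubjectModel:
    """Deterministic per-subject forward parameters."""

    mix_env_shared: np.ndarray  # (channels,), unit norm
    mix_pitch_shared: np.ndarray
    mix_env_private: np.ndarray
    mix_pitch_private: np.ndarray
    kernel_env_private: np.ndarray
    kernel_pitch_private: np.ndarray
    noise_mixing: np.ndarray  # (channels, channels)
    blink_mixing: np.ndarray  # (channels,)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _subject_model(rng: np.random.Generator, config: SimulationConfig,
                   positions: np.ndarray) -> SubjectModel:
    c = config.n_channels
    jit = lambda: float(np.clip(1.0 + 0.2 * rng.standard_normal(), 0.5, 1.5))
    frontal = positions[:, 1] > 0.6
    blink = np.where(frontal, np.abs(rng.standard_normal(c)) + 0.5, 0.0)
    return SubjectModel(
        mix_env_shared=_unit(rng.standard_normal(c)),
        mix_pitch_shared=_unit(rng.standard_normal(c)),
        mix_env_private=_unit(rng.standard_normal(c)),
        mix_pitch_private=_unit(rng.standard_normal(c)),
        kernel_env_private=default_kernel(config.rate, peak=0.10 * jit()),
        kernel_pitch_private=default_kernel(config.rate, peak=0.12 * jit()),
        noise_mixing=rng.standard_normal((c, c)) / math.sqrt(c),
        blink_mixing=_unit(blink) if frontal.any() else np.zeros(c),
    )


def _lowpass_1hz(x: np.ndarray, rate: float) -> np.ndarray:
    sos = signal.butter(4, 1.0 / (rate / 2), btype="low", output="sos")
    return signal.sosfiltfilt(sos, x)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.mean(x**2))
    return x / r if r > 0 else x


def _source_timecourses(features: StimulusFeatures, config: SimulationConfig,
                        k_env: np.ndarray, k_pitch: np.ndarray):
    T = len(features)
    if len(k_env) > T or len(k_pitch) > T:
        raise ValueError("forward kernel is longer than the trial")
    env_src = np.convolve(features.envelope, k_env)[:T]
    p = features.pitch_series - features.pitch_series.mean()
    if np.any(p != 0):
        p = _lowpass_1hz(p, config.rate)
    pitch_src = np.convolve(p, k_pitch)[:T]
    return _unit_rms(env_src), _unit_rms(pitch_src)


def stimulus_drive(features: StimulusFeatures, config: SimulationConfig,
                   subject: SubjectModel) -> np.ndarray:
    """Deterministic stimulus-driven part of a trial, time × channels."""
    k_env = config.kernel_envelope
    k_pitch = config.kernel_pitch
    if k_env is None:
        k_env = default_kernel(config.rate)
    if k_pitch is None:
        k_pitch = default_kernel(config.rate, peak=0.12)
    env_sh, pitch_sh = _source_timecourses(features, config, k_env, k_pitch)
    env_pr, pitch_pr = _source_timecourses(
        features, config, subject.kernel_env_private, subject.kernel_pitch_private
    )
    a = math.sqrt(config.shared_fraction)
    b = math.sqrt(1.0 - config.shared_fraction)
    drive = (
        a * config.env_gain * np.outer(env_sh, subject.mix_env_shared)
        + a * config.pitch_gain * np.outer(pitch_sh, subject.mix_pitch_shared)
        + b * config.env_gain * np.outer(env_pr, subject.mix_env_private)
        + b * config.pitch_gain * np.outer(pitch_pr, subject.mix_pitch_private)
    )
    return drive


def pink_noise(rng: np.random.Generator, n: int, n_channels: int) -> np.ndarray:
    """1/f-spectrum noise, unit variance per channel."""
    white = rng.standard_normal((n, n_channels))
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)[:, None]
    x = np.fft.irfft(spec, n=n, axis=0)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _blink_source(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Sparse smoothed positive deflections emulating eye blinks."""
    x = np.zeros(n)
    n_blinks = max(1, int(n / rate / 4))  # about one every 4 s
    idx = rng.integers(0, n, n_blinks)
    x[idx] = 1.0
    width = int(0.2 * rate)
    t = np.arange(-2 * width, 2 * width + 1)
    kern = np.exp(-0.5 * (t / width) ** 2)
    return np.convolve(x, kern, mode="same")


def simulate_trial(
    melody: Melody,
    features: StimulusFeatures,
    config: SimulationConfig,
    subject: SubjectModel,
    rng: np.random.Generator,
    subject_id: str = "sub00",
    condition: str = "listening",
    repetition: int = 0,
) -> EEGTrial:
    """One trial: stimulus drive + scaled spatially mixed pink noise.

    The drive is a function of (melody, subject) only, so repetitions are
    identical up to the noise.  Noise power is set per the configured SNR,
    defined as total stimulus-driven power over noise power averaged across
    channels.
    """
    if features.rate != config.rate:
        raise ValueError("features.rate must equal config.rate")
    drive = stimulus_drive(features, config, subject)
    data = drive.copy()
    if np.isfinite(config.snr_db):
        noise = pink_noise(rng, len(features), config.n_channels) @ subject.noise_mixing.T
        p_sig = float(np.mean(drive**2))
        p_noise = float(np.mean(noise**2))
        if p_noise > 0:
            target = p_sig / 10 ** (config.snr_db / 10) if p_sig > 0 else 1.0
            noise *= math.sqrt(target / p_noise)
        data = data + noise
        if config.blink_gain > 0 and subject.blink_mixing.any():
            blink = _blink_source(rng, len(features), config.rate)
            scale = config.blink_gain * math.sqrt(max(p_sig, 1.0))
            data = data + scale * np.outer(_unit_rms(blink), subject.blink_mixing)
    return EEGTrial(
        data=data,
        rate=config.rate,
        subject=subject_id,
        condition=condition,
        melody_id=melody.id,
        repetition=repetition,
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit-sphere points (x right, y anterior, z up)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def channel_layout(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Channel labels and unit-sphere positions for a simulated montage.

    Uses the standard BioSemi 64-channel layout when the count matches,
    otherwise a uniform spherical arrangement.
    """
    if n_channels == 64:
        from .preprocess import standard_layout_64

        return standard_layout_64()
    labels = [f"ch{i:02d}" for i in range(n_channels)]
    return labels, fibonacci_sphere(n_channels)


@dataclass
class Cohort:
    """A simulated experiment: melodies, their features, per-subject trials."""

    config: SimulationConfig
    melodies: list[Melody]
    features: dict[str, StimulusFeatures]
    trialsets: dict[str, TrialSet]

    @property
    def subjects(self) -> list[str]:
        return list(self.trialsets)


def simulate_cohort(config: SimulationConfig,
                    melodies: list[Melody] | None = None) -> Cohort:
    """Simulate every subject's full trial set (both conditions).

    Trial order is randomised per subject; metadata allows sorting back into
    the canonical (condition, melody, repetition) order.
    """
    ss = np.random.SeedSequence(config.seed)
    mel_rng = np.random.default_rng(ss.spawn(1)[0])
    if melodies is None:
        melodies = [
            generate_melody(
                mel_rng,
                n_bars=config.n_bars,
                tempo_bpm=config.tempo_bpm,
                beats_per_bar=config.beats_per_bar,
                pitch_range=config.pitch_range,
                step_bias=config.step_bias,
                half_note_prob=config.half_note_prob,
                melody_id=f"mel{m:02d}",
            )
            for m in range(config.n_melodies)
        ]
    features = {m.id: extract_features(m, config.rate) for m in melodies}
    labels, positions = channel_layout(config.n_channels)
    trialsets: dict[str, TrialSet] = {}
    subj_seeds = ss.spawn(config.n_subjects)
    for s in range(config.n_subjects):
        sid = f"sub{s:02d}"
        srng = np.random.default_rng(subj_seeds[s])
        model = _subject_model(srng, config, positions)
        trials = []
        for condition in config.conditions:
            for melody in melodies:
                for rep in range(config.n_repetitions):
                    trials.append(
                        simulate_trial(
                            melody,
                            features[melody.id],
                            config,
                            model,
                            srng,
                            subject_id=sid,
                            condition=condition,
                            repetition=rep,
                        )
                    )
        order = srng.permutation(len(trials))
        trialsets[sid] = TrialSet(
            [trials[i] for i in order], config.rate, list(labels), positions
        )
    return Cohort(config=config, melodies=melodies, features=features,
                  trialsets=trialsets)
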