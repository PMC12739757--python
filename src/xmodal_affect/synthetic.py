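"""Synthetic multimodal affective recordings.

Generates labelled trials with the statistical structure the recognition
pipeline assumes: a pink-noise EEG background carrying class-conditional
band-limited oscillations on a designated channel subset, peripheral
channels whose amplitude statistics are coupled to the class, and an
eye-movement event stream (fixations, saccades, blinks, pupil diameter)
whose event rates and pupil variability shift monotonically with the
class index.  Every trial is a pure, bit-reproducible function of
``(config, subject, trial_index)``.

The layout mirrors stimulus-locked affective experiments: each trial has
a pre-stimulus baseline segment (no class signal) followed by the
stimulus period that carries the class-conditional structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SimulationConfig",
    "EyeEventStream",
    "MultimodalRecording",
    "CLASS_BANDS",
    "generate_recording",
    "generate_dataset",
]

#: Band (low, high) in Hz boosted by each class, cycled by class index.
#: Class 0 boosts alpha, class 1 beta, class 2 theta, class 3 gamma.
CLASS_BANDS: tuple[tuple[float, float], ...] = (
    (8.0, 13.0),   # alpha
    (13.0, 30.0),  # beta
    (4.0, 8.0),    # theta
    (30.0, 45.0),  # gamma
)

#: Sampling rate of the simulated pupil-diameter trace (Hz).
PUPIL_RATE = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a small two-class study: 60 s stimulus trials with
    a 3 s pre-stimulus baseline, EEG at 128 Hz, and a class effect that
    boosts power in the class's designated band on a quarter of the EEG
    channels.  ``effect_size`` scales the amplitude of that oscillation
    relative to ``noise_sd``; 0 removes all class structure.
    """

    n_subjects: int = 2
    trials_per_subject: int = 40
    trial_seconds: float = 60.0
    baseline_seconds: float = 3.0
    eeg_rate: float = 128.0
    peri_rate: float = 128.0
    n_eeg_channels: int = 8
    n_peri_channels: int = 4
    n_classes: int = 2
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "trials_per_subject": self.trials_per_subject,
            "n_eeg_channels": self.n_eeg_channels,
            "n_peri_channels": self.n_peri_channels,
            "n_classes": self.n_classes,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        if self.trial_seconds <= 0:
            raise ValueError(f"trial_seconds must be > 0, got {self.trial_seconds!r}")
        if self.baseline_seconds < 0:
            raise ValueError(
                f"baseline_seconds must be >= 0, got {self.baseline_seconds!r}"
            )
        if self.eeg_rate <= 0 or self.peri_rate <= 0:
            raise ValueError("sampling rates must be > 0")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size!r}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd!r}")

    @property
    def total_seconds(self) -> float:
        return self.baseline_seconds + self.trial_seconds

    @property
    def signal_channels(self) -> int:
        """Number of EEG channels carrying the class oscillation (25 %, >= 1)."""
        return max(1, self.n_eeg_channels // 4)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EyeEventStream:
    """Oculomotor events and pupil trace for one trial.

    ``fixations`` rows are (onset s, duration ms, dispersion_x, dispersion_y);
    ``saccades`` rows are (onset s, duration ms, amplitude deg, latency ms);
    ``blinks`` rows are (onset s, duration ms).  ``pupil`` is an
    [samples x 2] diameter trace (X and Y) sampled at ``pupil_rate``.
    All event tables are time-ordered by onset.
    """

    fixations: np.ndarray
    saccades: np.ndarray
    blinks: np.ndarray
    pupil: np.ndarray
    pupil_rate: float
    duration_seconds: float

    def __post_init__(self) -> None:
        self.fixations = np.asarray(self.fixations, dtype=float).reshape(-1, 4)
        self.saccades = np.asarray(self.saccades, dtype=float).reshape(-1, 4)
        self.blinks = np.asarray(self.blinks, dtype=float).reshape(-1, 2)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.pupil.ndim != 2 or self.pupil.shape[1] != 2:
            raise ValueError("pupil trace must be [samples x 2]")
        for name, table in (
            ("fixations", self.fixations),
            ("saccades", self.saccades),
            ("blinks", self.blinks),
        ):
            if len(table) and np.any(np.diff(table[:, 0]) < 0):
                raise ValueError(f"{name} must be time-ordered by onset")
            if len(table) and np.any(table[:, 1] <= 0):
                raise ValueError(f"{name} durations must be > 0")


@dataclass
class MultimodalRecording:
    """One labelled trial: EEG block, peripheral block, eye events."""

    eeg: np.ndarray
    peripheral: np.ndarray
    eye_events: EyeEventStream
    label: int
    subject_id: int
    eeg_rate: float
    peri_rate: float
    baseline_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.peripheral = np.asarray(self.peripheral, dtype=float)
        if self.eeg.ndim != 2 or self.peripheral.ndim != 2:
            raise ValueError("signal blocks must be 2-D [samples x channels]")


def _trial_rng(config: SimulationConfig, subject_id: int, trial_index: int) -> np.random.Generator:
    """Independent generator for one (subject, trial) cell.

    Hierarchical seed split: the root seed plus a (subject, trial) spawn
    key gives reproducible, order-independent parallel generation.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(int(subject_id), int(trial_index)))
    return np.random.Generator(np.random.PCG64(ss))


def _pink_noise(rng: np.random.Generator, n_samples: int, n_channels: int, rate: float,
                sd: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise, unit-variance columns scaled to ``sd``.

    Shaped in the frequency domain: white Gaussian spectrum divided by
    sqrt(f) above a 0.5 Hz shoulder, which matches broadband EEG spectra
    far better than white noise.
    """
    n_fft = n_samples
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    shaping[0] = 0.0  # no DC
    white = rng.standard_normal((n_fft, n_channels)) + 1j * rng.standard_normal((n_fft, n_channels))
    spectrum = white[: len(freqs)] * shaping[:, None]
    x = np.fft.irfft(spectrum, n=n_fft, axis=0)
    x = x / x.std(axis=0, keepdims=True)
    return sd * x


def _class_oscillation(rng: np.random.Generator, config: SimulationConfig,
                       label: int, n_samples: int) -> np.ndarray:
    """Band-limited sinusoid with random phase for the trial's class."""
    low, high = CLASS_BANDS[label % len(CLASS_BANDS)]
    freq = rng.uniform(low + 0.5, high - 0.5)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n_samples) / config.eeg_rate
    amplitude = 0.5 * config.effect_size * config.noise_sd
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def _peripheral_block(rng: np.random.Generator, config: SimulationConfig,
                      label: int, n_samples: int) -> np.ndarray:
    """Baseline drift + class-coupled amplitude modulation + white noise."""
    t = np.arange(n_samples) / config.peri_rate
    out = np.empty((n_samples, config.n_peri_channels))
    class_frac = label / max(1, config.n_classes - 1)
    gain = 1.0 + 0.3 * config.effect_size * class_frac
    shift = 0.1 * config.effect_size * class_frac
    for ch in range(config.n_peri_channels):
        drift_f = rng.uniform(0.05, 0.2)
        drift = 0.5 * np.sin(2 * np.pi * drift_f * t + rng.uniform(0, 2 * np.pi))
        noise = rng.standard_normal(n_samples) * config.noise_sd
        out[:, ch] = drift + shift + gain * noise
    return out


def _poisson_events(rng: np.random.Generator, rate_hz: float, duration: float) -> np.ndarray:
    """Sorted event onsets of a homogeneous Poisson process on [0, duration)."""
    n = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _eye_stream(rng: np.random.Generator, config: SimulationConfig, label: int) -> EyeEventStream:
    """Poisson event streams with class-dependent rates; pupil variance grows with class."""
    duration = config.total_seconds
    class_frac = label / max(1, config.n_classes - 1)
    boost = 1.0 + 0.2 * config.effect_size * class_frac

    fix_onsets = _poisson_events(rng, 2.0 * boost, duration)
    fixations = np.column_stack([
        fix_onsets,
        rng.lognormal(np.log(250.0), 0.3, len(fix_onsets)),        # duration ms
        rng.exponential(0.8, len(fix_onsets)),                     # dispersion x
        rng.exponential(0.8, len(fix_onsets)),                     # dispersion y
    ]) if len(fix_onsets) else np.empty((0, 4))

    sac_onsets = _poisson_events(rng, 1.8 * boost, duration)
    saccades = np.column_stack([
        sac_onsets,
        rng.uniform(20.0, 80.0, len(sac_onsets)),                  # duration ms
        rng.gamma(2.0, 2.0, len(sac_onsets)),                      # amplitude deg
        rng.normal(200.0, 30.0, len(sac_onsets)).clip(min=50.0),   # latency ms
    ]) if len(sac_onsets) else np.empty((0, 4))

    blink_onsets = _poisson_events(rng, 0.25 * boost, duration)
    blinks = np.column_stack([
        blink_onsets,
        rng.lognormal(np.log(150.0), 0.25, len(blink_onsets)),     # duration ms
    ]) if len(blink_onsets) else np.empty((0, 2))

    n_pupil = int(round(duration * PUPIL_RATE))
    t = np.arange(n_pupil) / PUPIL_RATE
    pupil = np.empty((n_pupil, 2))
    sd = 0.1 * (1.0 + 0.2 * config.effect_size * class_frac)
    for axis in range(2):
        slow_f = rng.uniform(0.1, 0.5)
        slow = 0.05 * np.sin(2 * np.pi * slow_f * t + rng.uniform(0, 2 * np.pi))
        pupil[:, axis] = 4.0 + slow + sd * rng.standard_normal(n_pupil)

    return EyeEventStream(fixations, saccades, blinks, pupil, PUPIL_RATE, duration)


def label_for_trial(config: SimulationConfig, trial_index: int) -> int:
    """Balanced label assignment: classes cycle across trial indices."""
    return trial_index % config.n_classes


def generate_recording(config: SimulationConfig, subject_id: int,
                       trial_index: int) -> MultimodalRecording:
    """Simulate one labelled trial.

    The EEG block is pink noise plus, during the stimulus period only, a
    class-conditional sinusoid in the class's designated band on the
    first 25 % of channels, scaled by ``effect_size``.  The baseline
    segment is prepended and carries no class signal.
    """
    rng = _trial_rng(config, subject_id, trial_index)
    label = label_for_trial(config, trial_index)

    n_eeg = int(round(config.total_seconds * config.eeg_rate))
    n_base = int(round(config.baseline_seconds * config.eeg_rate))
    eeg = _pink_noise(rng, n_eeg, config.n_eeg_channels, config.eeg_rate, config.noise_sd)
    if config.effect_size > 0:
        osc = _class_oscillation(rng, config, label, n_eeg - n_base)
        eeg[n_base:, : config.signal_channels] += osc[:, None]

    n_peri = int(round(config.total_seconds * config.peri_rate))
    peripheral = _peripheral_block(rng, config, label, n_peri)
    eye = _eye_stream(rng, config, label)

    return MultimodalRecording(
        eeg=eeg,
        peripheral=peripheral,
        eye_events=eye,
        label=label,
        subject_id=int(subject_id),
        eeg_rate=config.eeg_rate,
        peri_rate=config.peri_rate,
        baseline_seconds=config.baseline_seconds,
    )


def generate_dataset(config: SimulationConfig) -> list[MultimodalRecording]:
    """All ``n_subjects x trials_per_subject`` trials, class-balanced per subject.

    Labels cycle through classes with the trial index, so per-class
    counts within a subject differ by at most one.
    """
    return [
        generate_recording(config, subject, trial)
        for subject in range(config.n_subjects)
        for trial in range(config.trials_per_subject)
    ]
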