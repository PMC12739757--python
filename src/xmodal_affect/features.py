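"""Feature extraction: band differential entropy, peripheral statistics, eye features.

Differential entropy (DE) of a Gaussian signal is ``0.5 * ln(2*pi*e*var)``
(nats).  EEG DE is computed per 4 s window and per frequency band from a
Hann-tapered periodogram: the one-sided PSD is integrated over the band
to give the variance of the band-limited component, and the Gaussian
closed form is applied to that variance.  Peripheral channels contribute
(mean, variance, DE) per window.  Eye-movement streams reduce to a
canonical 31-entry vector of pupil, fixation, saccade and blink
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocessing import BandDecomposition, BandDefinition, segment_windows
from .synthetic import EyeEventStream

__all__ = [
    "VARIANCE_FLOOR",
    "PUPIL_BANDS",
    "FeatureSequence",
    "EyeFeatureVector",
    "EYE_FEATURE_NAMES",
    "differential_entropy",
    "band_de",
    "extract_de_sequence",
    "peripheral_window_features",
    "peripheral_feature_names",
    "extract_peripheral_sequence",
    "extract_eye_features",
]

logger = logging.getLogger(__name__)

#: Lower bound on any variance entering a logarithm. A constant window
#: then yields a large negative but finite entropy instead of -inf.
VARIANCE_FLOOR = 1e-10

#: Sub-Hz pupil-diameter bands (Hz) for the pupil DE features.
PUPIL_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 0.2),
    (0.2, 0.4),
    (0.4, 0.6),
    (0.6, 1.0),
)


@dataclass
class FeatureSequence:
    """Time-ordered windows x features matrix for one modality of one trial."""

    values: np.ndarray
    window_seconds: float
    modality: str
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D [windows x features]")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.feature_names)} names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class EyeFeatureVector:
    """Canonical 31-entry eye-movement feature vector."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != 31 or len(self.names) != 31:
            raise ValueError(f"expected exactly 31 eye features, got {len(self.values)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("eye feature vector contains NaN/Inf")


def differential_entropy(samples: np.ndarray) -> float:
    """Gaussian differential entropy of a sample, ``0.5 * ln(2*pi*e*var)`` nats.

    The sample variance (ddof=1) is floored at ``VARIANCE_FLOOR`` so that
    constant input produces a finite value.  Shift-invariant by
    construction; strictly increasing in variance above the floor.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError(f"need at least 2 samples, got {len(x)}")
    var = max(float(np.var(x, ddof=1)), VARIANCE_FLOOR)
    return 0.5 * float(np.log(2.0 * np.pi * np.e * var))


def _band_variance(window: np.ndarray, rate: float, low: float, high: float) -> float:
    """Variance of the band-limited component via a Hann periodogram.

    Integrates the one-sided PSD over (low, high]; by Parseval the full
    integral recovers the total variance, so contiguous bands partition
    the signal power.
    """
    freqs, psd = sps.periodogram(window, fs=rate, window="hann", axis=0)
    df = freqs[1] - freqs[0]
    mask = (freqs > low) & (freqs <= high)
    return float(np.sum(psd[mask]) * df)


def band_de(window: np.ndarray, rate: float,
            band: BandDefinition | tuple[float, float]) -> float:
    """DE of a single window restricted to one frequency band (nats)."""
    if isinstance(band, BandDefinition):
        low, high = band.low, band.high
    else:
        low, high = band
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    if high >= rate / 2:
        raise ValueError(f"band high edge {high} Hz >= Nyquist {rate / 2} Hz")
    x = np.asarray(window, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("window too short")
    var = max(_band_variance(x, rate, low, high), VARIANCE_FLOOR)
    return 0.5 * float(np.log(2.0 * np.pi * np.e * var))


def extract_de_sequence(trial: BandDecomposition, window_seconds: float) -> FeatureSequence:
    """Windowed band-DE features for one trial.

    One row per window; columns ordered channel-major then band, so a
    62-channel, 5-band decomposition yields 310 features per row.
    """
    n_samples, n_channels = trial.shape
    if window_seconds * trial.rate > n_samples:
        raise ValueError("trial shorter than one window")
    per_band_windows = {
        b.name: segment_windows(trial.band_signals[b.name], trial.rate, window_seconds)
        for b in trial.bands
    }
    n_windows = len(next(iter(per_band_windows.values())))
    names = [
        f"ch{ch:02d}_{b.name}_de" for ch in range(n_channels) for b in trial.bands
    ]
    values = np.empty((n_windows, len(names)))
    for w in range(n_windows):
        col = 0
        for ch in range(n_channels):
            for b in trial.bands:
                values[w, col] = band_de(per_band_windows[b.name][w][:, ch], trial.rate, b)
                col += 1
    return FeatureSequence(values, window_seconds, "EEG", names)


def peripheral_window_features(window: np.ndarray) -> np.ndarray:
    """(mean, variance, DE) per channel, concatenated channel-major.

    8 channels therefore give a 24-dimensional vector.  A constant
    channel has zero variance; its DE is computed at the variance floor
    and the condition is logged.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples per channel")
    out = np.empty(3 * x.shape[1])
    for ch in range(x.shape[1]):
        col = x[:, ch]
        var = float(np.var(col, ddof=1))
        if var <= VARIANCE_FLOOR:
            logger.warning("constant peripheral channel %d: DE at variance floor", ch)
        out[3 * ch] = float(np.mean(col))
        out[3 * ch + 1] = var
        out[3 * ch + 2] = differential_entropy(col)
    return out


def peripheral_feature_names(n_channels: int) -> list[str]:
    return [
        f"ch{ch:02d}_{stat}" for ch in range(n_channels) for stat in ("mean", "var", "de")
    ]


def extract_peripheral_sequence(trial: np.ndarray, rate: float,
                                window_seconds: float) -> FeatureSequence:
    """Windowed peripheral statistics, aligned 1:1 with the EEG DE windows."""
    windows = segment_windows(trial, rate, window_seconds)
    values = np.stack([peripheral_window_features(w) for w in windows])
    n_channels = np.asarray(trial).shape[1] if np.asarray(trial).ndim == 2 else 1
    return FeatureSequence(values, window_seconds, "PERI",
                           peripheral_feature_names(n_channels))


def _event_stats(values: np.ndarray) -> tuple[float, float]:
    """(mean, sd) of an event attribute; zeros when the event list is empty."""
    if len(values) == 0:
        return 0.0, 0.0
    return float(np.mean(values)), float(np.std(values))


EYE_FEATURE_NAMES: list[str] = (
    [f"pupil_{ax}_{stat}" for ax in ("x", "y") for stat in ("mean", "sd")]
    + [f"pupil_{ax}_de_{lo:g}_{hi:g}hz" for ax in ("x", "y") for lo, hi in PUPIL_BANDS]
    + [f"dispersion_{ax}_{stat}" for ax in ("x", "y") for stat in ("mean", "sd")]
    + ["fixation_duration_mean", "fixation_duration_sd"]
    + ["blink_duration_mean", "blink_duration_sd"]
    + ["saccade_duration_mean", "saccade_duration_sd",
       "saccade_amplitude_mean", "saccade_amplitude_sd"]
    + ["blink_frequency", "fixation_frequency", "fixation_duration_max",
       "fixation_dispersion_total", "fixation_dispersion_max",
       "saccade_frequency", "saccade_latency_mean"]
)


def extract_eye_features(events: EyeEventStream) -> EyeFeatureVector:
    """Reduce an eye-movement stream to the canonical 31-entry vector.

    Pupil X/Y contribute mean, SD, and DE in four sub-Hz bands (12);
    fixation dispersion X/Y mean and SD (4); fixation, blink and saccade
    duration/amplitude means and SDs (8); and seven event statistics
    (frequencies, maxima, dispersion totals, saccade latency).  Empty
    event lists give zero frequency and zero duration statistics.
    """
    if events.pupil.size == 0:
        raise ValueError("pupil trace must be non-empty")
    duration = events.duration_seconds
    fix, sac, blink = events.fixations, events.saccades, events.blinks
    for name, table in (("fixations", fix), ("saccades", sac), ("blinks", blink)):
        if len(table) == 0:
            logger.info("no %s in trial: frequency and duration stats set to 0", name)

    values: list[float] = []
    for axis in range(2):
        trace = events.pupil[:, axis]
        values += [float(np.mean(trace)), float(np.std(trace))]
    for axis in range(2):
        trace = events.pupil[:, axis]
        values += [band_de(trace, events.pupil_rate, band) for band in PUPIL_BANDS]

    disp_x = fix[:, 2] if len(fix) else np.empty(0)
    disp_y = fix[:, 3] if len(fix) else np.empty(0)
    values += [*_event_stats(disp_x), *_event_stats(disp_y)]

    fix_dur = fix[:, 1] if len(fix) else np.empty(0)
    blink_dur = blink[:, 1] if len(blink) else np.empty(0)
    sac_dur = sac[:, 1] if len(sac) else np.empty(0)
    sac_amp = sac[:, 2] if len(sac) else np.empty(0)
    sac_lat = sac[:, 3] if len(sac) else np.empty(0)
    values += [*_event_stats(fix_dur), *_event_stats(blink_dur),
               *_event_stats(sac_dur), *_event_stats(sac_amp)]

    disp_mag = np.hypot(disp_x, disp_y)
    values += [
        len(blink) / duration,
        len(fix) / duration,
        float(fix_dur.max()) if len(fix) else 0.0,
        float(disp_mag.sum()),
        float(disp_mag.max()) if len(fix) else 0.0,
        len(sac) / duration,
        _event_stats(sac_lat)[0],
    ]
    return EyeFeatureVector(np.array(values), list(EYE_FEATURE_NAMES))
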