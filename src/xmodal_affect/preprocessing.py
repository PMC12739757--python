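"""Signal conditioning: baseline removal, decimation, band decomposition, windowing.

All filters are 4th-order Butterworth applied forward-backward
(zero-phase), so filtered signals stay temporally aligned across
modalities.  Resampling uses polyphase anti-aliased decimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "BandDecomposition",
    "DEAP_BANDS",
    "SEED4_BANDS",
    "remove_baseline",
    "resample",
    "bandpass",
    "decompose_bands",
    "segment_windows",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for_rate(self, rate: float) -> None:
        if self.high >= rate / 2:
            raise ValueError(
                f"band {self.name!r} high edge {self.high} Hz >= Nyquist {rate / 2} Hz"
            )


#: Four-band set for 128 Hz recordings (theta/alpha/beta/gamma).
DEAP_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

#: Five-band set for 200 Hz recordings (delta through gamma).
SEED4_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 31.0),
    BandDefinition("gamma", 31.0, 50.0),
)


@dataclass
class BandDecomposition:
    """One zero-phase filtered copy of a signal per band."""

    band_signals: dict[str, np.ndarray]
    bands: tuple[BandDefinition, ...]
    rate: float

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band list must be non-empty")
        shapes = {m.shape for m in self.band_signals.values()}
        if len(shapes) != 1:
            raise ValueError(f"band matrices must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.band_signals.values())).shape


def _as_2d(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D signal, got ndim={x.ndim}")
    return x


def remove_baseline(signal: np.ndarray, rate: float, baseline_seconds: float) -> np.ndarray:
    """Drop the pre-stimulus baseline segment from the front of a trial."""
    x = _as_2d(signal)
    n_drop = int(round(baseline_seconds * rate))
    if n_drop < 0:
        raise ValueError("baseline_seconds must be >= 0")
    if n_drop >= len(x):
        raise ValueError(
            f"baseline ({n_drop} samples) must be shorter than the signal ({len(x)})"
        )
    return x[n_drop:]


def resample(signal: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Anti-aliased polyphase downsampling from rate_in to rate_out.

    Only downsampling (or the identity) is supported; duration is
    preserved, so the sample count scales by ``rate_out / rate_in``.
    """
    if rate_out > rate_in:
        raise ValueError(f"upsampling unsupported: {rate_in} -> {rate_out} Hz")
    x = _as_2d(signal)
    if rate_out == rate_in:
        return x.copy()
    ratio = Fraction(rate_out / rate_in).limit_denominator(1000)
    return sps.resample_poly(x, up=ratio.numerator, down=ratio.denominator, axis=0)


def _butter_sos(band: BandDefinition, rate: float, order: int = 4):
    band.validate_for_rate(rate)
    return sps.butter(order, [band.low, band.high], btype="bandpass", fs=rate, output="sos")


def bandpass(signal: np.ndarray, rate: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass; shape preserved."""
    x = _as_2d(signal)
    sos = _butter_sos(band, rate)
    return sps.sosfiltfilt(sos, x, axis=0)


def decompose_bands(signal: np.ndarray, rate: float,
                    bands: tuple[BandDefinition, ...] | list[BandDefinition]) -> BandDecomposition:
    """One band-passed copy of the signal per band definition."""
    bands = tuple(bands)
    if not bands:
        raise ValueError("band list must be non-empty")
    x = _as_2d(signal)
    return BandDecomposition(
        band_signals={b.name: bandpass(x, rate, b) for b in bands},
        bands=bands,
        rate=rate,
    )


def segment_windows(signal: np.ndarray, rate: float, window_seconds: float,
                    overlap_seconds: float = 0.0) -> list[np.ndarray]:
    """Fixed-length windows in time order; a trailing partial window is discarded."""
    x = _as_2d(signal)
    win = int(round(window_seconds * rate))
    hop = win - int(round(overlap_seconds * rate))
    if win <= 0:
        raise ValueError("window_seconds must be > 0")
    if hop <= 0:
        raise ValueError("overlap must be shorter than the window")
    if win > len(x):
        raise ValueError(
            f"window ({win} samples) longer than signal ({len(x)} samples)"
        )
    return [x[start : start + win] for start in range(0, len(x) - win + 1, hop)]
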