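"""Band power estimation and the mu-desynchronization score.

Band power is estimated by Welch averaging of Hamming-windowed, 25%-overlapped
periodograms and integrated across the frequency bins inside the band (both
edges inclusive).  With density scaling the integral of the PSD over the band
recovers the in-band signal variance, so an in-band sinusoid of amplitude A
yields A**2/2 — the calibration constant of this normalization is 1.

The desynchronization score of an electrode is

    D = (ln P_task - ln P_rest) / ln P_rest * 100

with P the integrated mu/alpha (8-13 Hz) band power in µV².  Negative D means
task-related power suppression (event-related desynchronization).  The
denominator requires P_rest > 1 µV²; at or below 1 the score diverges or
flips sign, so smaller rest powers are a hard error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EpochSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high}) Hz")

    def validate_against(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} ({self.low}-{self.high} Hz) exceeds the "
                f"Nyquist frequency {fs / 2} Hz at fs={fs}"
            )


#: Classical EEG bands.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 60.0),
}

#: The mu band over sensorimotor cortex coincides with alpha (8-13 Hz).
MU_BAND = DEFAULT_BANDS["alpha"]


@dataclass(frozen=True)
class DesyncScore:
    """Per-electrode percent change of log band power, task vs. rest."""

    electrode: str
    value: float
    task_power: float
    rest_power: float


def band_power(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    window_len: float = 1.0,
    overlap_frac: float = 0.25,
) -> float:
    """Integrated band power (µV²) of a single-channel series.

    Welch average of Hamming-windowed periodograms of ``window_len`` seconds
    with fractional overlap ``overlap_frac``; PSD bins with
    ``low <= f <= high`` are summed and multiplied by the bin width.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("band_power expects a single-channel 1-D series")
    band.validate_against(fs)
    nperseg = int(round(window_len * fs))
    if nperseg < 2:
        raise ValueError(f"window of {window_len} s too short at fs={fs}")
    if len(x) < nperseg:
        raise ValueError(
            f"segment of {len(x)} samples shorter than one {nperseg}-sample window"
        )
    noverlap = int(round(nperseg * overlap_frac))
    freqs, psd = signal.welch(
        x, fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
        scaling="density", detrend="constant",
    )
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.low) & (freqs <= band.high)
    return float(psd[mask].sum() * df)


def desync_score(task_power: float, rest_power: float) -> float:
    """Percent change of log band power: (ln task - ln rest)/ln rest * 100."""
    if not rest_power > 1.0:
        raise ValueError(
            f"rest power must exceed 1 µV² (got {rest_power}); at or below 1 "
            "the log-ratio denominator ln(rest power) is zero or negative and "
            "the score is degenerate"
        )
    if not task_power > 0:
        raise ValueError(f"task power must be positive, got {task_power}")
    return (math.log(task_power) - math.log(rest_power)) / math.log(rest_power) * 100.0


def trial_average_desync(
    epochs_task: EpochSet,
    rest_segment: np.ndarray,
    electrode: str,
    band: BandDefinition = MU_BAND,
    window_len: float = 1.0,
    overlap_frac: float = 0.25,
) -> DesyncScore:
    """Average band power over task epochs, then score against the rest power.

    ``rest_segment`` is the (already screened) single-channel rest series for
    the same electrode.  Per-epoch powers are averaged before the log-ratio;
    epochs already removed by the artifact screen simply do not appear in the
    EpochSet and the average runs over what remains (count logged).
    """
    fs = epochs_task.source.fs
    powers = [
        band_power(seg, fs, band, window_len, overlap_frac)
        for seg in epochs_task.arrays(electrode)
    ]
    if not powers:
        raise ValueError("no task epochs to average")
    logger.info("averaging band power over %d task epoch(s) at %s", len(powers), electrode)
    task_p = float(np.mean(powers))
    rest_p = band_power(np.asarray(rest_segment), fs, band, window_len, overlap_frac)
    return DesyncScore(electrode, desync_score(task_p, rest_p), task_p, rest_p)
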