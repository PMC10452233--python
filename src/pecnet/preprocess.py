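"""Sensor-level preprocessing: filtering, downsampling, re-referencing, epoching.

All operations are deterministic and linear (epoch rejection aside), so
their order commutes up to numerical tolerance.  Filtering is zero-phase
(forward-backward 4th-order Butterworth per pass) to avoid group-delay
distortion of amplitude envelopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .bands import BANDS, BROADBAND, BandSpec

logger = logging.getLogger(__name__)

#: Default epoch window around stimulus onset, ms (closed interval).
DEFAULT_WINDOW = (-100.0, 500.0)
#: Default baseline window, ms.
DEFAULT_BASELINE = (-100.0, 0.0)


@dataclass
class SensorEpochs:
    """Epoched multichannel sensor data.

    data has shape (channels, samples, epochs); epoch_times gives the
    latency of every sample in ms relative to stimulus onset.
    """

    data: np.ndarray
    fs: float
    epoch_times: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    band: str = "broadband"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, epochs)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in epoched data")
        self.epoch_times = np.asarray(self.epoch_times, dtype=float)
        if self.epoch_times.shape != (self.data.shape[1],):
            raise ValueError("epoch_times must match the sample axis")
        step = np.diff(self.epoch_times)
        if step.size and (np.any(step <= 0)
                          or not np.allclose(step, 1000.0 / self.fs, rtol=1e-6)):
            raise ValueError("epoch_times must increase uniformly at 1000/fs ms")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis.

    `order` is the per-pass filter order; the forward-backward application
    doubles the effective roll-off and cancels the phase response.
    """
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got {lo}, {hi}")
    if hi >= fs / 2:
        raise ValueError(f"upper edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def downsample(x: np.ndarray, fs_in: float, fs_out: float = 256.0) -> np.ndarray:
    """Polyphase resampling (with built-in anti-alias filter) along the last axis."""
    if fs_out > fs_in:
        raise ValueError(f"cannot downsample {fs_in} Hz to {fs_out} Hz")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out).limit_denominator(10000) / Fraction(fs_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                                frac.denominator, axis=-1)


def average_reference(x: np.ndarray) -> np.ndarray:
    """Common-average re-referencing: subtract the instantaneous channel mean."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    return x - x.mean(axis=0, keepdims=True)


def epoch_and_baseline(x: np.ndarray, fs: float, onsets: np.ndarray,
                       window: tuple[float, float] = DEFAULT_WINDOW,
                       baseline: tuple[float, float] = DEFAULT_BASELINE,
                       band: str = "broadband",
                       channel_names: list[str] | None = None) -> SensorEpochs:
    """Cut stimulus-locked epochs and subtract the per-epoch baseline mean.

    The window is a closed interval with boundaries rounded to the nearest
    sample; at 256 Hz the default [-100, 500] ms window yields 155 samples.
    Onsets whose window falls outside the record are dropped with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be (channels, samples)")
    start = int(round(window[0] / 1000.0 * fs))
    stop = int(round(window[1] / 1000.0 * fs))
    if stop <= start:
        raise ValueError("empty epoch window")
    times = np.arange(start, stop + 1) / fs * 1000.0
    bmask = (times >= baseline[0]) & (times <= baseline[1])
    if not bmask.any():
        raise ValueError("baseline window contains no samples")

    epochs = []
    n = x.shape[1]
    for k, onset in enumerate(np.asarray(onsets, dtype=int)):
        a, b = onset + start, onset + stop
        if a < 0 or b >= n:
            logger.warning("epoch %d at onset %d outside recording; dropped", k, onset)
            continue
        epochs.append(x[:, a:b + 1])
    if not epochs:
        raise ValueError("no epochs fall inside the recording")
    data = np.stack(epochs, axis=-1)
    data = data - data[:, bmask, :].mean(axis=1, keepdims=True)
    return SensorEpochs(data=data, fs=fs, epoch_times=times,
                        channel_names=channel_names or [], band=band)


def reject_epochs(se: SensorEpochs, k: float = 8.0) -> tuple[SensorEpochs, np.ndarray]:
    """Amplitude-threshold epoch rejection (automatic stand-in for visual inspection).

    An epoch is rejected when any sample deviates from its channel median by
    more than k robust standard deviations (1.4826*MAD).  Returns the kept
    epochs and the indices of the kept epochs.
    """
    med = np.median(se.data, axis=(1, 2), keepdims=True)
    mad = np.median(np.abs(se.data - med), axis=(1, 2), keepdims=True)
    lim = k * 1.4826 * np.maximum(mad, np.finfo(float).tiny)
    bad = (np.abs(se.data - med) > lim).any(axis=(0, 1))
    keep = np.flatnonzero(~bad)
    if bad.any():
        logger.warning("rejected %d/%d epochs by amplitude threshold",
                       int(bad.sum()), se.n_epochs)
    if keep.size == 0:
        raise ValueError("all epochs rejected")
    return SensorEpochs(se.data[:, :, keep], se.fs, se.epoch_times,
                        list(se.channel_names), se.band), keep


def band_split(x: np.ndarray, fs: float,
               bands: dict[str, BandSpec] | None = None) -> dict[str, np.ndarray]:
    """Filter a continuous record into the four canonical bands."""
    out = {}
    for name, b in (bands or BANDS).items():
        out[name] = bandpass(x, fs, b.lo, b.hi)
    return out


def preprocess_continuous(x: np.ndarray, fs_in: float, fs_out: float = 256.0,
                          broadband: BandSpec = BROADBAND) -> np.ndarray:
    """Standard front end: downsample, broadband filter, average reference."""
    y = downsample(x, fs_in, fs_out)
    y = bandpass(y, fs_out, broadband.lo, broadband.hi)
    return average_reference(y)
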