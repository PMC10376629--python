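"""Core signal containers and pre-processing.

Holds the two raw inputs the pipeline understands — a uniformly sampled
1-D pulse trace and a per-frame mean-RGB trace — together with the three
front-end operations applied before any wavelet analysis:

* resampling onto the nearest power-of-two rate (cubic interpolation),
* zero-phase Butterworth band-pass pre-cleaning, and
* the POS (plane-orthogonal-to-skin) projection that converts a mean-RGB
  trace into an rPPG pulse candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "SampledSignal",
    "RGBTrace",
    "resample_to_pow2",
    "butter_bandpass",
    "pos_rppg",
]


@dataclass
class SampledSignal:
    """A uniformly sampled real-valued 1-D trace.

    Parameters
    ----------
    values : array-like
        Sample values, arbitrary amplitude units. Must be non-empty and
        finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values (NaN/inf)")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n samples / fs)."""
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    def copy(self) -> "SampledSignal":
        return SampledSignal(self.values.copy(), self.fs, self.t0)


@dataclass
class RGBTrace:
    """Per-frame spatial means of the R, G, B channels of a face video.

    The three channels must have equal length (>= 2 frames) and hold
    finite, non-negative intensities; ``fs`` is the frame rate in Hz.
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fs: float
    t0: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = self.r.size
        if not (self.g.size == n == self.b.size) or n < 2:
            raise ValueError("R, G, B must have equal length >= 2")
        stacked = np.stack([self.r, self.g, self.b])
        if not np.all(np.isfinite(stacked)):
            raise ValueError("RGB trace contains non-finite values")
        if np.any(stacked < 0):
            raise ValueError("RGB trace contains negative intensities")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValueError(f"frame rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.r.size

    def as_matrix(self) -> np.ndarray:
        """Channels stacked as a (3, n_frames) matrix in R, G, B order."""
        return np.stack([self.r, self.g, self.b])


def nearest_pow2_rate(fs: float) -> float:
    """Power of two 2**k minimising |2**k - fs|; ties resolve upward."""
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    k = math.log2(fs)
    lo = 2.0 ** math.floor(k)
    hi = 2.0 ** math.ceil(k)
    # tie goes to the larger power to avoid losing bandwidth
    return hi if (hi - fs) <= (fs - lo) else lo


def resample_to_pow2(sig: SampledSignal) -> SampledSignal:
    """Resample onto the power-of-two rate nearest the original rate.

    Cubic-spline interpolation on a uniform grid spanning the original
    record; the duration is preserved to within one output sample. A
    signal already at a power-of-two rate is returned unchanged (copy).
    """
    if len(sig) < 2:
        raise ValueError("need at least 2 samples to resample")
    new_fs = nearest_pow2_rate(sig.fs)
    if new_fs == sig.fs:
        return sig.copy()
    span = (len(sig) - 1) / sig.fs  # time of last original sample
    n_new = int(math.floor(span * new_fs)) + 1
    t_new = np.arange(n_new) / new_fs
    spline = CubicSpline(np.arange(len(sig)) / sig.fs, sig.values)
    return SampledSignal(spline(t_new), new_fs, sig.t0)


def _design_bandpass(fs: float, band: tuple[float, float], order: int) -> np.ndarray:
    low, high = band
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got band {band}")
    if high >= fs / 2:
        raise ValueError(
            f"band edge {high} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    return sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")


def butter_bandpass(
    sig: SampledSignal,
    band: tuple[float, float] = (0.7, 5.0),
    order: int = 7,
) -> SampledSignal:
    """Zero-phase Butterworth band-pass filter.

    The filter of the stated design ``order`` is applied forward and
    backward (``sosfiltfilt``), preserving peak positions exactly; the
    output has the same length and rate as the input. The signal is
    odd-extended by up to 3 s at each end before filtering — a
    narrow-band design of this order rings for a second or more, and
    the default padding leaves visible transients (hence shifted
    peaks) within the first/last beat of a record.
    """
    sos = _design_bandpass(sig.fs, band, order)
    padlen = min(len(sig) - 1, int(3.0 * sig.fs))
    out = sps.sosfiltfilt(sos, sig.values, padlen=padlen)
    return SampledSignal(out, sig.fs, sig.t0)


def min_bandpass_length(order: int = 7) -> int:
    """Smallest segment length sosfiltfilt accepts for the band-pass design."""
    # padlen for sosfiltfilt is 3 * (2 * n_sections + 1); the band-pass of
    # design order m yields m biquad sections.
    return 3 * (2 * order + 1) + 1


def pos_rppg(trace: RGBTrace, win_seconds: float = 1.6) -> SampledSignal:
    """POS projection of a mean-RGB trace onto a pulse candidate.

    In every sliding window the channels are temporally normalised by
    their window means, projected onto the plane orthogonal to the skin
    tone ([0, 1, -1] and [-2, 1, 1]), combined with the sigma ratio
    ``S1 + (std(S1)/std(S2)) * S2``, mean-removed and overlap-added.

    The default 1.6 s window spans at least one cardiac cycle at the
    slowest plausible heart rate while staying short enough for the
    stationarity assumption behind the per-window normalisation.
    """
    C = trace.as_matrix()
    n = C.shape[1]
    win = int(round(win_seconds * trace.fs))
    if win < 2:
        raise ValueError("POS window shorter than 2 frames")
    if n < win:
        raise ValueError(
            f"trace ({n} frames) shorter than POS window ({win} frames)"
        )
    h = np.zeros(n)
    for start in range(0, n - win + 1):
        block = C[:, start : start + win]
        mu = block.mean(axis=1)
        if np.any(mu == 0):
            raise ValueError("zero channel mean in a POS window")
        Cn = block / mu[:, None]
        s1 = Cn[1] - Cn[2]
        s2 = Cn[1] + Cn[2] - 2.0 * Cn[0]
        sd2 = s1.std(), s2.std()
        alpha = sd2[0] / sd2[1] if sd2[1] > 0 else 0.0
        hw = s1 + alpha * s2
        h[start : start + win] += hw - hw.mean()
    return SampledSignal(h, trace.fs, trace.t0)
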