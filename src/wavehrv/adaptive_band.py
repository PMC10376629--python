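"""Adaptive narrow-band filtering driven by scattering energies.

A window of length w slides over the pre-cleaned pulse trace with step
s. For each window the per-wavelet scattering energies are linearly
interpolated to the window's right edge, a K-means (K=3) clustering of
(frequency, energy) points picks a narrow heart-rate band, the window
is band-pass filtered to that band and mean-removed, and the refined
windows are summed back together (overlap-add). Because edge samples
are covered by fewer windows than interior ones, a coverage-equalising
gain is applied to the first and last w seconds of the reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .scattering import ScatteringCoeffs
from .signals import SampledSignal, butter_bandpass, min_bandpass_length

__all__ = [
    "WindowPlan",
    "FrequencyBand",
    "interp_window_energy",
    "estimate_band",
    "refine_window",
    "reconstruct_overlap_add",
    "amplify_edges",
]

logger = logging.getLogger(__name__)

GLOBAL_BAND = (0.7, 5.0)  # heart-rate band in Hz; all narrow bands clamp here


@dataclass(frozen=True)
class FrequencyBand:
    """A [low, high] Hz passband inside the global heart-rate band."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (GLOBAL_BAND[0] <= self.low < self.high <= GLOBAL_BAND[1]):
            raise ValueError(
                f"band [{self.low}, {self.high}] outside {GLOBAL_BAND}"
            )

    def contains(self, f: float) -> bool:
        return self.low <= f <= self.high


@dataclass
class WindowPlan:
    """Sliding-window tiling: window j covers [j*s, j*s + w) seconds.

    The final window is clipped to the signal end; window starts are
    chosen so every sample is covered and the clipped final window is
    always longer than w - s.
    """

    window_seconds: float
    step_seconds: float
    n_samples: int
    fs: float

    def __post_init__(self) -> None:
        if not (0 < self.step_seconds <= self.window_seconds):
            raise ValueError("need 0 < step <= window length")
        if self.n_samples < 2:
            raise ValueError("empty plan")

    @property
    def w_samples(self) -> int:
        return int(round(self.window_seconds * self.fs))

    @property
    def s_samples(self) -> int:
        return max(1, int(round(self.step_seconds * self.fs)))

    @property
    def n_windows(self) -> int:
        if self.n_samples <= self.w_samples:
            return 1
        return int(np.ceil((self.n_samples - self.w_samples) / self.s_samples)) + 1

    def slices(self) -> list[tuple[int, int]]:
        """(start, stop) sample index pairs, final stop clipped to the end."""
        out = []
        for j in range(self.n_windows):
            start = j * self.s_samples
            stop = min(start + self.w_samples, self.n_samples)
            out.append((start, stop))
        return out

    def coverage(self) -> np.ndarray:
        """Number of windows covering each sample."""
        cov = np.zeros(self.n_samples, dtype=int)
        for start, stop in self.slices():
            cov[start:stop] += 1
        return cov


def interp_window_energy(
    coeffs: ScatteringCoeffs, window_end: float
) -> np.ndarray:
    """Per-wavelet energy at ``window_end`` seconds.

    Linear interpolation between the two pooled frames bracketing the
    window's right edge: E = ((D - x)/D) * E_{i-1} + (x/D) * E_i with D
    the pooling spacing and x the offset past frame i-1. Ends clamp to
    the first/last frame; with a single frame its energies are returned
    as-is.
    """
    t = coeffs.frame_times
    if t.size == 1:
        return coeffs.S[:, 0].copy()
    te = float(np.clip(window_end, t[0], t[-1]))
    i = int(np.searchsorted(t, te, side="right"))
    i = min(max(i, 1), t.size - 1)
    delta = t[i] - t[i - 1]
    x = te - t[i - 1]
    frac = x / delta
    return (1.0 - frac) * coeffs.S[:, i - 1] + frac * coeffs.S[:, i]


def _minmax(v: np.ndarray) -> np.ndarray:
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def estimate_band(
    freqs: np.ndarray,
    energies: np.ndarray,
    seed: int = 0,
    rule: str = "centroid_span",
    energy_weight: float = 1.0 / 3.0,
) -> FrequencyBand:
    """Narrow band from K-means (K=3) on (frequency, energy) points.

    Both features are min-max normalised before clustering (raw Hz and
    energy scales are incommensurate). The frequency feature is taken
    in the log domain, matching the geometric spacing of the wavelet
    grid — on a linear axis the low-frequency wavelets collapse onto
    each other and the left cluster centroid lands on top of the
    spectral peak instead of below it. The energy feature is scaled to
    [0, ``energy_weight``]: with the frequency axis spanning [0, 1],
    within-cluster frequency spread is about 1/3 for three clusters,
    so an energy span kept below that keeps the partition spectrally
    contiguous — energy shifts the cluster boundaries toward where the
    power sits but cannot detach a lone spectral peak into a singleton
    cluster, which would put the band's low edge on top of the heart
    rate instead of below it.

    K-means uses k-means++ initialisation with a fixed seed, 10
    restarts and a 300 iteration cap. With ``rule='centroid_span'``
    the band is [frequency of leftmost centroid, frequency of
    rightmost centroid] (centroid frequencies are geometric means of
    the members); ``rule='peak_cluster'`` instead returns the
    frequency extent of the highest-energy cluster. The result clamps
    to the global 0.7-5 Hz band; degenerate clusterings fall back to
    the full band.
    """
    freqs = np.asarray(freqs, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if freqs.size != energies.size:
        raise ValueError("freqs and energies must align")
    if np.unique(freqs).size < 3:
        raise ValueError("need at least 3 distinct frequencies")
    logf = np.log(freqs)
    X = np.column_stack([_minmax(logf), energy_weight * _minmax(energies)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(
                n_clusters=3,
                init="k-means++",
                n_init=10,
                max_iter=300,
                random_state=seed,
            ).fit(X)
        labels = km.labels_
        if np.unique(labels).size < 3:
            raise ValueError("empty cluster")
        # denormalise centroid frequencies back to Hz (log domain)
        fspan = logf.max() - logf.min()
        cf = np.exp(km.cluster_centers_[:, 0] * fspan + logf.min())
        if rule == "centroid_span":
            low, high = float(cf.min()), float(cf.max())
        elif rule == "peak_cluster":
            mean_e = np.array(
                [energies[labels == k].mean() for k in range(3)]
            )
            members = freqs[labels == int(np.argmax(mean_e))]
            low, high = float(members.min()), float(members.max())
        else:
            raise ValueError(f"unknown band rule {rule!r}")
    except ValueError as exc:
        if "band rule" in str(exc):
            raise
        logger.warning("degenerate clustering (%s); using full band", exc)
        return FrequencyBand(*GLOBAL_BAND)
    low = max(low, GLOBAL_BAND[0])
    high = min(high, GLOBAL_BAND[1])
    if not low < high:
        logger.warning("clamped band collapsed; using full band")
        return FrequencyBand(*GLOBAL_BAND)
    return FrequencyBand(low, high)


def refine_window(
    segment: SampledSignal,
    band: FrequencyBand,
    order: int = 7,
    min_width_hz: float = 0.1,
) -> SampledSignal:
    """Band-pass a window to its narrow band and remove its mean.

    A degenerate band (width < 0.05 Hz) is widened symmetrically to
    ``min_width_hz`` before filtering, staying inside the global band.
    """
    low, high = band.low, band.high
    if high - low < 0.05:
        mid = 0.5 * (low + high)
        low = max(GLOBAL_BAND[0], mid - min_width_hz / 2)
        high = min(GLOBAL_BAND[1], low + min_width_hz)
        low = high - min_width_hz  # re-anchor if clamped at the top
        low = max(low, GLOBAL_BAND[0])
    if len(segment) < min_bandpass_length(order):
        raise ValueError(
            f"window of {len(segment)} samples too short for an order-"
            f"{order} zero-phase filter"
        )
    out = butter_bandpass(segment, (low, high), order)
    out.values -= out.values.mean()
    return out


def reconstruct_overlap_add(
    segments: list[SampledSignal], plan: WindowPlan
) -> SampledSignal:
    """Sum refined window segments back onto the full time axis."""
    slices = plan.slices()
    if len(segments) != len(slices):
        raise ValueError(
            f"{len(segments)} segments for {len(slices)} plan windows"
        )
    out = np.zeros(plan.n_samples)
    t0 = segments[0].t0 if segments else 0.0
    for seg, (start, stop) in zip(segments, slices):
        if len(seg) != stop - start:
            raise ValueError(
                f"segment length {len(seg)} does not fit plan slot "
                f"[{start}, {stop})"
            )
        out[start:stop] += seg.values
    return SampledSignal(out, plan.fs, t0)


def amplify_edges(sig: SampledSignal, plan: WindowPlan) -> SampledSignal:
    """Equalise overlap-add coverage at the two ends of the record.

    Interior samples are covered by ~w/s windows but the first step
    slice by one, the second by two, and so on, so edge peaks come out
    attenuated. Each sample within w seconds of either end is scaled by
    (w/s) / coverage, capped below at 1 — at the start this equals the
    per-slice gain c_j = (w/s)/(j+1); at the end the gain follows the
    actual coverage profile, which the clipped final window can shift
    off the mirrored pattern. Samples beyond w from both ends are left
    untouched.
    """
    target = plan.window_seconds / plan.step_seconds
    if target < 1:
        return sig.copy()
    out = sig.values.copy()
    n = plan.n_samples
    cov = plan.coverage().astype(float)
    cov[cov == 0] = 1.0
    w = plan.w_samples
    head = min(w, n // 2)
    tail_start = max(n - w, head)
    gain = np.maximum(1.0, target / cov)
    out[:head] *= gain[:head]
    out[tail_start:] *= gain[tail_start:]
    return SampledSignal(out, sig.fs, sig.t0)
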