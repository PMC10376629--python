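"""Time- and frequency-domain HRV metrics from a refined IBI series.

SDNN (overall variability), RMSSD (beat-to-beat, parasympathetic
marker), the Baevsky stress index derived from the IBI histogram, and
the LF/HF spectral power ratio of the tachogram. Normal short-term
(< 5 min) ranges quoted in the HRV literature: SDNN 32-93 ms, RMSSD
19-75 ms, Baevsky SI roughly 50-1500 depending on stress, LF/HF about
1-11.5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import detrend, periodogram

from .peaks_ibi import IBISeries

__all__ = [
    "HRVReport",
    "sdnn",
    "rmssd",
    "baevsky_si",
    "lf_hf",
    "compute_report",
]

LF_BAND = (0.04, 0.15)  # sympathetic-dominated band, Hz
HF_BAND = (0.15, 0.40)  # parasympathetic (respiratory) band, Hz


@dataclass
class HRVReport:
    """Bundle of HRV metrics plus bookkeeping.

    ``lf_hf`` and ``baevsky_si`` are None when undefined (record too
    short, constant IBIs, ...); ``flags`` lists why.
    """

    sdnn_ms: float | None
    rmssd_ms: float | None
    baevsky_si: float | None
    lf_hf: float | None
    mean_hr_bpm: float | None
    n_ibis_used: int
    n_ibis_dropped: int
    flags: list[str]
    schema_version: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def sdnn(series: IBISeries) -> float:
    """Standard deviation of NN intervals (N-1 denominator), in ms."""
    if len(series) < 2:
        raise ValueError("SDNN needs at least 2 intervals")
    return float(np.std(series.ibis_ms, ddof=1))


def rmssd(series: IBISeries) -> float:
    """Root mean square of successive differences, in ms.

    The mean runs over the N-1 successive differences of N intervals.
    """
    if len(series) < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(series.ibis_ms)
    return float(np.sqrt(np.mean(d**2)))


def baevsky_si(series: IBISeries, bin_ms: float = 50.0) -> float:
    """Baevsky stress index AMo / (2 * Mo * MxDMn).

    Intervals are histogrammed into fixed bins of width ``bin_ms``
    centred on multiples of the bin width (the convention of the
    Baevsky literature; 800 ms falls in the 775-825 ms bin). Mo is the
    centre of the tallest bin in *seconds*, AMo the percentage of
    intervals in that bin, MxDMn the interval range in seconds — units
    that land the index in its conventional 50-1500 range. Ties for the
    tallest bin resolve to the slower (lower-frequency) bin.
    """
    if len(series) < 10:
        raise ValueError("Baevsky SI needs at least 10 intervals")
    ibis = series.ibis_ms
    mxdmn_ms = float(ibis.max() - ibis.min())
    if mxdmn_ms == 0:
        raise ValueError("constant intervals: MxDMn = 0, SI undefined")
    bins = np.floor(ibis / bin_ms + 0.5).astype(int)
    counts = np.bincount(bins)
    mode_bin = int(np.argmax(counts))  # first maximum -> lowest bin
    mo_s = mode_bin * bin_ms / 1000.0
    amo_pct = 100.0 * counts[mode_bin] / ibis.size
    return float(amo_pct / (2.0 * mo_s * mxdmn_ms / 1000.0))


def lf_hf(
    series: IBISeries,
    resample_hz: float = 4.0,
    min_span_s: float = 30.0,
    welch: bool = False,
) -> float:
    """LF/HF spectral power ratio of the tachogram.

    The IBI-versus-beat-time series is cubically interpolated onto a
    uniform grid at ``resample_hz`` (4 Hz is standard HRV practice),
    linearly detrended, and its periodogram integrated over the LF
    (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands. Records spanning less
    than ``min_span_s`` are refused: below ~30 s the LF band holds
    barely one cycle and the ratio is meaningless.
    """
    if series.span_s < min_span_s:
        raise ValueError(
            f"record spans {series.span_s:.1f} s; LF/HF needs >= "
            f"{min_span_s:.0f} s"
        )
    if len(series) < 4:
        raise ValueError("too few intervals for spectral analysis")
    t = series.beat_times_s
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    tach = CubicSpline(t, series.ibis_ms)(grid)
    tach = detrend(tach)
    if welch:
        from scipy.signal import welch as _welch

        nper = min(tach.size, int(resample_hz * 120))
        f, p = _welch(tach, fs=resample_hz, nperseg=nper)
    else:
        f, p = periodogram(tach, fs=resample_hz)
    df = f[1] - f[0]
    lf = p[(f >= LF_BAND[0]) & (f < LF_BAND[1])].sum() * df
    hf = p[(f >= HF_BAND[0]) & (f < HF_BAND[1])].sum() * df
    if hf <= 0:
        raise ValueError("no HF power; LF/HF undefined")
    return float(lf / hf)


def compute_report(
    series: IBISeries,
    n_dropped: int = 0,
    baevsky_bin_ms: float = 50.0,
    tachogram_hz: float = 4.0,
    lfhf_min_span_s: float = 30.0,
) -> HRVReport:
    """All metrics with undefined ones flagged rather than raised."""
    flags: list[str] = []
    vals: dict[str, float | None] = {}
    for name, fn in (
        ("sdnn_ms", lambda: sdnn(series)),
        ("rmssd_ms", lambda: rmssd(series)),
        ("baevsky_si", lambda: baevsky_si(series, baevsky_bin_ms)),
        (
            "lf_hf",
            lambda: lf_hf(series, tachogram_hz, lfhf_min_span_s),
        ),
    ):
        try:
            vals[name] = fn()
        except ValueError as exc:
            vals[name] = None
            flags.append(f"{name}: {exc}")
    mean_hr = (
        float(60000.0 / series.ibis_ms.mean()) if len(series) else None
    )
    if len(series) == 0:
        flags.append("unreliable: no intervals survived refinement")
    return HRVReport(
        sdnn_ms=vals["sdnn_ms"],
        rmssd_ms=vals["rmssd_ms"],
        baevsky_si=vals["baevsky_si"],
        lf_hf=vals["lf_hf"],
        mean_hr_bpm=mean_hr,
        n_ibis_used=len(series),
        n_ibis_dropped=n_dropped,
        flags=flags,
    )
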