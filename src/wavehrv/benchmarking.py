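"""Ground-truth cleaning criteria and agreement statistics.

Contact PPG/ECG reference recordings are themselves noisy (device
disconnection, loose electrodes, finger motion inside the oximeter),
and a handful of false peaks shifts HRV dramatically, so reference IBI
series are screened before being used as a benchmark: records with a
covered face or physiologically impossible heart rate are rejected
outright, individual intervals off by more than 30% from their segment
mean are removed, and records whose cleaned SDNN or RMSSD still exceed
100 ms are rejected as beyond the plausible short-term range.

Agreement between estimated and reference HRV is summarised by MAE,
the RMS of paired differences, Pearson r, a paired t-test, and
Bland-Altman bias with 95% limits of agreement.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hrv_metrics import rmssd, sdnn
from .peaks_ibi import IBISeries

__all__ = ["CleaningReport", "AgreementStats", "clean_ground_truth", "agreement_stats"]


@dataclass
class CleaningReport:
    """Outcome of screening one reference IBI record."""

    accepted: bool
    reasons: list[str] = field(default_factory=list)
    ibis_removed: int = 0
    cleaned: IBISeries | None = None

    def to_dict(self) -> dict:
        d = {
            "accepted": self.accepted,
            "reasons": self.reasons,
            "ibis_removed": self.ibis_removed,
        }
        if self.cleaned is not None:
            d["n_ibis"] = len(self.cleaned)
        return d


@dataclass
class AgreementStats:
    """Paired agreement summary between estimates and reference values."""

    mae: float
    sd: float  # RMS of paired differences (uncentered, as defined)
    r: float | None
    t: float
    p: float
    n: int
    mean_diff: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def clean_ground_truth(
    series: IBISeries,
    face_covered: bool = False,
    segment_len: int = 25,
    segment_frac: float = 0.3,
    hr_limits_bpm: tuple[float, float] = (45.0, 200.0),
    sdnn_max_ms: float = 100.0,
    rmssd_max_ms: float = 100.0,
) -> CleaningReport:
    """Screen a reference IBI series against the cleaning criteria.

    Order of evaluation:

    1. a covered face at any instant rejects the record;
    2. any instantaneous HR (60000/IBI) outside ``hr_limits_bpm`` on
       the *raw* intervals rejects the record (a disconnected device
       produces intervals the segment rule below would quietly mask);
    3. intervals outside segment-mean +- ``segment_frac``*segment-mean
       are removed, over consecutive segments of ``segment_len``
       intervals (the final partial segment is screened too);
    4. SDNN or RMSSD above 100 ms on the *cleaned* series rejects the
       record as outside the physiologically plausible short-term range.
    """
    if len(series) == 0:
        raise ValueError("empty IBI series")
    reasons: list[str] = []
    if face_covered:
        reasons.append("face_covered")
    hr = 60000.0 / series.ibis_ms
    if np.any((hr < hr_limits_bpm[0]) | (hr > hr_limits_bpm[1])):
        reasons.append("hr_out_of_range")

    keep = np.ones(len(series), dtype=bool)
    ibis = series.ibis_ms
    for start in range(0, len(series), segment_len):
        seg = ibis[start : start + segment_len]
        m = seg.mean()
        keep[start : start + segment_len] = np.abs(seg - m) <= segment_frac * m
    cleaned = series.take(keep)
    removed = int((~keep).sum())

    if len(cleaned) == 0:
        reasons.append("empty_after_cleaning")
    else:
        if len(cleaned) >= 2:
            if sdnn(cleaned) > sdnn_max_ms:
                reasons.append("sdnn_too_high")
            if rmssd(cleaned) > rmssd_max_ms:
                reasons.append("rmssd_too_high")
    return CleaningReport(
        accepted=not reasons,
        reasons=reasons,
        ibis_removed=removed,
        cleaned=cleaned,
    )


def agreement_stats(estimates, truths) -> AgreementStats:
    """Paired agreement between estimated and reference values.

    MAE is the mean absolute difference; ``sd`` is the *root mean
    square* of the differences (uncentered — this definition, unlike a
    conventional SD, does not subtract the bias); ``r`` is Pearson
    correlation (None when either vector has zero variance); the paired
    t statistic is mean(d) / (SD(d)/sqrt(n)) with the sample SD (N-1)
    of the differences and a two-sided p from the t distribution with
    n-1 df. Bland-Altman limits are mean difference +- 1.96 * SD(d).
    Differences are estimate minus truth.
    """
    y = np.asarray(truths, dtype=float)
    yhat = np.asarray(estimates, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("estimates and truths must be equal-length vectors")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in inputs")
    d = yhat - y
    mae = float(np.mean(np.abs(d)))
    sd_rms = float(np.sqrt(np.mean(d**2)))
    if np.std(y) == 0 or np.std(yhat) == 0:
        r = None
    else:
        r = float(stats.pearsonr(y, yhat).statistic)
    mean_diff = float(d.mean())
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0:
        t = 0.0 if mean_diff == 0 else float(np.inf) * np.sign(mean_diff)
        p = 1.0 if mean_diff == 0 else 0.0
    else:
        t = mean_diff / (sd_d / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return AgreementStats(
        mae=mae,
        sd=sd_rms,
        r=r,
        t=float(t),
        p=p,
        n=n,
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd_d,
        loa_high=mean_diff + 1.96 * sd_d,
    )
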