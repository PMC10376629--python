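"""End-to-end orchestration: pulse trace (or RGB trace) to HRV report.

Stage order: POS projection (RGB input only) -> power-of-two
resampling -> global Butterworth pre-clean (0.7-5 Hz, order 7) ->
first-order scattering (16 s pooling, 20 wavelets) -> per-window
K-means band estimation + narrow band-pass + mean removal ->
overlap-add reconstruction -> edge amplification -> AMPD peak
detection -> IBI conversion -> three-rule IBI refinement -> HRV
metrics. Fully deterministic given the configuration seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import adaptive_band as ab
from .hrv_metrics import HRVReport, compute_report
from .peaks_ibi import detect_peaks_ampd, peaks_to_ibis, refine_ibis
from .scattering import build_filterbank, scatter_first_order
from .signals import RGBTrace, SampledSignal, butter_bandpass, pos_rppg, resample_to_pow2

__all__ = ["PipelineConfig", "PipelineResult", "run_wavehrv"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with their standard defaults."""

    # front end
    pos_window_seconds: float = 1.6
    band_low_hz: float = 0.7
    band_high_hz: float = 5.0
    filter_order: int = 7
    # scattering
    pooling_seconds: float = 16.0
    n_wavelets: int = 20
    # windowing
    window_seconds: float = 14.5
    step_seconds: float = 2.0
    band_rule: str = "centroid_span"  # or "peak_cluster"
    kmeans_seed: int = 0
    # peaks / IBIs
    max_scale_s: float = 1.5
    subsample_peaks: bool = True
    ibi_min_ms: float = 400.0
    ibi_max_ms: float = 1300.0
    ibi_mean_frac: float = 0.4
    ibi_block_size: int = 10
    ibi_block_frac: float = 0.2
    # metrics
    baevsky_bin_ms: float = 50.0
    tachogram_hz: float = 4.0
    # durations
    min_duration_s: float = 16.0
    lfhf_min_duration_s: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low < band_high")
        if self.filter_order < 1:
            raise ValueError("filter order must be >= 1")
        if self.pooling_seconds <= 0 or self.n_wavelets < 2:
            raise ValueError("invalid scattering configuration")
        if not (0 < self.step_seconds <= self.window_seconds):
            raise ValueError("need 0 < step <= window")
        if self.band_rule not in ("centroid_span", "peak_cluster"):
            raise ValueError(f"unknown band rule {self.band_rule!r}")
        if self.min_duration_s < self.pooling_seconds:
            raise ValueError(
                "minimum duration cannot be below one pooling window"
            )
        if not (0 < self.ibi_min_ms < self.ibi_max_ms):
            raise ValueError("invalid IBI bounds")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class PipelineResult:
    """HRV report plus every intermediate of the chain."""

    report: HRVReport
    intermediates: dict = field(default_factory=dict)

    def report_json(self, config: PipelineConfig | None = None) -> str:
        d = self.report.to_dict()
        if config is not None:
            d["config"] = config.to_dict()
        return json.dumps(d, sort_keys=True, indent=2)


def run_wavehrv(
    source: SampledSignal | RGBTrace,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full chain on a pulse trace or a mean-RGB trace.

    Records shorter than ``config.min_duration_s`` (default 16 s) are
    refused — below ~15 s no meaningful HRV can be extracted. LF/HF is
    additionally gated on a 30 s span. The returned intermediates hold
    the rPPG candidate, the resampled and pre-cleaned traces, the
    scattering coefficients, per-window bands, the reconstructed
    signal, detected peaks and raw/refined IBI series.
    """
    cfg = config or PipelineConfig()
    inter: dict = {}

    if isinstance(source, RGBTrace):
        sig = pos_rppg(source, cfg.pos_window_seconds)
        inter["rppg_candidate"] = sig
    elif isinstance(source, SampledSignal):
        sig = source
    else:
        raise TypeError("input must be a SampledSignal or RGBTrace")

    if sig.duration < cfg.min_duration_s:
        raise ValueError(
            f"record of {sig.duration:.1f} s is below the minimum of "
            f"{cfg.min_duration_s:.0f} s for HRV analysis"
        )

    sig = resample_to_pow2(sig)
    inter["resampled"] = sig
    band = (cfg.band_low_hz, cfg.band_high_hz)
    clean = butter_bandpass(sig, band, cfg.filter_order)
    inter["precleaned"] = clean

    bank = build_filterbank(
        clean.fs,
        n_in_band=cfg.n_wavelets,
        pooling_seconds=cfg.pooling_seconds,
        fmin=cfg.band_low_hz,
        fmax=cfg.band_high_hz,
    )
    coeffs = scatter_first_order(clean, bank)
    inter["scattering"] = coeffs

    plan = ab.WindowPlan(
        cfg.window_seconds, cfg.step_seconds, len(clean), clean.fs
    )
    segments = []
    bands = []
    for start, stop in plan.slices():
        window_end_s = clean.t0 + stop / clean.fs
        energies = ab.interp_window_energy(coeffs, window_end_s)
        wband = ab.estimate_band(
            coeffs.center_frequencies,
            energies,
            seed=cfg.kmeans_seed,
            rule=cfg.band_rule,
        )
        logger.debug(
            "window [%d, %d): band %.2f-%.2f Hz", start, stop, wband.low, wband.high
        )
        seg = SampledSignal(
            clean.values[start:stop], clean.fs, clean.t0 + start / clean.fs
        )
        segments.append(ab.refine_window(seg, wband, cfg.filter_order))
        bands.append(wband)
    inter["window_bands"] = bands
    inter["window_plan"] = plan

    recon = ab.reconstruct_overlap_add(segments, plan)
    recon = ab.amplify_edges(recon, plan)
    inter["reconstructed"] = recon

    peaks = detect_peaks_ampd(recon, cfg.max_scale_s)
    inter["peaks"] = peaks
    raw_ibis = peaks_to_ibis(
        peaks, recon.fs, sig=recon, subsample=cfg.subsample_peaks
    )
    inter["raw_ibis"] = raw_ibis

    if len(raw_ibis) == 0:
        report = compute_report(raw_ibis, 0, cfg.baevsky_bin_ms, cfg.tachogram_hz)
        report.flags.append("unreliable: no beats detected")
        return PipelineResult(report, inter)

    refined = refine_ibis(
        raw_ibis,
        min_ms=cfg.ibi_min_ms,
        max_ms=cfg.ibi_max_ms,
        mean_frac=cfg.ibi_mean_frac,
        block_size=cfg.ibi_block_size,
        block_frac=cfg.ibi_block_frac,
    )
    inter["refined_ibis"] = refined.series
    inter["drop_log"] = refined.dropped

    report = compute_report(
        refined.series,
        refined.n_dropped,
        cfg.baevsky_bin_ms,
        cfg.tachogram_hz,
        cfg.lfhf_min_duration_s,
    )
    if refined.unreliable:
        report.flags.append("unreliable: refinement removed every interval")
    return PipelineResult(report, inter)
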