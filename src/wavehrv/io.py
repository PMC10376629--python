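"""Plain-text I/O: trace CSVs, IBI CSVs, report JSONs, manifests.

Trace CSVs carry either ``t,value`` (seconds, arbitrary units) for a
pulse trace or ``t,R,G,B`` for a per-frame mean-RGB trace; the
sampling rate is inferred from the median spacing of ``t`` unless
given explicitly. IBI CSVs carry ``t_s,ibi_ms``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .peaks_ibi import IBISeries
from .signals import RGBTrace, SampledSignal

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_ibi_csv",
    "write_ibi_csv",
]


def _infer_fs(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    return float(1.0 / np.median(dt))


def read_trace_csv(path, fs: float | None = None) -> SampledSignal | RGBTrace:
    """Read a pulse or RGB trace CSV, inferring fs from ``t`` if needed."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "t" not in cols:
        raise ValueError("trace CSV needs a 't' column")
    t = df[cols["t"]].to_numpy(dtype=float)
    rate = fs if fs is not None else _infer_fs(t)
    if {"r", "g", "b"} <= set(cols):
        return RGBTrace(
            df[cols["r"]].to_numpy(dtype=float),
            df[cols["g"]].to_numpy(dtype=float),
            df[cols["b"]].to_numpy(dtype=float),
            fs=rate,
            t0=float(t[0]),
        )
    if "value" in cols:
        return SampledSignal(
            df[cols["value"]].to_numpy(dtype=float), fs=rate, t0=float(t[0])
        )
    raise ValueError("trace CSV needs either 'value' or 'R,G,B' columns")


def write_trace_csv(sig: SampledSignal, path) -> None:
    pd.DataFrame({"t": sig.times, "value": sig.values}).to_csv(path, index=False)


def read_ibi_csv(path) -> IBISeries:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if not {"t_s", "ibi_ms"} <= set(cols):
        raise ValueError("IBI CSV needs 't_s' and 'ibi_ms' columns")
    return IBISeries(
        df[cols["ibi_ms"]].to_numpy(dtype=float),
        df[cols["t_s"]].to_numpy(dtype=float),
    )


def write_ibi_csv(series: IBISeries, path) -> None:
    pd.DataFrame(
        {"t_s": series.beat_times_s, "ibi_ms": series.ibis_ms}
    ).to_csv(path, index=False)


def write_drop_log_csv(dropped: list[tuple[int, int]], path) -> None:
    pd.DataFrame(dropped, columns=["index", "rule"]).to_csv(path, index=False)
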