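"""Screen a noisy reference (contact PPG) interval series before use.

Reference recordings are imperfect too — a loose pulse oximeter
produces spurious intervals that distort HRV benchmarks. This example
corrupts a clean synthetic interval series two ways: repairable
interval outliers (removed by the 30% segment rule) and a
physiologically impossible interval (which rejects the whole record
via the heart-rate limits).
"""

import wavehrv as w

truth = w.generate_ibi_series(w.SyntheticSpec(seed=3, mean_rr_ms=700.0))

outliers, log = w.inject_artifacts(
    truth, "outlier_ibi", {"n": 3, "factor": 1.5}, seed=9
)
impossible, _ = w.inject_artifacts(
    truth, "outlier_ibi", {"n": 1, "factor": 0.35}, seed=9
)

for rec, label in (
    (truth, "clean"),
    (outliers, "outliers"),
    (impossible, "impossible"),
):
    rep = w.clean_ground_truth(rec)
    verdict = "accepted" if rep.accepted else f"rejected {rep.reasons}"
    print(f"{label:>10}: {verdict}, {rep.ibis_removed} interval(s) removed, "
          f"SDNN {w.sdnn(rep.cleaned):.1f} ms after cleaning")

print(f"\n1.5x outliers (indices {[e['index'] for e in log]}) exceed their "
      "segment's 30% bound and are repaired away, so that record stays "
      "usable; a 0.35x interval implies ~245 bpm — outside the 45-200 "
      "bpm device limits — so that record is discarded outright.")
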