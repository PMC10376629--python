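"""Agreement between pipeline HRV and ground truth over many records.

Runs the full pipeline on ten synthetic recordings, pairs the
estimated SDNN/RMSSD with the values from the generated intervals,
and summarises agreement the way method-comparison studies do: MAE,
RMS of paired differences, Pearson r, a paired t-test, and
Bland-Altman bias with 95% limits of agreement.
"""

import wavehrv as w

est_sdnn, true_sdnn, est_rmssd, true_rmssd = [], [], [], []
for seed in range(10):
    spec = w.SyntheticSpec(seed=seed, sigma_ms=10.0 + 3.0 * seed)
    sig, beats, ibis = w.synthetic_record(spec)
    rep = w.run_wavehrv(sig).report
    est_sdnn.append(rep.sdnn_ms)
    true_sdnn.append(w.sdnn(ibis))
    est_rmssd.append(rep.rmssd_ms)
    true_rmssd.append(w.rmssd(ibis))

for name, est, truth in (
    ("SDNN", est_sdnn, true_sdnn),
    ("RMSSD", est_rmssd, true_rmssd),
):
    s = w.agreement_stats(est, truth)
    print(f"{name}: MAE {s.mae:.2f} ms, RMS diff {s.sd:.2f} ms, "
          f"r {s.r:.3f}, paired t p={s.p:.2f}")
    print(f"      Bland-Altman bias {s.mean_diff:+.2f} ms, "
          f"95% LoA [{s.loa_low:+.2f}, {s.loa_high:+.2f}] ms")

print("\nTight limits of agreement mean the pipeline and the "
      "reference would be interchangeable for these recordings. Note "
      "the paired t-test flags even a fraction-of-a-millisecond bias "
      "as significant when the limits are this tight — statistical "
      "significance is not clinical relevance.")
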