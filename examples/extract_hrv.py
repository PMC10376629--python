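"""Extract HRV from a synthetic pulse trace and compare with ground truth.

Builds a 2-minute synthetic PPG recording (75 bpm resting rhythm, 30 dB
SNR, baseline drift), runs the full pipeline — band-pass pre-clean,
wavelet scattering, adaptive narrow-band filtering, AMPD beat detection,
interval refinement — and prints the recovered metrics next to the
values computed directly from the generator's beat intervals.
"""

import wavehrv as w

spec = w.SyntheticSpec(seed=42)  # 120 s at 64 Hz, mean RR 800 ms
signal, beat_times, true_ibis = w.synthetic_record(spec)

result = w.run_wavehrv(signal)
rep = result.report

print(f"record: {signal.duration:.0f} s at {signal.fs:.0f} Hz, "
      f"{beat_times.size} true beats")
print(f"{'metric':<12}{'estimated':>12}{'ground truth':>14}")
print(f"{'HR (bpm)':<12}{rep.mean_hr_bpm:>12.1f}"
      f"{60000.0 / true_ibis.ibis_ms.mean():>14.1f}")
print(f"{'SDNN (ms)':<12}{rep.sdnn_ms:>12.1f}{w.sdnn(true_ibis):>14.1f}")
print(f"{'RMSSD (ms)':<12}{rep.rmssd_ms:>12.1f}{w.rmssd(true_ibis):>14.1f}")
print(f"{'Baevsky SI':<12}{rep.baevsky_si:>12.1f}"
      f"{w.baevsky_si(true_ibis):>14.1f}")
print(f"\nintervals kept {rep.n_ibis_used}, dropped {rep.n_ibis_dropped}")
print("SDNN tracks overall variability, RMSSD beat-to-beat "
      "(parasympathetic) variability; the Baevsky index rises with "
      "stress as the interval histogram tightens.")
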