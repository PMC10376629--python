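"""From a camera mean-RGB trace to a pulse signal via POS.

Embeds a synthetic blood-volume pulse into the three colour channels
with skin-like relative strengths (strongest in green), projects the
trace onto the plane orthogonal to the skin tone, and shows that the
recovered pulse carries the right heart rate end-to-end.
"""

import numpy as np

import wavehrv as w

spec = w.SyntheticSpec(seed=7, duration_s=60.0, fs=30.0, snr_db=40.0)
pulse_sig, beats, true_ibis = w.synthetic_record(spec)
pulse = 0.015 * pulse_sig.values / np.abs(pulse_sig.values).max()

trace = w.RGBTrace(
    r=120 * (1 + 0.3 * pulse),
    g=90 * (1 + 1.0 * pulse),
    b=70 * (1 + 0.6 * pulse),
    fs=30.0,
)

candidate = w.pos_rppg(trace)
freqs = np.fft.rfftfreq(len(candidate), 1 / candidate.fs)
spectrum = np.abs(np.fft.rfft(candidate.values - candidate.values.mean()))
f_dom = freqs[np.argmax(spectrum)]

result = w.run_wavehrv(trace)
true_hr = 60000.0 / true_ibis.ibis_ms.mean()

print(f"POS candidate dominant frequency: {f_dom:.2f} Hz "
      f"({60 * f_dom:.0f} bpm)")
print(f"pipeline mean HR: {result.report.mean_hr_bpm:.1f} bpm "
      f"(ground truth {true_hr:.1f} bpm)")
print("The POS projection cancels intensity and specular variation "
      "common to all channels, leaving the pulsatile skin-colour "
      "component the rest of the pipeline refines.")
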