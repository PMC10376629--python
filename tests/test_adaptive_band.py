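import numpy as np
import pytest

from wavehrv import (
    SampledSignal,
    WindowPlan,
    amplify_edges,
    estimate_band,
    interp_window_energy,
    reconstruct_overlap_add,
    refine_window,
)
from wavehrv.adaptive_band import FrequencyBand
from wavehrv.scattering import ScatteringCoeffs

from conftest import dominant_frequency


def make_coeffs(S, pooling=16.0, freqs=None):
    S = np.asarray(S, dtype=float)
    if freqs is None:
        freqs = np.geomspace(0.7, 5.0, S.shape[0])
    times = (np.arange(S.shape[1]) + 0.5) * pooling
    return ScatteringCoeffs(S, times, np.asarray(freqs), pooling)


class TestInterpWindowEnergy:
    def test_endpoints_and_midpoint(self):
        co = make_coeffs(np.array([[2.0, 4.0], [1.0, 3.0], [5.0, 5.0]]))
        t0, t1 = co.frame_times
        np.testing.assert_allclose(interp_window_energy(co, t0), [2, 1, 5])
        np.testing.assert_allclose(interp_window_energy(co, t1), [4, 3, 5])
        np.testing.assert_allclose(
            interp_window_energy(co, (t0 + t1) / 2), [3, 2, 5]
        )

    def test_clamps_beyond_frame_range(self):
        co = make_coeffs(np.array([[2.0, 4.0], [1.0, 3.0], [0.0, 1.0]]))
        np.testing.assert_allclose(interp_window_energy(co, -100.0), [2, 1, 0])
        np.testing.assert_allclose(interp_window_energy(co, 1e6), [4, 3, 1])

    def test_single_frame_fallback(self):
        co = make_coeffs(np.array([[2.0], [1.0], [7.0]]))
        np.testing.assert_allclose(interp_window_energy(co, 99.0), [2, 1, 7])


class TestEstimateBand:
    def test_unimodal_profile_band_contains_peak_and_is_narrow(self):
        freqs = np.geomspace(0.7, 5.0, 20)
        energies = np.exp(-(((freqs - 1.2) / 0.25) ** 2))
        band = estimate_band(freqs, energies, seed=0)
        assert band.contains(1.2)
        assert band.high - band.low < 5.0 - 0.7

    def test_uniform_profile_deterministic_and_clamped(self):
        freqs = np.geomspace(0.7, 5.0, 20)
        e = np.ones(20)
        b1 = estimate_band(freqs, e, seed=0)
        b2 = estimate_band(freqs, e, seed=0)
        assert (b1.low, b1.high) == (b2.low, b2.high)
        assert 0.7 <= b1.low < b1.high <= 5.0

    def test_same_seed_same_band(self):
        rng = np.random.default_rng(5)
        freqs = np.geomspace(0.7, 5.0, 20)
        e = rng.uniform(size=20)
        assert estimate_band(freqs, e, seed=3) == estimate_band(freqs, e, seed=3)

    def test_peak_cluster_rule_hugs_peak(self):
        freqs = np.geomspace(0.7, 5.0, 20)
        energies = np.exp(-(((freqs - 1.3) / 0.3) ** 2))
        band = estimate_band(freqs, energies, seed=0, rule="peak_cluster")
        assert band.low >= 0.7 and band.high <= 2.5

    def test_rejects_too_few_frequencies(self):
        with pytest.raises(ValueError, match="distinct"):
            estimate_band(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestRefineWindow:
    def test_in_band_tone_preserved(self, sine):
        seg = sine(freq=1.2, fs=32.0, duration=14.5)
        out = refine_window(seg, FrequencyBand(0.9, 2.0))
        n = len(seg)
        central = slice(n // 4, 3 * n // 4)
        ratio = np.max(np.abs(out.values[central])) / np.max(
            np.abs(seg.values[central])
        )
        assert 0.9 <= ratio <= 1.1

    def test_out_of_band_drift_attenuated(self):
        # 60 s segment holds integer cycles of both tones, so spectral
        # leakage cannot mask the stopband attenuation
        fs = 32.0
        t = np.arange(0, 60.0, 1 / fs)
        seg = SampledSignal(
            np.sin(2 * np.pi * 0.3 * t) + 0.5 * np.sin(2 * np.pi * 1.2 * t), fs
        )
        out = refine_window(seg, FrequencyBand(0.9, 2.0))
        spec = np.abs(np.fft.rfft(out.values))
        freqs = np.fft.rfftfreq(len(out), 1 / fs)
        a_drift = spec[np.argmin(np.abs(freqs - 0.3))]
        a_tone = spec[np.argmin(np.abs(freqs - 1.2))]
        assert 20 * np.log10(a_tone / (a_drift * 0.5)) >= 40

    def test_output_mean_is_zero(self, sine):
        seg = sine(freq=1.0, fs=32.0, duration=14.5)
        seg.values += 3.7  # offset to be removed
        out = refine_window(seg, FrequencyBand(0.8, 1.5))
        assert abs(out.values.mean()) < 1e-9 * out.values.std()

    def test_degenerate_band_widened(self, sine):
        seg = sine(freq=1.2, fs=32.0, duration=14.5)
        out = refine_window(seg, FrequencyBand(1.19, 1.21))
        # the widened (0.1 Hz minimum width) band keeps the tone dominant;
        # an unwidened 0.02 Hz band would leave almost nothing
        assert np.max(np.abs(out.values)) > 0.25
        assert abs(dominant_frequency(out) - 1.2) < 0.1


class TestWindowPlanReconstruct:
    def test_single_window_identity(self, sine):
        seg = sine(freq=1.0, fs=32.0, duration=10.0)
        plan = WindowPlan(14.5, 2.0, len(seg), 32.0)
        assert plan.n_windows == 1
        out = reconstruct_overlap_add([seg], plan)
        np.testing.assert_allclose(out.values, seg.values)

    def test_two_half_overlapping_windows_double_in_overlap(self, sine):
        fs = 32.0
        full = sine(freq=1.0, fs=fs, duration=16.0)
        plan = WindowPlan(12.0, 4.0, len(full), fs)
        slices = plan.slices()
        assert len(slices) == 2
        segs = [
            SampledSignal(full.values[a:b], fs, a / fs) for a, b in slices
        ]
        out = reconstruct_overlap_add(segs, plan)
        overlap = slice(4 * 32, 12 * 32)
        np.testing.assert_allclose(out.values[overlap], 2 * full.values[overlap])
        np.testing.assert_allclose(out.values[: 4 * 32], full.values[: 4 * 32])

    def test_coverage_matches_brute_force(self):
        fs, dur = 32.0, 60.0
        n = int(fs * dur)
        plan = WindowPlan(14.5, 2.0, n, fs)
        cov = plan.coverage()
        brute = np.zeros(n)
        for start, stop in plan.slices():
            brute[start:stop] += 1
        np.testing.assert_array_equal(cov, brute)
        w_s = plan.window_seconds / plan.step_seconds
        interior = cov[plan.w_samples : n - plan.w_samples]
        assert set(np.unique(interior)) <= {int(np.floor(w_s)), int(np.ceil(w_s))}

    def test_final_window_longer_than_w_minus_s(self):
        plan = WindowPlan(14.5, 2.0, int(32 * 61.3), 32.0)
        start, stop = plan.slices()[-1]
        assert (stop - start) / 32.0 > 14.5 - 2.0
        assert stop == plan.n_samples

    def test_linearity_in_segments(self, sine):
        fs = 32.0
        full = sine(freq=1.0, fs=fs, duration=30.0)
        plan = WindowPlan(14.5, 2.0, len(full), fs)
        segs = [SampledSignal(full.values[a:b], fs) for a, b in plan.slices()]
        segs2 = [SampledSignal(2.0 * s.values, fs) for s in segs]
        out1 = reconstruct_overlap_add(segs, plan)
        out2 = reconstruct_overlap_add(segs2, plan)
        np.testing.assert_allclose(out2.values, 2.0 * out1.values, rtol=1e-12)

    def test_segment_length_mismatch_rejected(self, sine):
        fs = 32.0
        full = sine(fs=fs, duration=30.0)
        plan = WindowPlan(14.5, 2.0, len(full), fs)
        segs = [SampledSignal(full.values[a:b], fs) for a, b in plan.slices()]
        segs[0] = SampledSignal(segs[0].values[:-3], fs)
        with pytest.raises(ValueError, match="slot"):
            reconstruct_overlap_add(segs, plan)


class TestAmplifyEdges:
    def test_first_step_slice_gain_equals_w_over_s(self, sine):
        fs = 32.0
        full = sine(freq=1.2, fs=fs, duration=60.0)
        plan = WindowPlan(14.5, 2.0, len(full), fs)
        segs = [SampledSignal(full.values[a:b], fs) for a, b in plan.slices()]
        recon = reconstruct_overlap_add(segs, plan)
        amp = amplify_edges(recon, plan)
        s = plan.s_samples
        np.testing.assert_allclose(amp.values[:s], recon.values[:s] * 7.25)
        np.testing.assert_allclose(
            amp.values[s : 2 * s], recon.values[s : 2 * s] * 7.25 / 2
        )

    def test_interior_bit_identical(self, sine):
        fs = 32.0
        full = sine(freq=1.2, fs=fs, duration=60.0)
        plan = WindowPlan(14.5, 2.0, len(full), fs)
        segs = [SampledSignal(full.values[a:b], fs) for a, b in plan.slices()]
        recon = reconstruct_overlap_add(segs, plan)
        amp = amplify_edges(recon, plan)
        w = plan.w_samples
        assert np.array_equal(amp.values[w:-w], recon.values[w:-w])

    def test_noop_when_step_exceeds_window_ratio_one(self, sine):
        fs = 32.0
        full = sine(fs=fs, duration=30.0)
        plan = WindowPlan(10.0, 10.0, len(full), fs)  # w/s = 1
        segs = [SampledSignal(full.values[a:b], fs) for a, b in plan.slices()]
        recon = reconstruct_overlap_add(segs, plan)
        amp = amplify_edges(recon, plan)
        np.testing.assert_array_equal(amp.values, recon.values)
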