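"""EMG conditioning, burst detection and partial-burst classification."""

import numpy as np
import pytest

from selstop.emg import (
    Burst,
    EMGTrace,
    average_profiles,
    bandpass,
    cancel_time,
    detect_bursts,
    envelope,
    find_partial_burst,
    find_rt_burst,
    merge_bursts,
    normalize,
)

FS = 2000.0


def tone(freq, dur_ms, amp=1.0, fs=FS):
    t = np.arange(int(dur_ms * fs / 1000)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def plant_tone_burst(n, start_ms, dur_ms, amp, freq=150.0, noise_sd=0.01, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise_sd, n)
    i0 = int(start_ms * FS / 1000)
    seg = tone(freq, dur_ms, amp)
    x[i0 : i0 + seg.size] += seg
    return x


class TestFilters:
    def test_bandpass_attenuates_below_passband(self):
        x = tone(5.0, 2000.0)
        y = bandpass(x, FS)
        # compare RMS in the central section (avoid filter edges)
        sl = slice(1000, -1000)
        ratio = np.sqrt(np.mean(y[sl] ** 2)) / np.sqrt(np.mean(x[sl] ** 2))
        assert ratio < 10 ** (-20 / 20)

    def test_bandpass_preserves_passband(self):
        x = tone(100.0, 2000.0)
        y = bandpass(x, FS)
        sl = slice(1000, -1000)
        ratio = np.sqrt(np.mean(y[sl] ** 2)) / np.sqrt(np.mean(x[sl] ** 2))
        assert 10 ** (-1 / 20) < ratio < 10 ** (1 / 20)

    def test_bandpass_reduces_white_noise_power(self, rng):
        x = rng.standard_normal(8000)
        y = bandpass(x, FS)
        assert np.std(y) < np.std(x)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            bandpass(np.zeros(1000), 900.0)

    def test_envelope_of_zero_is_zero(self):
        assert np.allclose(envelope(np.zeros(4000), FS), 0.0)

    def test_envelope_sign_invariant(self, rng):
        x = rng.standard_normal(4000)
        assert np.allclose(envelope(x, FS), envelope(-x, FS))

    def test_envelope_plateau_of_tone(self):
        a = 0.8
        x = tone(150.0, 3000.0, amp=a)
        env = envelope(x, FS)
        plateau = env[2000:-2000].mean()
        assert plateau == pytest.approx(2 * a / np.pi, rel=0.1)


class TestDetection:
    def test_planted_burst_onset_accuracy(self):
        x = plant_tone_burst(4000, 300.0, 150.0, amp=0.1, seed=1)
        bursts = detect_bursts(x, FS)
        assert len(bursts) == 1
        assert bursts[0].onset_ms == pytest.approx(300.0, abs=5.0)
        assert bursts[0].offset_ms == pytest.approx(450.0, abs=10.0)

    def test_noise_only_trace_yields_no_bursts(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 0.01, 4200)
            assert detect_bursts(x, FS) == []

    def test_scale_invariance(self):
        x = plant_tone_burst(4000, 300.0, 150.0, amp=0.1, seed=2)
        b1 = detect_bursts(x, FS)
        b2 = detect_bursts(5.0 * x, FS)
        assert [(b.onset_ms, b.offset_ms) for b in b1] == [
            (b.onset_ms, b.offset_ms) for b in b2]

    def test_close_bursts_merge(self):
        x = plant_tone_burst(4000, 100.0, 50.0, amp=0.1, seed=3)
        x += plant_tone_burst(4000, 160.0, 40.0, amp=0.1, seed=4) \
            - np.random.default_rng(4).normal(0, 0.01, 4000)
        bursts = detect_bursts(x, FS)
        assert len(bursts) == 1  # 10 ms gap < 20 ms merge rule
        assert bursts[0].onset_ms == pytest.approx(100.0, abs=5.0)
        assert bursts[0].offset_ms == pytest.approx(200.0, abs=10.0)

    def test_distant_bursts_stay_separate(self):
        x = plant_tone_burst(4000, 100.0, 50.0, amp=0.1, seed=5)
        x += plant_tone_burst(4000, 185.0, 40.0, amp=0.1, seed=6) \
            - np.random.default_rng(6).normal(0, 0.01, 4000)
        bursts = detect_bursts(x, FS)
        assert len(bursts) == 2  # 35 ms gap > 20 ms merge rule

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_bursts(np.zeros(100), FS)

    def test_merge_idempotent_and_order_independent(self):
        bursts = [Burst(100, 150), Burst(160, 200), Burst(300, 350)]
        merged = merge_bursts(bursts)
        assert [(b.onset_ms, b.offset_ms) for b in merged] == [(100, 200), (300, 350)]
        assert merge_bursts(merged) == merged
        assert merge_bursts(list(reversed(bursts))) == merged


class TestClassification:
    def test_rt_burst_is_last_qualifying(self):
        bursts = [Burst(250, 300), Burst(380, 480)]
        found = find_rt_burst(bursts, go_time_ms=0.0, rt_ms=430.0)
        assert found.onset_ms == 380

    def test_rt_burst_needs_50ms_lead(self):
        assert find_rt_burst([Burst(400, 480)], 0.0, 430.0) is None

    def test_rt_burst_must_follow_go(self):
        assert find_rt_burst([Burst(-50, 100)], 0.0, 430.0) is None

    def _mk(self, onset, peak, amp):
        return Burst(onset, peak + 60, peak_time_ms=peak, peak_amp=amp)

    def test_partial_peak_must_follow_stop_signal(self):
        b = self._mk(100, 180, 0.5)
        assert find_partial_burst([b], 0.0, 200.0, 470.0, reference_peak=1.0) is None

    def test_partial_peak_before_rt_burst_onset(self):
        b = self._mk(380, 500, 0.5)
        assert find_partial_burst([b], 0.0, 200.0, 470.0, reference_peak=1.0) is None

    def test_partial_amplitude_threshold(self):
        b = self._mk(260, 330, 0.05)
        assert find_partial_burst([b], 0.0, 200.0, 470.0, reference_peak=1.0) is None

    def test_partial_earliest_qualifying(self):
        early = self._mk(250, 320, 0.4)
        late = self._mk(330, 400, 0.6)
        found = find_partial_burst([late, early], 0.0, 200.0, 470.0, 1.0)
        assert found is early

    def test_cancel_time_definition(self):
        b = self._mk(300, 380, 0.4)
        assert cancel_time(b, 250.0) == pytest.approx(130.0)


class TestNormalization:
    def test_reference_mean(self):
        envs = [np.array([0.1, 0.5]), np.array([0.2, 0.3])]
        refs = [np.array([0.0, 0.4]), np.array([0.6, 0.1])]
        normed, ref_peak = normalize(envs, refs)
        assert ref_peak == pytest.approx(0.5)
        assert np.allclose(normed[0], [0.2, 1.0])
        # reference trials normalize to mean peak exactly 1
        ref_normed, _ = normalize(refs, refs)
        assert np.mean([r.max() for r in ref_normed]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        envs = [np.array([0.1, 0.5])]
        refs = [np.array([0.4])]
        n1, _ = normalize(envs, refs)
        n2, _ = normalize([2 * e for e in envs], [2 * r for r in refs])
        assert np.allclose(n1[0], n2[0])

    def test_single_reference_trial(self):
        normed, ref = normalize([np.array([0.3])], [np.array([0.3])])
        assert normed[0][0] == pytest.approx(1.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize([np.ones(4)], [])


class TestProfileAveraging:
    def _profiles(self, n_subj=3, shift=0.0, jitter=None):
        base = envelope(tone(150.0, 200.0, 0.5), FS)
        out = []
        rng = np.random.default_rng(0)
        for s in range(n_subj):
            for t in range(4):
                off = shift + (rng.uniform(-50, 50) if jitter else 0.0)
                pad = int((300 + off) * FS / 1000)
                env = np.concatenate([np.zeros(pad), base, np.zeros(400)])
                peak = (pad + int(np.argmax(base))) / FS * 1000
                out.append({"env": env, "participant": s, "go_ms": 300.0,
                            "stop_ms": 500.0, "emg_onset_ms": 300 + off,
                            "peak_ms": peak})
        return out

    def test_identical_profiles_zero_ci(self):
        res = average_profiles(self._profiles(), "go", FS)
        width = np.nanmax(res["ci_high"] - res["ci_low"])
        assert width == pytest.approx(0.0, abs=1e-12)

    def test_peak_alignment_recovers_shape(self):
        res = average_profiles(self._profiles(jitter=True), "peak", FS,
                               window_ms=(-100, 100))
        # peak sits at t=0 after alignment
        mid = np.nanargmax(res["mean"])
        assert abs(res["time_ms"][mid]) < 2.0

    def test_jittered_go_alignment_flattens_peak(self):
        jittered = self._profiles(jitter=True)
        go = average_profiles(jittered, "go", FS)
        pk = average_profiles(jittered, "peak", FS)
        assert np.nanmax(go["mean"]) < np.nanmax(pk["mean"])

    def test_requires_two_participants(self):
        with pytest.raises(ValueError, match="participants"):
            average_profiles(self._profiles(n_subj=1), "go", FS)

    def test_unknown_alignment(self):
        with pytest.raises(ValueError, match="alignment"):
            average_profiles(self._profiles(), "press", FS)
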