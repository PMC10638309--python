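"""EMG conditioning, burst detection and partial-burst (CancelTime) analysis.

Pipeline: band-pass filter the raw two-channel signal (4th-order Butterworth,
20-500 Hz, zero phase), detect burst onsets/offsets on the rectified raw
signal with a single baseline-relative threshold (mean + 3 SD of the quietest
500 ms segment), compute the 10 Hz low-pass envelope for all amplitude/peak
measures, then classify up to two bursts per hand: the RT-generating burst
(last burst starting after the go signal and at least 50 ms before the press)
and, on successful stop trials, the partial burst — the earliest burst whose
onset follows the go signal, whose envelope peak follows the stop signal and
precedes the responding hand's RT-burst onset, and whose peak exceeds 10% of
the participant's mean successful-bi-go peak.  CancelTime is the partial-peak
latency relative to the stop signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

HANDS = ("left", "right")


@dataclass
class EMGTrace:
    """Raw two-channel (left/right FDI) trial recording.

    Signals in mV; all event markers in ms from trace start.
    """

    left: np.ndarray
    right: np.ndarray
    fs_hz: float = 2000.0
    go_time_ms: float = 0.0
    stop_time_ms: Optional[float] = None
    press_left_ms: Optional[float] = None
    press_right_ms: Optional[float] = None
    participant: Optional[int] = None
    trial: Optional[int] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise ValueError("channels must be equal-length 1-D arrays")
        extent = self.duration_ms
        for name in ("go_time_ms", "stop_time_ms", "press_left_ms", "press_right_ms"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= extent):
                raise ValueError(f"{name}={val} outside trace extent [0, {extent}] ms")

    @property
    def duration_ms(self) -> float:
        return self.left.size / self.fs_hz * 1000.0

    def channel(self, hand: str) -> np.ndarray:
        if hand not in HANDS:
            raise ValueError(f"unknown hand {hand!r}")
        return self.left if hand == "left" else self.right


@dataclass(frozen=True)
class Burst:
    """One detected burst: onset/offset from raw-signal threshold crossings,
    peak time/amplitude from the envelope inside [onset, offset]."""

    onset_ms: float
    offset_ms: float
    peak_time_ms: Optional[float] = None
    peak_amp: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("burst onset must precede offset")
        if self.peak_time_ms is not None and not (
            self.onset_ms <= self.peak_time_ms <= self.offset_ms
        ):
            raise ValueError("burst peak must lie within [onset, offset]")


@dataclass
class HandFeatures:
    rt_burst: Optional[Burst] = None
    partial_burst: Optional[Burst] = None
    cancel_time_ms: Optional[float] = None


@dataclass
class TrialEMGFeatures:
    """Per-trial, per-hand classified bursts plus the normalization used."""

    hands: dict = field(default_factory=lambda: {h: HandFeatures() for h in HANDS})
    cancel_time_ms: Optional[float] = None  # earliest partial peak - stop time
    reference_peak: Optional[float] = None


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def bandpass(
    x: np.ndarray, fs_hz: float, low_hz: float = 20.0, high_hz: float = 500.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass; removes DC."""
    if fs_hz <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {fs_hz} Hz too low for a {high_hz} Hz cutoff "
            f"(need fs > {2 * high_hz} Hz)"
        )
    sos = signal.butter(order, (low_hz, high_hz), btype="bandpass", fs=fs_hz,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def bandpass_trace(trace: EMGTrace, **kwargs) -> EMGTrace:
    """Band-pass both channels of a trace, preserving markers."""
    out = EMGTrace(
        left=bandpass(trace.left, trace.fs_hz, **kwargs),
        right=bandpass(trace.right, trace.fs_hz, **kwargs),
        fs_hz=trace.fs_hz,
        go_time_ms=trace.go_time_ms,
        stop_time_ms=trace.stop_time_ms,
        press_left_ms=trace.press_left_ms,
        press_right_ms=trace.press_right_ms,
        participant=trace.participant,
        trial=trace.trial,
        condition=trace.condition,
    )
    return out


def envelope(x: np.ndarray, fs_hz: float, cutoff_hz: float = 10.0,
             order: int = 4) -> np.ndarray:
    """EMG envelope: full-wave rectification then zero-phase low-pass.

    Non-negative by construction (the small filtfilt undershoot is clipped);
    invariant to sign flips of the input.
    """
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(np.asarray(x, dtype=float)))
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------

def _moving_mean(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_bursts(
    x: np.ndarray,
    fs_hz: float,
    baseline_window_ms: float = 500.0,
    threshold_sd: float = 3.0,
    merge_gap_ms: float = 20.0,
    min_duration_ms: float = 10.0,
    smooth_ms: float = 5.0,
) -> list[Burst]:
    """Single-threshold burst detection on one (filtered) channel.

    The quietest ``baseline_window_ms`` segment (minimum RMS, 1-sample stride,
    earliest tie wins) defines the threshold: rectified-baseline mean +
    ``threshold_sd`` SDs.  The rectified signal, lightly smoothed with a
    ``smooth_ms`` moving average so individual zero crossings do not fragment
    a burst, is compared against the threshold; supra-threshold runs closer
    than ``merge_gap_ms`` are merged (idempotent), and merged bursts shorter
    than ``min_duration_ms`` are discarded.  Detection is invariant to
    positive rescaling of the trace.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = int(round(baseline_window_ms * fs_hz / 1000.0))
    if n < w:
        raise ValueError(
            f"trace ({n / fs_hz * 1000:.0f} ms) shorter than the "
            f"{baseline_window_ms:.0f} ms baseline window"
        )
    rect = np.abs(x)
    # sliding RMS of the rectified signal via cumulative sums
    c2 = np.concatenate([[0.0], np.cumsum(rect**2)])
    ms = (c2[w:] - c2[:-w]) / w
    start = int(np.argmin(ms))  # earliest minimum (argmin returns first)
    base = rect[start : start + w]
    thr = base.mean() + threshold_sd * base.std()

    smooth_n = max(int(round(smooth_ms * fs_hz / 1000.0)), 1)
    supra = _moving_mean(rect, smooth_n) > thr
    if not supra.any():
        return []
    idx = np.flatnonzero(supra)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])  # inclusive

    merged: list[list[float]] = []
    gap = merge_gap_ms * fs_hz / 1000.0
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        onset = s / fs_hz * 1000.0
        offset = (e + 1) / fs_hz * 1000.0
        if offset - onset >= min_duration_ms:
            out.append(Burst(onset_ms=onset, offset_ms=offset))
    return out


def merge_bursts(bursts: Sequence[Burst], merge_gap_ms: float = 20.0) -> list[Burst]:
    """Merge bursts separated by less than ``merge_gap_ms`` (idempotent,
    order-independent)."""
    if not bursts:
        return []
    ordered = sorted(bursts, key=lambda b: b.onset_ms)
    merged = [[ordered[0].onset_ms, ordered[0].offset_ms]]
    for b in ordered[1:]:
        if b.onset_ms - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = max(merged[-1][1], b.offset_ms)
        else:
            merged.append([b.onset_ms, b.offset_ms])
    return [Burst(onset_ms=a, offset_ms=b) for a, b in merged]


def attach_peaks(bursts: Sequence[Burst], env: np.ndarray, fs_hz: float) -> list[Burst]:
    """Set each burst's peak time/amplitude from the envelope within its span."""
    out = []
    for b in bursts:
        i0 = int(round(b.onset_ms * fs_hz / 1000.0))
        i1 = max(int(round(b.offset_ms * fs_hz / 1000.0)), i0 + 1)
        seg = env[i0:i1]
        k = int(np.argmax(seg))
        out.append(
            Burst(
                onset_ms=b.onset_ms,
                offset_ms=b.offset_ms,
                peak_time_ms=(i0 + k) / fs_hz * 1000.0,
                peak_amp=float(seg[k]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# burst classification
# ---------------------------------------------------------------------------

def find_rt_burst(
    bursts: Sequence[Burst], go_time_ms: float, rt_ms: float,
    min_lead_ms: float = 50.0,
) -> Optional[Burst]:
    """The RT-generating burst: the LAST burst whose onset falls after the go
    signal and at least ``min_lead_ms`` before the press.  ``rt_ms`` is the
    press time on the same clock as the bursts (trace time)."""
    candidates = [
        b for b in bursts
        if go_time_ms < b.onset_ms <= rt_ms - min_lead_ms
    ]
    return candidates[-1] if candidates else None


def find_partial_burst(
    bursts: Sequence[Burst],
    go_time_ms: float,
    stop_time_ms: float,
    rt_burst_onset_ms: Optional[float],
    reference_peak: float,
    min_amp_frac: float = 0.10,
) -> Optional[Burst]:
    """The partial (cancelled) burst of one hand on a successful stop trial:
    the EARLIEST burst satisfying all four constraints — onset after the go
    signal, envelope peak after the stop signal, peak before the responding
    hand's RT-burst onset, and peak amplitude above ``min_amp_frac`` of the
    successful-bi-go reference peak.  Bursts must carry peaks
    (see ``attach_peaks``)."""
    if reference_peak is None or reference_peak <= 0:
        raise ValueError("a positive normalization reference peak is required")
    for b in sorted(bursts, key=lambda x: x.onset_ms):
        if b.peak_time_ms is None or b.peak_amp is None:
            raise ValueError("partial-burst search requires bursts with peaks")
        if b.onset_ms <= go_time_ms:
            continue  # (i) initiated before the go signal
        if b.peak_time_ms <= stop_time_ms:
            continue  # (ii) cancelled before the stop signal could act
        if rt_burst_onset_ms is not None and b.peak_time_ms >= rt_burst_onset_ms:
            continue  # (iii) mirror/spurious activity after the new response
        if b.peak_amp <= min_amp_frac * reference_peak:
            continue  # (iv) negligible amplitude
        return b
    return None


def cancel_time(partial: Burst, stop_time_ms: float) -> float:
    """CancelTime: latency of the partial-burst envelope peak relative to the
    stop signal (strictly positive by the peak-after-SSD constraint)."""
    if partial.peak_time_ms is None:
        raise ValueError("partial burst carries no peak")
    return partial.peak_time_ms - stop_time_ms


# ---------------------------------------------------------------------------
# normalization and trial-level extraction
# ---------------------------------------------------------------------------

def normalize(
    envelopes: Sequence[np.ndarray], reference_envelopes: Sequence[np.ndarray]
) -> tuple[list[np.ndarray], float]:
    """Normalize envelopes by the participant's mean peak amplitude across the
    reference trials (successful reactive bi-go); returns the scaled
    envelopes and the reference peak.  The reference set's mean normalized
    peak is exactly 1."""
    refs = [np.max(e) for e in reference_envelopes]
    if len(refs) == 0:
        raise ValueError("empty normalization reference set")
    reference_peak = float(np.mean(refs))
    return [e / reference_peak for e in envelopes], reference_peak


def extract_trial_features(
    trace: EMGTrace,
    successful_stop: bool,
    reference_peak: Optional[float] = None,
    min_lead_ms: float = 50.0,
    min_amp_frac: float = 0.10,
    **detect_kwargs,
) -> TrialEMGFeatures:
    """Run the full per-trial chain: band-pass, detect, envelope peaks,
    RT-burst and (on successful stops) partial-burst classification.

    ``reference_peak`` is the participant's raw-scale successful-bi-go mean
    envelope peak; required for partial-burst search.
    """
    filt = bandpass_trace(trace)
    feats = TrialEMGFeatures(reference_peak=reference_peak)
    presses = {"left": trace.press_left_ms, "right": trace.press_right_ms}
    bursts_by_hand, envs = {}, {}
    for hand in HANDS:
        ch = filt.channel(hand)
        env = envelope(ch, trace.fs_hz)
        bursts = attach_peaks(
            detect_bursts(ch, trace.fs_hz, **detect_kwargs), env, trace.fs_hz
        )
        bursts_by_hand[hand] = bursts
        envs[hand] = env
        if presses[hand] is not None:
            feats.hands[hand].rt_burst = find_rt_burst(
                bursts, trace.go_time_ms, presses[hand], min_lead_ms
            )

    if successful_stop:
        if trace.stop_time_ms is None:
            raise ValueError("successful stop trial without a stop-time marker")
        responding = [h for h in HANDS if presses[h] is not None]
        rt_onset = None
        if len(responding) == 1 and feats.hands[responding[0]].rt_burst is not None:
            rt_onset = feats.hands[responding[0]].rt_burst.onset_ms
        if reference_peak is None:
            raise ValueError("partial-burst search requires a reference peak")
        peaks = []
        for hand in HANDS:
            partial = find_partial_burst(
                bursts_by_hand[hand],
                trace.go_time_ms,
                trace.stop_time_ms,
                rt_onset,
                reference_peak,
                min_amp_frac,
            )
            # a hand's own RT burst is never its partial burst
            rtb = feats.hands[hand].rt_burst
            if partial is not None and rtb is not None and (
                partial.onset_ms == rtb.onset_ms
            ):
                partial = None
            feats.hands[hand].partial_burst = partial
            if partial is not None:
                ct = cancel_time(partial, trace.stop_time_ms)
                feats.hands[hand].cancel_time_ms = ct
                peaks.append(partial.peak_time_ms)
        if peaks:
            feats.cancel_time_ms = min(peaks) - trace.stop_time_ms
    return feats


def reference_peak_from_traces(traces: Sequence[EMGTrace]) -> float:
    """Mean envelope peak (band-passed, post-go window) across reference
    trials — the participant's normalization constant."""
    peaks = []
    for tr in traces:
        filt = bandpass_trace(tr)
        i0 = int(round(tr.go_time_ms * tr.fs_hz / 1000.0))
        pk = 0.0
        for hand in HANDS:
            env = envelope(filt.channel(hand), tr.fs_hz)
            pk = max(pk, float(np.max(env[i0:])))
        peaks.append(pk)
    if not peaks:
        raise ValueError("empty normalization reference set")
    return float(np.mean(peaks))


# ---------------------------------------------------------------------------
# profile averaging
# ---------------------------------------------------------------------------

def average_profiles(
    profiles: Sequence[dict],
    alignment: str,
    fs_hz: float = 2000.0,
    window_ms: tuple = (-200.0, 600.0),
) -> dict:
    """Across-participant mean EMG profile with pointwise t-based 95% CI.

    ``profiles``: one dict per trial with keys ``env`` (normalized envelope),
    ``participant`` and the alignment markers ``go_ms``, ``stop_ms``,
    ``emg_onset_ms``, ``peak_ms`` (trace time; missing/None markers skip the
    trial).  ``alignment`` is one of go/stop/emg_onset/peak; each trial is
    shifted so its reference sits at t = 0, then trials are averaged within
    participant and participants averaged with a 95% CI.
    """
    key = {"go": "go_ms", "stop": "stop_ms", "emg_onset": "emg_onset_ms",
           "peak": "peak_ms"}.get(alignment)
    if key is None:
        raise ValueError(f"unknown alignment {alignment!r}")
    t_rel = np.arange(window_ms[0], window_ms[1], 1000.0 / fs_hz)
    per_subject: dict = {}
    skipped = 0
    for p in profiles:
        ref = p.get(key)
        if ref is None or not np.isfinite(ref):
            skipped += 1
            continue
        env = np.asarray(p["env"], dtype=float)
        t_trace = np.arange(env.size) / fs_hz * 1000.0 - ref
        resampled = np.interp(t_rel, t_trace, env, left=np.nan, right=np.nan)
        per_subject.setdefault(p["participant"], []).append(resampled)
    if len(per_subject) < 2:
        raise ValueError("profile averaging requires >= 2 participants")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN window edges
        subj_means = np.vstack([
            np.nanmean(np.vstack(v), axis=0) for v in per_subject.values()
        ])
    n = subj_means.shape[0]
    mean = subj_means.mean(axis=0)
    sem = subj_means.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return {
        "time_ms": t_rel,
        "mean": mean,
        "ci_low": mean - tcrit * sem,
        "ci_high": mean + tcrit * sem,
        "n_participants": n,
        "n_skipped": skipped,
    }
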