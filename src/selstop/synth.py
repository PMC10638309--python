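"""Synthetic selective-stopping studies with full ground truth.

Generates cohorts of SIS-model subjects, trial-by-trial behaviour with a live
SSD staircase, and raw two-channel EMG traces whose bursts are tied to the
model's latent finish times: RT-generating bursts precede each button press
by the electromechanical offset, and partial (cancelled) bursts peak at
``SSD + stop-runner finish`` on successful stops whose stop-over-go margin
falls inside the detectability window.  Every planted burst is recorded in a
ground-truth table so the EMG pipeline can be validated end to end.

Defaults emulate the study structure the analysis assumes: 2 conditions x 576
trials, one third selective-stop trials balanced left/right, SSD staircased
+/-50 ms from 200 ms, bimanual go means ~450 (reactive) / ~480 ms (proactive),
stop-runner mean ~175 ms and selective means ~316/~289 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import ndtr
from scipy.stats import truncnorm

from .emg import EMGTrace
from .exgauss import RunnerParams
from .sis import CensoringWindow, SISParams, simulate_trials
from .task_design import (
    CONDITIONS,
    DEFAULT_DEADLINE_MS,
    DR,
    LR,
    LS,
    RR,
    RS,
    STOP_SIDE,
    build_schedule,
)

#: supports shared with the hierarchical prior (ms; probit unitless)
SUPPORTS = {"mu": (0.0, 2000.0), "sigma": (1.0, 500.0), "tau": (1.0, 1000.0)}


@dataclass(frozen=True)
class GroupTruth:
    """Hyper-level ground truth: population means of each runner's
    (mu, sigma, tau) per condition, between-subject SDs, and probit-scale
    failure probabilities."""

    runner_means: dict
    between_subject_sd: tuple = (30.0, 8.0, 12.0)  # SD of mu, sigma, tau
    gf_probit: tuple = (-2.05, 0.25)  # mean, SD on probit scale (~2% go failures)
    tf_probit: tuple = (-1.64, 0.25)  # ~5% stop trigger failures
    eps_probit: tuple = (-2.33, 0.20)  # ~1% wrong-hand mis-triggers
    shared_runners: tuple = ("dual_stop",)
    p_floor: float = 1e-10

    def __post_init__(self) -> None:
        for runner, conds in self.runner_means.items():
            for cond, (mu, sg, tu) in conds.items():
                for name, val in (("mu", mu), ("sigma", sg), ("tau", tu)):
                    lo, hi = SUPPORTS[name]
                    if not lo < val < hi:
                        raise ValueError(
                            f"hyper-mean {name}={val} of {runner}/{cond} outside "
                            f"support ({lo}, {hi})"
                        )


def default_group_truth() -> GroupTruth:
    """Study-scale conditions: proactive slowing of +30 ms on the
    dual-go runner, faster proactive selective runners, condition-invariant
    stop runner (mean 175 ms)."""
    return GroupTruth(
        runner_means={
            "dual_go": {
                "reactive": (391.0, 45.0, 60.0),  # mu+tau = 451 ms
                "proactive": (421.0, 45.0, 60.0),  # 481 ms (+30 slowing)
            },
            "dual_stop": {
                "reactive": (145.0, 25.0, 30.0),  # 175 ms, shared
                "proactive": (145.0, 25.0, 30.0),
            },
            "sel_left": {
                "reactive": (266.0, 35.0, 50.0),  # 316 ms
                "proactive": (239.0, 35.0, 50.0),  # 289 ms
            },
            "sel_right": {
                "reactive": (266.0, 35.0, 50.0),
                "proactive": (239.0, 35.0, 50.0),
            },
        }
    )


def _draw_trunc(rng, mean, sd, lo, hi, n=None):
    if sd == 0:
        return np.full(n, mean) if n is not None else mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_group(
    truth: GroupTruth, n_subjects: int, seed: Optional[int] = None
) -> list[SISParams]:
    """Draw a reproducible cohort of subject-level SISParams from the
    hyper-distribution."""
    rng = np.random.default_rng(seed)
    sds = dict(zip(("mu", "sigma", "tau"), truth.between_subject_sd))
    subjects = []
    for _ in range(n_subjects):
        runners = {}
        for runner, conds in truth.runner_means.items():
            per_cond = {}
            if runner in truth.shared_runners:
                mu0, sg0, tu0 = conds["reactive"]
                vals = tuple(
                    float(_draw_trunc(rng, m, sds[nm], *SUPPORTS[nm]))
                    for nm, m in (("mu", mu0), ("sigma", sg0), ("tau", tu0))
                )
                rp = RunnerParams(*vals)
                per_cond = {c: rp for c in CONDITIONS}
            else:
                for cond in CONDITIONS:
                    mu0, sg0, tu0 = conds[cond]
                    vals = tuple(
                        float(_draw_trunc(rng, m, sds[nm], *SUPPORTS[nm]))
                        for nm, m in (("mu", mu0), ("sigma", sg0), ("tau", tu0))
                    )
                    per_cond[cond] = RunnerParams(*vals)
            runners[runner] = per_cond
        gf = float(ndtr(rng.normal(*truth.gf_probit)))
        tf = float(ndtr(rng.normal(*truth.tf_probit)))
        eps = float(ndtr(rng.normal(*truth.eps_probit)))
        subjects.append(
            SISParams(
                dual_go=runners["dual_go"],
                dual_stop=runners["dual_stop"],
                sel_left=runners["sel_left"],
                sel_right=runners["sel_right"],
                gf=gf,
                tf=tf,
                eps_wrong=eps,
                p_floor=truth.p_floor,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConfig:
    """Per-condition design settings (defaults match the task schedule)."""

    n_trials_per_condition: int = 576
    stop_fraction: float = 1.0 / 3.0
    ssd_init_ms: float = 200.0
    ssd_step_ms: float = 50.0
    deadline_ms: float = DEFAULT_DEADLINE_MS
    #: SD of the left-right press asynchrony on bimanual responses (ms);
    #: 25/sqrt(2) per hand gives ~4-5% of trials beyond the 50 ms cutoff
    bimanual_async_sd_ms: float = 25.0


def generate_behaviour(
    subject_params: Sequence[SISParams],
    design: DesignConfig = DesignConfig(),
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the full study trial by trial with live staircases.

    Returns (observed, latent, staircase) tables aligned row-by-row on
    (participant, condition, trial); `latent` keeps the runner finish times
    and margins for recovery tests, `staircase` the per-stop-trial SSD path.
    """
    root = np.random.SeedSequence(seed)
    obs_rows, lat_rows, stair_rows = [], [], []
    for pid, (params, child) in enumerate(
        zip(subject_params, root.spawn(len(subject_params)))
    ):
        rng = np.random.default_rng(child)
        for condition in CONDITIONS:
            schedule = build_schedule(
                condition,
                design.n_trials_per_condition,
                design.stop_fraction,
                seed=int(rng.integers(2**31)),
            )
            ssd = {LS: design.ssd_init_ms, RS: design.ssd_init_ms}
            for trial in schedule:
                d = ssd[trial.stimulus] if trial.is_stop else np.nan
                sim = simulate_trials(
                    params, condition, trial.stimulus,
                    0.0 if not trial.is_stop else float(d),
                    1, rng, design.deadline_ms,
                )
                resp = str(sim["response"][0])
                rt = float(sim["rt"][0])
                rt_left = rt_right = np.nan
                if resp == DR:
                    delta = rng.normal(0.0, design.bimanual_async_sd_ms)
                    rt_left, rt_right = rt - delta / 2.0, rt + delta / 2.0
                elif resp == LR:
                    rt_left = rt
                elif resp == RR:
                    rt_right = rt
                success = bool(sim["stop_success"][0])
                obs_rows.append(
                    (pid, condition, trial.index, trial.stimulus, d, resp, rt,
                     rt_left, rt_right, design.deadline_ms)
                )
                lat_rows.append(
                    (pid, condition, trial.index, trial.stimulus, d,
                     float(sim["t_go"][0]), float(sim["t_stop"][0]),
                     float(sim["t_sel"][0]), bool(sim["go_launched"][0]),
                     bool(sim["stop_launched"][0]), sim["sel_runner"][0],
                     success, float(sim["margin"][0]))
                )
                if trial.is_stop:
                    stair_rows.append(
                        (pid, condition, trial.index, trial.stimulus, d, success)
                    )
                    # harder after success, easier after failure (tracks 50%)
                    delta_ssd = design.ssd_step_ms if success else -design.ssd_step_ms
                    ssd[trial.stimulus] = float(
                        np.clip(ssd[trial.stimulus] + delta_ssd, 0.0,
                                design.deadline_ms - 100.0)
                    )
    observed = pd.DataFrame(
        obs_rows,
        columns=["participant", "condition", "trial", "stimulus", "ssd_ms",
                 "response", "rt_ms", "rt_left_ms", "rt_right_ms", "deadline_ms"],
    )
    latent = pd.DataFrame(
        lat_rows,
        columns=["participant", "condition", "trial", "stimulus", "ssd_ms",
                 "t_go", "t_stop", "t_sel", "go_launched", "stop_launched",
                 "sel_runner", "stop_success", "margin_ms"],
    )
    staircase = pd.DataFrame(
        stair_rows,
        columns=["participant", "condition", "trial", "stimulus", "ssd_ms",
                 "stop_success"],
    )
    return observed, latent, staircase


# ---------------------------------------------------------------------------
# raw EMG synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthBurstSpec:
    """Ground truth of one planted burst."""

    hand: str
    kind: str  # "rt", "partial", "mirror"
    onset_ms: float  # trace time
    peak_ms: float
    offset_ms: float
    amp_mv: float
    cancelled: bool


@dataclass(frozen=True)
class EMGSynthConfig:
    fs_hz: float = 2000.0
    pre_go_ms: float = 500.0
    post_deadline_ms: float = 500.0
    noise_sd_mv: float = 0.01
    #: plateau RMS of the RT-generating burst relative to baseline noise SD
    snr: float = 10.0
    #: partial-burst peak amplitude as a fraction of the RT-burst amplitude
    partial_amp_frac: float = 0.4
    #: press occurs this long after the RT-burst onset
    em_offset_ms: float = 60.0
    rt_rise_ms: float = 6.0
    rt_plateau_ms: float = 110.0
    rt_decay_ms: float = 40.0
    partial_rise_ms: float = 50.0
    partial_decay_ms: float = 50.0
    band_hz: tuple = (20.0, 500.0)
    window: CensoringWindow = field(default_factory=CensoringWindow)
    #: probability of planting a spurious "mirror" burst (peak after the
    #: responding hand's RT-burst onset) in the stopping hand — detector
    #: stress tests only
    mirror_rate: float = 0.0
    #: minimum partial-offset to RT-onset gap for the responding-hand copy
    min_separation_ms: float = 20.0


def _band_noise(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (the EMG carrier)."""
    pad = 256
    x = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)[pad:-pad]
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _burst_window(n_rise: int, n_plateau: int, n_decay: int) -> np.ndarray:
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / max(n_rise, 1)))
    plateau = np.ones(n_plateau)
    decay = 0.5 * (1 + np.cos(np.pi * np.arange(n_decay) / max(n_decay, 1)))
    return np.concatenate([rise, plateau, decay])


def _envelope_peak_idx(x: np.ndarray, fs: float) -> int:
    # zero-pad before the 10 Hz low-pass so filter edge transients on the
    # short burst array do not displace the envelope peak
    pad = int(round(0.3 * fs))
    sos = signal.butter(4, 10.0, btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, np.pad(np.abs(x), pad))
    return int(np.argmax(env)) - pad


def _place(trace: np.ndarray, burst: np.ndarray, start_idx: int) -> tuple[int, int]:
    """Add ``burst`` into ``trace`` starting at start_idx, clipping to the
    trace extent; returns the realized (start, stop) sample range."""
    n = trace.size
    lo = max(start_idx, 0)
    hi = min(start_idx + burst.size, n)
    if hi <= lo:
        raise ValueError("burst events fall outside the trace extent")
    trace[lo:hi] += burst[lo - start_idx : hi - start_idx]
    return lo, hi


def synth_emg(
    latent_row: pd.Series | dict,
    config: EMGSynthConfig = EMGSynthConfig(),
    seed: Optional[int] = None,
) -> tuple[EMGTrace, list[SynthBurstSpec]]:
    """Synthesize the two-channel raw EMG of one trial from its latents.

    ``latent_row`` needs: stimulus, ssd_ms, response, rt plus per-hand press
    times (rt_left_ms / rt_right_ms), stop_success, margin_ms and t_stop
    (observed and latent tables joined on the row).  Returns a trace dict
    (left, right, fs_hz, markers) and the planted-burst ground truth.

    All trace times are ms from trace start; the go stimulus sits at
    ``pre_go_ms``.
    """
    row = dict(latent_row)
    rng = np.random.default_rng(seed)
    fs = config.fs_hz
    deadline = float(row.get("deadline_ms", DEFAULT_DEADLINE_MS))
    dur_ms = config.pre_go_ms + deadline + config.post_deadline_ms
    n = int(round(dur_ms * fs / 1000.0))
    ms2i = lambda t: int(round(t * fs / 1000.0))

    channels = {
        "left": rng.normal(0.0, config.noise_sd_mv, n),
        "right": rng.normal(0.0, config.noise_sd_mv, n),
    }
    truth: list[SynthBurstSpec] = []
    go_ms = config.pre_go_ms
    amp_rt = config.snr * config.noise_sd_mv
    stimulus = row["stimulus"]
    is_stop = stimulus in (LS, RS)
    ssd = float(row["ssd_ms"]) if is_stop else np.nan
    stop_ms = go_ms + ssd if is_stop else None

    def plant_rt(hand: str, press_trace_ms: float) -> SynthBurstSpec:
        onset = press_trace_ms - config.em_offset_ms
        n_r, n_p, n_d = (ms2i(config.rt_rise_ms), ms2i(config.rt_plateau_ms),
                         ms2i(config.rt_decay_ms))
        w = _burst_window(n_r, n_p, n_d)
        carrier = _band_noise(rng, w.size, fs, config.band_hz)
        burst = amp_rt * w * carrier
        lo, hi = _place(channels[hand], burst, ms2i(onset))
        pk = (ms2i(onset) + _envelope_peak_idx(burst, fs)) / fs * 1000.0
        spec = SynthBurstSpec(hand, "rt", lo / fs * 1000.0, pk, hi / fs * 1000.0,
                              amp_rt, cancelled=False)
        truth.append(spec)
        return spec

    def plant_partial(hand: str, peak_trace_ms: float, kind: str = "partial") -> SynthBurstSpec:
        amp = config.partial_amp_frac * amp_rt
        n_r, n_d = ms2i(config.partial_rise_ms), ms2i(config.partial_decay_ms)
        w = _burst_window(n_r, 0, n_d)
        carrier = _band_noise(rng, w.size, fs, config.band_hz)
        burst = amp * w * carrier
        # centre so the noise-free envelope peak lands exactly on target
        pk_idx = _envelope_peak_idx(burst, fs)
        start = ms2i(peak_trace_ms) - pk_idx
        lo, hi = _place(channels[hand], burst, start)
        spec = SynthBurstSpec(hand, kind, lo / fs * 1000.0, peak_trace_ms,
                              hi / fs * 1000.0, amp, cancelled=True)
        truth.append(spec)
        return spec

    response = row["response"]
    presses = {"left": row.get("rt_left_ms", np.nan), "right": row.get("rt_right_ms", np.nan)}
    rt_specs: dict[str, SynthBurstSpec] = {}
    for hand, press in presses.items():
        if press is not None and np.isfinite(press):
            if not (0 < press <= deadline + 1e-9):
                raise ValueError(f"press at {press} ms outside the response window")
            rt_specs[hand] = plant_rt(hand, go_ms + float(press))

    if is_stop and bool(row.get("stop_success", False)):
        margin = float(row.get("margin_ms", np.nan))
        if np.isfinite(margin) and config.window.contains(margin):
            peak = stop_ms + float(row["t_stop"])
            stop_side = STOP_SIDE[stimulus]
            respond_side = "left" if stop_side == "right" else "right"
            plant_partial(stop_side, peak)
            rt_spec = rt_specs.get(respond_side)
            # responding-hand copy only when separable from the RT burst
            if rt_spec is not None and (
                peak + config.partial_decay_ms + config.min_separation_ms
                <= rt_spec.onset_ms
            ):
                plant_partial(respond_side, peak)
        elif config.mirror_rate > 0 and rng.random() < config.mirror_rate:
            stop_side = STOP_SIDE[stimulus]
            respond_side = "left" if stop_side == "right" else "right"
            rt_spec = rt_specs.get(respond_side)
            if rt_spec is not None:
                # spurious mirror burst: peak after the RT-burst onset
                peak = rt_spec.onset_ms + config.partial_rise_ms + 10.0
                plant_partial(stop_side, peak, kind="mirror")

    def _press_marker(hand: str) -> Optional[float]:
        press = presses[hand]
        if press is None or not np.isfinite(press):
            return None
        return go_ms + float(press)

    trace = EMGTrace(
        left=channels["left"],
        right=channels["right"],
        fs_hz=fs,
        go_time_ms=go_ms,
        stop_time_ms=stop_ms,
        press_left_ms=_press_marker("left"),
        press_right_ms=_press_marker("right"),
        participant=row.get("participant"),
        trial=row.get("trial"),
        condition=row.get("condition"),
    )
    return trace, truth
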