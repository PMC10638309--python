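"""SIS ("simultaneously inhibit and start") race model of selective stopping.

Architecture.  On every trial a *dual-go* runner starts at the go stimulus and,
if it finishes first, produces the bimanual response.  On selective-stop
trials the stop signal (at SSD) simultaneously launches a *dual-stop* runner,
which races to cancel the bimanual response, and a *selective* (unimanual)
runner for the hand that must continue.  Successful inhibition therefore
yields a unimanual response at ``SSD + selective finish time``.  All finish
times are ex-Gaussian.  Rare events are captured by three probabilities:
``gf`` (go trigger failure), ``tf`` (stop trigger failure, suppressing both
stop-launched runners) and ``eps_wrong`` (the wrong hand's selective runner is
launched).

The module provides trial simulation, the per-trial likelihood over
stimulus x response cells, the stop-wins-the-race probability, and the
censoring simulation that quantifies the selection bias of EMG CancelTime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad

from . import exgauss as xg
from .exgauss import RunnerParams
from .task_design import (
    CONDITIONS,
    CORRECT_UNIMANUAL,
    DEFAULT_DEADLINE_MS,
    DR,
    DS,
    LR,
    LS,
    NR,
    RR,
    RS,
    TrialSpec,
)

RUNNERS = ("dual_go", "dual_stop", "sel_left", "sel_right")


@dataclass(frozen=True)
class SISParams:
    """Full parameter set of the SIS model (theta), per condition.

    Each runner maps condition -> RunnerParams; a runner whose speed is shared
    across conditions simply maps both conditions to the same values.
    """

    dual_go: Mapping[str, RunnerParams]
    dual_stop: Mapping[str, RunnerParams]
    sel_left: Mapping[str, RunnerParams]
    sel_right: Mapping[str, RunnerParams]
    gf: float = 0.0
    tf: float = 0.0
    eps_wrong: float = 0.0
    p_floor: float = 1e-10

    def __post_init__(self) -> None:
        for p, name in ((self.gf, "gf"), (self.tf, "tf"), (self.eps_wrong, "eps_wrong")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not self.p_floor > 0:
            raise ValueError("p_floor must be > 0")
        for rname in RUNNERS:
            m = getattr(self, rname)
            for cond in CONDITIONS:
                if cond not in m:
                    raise ValueError(f"runner {rname} missing condition {cond!r}")

    def runner(self, name: str, condition: str) -> RunnerParams:
        return getattr(self, name)[condition]

    def selective(self, stimulus: str, condition: str, correct: bool = True) -> RunnerParams:
        """Selective runner racing on a stop trial: the continuing hand's
        runner if ``correct``, the cued-to-stop hand's if not."""
        if stimulus == LS:
            name = "sel_left" if correct else "sel_right"
        elif stimulus == RS:
            name = "sel_right" if correct else "sel_left"
        else:
            raise ValueError(f"{stimulus} is not a stop stimulus")
        return self.runner(name, condition)


@dataclass(frozen=True)
class RaceOutcome:
    """Latent and observed outcome of one simulated trial (ms from go onset
    except ``t_stop``/``t_sel`` which run from stop-signal onset)."""

    response: str
    rt_ms: float  # nan for NR
    t_go: float  # nan if go runner did not launch
    t_stop: float  # nan if stop not launched / go trial
    t_sel: float  # nan if stop not launched / go trial
    go_launched: bool
    stop_launched: bool
    sel_runner: Optional[str]  # "left" / "right" / None
    stop_success: bool
    margin_ms: float  # t_go - (ssd + t_stop); nan unless both ran


@dataclass(frozen=True)
class CensoringWindow:
    """Margin range (go finish minus stop finish) inside which a partial EMG
    burst is physically detectable.  A stop that wins by less than
    ``lower_margin_ms`` leaves a partial merged into the response burst
    ("too slow" stopping); one that wins by more than ``upper_margin_ms``
    cancels the response before any muscle activity arises ("too fast")."""

    lower_margin_ms: float = 90.0
    upper_margin_ms: float = 115.0

    def __post_init__(self) -> None:
        if not 0 < self.lower_margin_ms < self.upper_margin_ms:
            raise ValueError("need 0 < lower_margin < upper_margin")

    def contains(self, margin_ms) -> np.ndarray:
        m = np.asarray(margin_ms, dtype=float)
        return (m >= self.lower_margin_ms) & (m <= self.upper_margin_ms)


def detectability_margin_ms(
    peak_to_offset_ms: float = 50.0,
    offset_to_onset_ms: float = 20.0,
    onset_to_press_ms: float = 20.0,
) -> float:
    """Smallest stop-over-go margin at which a partial burst is separable from
    the RT-generating burst: partial peak-to-offset time, plus the detector's
    minimum offset-to-onset gap, plus RT-burst onset-to-press time.  With the
    default component estimates this is 90 ms."""
    return peak_to_offset_ms + offset_to_onset_ms + onset_to_press_ms


# ---------------------------------------------------------------------------
# stop-wins probability
# ---------------------------------------------------------------------------

def stop_win_probability(
    go: RunnerParams, stop: RunnerParams, ssd: float, method: str = "exact"
) -> float:
    """P(SSD + stop finish < go finish): the dual-stop runner beats the
    dual-go runner at stop-signal delay ``ssd``.

    ``method="exact"`` evaluates the closed form obtained by writing the
    finish-time difference as Normal + asymmetric-Laplace; ``"quad"`` runs
    adaptive quadrature of ``f_stop(s) * S_go(ssd + s)`` to 1e-6.
    """
    if method == "exact":
        return float(_pwin_exact(go, stop, np.asarray([ssd]))[0])
    if method == "quad":
        # upper limit where the stop density has mass below ~1e-17
        ub = stop.mu + 9.0 * stop.sigma + 40.0 * stop.tau
        val, err = quad(
            lambda s: xg.pdf(s, stop.mu, stop.sigma, stop.tau)
            * xg.exg_survivor(ssd + s, go),
            0.0,
            ub,
            epsabs=1e-6,
            limit=200,
        )
        if not np.isfinite(val) or err > 1e-4:
            raise RuntimeError(
                f"stop_win_probability quadrature did not converge "
                f"(value={val}, abs err estimate={err}, ssd={ssd})"
            )
        return float(np.clip(val, 0.0, 1.0))
    raise ValueError(f"unknown method {method!r}")


def _pwin_exact(go: RunnerParams, stop: RunnerParams, ssd: np.ndarray) -> np.ndarray:
    """Vectorized closed form of P(T_go - T_stop > ssd).

    T_go - T_stop = (mu_g - mu_s) + N(0, sqrt(sg^2 + ss^2)) + Exp(tau_g)
    - Exp(tau_s); integrating the two exponential tails separately gives
    P(X > c) = w_g * S_exG(c; 0, s, tau_g) + w_s * F_exG(-c; 0, s, tau_s)
    with weights w_g = tau_g/(tau_g+tau_s), w_s = 1 - w_g.
    """
    c = np.asarray(ssd, dtype=float) - (go.mu - stop.mu)
    s = float(np.hypot(go.sigma, stop.sigma))
    wg = go.tau / (go.tau + stop.tau)
    out = wg * xg.sf(c, 0.0, s, go.tau) + (1.0 - wg) * xg.cdf(-c, 0.0, s, stop.tau)
    return np.clip(out, 0.0, 1.0)


def _gauss_legendre_nodes(a: np.ndarray, b: float, n: int = 64):
    """Nodes/weights of n-point Gauss-Legendre on [a_i, b] for each a_i."""
    x, w = leggauss(n)
    a = np.asarray(a, dtype=float)[:, None]
    half = (b - a) / 2.0
    nodes = half * (x[None, :] + 1.0) + a
    weights = half * w[None, :]
    return nodes, weights


def _go_beats_stop_by_T(go: RunnerParams, stop: RunnerParams, ssd: np.ndarray,
                        T: float, n_nodes: int = 64) -> np.ndarray:
    """I(T, d) = integral_0^T f_go(t) * S_stop(t - d) dt for each d (the go
    runner finishes first, before the deadline).  For t <= d the stop survivor
    is 1, giving F_go(min(T, d)); the remainder is smooth and handled by fixed
    Gauss-Legendre quadrature."""
    d = np.asarray(ssd, dtype=float)
    out = xg.cdf(np.minimum(T, d), go.mu, go.sigma, go.tau)
    lo = np.minimum(d, T)
    nodes, weights = _gauss_legendre_nodes(lo, T, n_nodes)
    integ = xg.pdf(nodes, go.mu, go.sigma, go.tau) * np.clip(
        xg.sf(nodes - d[:, None], stop.mu, stop.sigma, stop.tau), 0.0, 1.0
    )
    out = out + np.sum(weights * integ, axis=1)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    params: SISParams,
    condition: str,
    stimulus: str,
    ssd: float,
    n: int,
    rng: np.random.Generator,
    deadline_ms: float = DEFAULT_DEADLINE_MS,
) -> dict:
    """Vectorized simulation of ``n`` trials of one design cell.

    Returns a dict of aligned arrays: response (str), rt (nan for NR), latent
    finish times, launch flags, stop_success and margin.
    """
    t_go = xg.exg_sample(params.runner("dual_go", condition), n, rng)
    go_launched = rng.random(n) >= params.gf
    response = np.full(n, NR, dtype=object)
    rt = np.full(n, np.nan)
    t_stop = np.full(n, np.nan)
    t_sel = np.full(n, np.nan)
    stop_launched = np.zeros(n, dtype=bool)
    sel_runner = np.full(n, None, dtype=object)
    stop_success = np.zeros(n, dtype=bool)
    margin = np.full(n, np.nan)

    if stimulus == DS:
        ok = go_launched & (t_go <= deadline_ms)
        response[ok] = DR
        rt[ok] = t_go[ok]
        t_go[~go_launched] = np.nan
        return dict(
            response=response, rt=rt, t_go=t_go, t_stop=t_stop, t_sel=t_sel,
            go_launched=go_launched, stop_launched=stop_launched,
            sel_runner=sel_runner, stop_success=stop_success, margin=margin,
        )

    if stimulus not in (LS, RS):
        raise ValueError(f"unknown stimulus {stimulus!r}")

    stop_launched = rng.random(n) >= params.tf
    wrong = rng.random(n) < params.eps_wrong
    t_stop_all = xg.exg_sample(params.runner("dual_stop", condition), n, rng)
    t_correct = xg.exg_sample(params.selective(stimulus, condition, True), n, rng)
    t_wrong = xg.exg_sample(params.selective(stimulus, condition, False), n, rng)
    t_sel_all = np.where(wrong, t_wrong, t_correct)

    t_stop[stop_launched] = t_stop_all[stop_launched]
    t_sel[stop_launched] = t_sel_all[stop_launched]
    both = go_launched & stop_launched
    margin[both] = t_go[both] - (ssd + t_stop[both])

    # go wins (or stop never launched): bimanual response escapes inhibition
    go_wins = go_launched & (~stop_launched | (margin < 0))
    dr_obs = go_wins & (t_go <= deadline_ms)
    response[dr_obs] = DR
    rt[dr_obs] = t_go[dr_obs]

    # stop wins (or go never launched): unimanual response of launched runner
    stop_wins = stop_launched & (~go_launched | (margin >= 0))
    uni_rt = ssd + t_sel_all
    uni_obs = stop_wins & (uni_rt <= deadline_ms)
    correct_resp = CORRECT_UNIMANUAL[stimulus]
    wrong_resp = LR if correct_resp == RR else RR
    response[uni_obs & ~wrong] = correct_resp
    response[uni_obs & wrong] = wrong_resp
    rt[uni_obs] = uni_rt[uni_obs]
    side_correct = "left" if correct_resp == LR else "right"
    side_wrong = "right" if side_correct == "left" else "left"
    sel_runner[stop_launched & ~wrong] = side_correct
    sel_runner[stop_launched & wrong] = side_wrong

    stop_success = uni_obs & ~wrong
    t_go[~go_launched] = np.nan
    return dict(
        response=response, rt=rt, t_go=t_go, t_stop=t_stop, t_sel=t_sel,
        go_launched=go_launched, stop_launched=stop_launched,
        sel_runner=sel_runner, stop_success=stop_success, margin=margin,
    )


def simulate_trial(
    params: SISParams,
    trial: TrialSpec,
    ssd: Optional[float],
    rng: np.random.Generator,
) -> RaceOutcome:
    """Simulate a single scheduled trial (thin wrapper over the vectorized
    path), returning the full latent RaceOutcome."""
    if trial.is_stop and ssd is None:
        raise ValueError("stop trials require an SSD")
    sim = simulate_trials(
        params, trial.condition, trial.stimulus,
        0.0 if ssd is None else float(ssd), 1, rng, trial.deadline_ms,
    )
    return RaceOutcome(
        response=str(sim["response"][0]),
        rt_ms=float(sim["rt"][0]),
        t_go=float(sim["t_go"][0]),
        t_stop=float(sim["t_stop"][0]),
        t_sel=float(sim["t_sel"][0]),
        go_launched=bool(sim["go_launched"][0]),
        stop_launched=bool(sim["stop_launched"][0]),
        sel_runner=sim["sel_runner"][0],
        stop_success=bool(sim["stop_success"][0]),
        margin_ms=float(sim["margin"][0]),
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _mix_sf(pu: RunnerParams, pw: RunnerParams, eps: float, t) -> np.ndarray:
    return (1.0 - eps) * np.clip(xg.sf(t, pu.mu, pu.sigma, pu.tau), 0, 1) + eps * np.clip(
        xg.sf(t, pw.mu, pw.sigma, pw.tau), 0, 1
    )


def category_probabilities(
    params: SISParams,
    condition: str,
    stimulus: str,
    ssd: Optional[float] = None,
    deadline_ms: float = DEFAULT_DEADLINE_MS,
) -> dict:
    """Probability of each observable response category (RT integrated out)
    for one design cell.  The four categories sum to 1 up to integration
    tolerance; used to cross-check the likelihood against the simulator."""
    gf, tf, eps = params.gf, params.tf, params.eps_wrong
    T = deadline_ms
    pg = params.runner("dual_go", condition)
    if stimulus == DS:
        p_dr = (1 - gf) * float(xg.cdf(T, pg.mu, pg.sigma, pg.tau))
        p_nr = gf + (1 - gf) * float(xg.exg_survivor(T, pg))
        return {DR: p_dr, NR: p_nr, LR: 0.0, RR: 0.0}

    if ssd is None:
        raise ValueError("stop cells require an SSD")
    d = float(ssd)
    ps = params.runner("dual_stop", condition)
    pu = params.selective(stimulus, condition, True)
    pw = params.selective(stimulus, condition, False)
    pwin = float(_pwin_exact(pg, ps, np.asarray([d]))[0])
    I_T = float(_go_beats_stop_by_T(pg, ps, np.asarray([d]), T)[0])
    uni_gate = gf + (1 - gf) * pwin
    F_u = float(xg.cdf(T - d, pu.mu, pu.sigma, pu.tau)) if T > d else 0.0
    F_w = float(xg.cdf(T - d, pw.mu, pw.sigma, pw.tau)) if T > d else 0.0
    F_g = float(xg.cdf(T, pg.mu, pg.sigma, pg.tau))

    p_dr = (1 - gf) * (tf * F_g + (1 - tf) * I_T)
    p_uni_correct = (1 - tf) * (1 - eps) * F_u * uni_gate
    p_uni_wrong = (1 - tf) * eps * F_w * uni_gate
    # no-response: nothing launched, or every launched path missed the deadline
    S_mix_T = _mix_sf(pu, pw, eps, np.asarray([T - d]))[0]
    p_nr = (
        gf * tf
        + gf * (1 - tf) * S_mix_T
        + (1 - gf) * tf * (1.0 - F_g)
        + (1 - gf) * (1 - tf) * ((1.0 - pwin) - I_T + pwin * S_mix_T)
    )
    correct = CORRECT_UNIMANUAL[stimulus]
    wrong = LR if correct == RR else RR
    return {DR: p_dr, correct: p_uni_correct, wrong: p_uni_wrong, NR: p_nr}


def trial_loglik(
    params: SISParams,
    condition: str,
    stimulus: str,
    response: str,
    rt_ms: Optional[float] = None,
    ssd_ms: Optional[float] = None,
    deadline_ms: float = DEFAULT_DEADLINE_MS,
) -> float:
    """Log density (responses with an RT) or log probability (NR) of a single
    observed trial under the SIS model, floored at ``p_floor``."""
    if response != NR:
        if rt_ms is None or not (0.0 < rt_ms <= deadline_ms):
            raise ValueError(
                f"response {response} requires an RT in (0, {deadline_ms}] ms; "
                f"got {rt_ms!r} (late/absent responses must be classified NR)"
            )
    gf, tf, eps = params.gf, params.tf, params.eps_wrong
    pg = params.runner("dual_go", condition)
    floor = params.p_floor

    if stimulus == DS:
        if response == DR:
            val = (1 - gf) * float(xg.pdf(rt_ms, pg.mu, pg.sigma, pg.tau))
        elif response == NR:
            val = gf + (1 - gf) * float(xg.exg_survivor(deadline_ms, pg))
        else:  # unimanual response to a dual stimulus: not modelled mechanistically
            val = 0.0
        return float(np.log(max(val, floor)))

    if ssd_ms is None:
        raise ValueError("stop trials require ssd_ms")
    d = float(ssd_ms)
    ps = params.runner("dual_stop", condition)
    if response == DR:  # failed stop
        surv = float(xg.exg_survivor(rt_ms - d, ps))
        val = (1 - gf) * float(xg.pdf(rt_ms, pg.mu, pg.sigma, pg.tau)) * (
            tf + (1 - tf) * surv
        )
    elif response == NR:
        val = category_probabilities(params, condition, stimulus, d, deadline_ms)[NR]
    else:
        correct = response == CORRECT_UNIMANUAL[stimulus]
        psel = params.selective(stimulus, condition, correct)
        w = (1 - eps) if correct else eps
        pwin = float(_pwin_exact(pg, ps, np.asarray([d]))[0])
        val = (
            (1 - tf) * w * float(xg.pdf(rt_ms - d, psel.mu, psel.sigma, psel.tau))
            * (gf + (1 - gf) * pwin)
        )
    return float(np.log(max(val, floor)))


# ---------------------------------------------------------------------------
# censoring simulation
# ---------------------------------------------------------------------------

def staircase_stop_run(
    params: SISParams,
    condition: str,
    n: int,
    rng: np.random.Generator,
    ssd_init_ms: float = 200.0,
    step_ms: float = 50.0,
    deadline_ms: float = DEFAULT_DEADLINE_MS,
) -> dict:
    """Simulate ``n`` consecutive selective-stop trials (balanced LS/RS, one
    independent staircase per side) and return aligned arrays: ssd, success,
    latent stop finish and margin.

    Latent draws are precomputed in bulk; only the SSD walk is sequential, so
    long runs are cheap.  Used by the censoring simulation and the staircase
    fixed-point checks.
    """
    go = params.runner("dual_go", condition)
    st = params.runner("dual_stop", condition)
    t_go = xg.exg_sample(go, n, rng)
    t_stop = xg.exg_sample(st, n, rng)
    go_launched = rng.random(n) >= params.gf
    stop_launched = rng.random(n) >= params.tf
    wrong = rng.random(n) < params.eps_wrong
    stims = np.array([LS, RS] * (n // 2 + 1), dtype=object)[:n]
    t_sel = np.empty(n)
    for stim in (LS, RS):
        mask = stims == stim
        t_c = xg.exg_sample(params.selective(stim, condition, True), int(mask.sum()), rng)
        t_w = xg.exg_sample(params.selective(stim, condition, False), int(mask.sum()), rng)
        t_sel[mask] = np.where(wrong[mask], t_w, t_c)

    ssd = {LS: ssd_init_ms, RS: ssd_init_ms}
    floor, ceil = 0.0, deadline_ms - 100.0
    d_out = np.empty(n)
    success = np.zeros(n, dtype=bool)
    margin = np.full(n, np.nan)
    for i in range(n):
        stim = stims[i]
        d = ssd[stim]
        d_out[i] = d
        if go_launched[i] and stop_launched[i]:
            margin[i] = t_go[i] - (d + t_stop[i])
        if stop_launched[i] and not wrong[i] and (d + t_sel[i]) <= deadline_ms:
            success[i] = (not go_launched[i]) or margin[i] >= 0
        delta = step_ms if success[i] else -step_ms
        ssd[stim] = min(max(d + delta, floor), ceil)
    return {
        "stimulus": stims, "ssd": d_out, "success": success,
        "t_stop": np.where(stop_launched, t_stop, np.nan), "margin": margin,
    }


def censoring_bias_sim(
    params: SISParams,
    window: CensoringWindow,
    n: int,
    rng: np.random.Generator,
    ssd_init_ms: float = 200.0,
    step_ms: float = 50.0,
    deadline_ms: float = DEFAULT_DEADLINE_MS,
) -> dict:
    """Quantify the CancelTime selection bias per condition.

    Simulates ``n`` selective-stop trials per condition (balanced LS/RS, SSD
    staircased per side), then compares the mean stop-runner finish time over
    all successful stops against the mean over the margin-censored subset —
    the trials on which a partial EMG burst would actually be detectable.

    Returns per condition: uncensored/censored mean stop finish, bias
    (censored - uncensored; negative = down-bias) and the censored fraction.
    """
    out = {}
    for condition in CONDITIONS:
        run = staircase_stop_run(params, condition, n, rng, ssd_init_ms,
                                 step_ms, deadline_ms)
        keep = run["success"] & np.isfinite(run["margin"])
        t_stop_success = run["t_stop"][keep]
        margins = run["margin"][keep]
        if t_stop_success.size == 0:
            raise RuntimeError(
                f"no successful stops with a defined margin in condition "
                f"{condition}; increase n or check parameters"
            )
        inside = window.contains(margins)
        if not inside.any():
            raise RuntimeError(
                f"censored subset empty in condition {condition}: no margins in "
                f"[{window.lower_margin_ms}, {window.upper_margin_ms}] ms; "
                f"increase n or widen the window"
            )
        unc = float(t_stop_success.mean())
        cen = float(t_stop_success[inside].mean())
        out[condition] = {
            "mean_stop_finish_ms": unc,
            "mean_stop_finish_censored_ms": cen,
            "bias_ms": cen - unc,
            "censored_fraction": float(inside.mean()),
            "n_successful_stops": int(t_stop_success.size),
        }
    return out
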