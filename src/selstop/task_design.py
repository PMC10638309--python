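"""Experiment schedules and SSD staircase for the response-selective stop task.

The task requires a bimanual button press to a dual go stimulus (DS).  On one
third of trials a selective stop signal follows after the stop-signal delay
(SSD): a left stimulus (LS) means "stop the right hand, continue left", a
right stimulus (RS) means "stop the left hand, continue right".  In the
proactive condition a cue announces which hand might have to stop; in the
reactive condition only a fixation cross precedes the go stimulus.

The SSD is tracked by a 1-up/1-down staircase in 50 ms steps starting at
200 ms, independently for each (condition, stop-side) combination, so that
long-run stop success converges to 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

REACTIVE = "reactive"
PROACTIVE = "proactive"
CONDITIONS = (REACTIVE, PROACTIVE)

# stimuli: DS dual go; LS left stimulus (stop right); RS right stimulus (stop left)
DS, LS, RS = "DS", "LS", "RS"
STIMULI = (DS, LS, RS)
# responses: no response, dual response, left-only, right-only
NR, DR, LR, RR = "NR", "DR", "LR", "RR"
RESPONSES = (NR, DR, LR, RR)

#: hand that must stop for each stop stimulus
STOP_SIDE = {LS: "right", RS: "left"}
#: correct unimanual response for each stop stimulus
CORRECT_UNIMANUAL = {LS: LR, RS: RR}

DEFAULT_DEADLINE_MS = 1100.0
DEFAULT_FOREPERIOD_MS = (500.0, 700.0)
DEFAULT_SSD_INIT_MS = 200.0
DEFAULT_SSD_STEP_MS = 50.0


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    index: int
    condition: str
    cue: str  # "none", "maybe-stop-left", "maybe-stop-right"
    stimulus: str  # DS / LS / RS
    foreperiod_ms: float
    deadline_ms: float = DEFAULT_DEADLINE_MS

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}")
        if self.condition == REACTIVE and self.cue != "none":
            raise ValueError("reactive trials carry no cue")
        if self.condition == PROACTIVE and self.cue == "none":
            raise ValueError("proactive trials require a cue")
        # proactive stop cue must be congruent with the hand required to stop
        if self.condition == PROACTIVE and self.stimulus in STOP_SIDE:
            expected = f"maybe-stop-{STOP_SIDE[self.stimulus]}"
            if self.cue != expected:
                raise ValueError(
                    f"proactive cue {self.cue!r} incongruent with stimulus "
                    f"{self.stimulus} (expected {expected!r})"
                )
        if not (DEFAULT_FOREPERIOD_MS[0] <= self.foreperiod_ms <= DEFAULT_FOREPERIOD_MS[1]):
            raise ValueError("foreperiod must lie in [500, 700] ms")

    @property
    def is_stop(self) -> bool:
        return self.stimulus in STOP_SIDE


def build_schedule(
    condition: str,
    n_trials: int,
    stop_fraction: float = 1.0 / 3.0,
    seed: Optional[int] = None,
) -> list[TrialSpec]:
    """Build a randomized trial schedule for one condition block.

    ``n_trials * stop_fraction`` stop trials are split equally into LS and RS;
    the remainder are DS go trials.  Proactive go trials receive cues balanced
    left/right; proactive stop trials are cued congruently.  Foreperiods are
    drawn uniformly from [500, 700] ms.  The order is a uniform shuffle under
    ``seed``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n_stop = n_trials * stop_fraction
    n_side = n_stop / 2.0
    if n_trials % 6 != 0 or abs(n_side - round(n_side)) > 1e-9:
        raise ValueError(
            f"n_trials={n_trials} must be divisible by 6 so stop trials at "
            f"fraction {stop_fraction} split evenly into left- and right-stop"
        )
    n_side = int(round(n_side))
    n_go = n_trials - 2 * n_side

    rng = np.random.default_rng(seed)
    stimuli = [DS] * n_go + [LS] * n_side + [RS] * n_side
    if condition == REACTIVE:
        cues = ["none"] * n_trials
    else:
        # go-trial cues balanced left/right; stop-trial cues congruent
        half = n_go // 2
        go_cues = ["maybe-stop-left"] * half + ["maybe-stop-right"] * (n_go - half)
        cues = (
            go_cues
            + [f"maybe-stop-{STOP_SIDE[LS]}"] * n_side
            + [f"maybe-stop-{STOP_SIDE[RS]}"] * n_side
        )
    order = rng.permutation(n_trials)
    fore = rng.uniform(*DEFAULT_FOREPERIOD_MS, size=n_trials)
    return [
        TrialSpec(
            index=i,
            condition=condition,
            cue=cues[j],
            stimulus=stimuli[j],
            foreperiod_ms=float(fore[i]),
        )
        for i, j in enumerate(order)
    ]


def schedule_to_frame(schedule: list[TrialSpec]) -> pd.DataFrame:
    """Tabular view of a schedule (one row per trial, ms units)."""
    return pd.DataFrame(
        {
            "trial": [t.index for t in schedule],
            "condition": [t.condition for t in schedule],
            "cue": [t.cue for t in schedule],
            "stimulus": [t.stimulus for t in schedule],
            "foreperiod_ms": [t.foreperiod_ms for t in schedule],
            "deadline_ms": [t.deadline_ms for t in schedule],
        }
    )


@dataclass(frozen=True)
class StaircaseState:
    """1-up/1-down SSD tracker, one independent SSD per (condition, side)."""

    ssd_ms: dict = field(default_factory=dict)
    step_ms: float = DEFAULT_SSD_STEP_MS
    floor_ms: float = 0.0
    ceiling_ms: float = DEFAULT_DEADLINE_MS - 100.0

    def __post_init__(self) -> None:
        for key, val in self.ssd_ms.items():
            if not (self.floor_ms <= val <= self.ceiling_ms):
                raise ValueError(f"SSD {val} for {key} outside [{self.floor_ms}, {self.ceiling_ms}]")

    @classmethod
    def initial(
        cls,
        ssd_init_ms: float = DEFAULT_SSD_INIT_MS,
        step_ms: float = DEFAULT_SSD_STEP_MS,
        floor_ms: float = 0.0,
        ceiling_ms: float = DEFAULT_DEADLINE_MS - 100.0,
    ) -> "StaircaseState":
        keys = [(c, s) for c in CONDITIONS for s in ("left", "right")]
        return cls(
            ssd_ms={k: ssd_init_ms for k in keys},
            step_ms=step_ms,
            floor_ms=floor_ms,
            ceiling_ms=ceiling_ms,
        )


def staircase_update(
    state: StaircaseState, key: tuple, stop_success: bool
) -> StaircaseState:
    """One 1-up/1-down staircase step, clamped to [floor, ceiling]; other
    keys untouched.

    After a successful stop the task gets harder (SSD + step, the stop signal
    arrives later); after a failed stop it gets easier (SSD - step).  This is
    the only direction under which the tracker is self-correcting: because
    stop-success probability falls as SSD grows, the staircase equilibrates
    where P(success) = 0.5.  (Stepping the other way is a positive feedback
    loop that pins SSD at the floor.)
    """
    if key not in state.ssd_ms:
        raise KeyError(f"unknown staircase key {key!r}; known: {sorted(state.ssd_ms)}")
    delta = state.step_ms if stop_success else -state.step_ms
    new = float(np.clip(state.ssd_ms[key] + delta, state.floor_ms, state.ceiling_ms))
    ssd = dict(state.ssd_ms)
    ssd[key] = new
    return replace(state, ssd_ms=ssd)


def classify_response(
    trial: TrialSpec,
    left_press_ms: Optional[float] = None,
    right_press_ms: Optional[float] = None,
) -> tuple[str, str]:
    """Classify one trial's observed presses (ms from go onset).

    Returns ``(response, feedback)`` with response in {NR, DR, LR, RR}.
    Presses after the deadline count as absent.  Total function: every press
    combination maps to a category.
    """
    T = trial.deadline_ms
    left = left_press_ms is not None and left_press_ms <= T
    right = right_press_ms is not None and right_press_ms <= T

    if not left and not right:
        return NR, "missed"
    if left and right:
        if trial.is_stop:
            return DR, "failed to stop"
        return DR, "ok"
    resp = LR if left else RR
    if not trial.is_stop:
        return resp, "unimanual response to dual stimulus"
    if resp == CORRECT_UNIMANUAL[trial.stimulus]:
        return resp, "successful stop"
    return resp, "stopped wrong hand"
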