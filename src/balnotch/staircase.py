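"""2I-2AFC 2-up/1-down adaptive staircase on the masker level.

Two consecutive correct responses raise the masker level (making the task
harder); any incorrect response lowers it.  The track asymptotes at the
70.7%-correct point.  Step sizes follow the 5/3/1-dB schedule: 5 dB until
the second reversal, 3 dB until the fourth, 1 dB thereafter; the run stops
at the tenth reversal and the threshold is the mean masker level at the
last four reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import max_masker_level
from .listener_sim import ListenerProfile, ground_truth_threshold, respond_2afc
from .types import DEFAULT_NOTCH_SET, NotchCondition, StimulusPoint

_STEP_SCHEDULE_DB = (5.0, 3.0, 1.0)  # until reversal 2, until 4, thereafter
_N_REVERSALS = 10
_N_AVERAGED = 4

__all__ = ["StaircaseState", "StaircaseResult", "next_level", "run_staircase",
           "run_staircase_pair"]


@dataclass
class StaircaseState:
    """Mutable track state of one 2-up/1-down run."""

    level: float
    n_correct_streak: int = 0
    reversal_levels: list = field(default_factory=list)
    last_direction: int = 0  # +1 up, -1 down, 0 before the first move
    history: list = field(default_factory=list)  # (level, correct) pairs
    terminated: bool = False

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)

    @property
    def step_db(self) -> float:
        if self.n_reversals < 2:
            return _STEP_SCHEDULE_DB[0]
        if self.n_reversals < 4:
            return _STEP_SCHEDULE_DB[1]
        return _STEP_SCHEDULE_DB[2]


def next_level(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one response to the track (mutates and returns ``state``)."""
    if state.terminated:
        raise RuntimeError("staircase already terminated")
    state.history.append((state.level, bool(correct)))
    direction = 0
    if correct:
        state.n_correct_streak += 1
        if state.n_correct_streak >= 2:
            direction = +1
            state.n_correct_streak = 0
    else:
        direction = -1
        state.n_correct_streak = 0
    if direction == 0:
        return state
    if state.last_direction != 0 and direction != state.last_direction:
        state.reversal_levels.append(state.level)
        if state.n_reversals >= _N_REVERSALS:
            state.terminated = True
            state.last_direction = direction
            return state
    state.last_direction = direction
    state.level += direction * state.step_db
    return state


@dataclass
class StaircaseResult:
    threshold_db: float
    state: StaircaseState
    aborted: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.state.history)

    def track_frame(self) -> pd.DataFrame:
        lv, cr = zip(*self.state.history)
        return pd.DataFrame({"trial": np.arange(1, len(lv) + 1),
                             "L_m_db": lv, "correct": cr})


def run_staircase(
    listener: ListenerProfile,
    notch: NotchCondition,
    f_s: float,
    rng: np.random.Generator,
    start_level: float | None = None,
    L_min: float = -30.0,
    level_cap: float | None = None,
    notch_idx: int | None = None,
    max_trials: int = 400,
) -> StaircaseResult:
    """Run one staircase to the 10th reversal and return its threshold.

    The start level defaults to 10 dB below the listener's true threshold
    (an audible starting point).  Hitting a level bound three times in a row
    aborts the run with a flag.
    """
    if notch_idx is None:
        notch_idx = next(
            (i for i, nc in enumerate(DEFAULT_NOTCH_SET) if nc == notch), 0
        )
    true_t = ground_truth_threshold(listener, notch, f_s, notch_idx=notch_idx)
    if start_level is None:
        start_level = true_t - 10.0
    L_max = float(max_masker_level(f_s, cap=level_cap))
    state = StaircaseState(level=float(np.clip(start_level, L_min, L_max)))
    bound_hits = 0
    aborted = False
    while not state.terminated and len(state.history) < max_trials:
        stim = StimulusPoint(f_hz=f_s, L_m=state.level, notch_idx=notch_idx)
        correct = respond_2afc(listener, stim, rng, threshold=true_t)
        next_level(state, correct)
        clipped = float(np.clip(state.level, L_min, L_max))
        if clipped != state.level:
            state.level = clipped
            bound_hits += 1
            if bound_hits >= 3:
                aborted = True
                break
        else:
            bound_hits = 0
    if state.n_reversals < _N_REVERSALS:
        aborted = True
    tail = state.reversal_levels[-_N_AVERAGED:]
    threshold = float(np.mean(tail)) if tail else float("nan")
    return StaircaseResult(threshold_db=threshold, state=state, aborted=aborted)


def run_staircase_pair(
    listener: ListenerProfile,
    notch: NotchCondition,
    f_s: float,
    rng: np.random.Generator,
    **kwargs,
) -> float:
    """Mean threshold of two independent runs (the filter-fitting protocol)."""
    r1 = run_staircase(listener, notch, f_s, rng, **kwargs)
    r2 = run_staircase(listener, notch, f_s, rng, **kwargs)
    return 0.5 * (r1.threshold_db + r2.threshold_db)
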