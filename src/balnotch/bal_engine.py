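"""Orchestration of a full Bayesian active-learning notched-noise run.

A run starts with a deterministic warm-up grid per notch condition (four
frequency anchors with up/down level rules), then enters the active phase:
before each trial the constant mean of the GP that received the last
response is re-optimized, its posterior refit and its candidate grid
rescored, and the stimulus with the globally maximal mutual information
across the nine grids is presented.  Ten percent of trials are signal-free
catch trials interleaved at random positions; their responses estimate the
false-alarm rate and do not train the GPs (configurable).  The run
terminates at the exact configured totals (594 = 540 signal + 54 catch at
the defaults) and is fully reproducible under a fixed seed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import listener_sim
from .acquisition import CandidateGrid, score_grid, select_next_stimulus
from .gp_model import (
    GPDataset,
    GPHyperparameters,
    GPInferenceError,
    LatentPosterior,
    infer_posterior,
    optimize_constant_mean,
    threshold_from_gp,
)
from .types import (
    DEFAULT_NOTCH_SET,
    PHASE_BAL,
    PHASE_CATCH,
    PHASE_INITIAL_GRID,
    NotchCondition,
    StimulusPoint,
    TrialRecord,
    hz_to_octaves,
)

logger = logging.getLogger("balnotch")

__all__ = ["RunConfig", "TrialLog", "BALRunResult", "run_initial_grid",
           "schedule_trials", "run_bal", "extract_threshold_surface",
           "rebuild_posteriors"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one BAL run."""

    notches: tuple[NotchCondition, ...] = DEFAULT_NOTCH_SET
    f_min: float = 500.0
    f_max: float = 4000.0
    signal_trials_per_notch: int = 60
    catch_fraction: float = 0.1
    L_min: float = -30.0
    level_cap: float | None = None
    level_step: float = 1.0
    freq_step_oct: float = 0.1
    seed: int = 0
    hypers: GPHyperparameters = field(default_factory=GPHyperparameters)
    feed_catch_to_gp: bool = False

    def __post_init__(self):
        if self.f_min >= self.f_max:
            raise ValueError("f_min must be below f_max")
        if not 0.0 <= self.catch_fraction < 0.5:
            raise ValueError("catch_fraction must lie in [0, 0.5)")
        if self.signal_trials_per_notch < 1:
            raise ValueError("need at least one signal trial per notch")

    @property
    def total_signal_trials(self) -> int:
        return self.signal_trials_per_notch * len(self.notches)

    @property
    def n_catch_trials(self) -> int:
        return int(round(self.catch_fraction * self.total_signal_trials))

    @property
    def total_trials(self) -> int:
        return self.total_signal_trials + self.n_catch_trials

    def level_grid(self, f_hz: float) -> np.ndarray:
        from .acquisition import max_masker_level

        lmax = float(max_masker_level(f_hz, cap=self.level_cap))
        n = int(np.floor((lmax - self.L_min) / self.level_step)) + 1
        return self.L_min + self.level_step * np.arange(n)


@dataclass
class TrialLog:
    """Ordered trial records with phase bookkeeping and CSV round-tripping."""

    records: list = field(default_factory=list)

    def append(self, rec: TrialRecord) -> None:
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def count(self, phase: str) -> int:
        return sum(1 for r in self.records if r.phase == phase)

    @property
    def n_signal(self) -> int:
        return sum(1 for r in self.records if not r.stimulus.is_catch)

    @property
    def n_catch(self) -> int:
        return sum(1 for r in self.records if r.stimulus.is_catch)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trial": i + 1,
                "notch_id": r.stimulus.notch_idx,
                "f_hz": r.stimulus.f_hz,
                "log2f": r.stimulus.log2f,
                "L_m_db": r.stimulus.L_m,
                "response": int(r.response),
                "is_catch": int(r.stimulus.is_catch),
                "phase": r.phase,
            }
            for i, r in enumerate(self.records)
        ]
        return pd.DataFrame(
            rows,
            columns=["trial", "notch_id", "f_hz", "log2f", "L_m_db",
                     "response", "is_catch", "phase"],
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialLog":
        log = cls()
        for _, row in frame.iterrows():
            stim = StimulusPoint(
                f_hz=float(row["f_hz"]),
                L_m=float(row["L_m_db"]),
                notch_idx=int(row["notch_id"]),
                is_catch=bool(int(row["is_catch"])),
            )
            log.append(TrialRecord(stim, bool(int(row["response"])), str(row["phase"])))
        return log

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialLog":
        # round_trip parsing: the default float parser can be 1 ulp off,
        # which would break bytewise log regeneration
        return cls.from_frame(pd.read_csv(path_or_buf, float_precision="round_trip"))


@dataclass
class BALRunResult:
    config: RunConfig
    log: TrialLog
    posteriors: list  # LatentPosterior per notch
    hypers: list  # per-notch hyperparameters after the final mean fit
    n_inference_failures: int = 0


def _respond(listener, stimulus, rng, config, cache, responder=None) -> bool:
    if responder is not None:
        return bool(responder(stimulus, rng))
    if stimulus.is_catch:
        return listener_sim.respond_yes_no(listener, stimulus, rng)
    key = (stimulus.notch_idx, round(stimulus.f_hz, 6))
    if key not in cache:
        cache[key] = listener_sim.ground_truth_threshold(
            listener, config.notches[stimulus.notch_idx], stimulus.f_hz,
            notch_idx=stimulus.notch_idx,
        )
    return listener_sim.respond_yes_no(
        listener, stimulus, rng, threshold=cache[key]
    )


def run_initial_grid(
    listener,
    notch_idx: int,
    config: RunConfig,
    rng: np.random.Generator,
    responder=None,
    threshold_cache=None,
    max_trials_per_step: int = 25,
) -> list[TrialRecord]:
    """Deterministic warm-up for one notch condition.

    (a) 1 kHz from -20 dB SPL, +20 dB after Yes / -10 dB after No (floor
    -30 dB SPL) until both responses occur; (b) one trial at 2 kHz at the
    mean of the last two 1-kHz levels; (c) the highest test frequency,
    starting 10 dB above/below the 2-kHz level depending on that response,
    stepping +/-10 dB until both responses occur; (d) 500 Hz analogously,
    starting at the 2-kHz level.  A level bound reached without both
    responses terminates the step with a warning.
    """
    if threshold_cache is None:
        threshold_cache = {}
    from .acquisition import max_masker_level

    records: list[TrialRecord] = []

    def present(f_hz: float, level: float) -> bool:
        stim = StimulusPoint(f_hz=f_hz, L_m=float(level), notch_idx=notch_idx)
        yes = _respond(listener, stim, rng, config, threshold_cache, responder)
        records.append(TrialRecord(stim, yes, PHASE_INITIAL_GRID))
        return yes

    def lmax(f_hz: float) -> float:
        return float(max_masker_level(f_hz, cap=config.level_cap))

    def staircase_until_both(f_hz, level, up_db, down_db, first_response=None):
        """Step until both a Yes and a No occur; returns levels used."""
        seen = set()
        levels = []
        if first_response is not None:
            seen.add(first_response)
        for _ in range(max_trials_per_step):
            level = float(np.clip(level, config.L_min, lmax(f_hz)))
            yes = present(f_hz, level)
            levels.append(level)
            seen.add(yes)
            if len(seen) == 2:
                return levels, True
            nxt = level + up_db if yes else level - down_db
            if nxt < config.L_min - 1e-9 or nxt > lmax(f_hz) + 1e-9:
                clipped = float(np.clip(nxt, config.L_min, lmax(f_hz)))
                if clipped == level:  # stuck at a bound
                    logger.warning(
                        "initial grid bound reached at %.0f Hz, notch %d",
                        f_hz, notch_idx,
                    )
                    return levels, False
            level = nxt
        return levels, False

    # (a) 1 kHz
    levels_a, _ = staircase_until_both(1000.0, -20.0, up_db=20.0, down_db=10.0)
    # (b) 2 kHz at the mean of the last two 1-kHz levels
    if len(levels_a) >= 2:
        level_b = 0.5 * (levels_a[-1] + levels_a[-2])
    else:
        level_b = levels_a[-1]
    level_b = float(np.clip(level_b, config.L_min, lmax(2000.0)))
    yes_b = present(2000.0, level_b)
    # (c) highest frequency, start 10 dB above/below the 2-kHz level
    start_c = level_b + 10.0 if yes_b else level_b - 10.0
    staircase_until_both(config.f_max, start_c, up_db=10.0, down_db=10.0)
    # (d) 500 Hz, start at the 2-kHz level
    staircase_until_both(config.f_min if config.f_min >= 500.0 else 500.0,
                         level_b, up_db=10.0, down_db=10.0)
    return records


def schedule_trials(
    config: RunConfig, rng: np.random.Generator, n_initial_signal: int = 0
) -> list[str]:
    """Interleaved plan of the active phase: 'signal' and 'catch' slots.

    The warm-up trials count toward the signal budget, so the plan holds
    ``total_signal - n_initial_signal`` signal slots plus the exact catch
    count, uniformly shuffled under the run seed.
    """
    n_signal = config.total_signal_trials - n_initial_signal
    if n_signal < 0:
        raise ValueError(
            f"initial grid used {n_initial_signal} trials, exceeding the "
            f"signal budget of {config.total_signal_trials}"
        )
    plan = np.array(["signal"] * n_signal + ["catch"] * config.n_catch_trials)
    rng.shuffle(plan)
    return plan.tolist()


def run_bal(listener, config: RunConfig, responder=None) -> BALRunResult:
    """Execute a complete BAL run against a (simulated) listener.

    ``listener`` is a :class:`~balnotch.listener_sim.ListenerProfile`; pass
    ``responder(stimulus, rng) -> bool`` to substitute any other response
    source.  Returns the trial log and the nine final posteriors.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict = {}
    log = TrialLog()
    datasets = [GPDataset.empty() for _ in config.notches]

    # warm-up per notch; truncated if a small signal budget is exhausted
    budget = config.total_signal_trials
    for k in range(len(config.notches)):
        if log.n_signal >= budget:
            break
        recs = run_initial_grid(
            listener, k, config, rng, responder=responder, threshold_cache=cache
        )
        for r in recs:
            if log.n_signal >= budget:
                break
            log.append(r)
            datasets[k] = datasets[k].add(r.stimulus.log2f, r.stimulus.L_m, r.response)
    if any(len(ds) == 0 for ds in datasets):
        raise ValueError(
            "signal budget too small: a notch condition received no warm-up "
            "trials; increase signal_trials_per_notch"
        )

    grids = [
        CandidateGrid.build(
            k, config.f_min, config.f_max, config.L_min,
            config.level_cap, config.level_step, config.freq_step_oct,
        )
        for k in range(len(config.notches))
    ]

    hypers = [config.hypers for _ in config.notches]
    posteriors: list[LatentPosterior | None] = [None] * len(config.notches)
    scores: list[np.ndarray | None] = [None] * len(config.notches)
    n_failures = 0

    def refit(k: int) -> None:
        nonlocal n_failures
        try:
            hypers[k] = optimize_constant_mean(datasets[k], hypers[k])
            posteriors[k] = infer_posterior(datasets[k], hypers[k])
            scores[k] = score_grid(posteriors[k], grids[k])
        except GPInferenceError:
            n_failures += 1
            logger.warning("GP inference failed for notch %d; keeping previous fit", k)
            if posteriors[k] is None:
                raise

    for k in range(len(config.notches)):
        refit(k)

    plan = schedule_trials(config, rng, n_initial_signal=log.n_signal)
    for slot in plan:
        stim = select_next_stimulus(list(zip(grids, scores)))
        if slot == "catch":
            stim = replace(stim, is_catch=True)
            yes = _respond(listener, stim, rng, config, cache, responder)
            log.append(TrialRecord(stim, yes, PHASE_CATCH))
            if config.feed_catch_to_gp:
                k = stim.notch_idx
                datasets[k] = datasets[k].add(stim.log2f, stim.L_m, yes)
                refit(k)
            continue
        yes = _respond(listener, stim, rng, config, cache, responder)
        log.append(TrialRecord(stim, yes, PHASE_BAL))
        k = stim.notch_idx
        datasets[k] = datasets[k].add(stim.log2f, stim.L_m, yes)
        refit(k)

    assert len(log) == config.total_trials, "trial-count conservation violated"
    return BALRunResult(
        config=config, log=log, posteriors=posteriors, hypers=hypers,
        n_inference_failures=n_failures,
    )


def extract_threshold_surface(
    posteriors: list, config: RunConfig
) -> pd.DataFrame:
    """50%-detection masker level per notch and 0.1-octave frequency node.

    Out-of-range nodes carry the boundary level plus a flag rather than a
    fabricated crossing.
    """
    o_min = float(hz_to_octaves(config.f_min))
    o_max = float(hz_to_octaves(config.f_max))
    n_f = int(round((o_max - o_min) / config.freq_step_oct)) + 1
    octs = o_min + config.freq_step_oct * np.arange(n_f)
    rows = []
    for k, post in enumerate(posteriors):
        for o in octs:
            f_hz = float(2.0**o * 1000.0)
            res = threshold_from_gp(post, f_hz, config.level_grid(f_hz))
            rows.append(
                {
                    "notch_id": k,
                    "f_hz": f_hz,
                    "log2f": float(o),
                    "threshold_db": res.level,
                    "flag": res.flag if res.flag else "",
                }
            )
    return pd.DataFrame(rows, columns=["notch_id", "f_hz", "log2f",
                                       "threshold_db", "flag"])


def rebuild_posteriors(log: TrialLog, config: RunConfig,
                       up_to_signal_trials: int | None = None):
    """Refit the per-notch GPs from a saved trial log.

    Catch trials are excluded (unless the config fed them to the GPs).
    ``up_to_signal_trials`` truncates the log to its first N signal trials,
    which supports convergence analyses.  Returns (posteriors, hypers).
    """
    datasets = [GPDataset.empty() for _ in config.notches]
    n_sig = 0
    for r in log.records:
        if r.stimulus.is_catch and not config.feed_catch_to_gp:
            continue
        n_sig += 1
        if up_to_signal_trials is not None and n_sig > up_to_signal_trials:
            break
        k = r.stimulus.notch_idx
        datasets[k] = datasets[k].add(r.stimulus.log2f, r.stimulus.L_m, r.response)
    posteriors, hypers = [], []
    for k, ds in enumerate(datasets):
        if len(ds) == 0:
            raise ValueError(f"no signal trials for notch {k} in the log")
        h = optimize_constant_mean(ds, config.hypers)
        posteriors.append(infer_posterior(ds, h))
        hypers.append(h)
    return posteriors, hypers
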