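"""Convergence, reliability and end-to-end study analyses.

Convergence is summarized by the fold ratio of the estimated auditory-filter
width (ERB) to a reference — either the run's own final estimate or a
simulated listener's ground truth.  Ratios below 1 are inverted before
averaging, and aggregation is geometric (mean and SD in log space) across
frequency nodes and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import listener_sim, roex_filter, staircase
from .bal_engine import (
    BALRunResult,
    RunConfig,
    TrialLog,
    extract_threshold_surface,
    rebuild_posteriors,
    run_bal,
)
from .types import DEFAULT_NOTCH_SET

__all__ = [
    "fold_ratio",
    "geometric_mean",
    "geometric_sd",
    "ConvergenceCurve",
    "convergence_curve",
    "test_retest_stats",
    "ground_truth_erb",
    "erb_recovery",
    "StudyReport",
    "simulate_study",
]


def fold_ratio(r):
    """max(r, 1/r): ratio folded to be >= 1."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    out = np.maximum(r, 1.0 / r)
    return out if out.ndim else float(out)


def geometric_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.mean(np.log(x))))


def geometric_sd(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.exp(np.std(np.log(x))))


@dataclass
class ConvergenceCurve:
    """Folded ERB-ratio statistics vs trials per notch condition."""

    table: pd.DataFrame  # trials_per_notch, geo_mean_fold, geo_sd_fold, n_nodes, n_excluded

    def final_fold(self) -> float:
        return float(self.table["geo_mean_fold"].iloc[-1])


def _erb_by_node(posteriors, config: RunConfig, L_s) -> pd.Series:
    surface = extract_threshold_surface(posteriors, config)
    fits = roex_filter.fit_threshold_surface(surface, L_s, notches=config.notches)
    return fits.set_index("f_hz")["erb_hz"]


def ground_truth_erb(profile, config: RunConfig) -> pd.Series:
    """Ground-truth ERB of a simulated listener at the run's frequency nodes."""
    from .types import hz_to_octaves

    o_min = float(hz_to_octaves(config.f_min))
    o_max = float(hz_to_octaves(config.f_max))
    n_f = int(round((o_max - o_min) / config.freq_step_oct)) + 1
    f_nodes = 1000.0 * 2.0 ** (o_min + config.freq_step_oct * np.arange(n_f))
    erbs = [
        (2.0 / profile.p_l(f) + 2.0 / profile.p_u(f)) * f for f in f_nodes
    ]
    return pd.Series(erbs, index=f_nodes, name="erb_hz")


def convergence_curve(
    logs,
    config: RunConfig,
    L_s,
    reference: pd.Series | str = "final",
    stride: int = 10,
) -> ConvergenceCurve:
    """Recompute the filter-width estimate at trial checkpoints.

    ``logs`` is one TrialLog or a list of them (aggregated jointly);
    ``reference`` is a per-frequency ERB series (ground-truth style) or
    ``"final"`` to use each run's own last estimate.  ``stride`` sets the
    checkpoint spacing in signal trials (the curve is identical at finer
    strides, just denser).  Early checkpoints where no frequency node is
    fittable are excluded, with the count reported.
    """
    if isinstance(logs, TrialLog):
        logs = [logs]
    n_notch = len(config.notches)
    per_run: list[tuple[list[int], list[pd.Series]]] = []
    for log in logs:
        n_signal = sum(1 for r in log.records if not r.stimulus.is_catch)
        checkpoints = list(range(stride * n_notch, n_signal, stride * n_notch))
        if not checkpoints or checkpoints[-1] != n_signal:
            checkpoints.append(n_signal)
        series = []
        for cp in checkpoints:
            try:
                posteriors, _ = rebuild_posteriors(log, config, up_to_signal_trials=cp)
                series.append(_erb_by_node(posteriors, config, L_s))
            except ValueError:
                series.append(pd.Series(dtype=float))
        per_run.append((checkpoints, series))

    rows = []
    n_checkpoints = max(len(cps) for cps, _ in per_run)
    for j in range(n_checkpoints):
        folds = []
        n_excluded = 0
        trials_per_notch = None
        for cps, series in per_run:
            if j >= len(cps):
                continue
            trials_per_notch = cps[j] / n_notch
            est = series[j]
            ref = series[-1] if isinstance(reference, str) else reference
            joined = pd.concat([est, ref], axis=1, join="inner", keys=["est", "ref"])
            joined = joined.dropna()
            if joined.empty:
                n_excluded += 1
                continue
            folds.append(fold_ratio(joined["est"] / joined["ref"]))
        if not folds:
            continue
        allf = np.concatenate([np.atleast_1d(f) for f in folds])
        rows.append(
            {
                "trials_per_notch": trials_per_notch,
                "geo_mean_fold": geometric_mean(allf),
                "geo_sd_fold": geometric_sd(allf),
                "n_nodes": len(allf),
                "n_excluded": n_excluded,
            }
        )
    return ConvergenceCurve(table=pd.DataFrame(rows))


def test_retest_stats(run1: pd.Series, run2: pd.Series) -> tuple[float, float]:
    """Signed mean and RMS of per-node threshold differences (run2 - run1).

    The two series must share an identical frequency index.
    """
    if len(run1) != len(run2) or not np.allclose(run1.index, run2.index):
        raise ValueError("frequency grids do not match")
    d = run2.to_numpy(dtype=float) - run1.to_numpy(dtype=float)
    return float(np.mean(d)), float(np.sqrt(np.mean(d**2)))


def erb_recovery(result: BALRunResult, profile) -> pd.DataFrame:
    """Per-node fold ratio of estimated vs ground-truth ERB for one run."""
    est = _erb_by_node(result.posteriors, result.config, profile.signal_level)
    ref = ground_truth_erb(profile, result.config)
    joined = pd.concat([est, ref], axis=1, join="inner", keys=["est", "ref"]).dropna()
    out = pd.DataFrame(
        {
            "f_hz": joined.index,
            "erb_est_hz": joined["est"].to_numpy(),
            "erb_true_hz": joined["ref"].to_numpy(),
        }
    )
    out["fold"] = fold_ratio(out["erb_est_hz"] / out["erb_true_hz"])
    return out.reset_index(drop=True)


@dataclass
class StudyReport:
    """Outputs of an end-to-end simulated study."""

    surfaces: pd.DataFrame  # per profile/seed threshold surfaces
    fits: pd.DataFrame  # per profile/seed roex fits by frequency node
    recovery: pd.DataFrame  # per profile/seed ERB fold ratios
    staircase_cmp: pd.DataFrame | None = None
    logs: dict = field(default_factory=dict)  # (profile, seed) -> TrialLog


def simulate_study(
    profiles: dict,
    config: RunConfig,
    seeds,
    include_staircase: bool = False,
    staircase_f_hz: float = 1400.0,
) -> StudyReport:
    """Run BAL end-to-end for each profile and seed; optionally compare with
    a two-run-averaged 2-up/1-down staircase at one centre frequency."""
    surfaces, fits, recovery, cmp_rows, logs = [], [], [], [], {}
    for name, profile in profiles.items():
        for seed in seeds:
            from dataclasses import replace as _rep

            cfg = _rep(config, seed=int(seed))
            result = run_bal(profile, cfg)
            logs[(name, int(seed))] = result.log
            surf = extract_threshold_surface(result.posteriors, cfg)
            surf.insert(0, "profile", name)
            surf.insert(1, "seed", int(seed))
            surfaces.append(surf)
            fit = roex_filter.fit_threshold_surface(
                surf, profile.signal_level, notches=cfg.notches
            )
            fit.insert(0, "profile", name)
            fit.insert(1, "seed", int(seed))
            fits.append(fit)
            rec = erb_recovery(result, profile)
            rec.insert(0, "profile", name)
            rec.insert(1, "seed", int(seed))
            recovery.append(rec)
            if include_staircase:
                rng = np.random.default_rng(int(seed) + 10_000)
                bal_surface = surf.set_index(["notch_id", "f_hz"])
                for k, nc in enumerate(cfg.notches):
                    if not nc.symmetric:
                        continue
                    thr = staircase.run_staircase_pair(
                        profile, nc, staircase_f_hz, rng, notch_idx=k
                    )
                    # nearest BAL node to the staircase frequency
                    node_f = surf[surf["notch_id"] == k]["f_hz"]
                    nearest = node_f.iloc[(node_f - staircase_f_hz).abs().argmin()]
                    bal_thr = bal_surface.loc[(k, nearest), "threshold_db"]
                    cmp_rows.append(
                        {
                            "profile": name,
                            "seed": int(seed),
                            "notch_id": k,
                            "notch": str(nc),
                            "staircase_db": thr,
                            "bal_db": float(bal_thr),
                            "diff_db": thr - float(bal_thr),
                        }
                    )
    return StudyReport(
        surfaces=pd.concat(surfaces, ignore_index=True),
        fits=pd.concat(fits, ignore_index=True),
        recovery=pd.concat(recovery, ignore_index=True),
        staircase_cmp=pd.DataFrame(cmp_rows) if cmp_rows else None,
        logs=logs,
    )
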