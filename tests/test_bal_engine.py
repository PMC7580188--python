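"""BAL run orchestration: warm-up rules, scheduling, trial accounting,
determinism and surface extraction."""

import numpy as np
import pandas as pd
import pytest

from balnotch.bal_engine import (
    RunConfig,
    TrialLog,
    extract_threshold_surface,
    run_bal,
    run_initial_grid,
    schedule_trials,
)
from balnotch.listener_sim import ground_truth_threshold, make_profile
from balnotch.types import NotchCondition, PHASE_INITIAL_GRID


@pytest.fixture(scope="module")
def profile():
    return make_profile("flat_loss")


@pytest.fixture(scope="module")
def single_notch_config():
    return RunConfig(
        notches=(NotchCondition(0.2, 0.2),), signal_trials_per_notch=60, seed=7
    )


class TestInitialGrid:
    def test_easy_listener_trace(self):
        """A listener with a very low threshold answers Yes at -20 dB SPL and
        keeps detecting until the level rule produces a No."""
        responses = []

        def responder(stim, rng):
            yes = stim.L_m < 35.0
            responses.append((stim.f_hz, stim.L_m, yes))
            return yes

        cfg = RunConfig(seed=0)
        recs = run_initial_grid(None, 0, cfg, np.random.default_rng(0),
                                responder=responder)
        # step (a): -20 (yes) -> 0 (yes) -> +20 (yes) -> +40 (no), both seen
        lead = [(r.stimulus.f_hz, r.stimulus.L_m, r.response) for r in recs[:4]]
        assert lead == [
            (1000.0, -20.0, True),
            (1000.0, 0.0, True),
            (1000.0, 20.0, True),
            (1000.0, 40.0, False),
        ]
        # step (b): 2 kHz at the mean of the last two 1-kHz levels
        assert recs[4].stimulus.f_hz == 2000.0
        assert recs[4].stimulus.L_m == 30.0
        # steps (c) and (d) visit the range edges
        freqs = {r.stimulus.f_hz for r in recs}
        assert {1000.0, 2000.0, 4000.0, 500.0} <= freqs
        assert all(r.phase == PHASE_INITIAL_GRID for r in recs)

    def test_never_listener_respects_floor(self):
        def responder(stim, rng):
            return False

        cfg = RunConfig(seed=0)
        recs = run_initial_grid(None, 0, cfg, np.random.default_rng(0),
                                responder=responder)
        levels = [r.stimulus.L_m for r in recs if r.stimulus.f_hz == 1000.0]
        assert min(levels) == -30.0
        assert all(lv >= -30.0 for r in recs for lv in [r.stimulus.L_m])

    def test_typical_length_about_ten_trials(self, profile):
        """The four warm-up steps need few trials for a regular listener."""
        counts = []
        for seed in range(100):
            cfg = RunConfig(seed=seed)
            recs = run_initial_grid(
                profile, 2, cfg, np.random.default_rng(seed)
            )
            counts.append(len(recs))
        assert np.median(counts) <= 14
        assert np.median(counts) >= 6


class TestScheduling:
    def test_default_study_counts(self):
        cfg = RunConfig()
        assert cfg.total_signal_trials == 540
        assert cfg.n_catch_trials == 54
        assert cfg.total_trials == 594

    def test_retest_counts(self, single_notch_config):
        assert single_notch_config.total_signal_trials == 60
        assert single_notch_config.n_catch_trials == 6
        assert single_notch_config.total_trials == 66

    def test_zero_catch_fraction(self):
        cfg = RunConfig(catch_fraction=0.0)
        plan = schedule_trials(cfg, np.random.default_rng(0), n_initial_signal=90)
        assert plan.count("catch") == 0
        assert plan.count("signal") == 450

    def test_plan_is_shuffled_but_exact(self):
        cfg = RunConfig()
        plan = schedule_trials(cfg, np.random.default_rng(3), n_initial_signal=100)
        assert plan.count("signal") == 440
        assert plan.count("catch") == 54
        # catch slots spread through the plan, not clustered at one end
        idx = [i for i, s in enumerate(plan) if s == "catch"]
        assert idx[0] < len(plan) / 3
        assert idx[-1] > 2 * len(plan) / 3

    def test_overspent_warmup_rejected(self):
        cfg = RunConfig(signal_trials_per_notch=1)
        with pytest.raises(ValueError):
            schedule_trials(cfg, np.random.default_rng(0), n_initial_signal=100)


@pytest.fixture(scope="module")
def result(profile, single_notch_config):
    return run_bal(profile, single_notch_config)


class TestRunBal:
    def test_trial_count_conservation(self, result, single_notch_config):
        assert len(result.log) == single_notch_config.total_trials == 66
        assert result.log.n_signal == 60
        assert result.log.n_catch == 6

    def test_phases_partition_the_log(self, result):
        df = result.log.to_frame()
        assert set(df["phase"]) <= {"initial_grid", "bal", "catch"}
        assert (df["phase"] == "catch").sum() == 6
        assert ((df["phase"] == "initial_grid") | (df["phase"] == "bal")).sum() == 60

    def test_levels_respect_bounds(self, result):
        df = result.log.to_frame()
        assert df["L_m_db"].min() >= -30.0
        from balnotch.acquisition import max_masker_level

        assert np.all(
            df["L_m_db"].to_numpy()
            <= max_masker_level(df["f_hz"].to_numpy()) + 1e-9
        )

    def test_seed_reproducibility_bytewise(self, profile, single_notch_config, result):
        again = run_bal(profile, single_notch_config)
        assert again.log.to_csv_bytes() == result.log.to_csv_bytes()

    def test_different_seed_differs(self, profile, single_notch_config):
        import dataclasses

        other = run_bal(
            profile, dataclasses.replace(single_notch_config, seed=8)
        )
        assert other.log.to_frame()["L_m_db"].tolist() != (
            run_bal(profile, single_notch_config).log.to_frame()["L_m_db"].tolist()
        )

    def test_log_csv_round_trip(self, result, tmp_path):
        p = tmp_path / "log.csv"
        result.log.to_csv(p)
        back = TrialLog.from_csv(p)
        assert back.to_csv_bytes() == result.log.to_csv_bytes()


class TestThresholdSurface:
    def test_grid_spacing_and_flags(self, profile, single_notch_config):
        result = run_bal(profile, single_notch_config)
        surf = extract_threshold_surface(result.posteriors, single_notch_config)
        octs = np.sort(surf["log2f"].unique())
        assert np.allclose(np.diff(octs), 0.1)
        assert len(surf) == 31  # 3 octaves at 0.1-octave steps, one notch
        assert {"notch_id", "f_hz", "threshold_db", "flag"} <= set(surf.columns)

    def test_surface_tracks_ground_truth(self, profile, single_notch_config):
        result = run_bal(profile, single_notch_config)
        surf = extract_threshold_surface(result.posteriors, single_notch_config)
        clean = surf[surf["flag"] == ""]
        errs = [
            row.threshold_db
            - ground_truth_threshold(
                profile, single_notch_config.notches[0], row.f_hz
            )
            for row in clean.itertuples()
        ]
        assert np.sqrt(np.mean(np.square(errs))) < 4.0

    def test_out_of_range_listener_flagged(self, single_notch_config):
        """A listener whose thresholds sit far above the level cap must yield
        flagged nodes, not fabricated crossings."""
        # flat loss with an extremely efficient detector: masked thresholds
        # sit above the overall-level cap at every frequency
        golden_ear = make_profile("flat_loss", K_db=-40.0)
        result = run_bal(golden_ear, single_notch_config)
        surf = extract_threshold_surface(result.posteriors, single_notch_config)
        assert (surf["flag"] != "").any()


class TestBudgetMonotonicity:
    def test_surface_error_shrinks_with_budget(self, profile):
        """Mean RMS error of the extracted surface vs ground truth does not
        grow when the trial budget per notch increases (20 seeds)."""
        budgets = (10, 30, 60)
        mean_rms = []
        nc = NotchCondition(0.2, 0.2)
        truth = {}
        for budget in budgets:
            rms = []
            for seed in range(20):
                cfg = RunConfig(
                    notches=(nc,), signal_trials_per_notch=budget, seed=100 + seed
                )
                res = run_bal(profile, cfg)
                surf = extract_threshold_surface(res.posteriors, cfg)
                errs = []
                for row in surf.itertuples():
                    if row.f_hz not in truth:
                        truth[row.f_hz] = ground_truth_threshold(profile, nc, row.f_hz)
                    errs.append(row.threshold_db - truth[row.f_hz])
                rms.append(float(np.sqrt(np.mean(np.square(errs)))))
            mean_rms.append(float(np.mean(rms)))
        assert mean_rms[1] <= mean_rms[0] + 0.25
        assert mean_rms[2] <= mean_rms[1] + 0.25
        assert mean_rms[2] < mean_rms[0]
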