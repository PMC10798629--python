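"""Generative model and schedule structure of the coin task."""

import numpy as np
import pandas as pd
import pytest

from cointransfer.task_protocol import (Condition, DesignError, TaskDesign,
                                        build_likelihood_only_schedule,
                                        build_schedule, exp1_combos,
                                        read_trial_table, sample_trial,
                                        write_trial_table)
from cointransfer.observers import CohortConfig, simulate_cohort


class TestTaskDesign:
    def test_printed_design_values(self, exp1_design, exp2_design):
        assert exp1_design.priors == {"Pn": 0.025, "Pw": 0.085}
        assert exp1_design.likelihoods == {"Ln": 0.06, "Lw": 0.15}
        assert exp2_design.likelihoods == {"Ln": 0.024, "Lm": 0.06, "Lw": 0.15}
        assert exp2_design.priors == {"Pw": 0.085}
        # catch window is net width plus coin diameter
        assert exp1_design.hit_window == pytest.approx(0.03)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(DesignError):
            TaskDesign(priors={"P": 0.0}, likelihoods={"L": 0.1})

    def test_novelty_only_in_transfer(self):
        with pytest.raises(DesignError):
            Condition("Pw", "Ln", "learning", novelty="new")


class TestSampleTrial:
    def test_degenerate_likelihood_puts_all_dots_on_coin(self, rng):
        trial = sample_trial((0.0, 0.085), 0.0, rng)
        assert all(d == trial.coin_x for d in trial.dot_xs)
        assert trial.mu_l == trial.coin_x

    def test_generative_variances_match_design(self, rng):
        """Coin positions vary as sigma_P^2 and centroid error as sigma_L^2/5."""
        n = 100_000
        coin = np.empty(n)
        err = np.empty(n)
        for i in range(n):
            t = sample_trial((0.0, 0.085), 0.15, rng)
            coin[i] = t.coin_x
            err[i] = t.mu_l - t.coin_x
        assert np.var(coin) == pytest.approx(0.085 ** 2, rel=0.05)
        assert np.var(err) == pytest.approx(0.15 ** 2 / 5, rel=0.05)

    def test_deterministic_under_fixed_seed(self):
        t1 = sample_trial((0.0, 0.025), 0.06, np.random.default_rng(7))
        t2 = sample_trial((0.0, 0.025), 0.06, np.random.default_rng(7))
        assert t1 == t2

    def test_nonpositive_prior_sigma_rejected(self, rng):
        with pytest.raises(DesignError):
            sample_trial((0.0, 0.0), 0.06, rng)


def _max_run(labels):
    longest = run = 1
    for a, b in zip(labels, labels[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


class TestSchedules:
    @pytest.mark.parametrize("group", ["serial", "parallel"])
    @pytest.mark.parametrize("cb", [0, 1, 2, 3])
    def test_exp1_counts(self, group, cb, rng):
        sched = build_schedule("exp1", group, cb, rng)
        counts = sched.counts()
        learning = {k: v for k, v in counts.items() if k[0] == "learning"}
        transfer = {k: v for k, v in counts.items() if k[0] == "transfer"}
        assert sorted(learning.values()) == [200, 200]
        assert sorted(transfer.values()) == [90, 90]
        # transfer uses a single prior with both likelihoods, one combo novel
        transfer_priors = {k[1][:2] for k in transfer}
        assert len(transfer_priors) == 1
        assert sorted(k[2] for k in transfer) == ["new", "old"]

    def test_exp1_serial_blocks_and_parallel_interleaving(self, rng):
        serial = build_schedule("exp1", "serial", 0, rng)
        first200 = {t.condition.combo for t in serial.trials[:200]}
        assert len(first200) == 1
        parallel = build_schedule("exp1", "parallel", 0, rng)
        learn = [t.condition.combo for t in parallel.trials[:400]]
        assert _max_run(learn) <= 6

    def test_exp1_new_combo_shares_transfer_prior(self, rng):
        _, transfer_prior, new_pair, old_pair = exp1_combos(2)
        assert new_pair[0] == old_pair[0] == transfer_prior
        sched = build_schedule("exp1", "serial", 2, rng)
        trained = {t.condition.combo for t in sched.trials[:400]}
        new = {t.condition.combo for t in sched.trials[400:]
               if t.condition.novelty == "new"}
        assert new.isdisjoint(trained)

    @pytest.mark.parametrize("group,new_lik", [("interpolation", "Lm"),
                                               ("extrapolation", "Lw")])
    def test_exp2_groups(self, group, new_lik, rng):
        sched = build_schedule("exp2", group, 0, rng)
        counts = sched.counts()
        learning_liks = {k[1][2:] for k in counts if k[0] == "learning"}
        assert new_lik not in learning_liks
        assert len(learning_liks) == 2
        transfer = {k[1]: v for k, v in counts.items() if k[0] == "transfer"}
        assert transfer == {"PwLn": 75, "PwLm": 75, "PwLw": 75}
        new = [k for k in counts if k[0] == "transfer" and k[2] == "new"]
        assert new == [("transfer", f"Pw{new_lik}", "new")]
        liks = [t.condition.likelihood_label for t in sched.trials]
        assert _max_run(liks[:200]) <= 6 and _max_run(liks[200:]) <= 6

    def test_invalid_combinations_rejected(self, rng):
        with pytest.raises(DesignError):
            build_schedule("exp1", "interpolation", 0, rng)
        with pytest.raises(DesignError):
            build_schedule("exp2", "serial", 0, rng)
        with pytest.raises(DesignError):
            build_schedule("exp3", "serial", 0, rng)

    @pytest.mark.parametrize("experiment,total,per_lik", [
        ("exp1", 80, {"Ln": 40, "Lw": 40}),
        ("exp2", 90, {"Ln": 30, "Lm": 30, "Lw": 30}),
    ])
    def test_likelihood_only_counts(self, experiment, total, per_lik, rng):
        sched = build_likelihood_only_schedule(experiment, rng)
        assert len(sched.trials) == total
        seen = {}
        for t in sched.trials:
            seen[t.condition.likelihood_label] = \
                seen.get(t.condition.likelihood_label, 0) + 1
        assert seen == per_lik
        assert sum(seen.values()) == total


class TestTrialTableIO:
    def test_round_trip(self, tmp_path):
        cfg = CohortConfig(n_participants=2, strategy="bayes", bias_l=1.0,
                           motor_sd=0.0, seed=5)
        trials, _ = simulate_cohort(cfg)
        path = tmp_path / "trials.csv"
        write_trial_table(trials, path)
        back = read_trial_table(path)
        assert list(back.columns) == list(trials.columns)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), trials.reset_index(drop=True),
            check_dtype=False)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"participant_id": ["a"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_trial_table(path)
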