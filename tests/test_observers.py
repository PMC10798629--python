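"""Observer strategies: responses, exemplar sampling, cohort generation."""

import numpy as np
import pytest

from cointransfer.estimation import estimate_cohort, fit_slope, optimal_slope
from cointransfer.observers import (CohortConfig, ObserverError, ObserverSpec,
                                    exemplar_estimate, respond_coin,
                                    respond_likelihood_only, simulate_cohort,
                                    simulate_participant)
from cointransfer.task_protocol import (Condition, Trial,
                                        build_likelihood_only_schedule,
                                        build_schedule)


def _lik_trial(dots):
    cond = Condition(None, "Ln", "learning")
    return Trial(0, cond, 0.0, tuple(dots), task="likelihood_only")


def _coin_trial(dots, prior="Pw", lik="Ln", coin=0.0):
    return Trial(0, Condition(prior, lik, "learning", "old"), coin,
                 tuple(dots), task="coin")


class TestLikelihoodOnlyResponses:
    def test_symmetric_cloud_centroid(self, rng):
        obs = ObserverSpec("bayes", motor_sd=0.0)
        t = _lik_trial((-0.02, -0.01, 0.0, 0.01, 0.02))
        assert respond_likelihood_only(obs, t, rng) == 0.0

    def test_asymmetric_cloud_centroid(self, rng):
        obs = ObserverSpec("bayes", motor_sd=0.0)
        t = _lik_trial((0.1, 0.1, 0.1, 0.1, 0.2))
        assert respond_likelihood_only(obs, t, rng) == pytest.approx(0.12)

    def test_motor_noise_variance(self, rng):
        obs = ObserverSpec("bayes", motor_sd=0.02)
        t = _lik_trial((0.0, 0.01, -0.01, 0.02, -0.02))
        resp = np.array([respond_likelihood_only(obs, t, rng)
                         for _ in range(10_000)])
        assert np.var(resp) == pytest.approx(4e-4, rel=0.1)


class TestCoinResponses:
    def test_ideal_bayes_weight_on_narrow_likelihood(self, exp1_design, rng):
        """Noiseless ideal weighting reproduces the analytic slope exactly."""
        obs = ObserverSpec.ideal(exp1_design)
        mu_ls, resps = [], []
        for _ in range(50):
            dots = tuple(rng.normal(0.05, 0.06, 5))
            t = _coin_trial(dots, "Pw", "Ln")
            mu_ls.append(t.mu_l)
            resps.append(respond_coin(obs, t, rng))
        fit = fit_slope(mu_ls, resps)
        w = optimal_slope(0.085, 0.06, 5)
        assert fit.slope == pytest.approx(w, abs=1e-10)
        assert w == pytest.approx(0.90937, abs=1e-5)

    def test_likelihood_only_and_prior_only_extremes(self, rng):
        t = _coin_trial((0.1, 0.12, 0.08, 0.11, 0.09))
        lik = ObserverSpec("likelihood_only")
        pri = ObserverSpec("prior_only")
        assert respond_coin(lik, t, rng) == pytest.approx(t.mu_l)
        assert respond_coin(pri, t, rng) == 0.0

    def test_linear_map_clipping(self, rng):
        obs = ObserverSpec("linear_map", internal_sigma_p={"Pw": 0.085},
                           internal_sigma_l={"Ln": 0.06},
                           linear_coeffs=(5.0, 0.0, 0.0))
        t = _coin_trial((0.1, 0.1, 0.1, 0.1, 0.1))
        assert respond_coin(obs, t, rng) == pytest.approx(0.1)  # w clipped to 1

    def test_rote_without_training_errors(self, rng):
        obs = ObserverSpec("rote", internal_sigma_p={"Pw": 0.085},
                           internal_sigma_l={"Ln": 0.06})
        t = _coin_trial((0.1,) * 5)
        with pytest.raises(ObserverError, match="never trained"):
            respond_coin(obs, t, rng, rote_weights={})


class TestExemplarEstimate:
    def test_singleton_memory_ignores_evidence(self, rng):
        assert exemplar_estimate([0.03], 0.2, 0.06, 50, rng) == \
            pytest.approx(0.03)

    def test_converges_to_posterior_mean(self, rng):
        """Self-normalized resampling of prior draws approaches the analytic
        posterior mean as N grows."""
        sigma_p, sigma_w, mu_l = 0.085, 0.06, 0.05
        memory = rng.normal(0.0, sigma_p, 100_000)
        est = exemplar_estimate(memory, mu_l, sigma_w, 100_000, rng)
        expected = sigma_p ** 2 / (sigma_p ** 2 + sigma_w ** 2) * mu_l
        assert est == pytest.approx(expected, abs=0.01 * sigma_p)

    def test_sampling_variability_shrinks_with_n(self, rng):
        memory = rng.normal(0.0, 0.085, 2_000)
        small = [exemplar_estimate(memory, 0.05, 0.06, 5, rng)
                 for _ in range(200)]
        large = [exemplar_estimate(memory, 0.05, 0.06, 500, rng)
                 for _ in range(200)]
        assert len(set(small)) > 1
        assert np.var(large) < np.var(small)

    def test_underflow_falls_back_to_sample_mean(self, rng):
        # memory impossibly far from the evidence: all weights underflow
        memory = np.full(10, 100.0)
        est = exemplar_estimate(memory, -100.0, 1e-3, 10, rng)
        assert est == pytest.approx(100.0)

    def test_empty_memory_errors(self, rng):
        with pytest.raises(ObserverError, match="empty"):
            exemplar_estimate([], 0.0, 0.06, 5, rng)


class TestSimulateParticipant:
    def test_row_counts_and_hit_window(self, exp1_design, rng):
        obs = ObserverSpec.ideal(exp1_design)
        lik = build_likelihood_only_schedule("exp1", rng)
        coin = build_schedule("exp1", "serial", 0, rng)
        df = simulate_participant(obs, lik, coin, rng)
        assert len(df) == 80 + 400 + 180
        assert (df["phase"] == "likelihood_only").sum() == 80
        coin_rows = df[df["phase"] != "likelihood_only"]
        err = (coin_rows["response_x"] - coin_rows["coin_x"]).abs()
        # hit iff within half the catch window (L/2 = 0.015)
        assert (coin_rows["hit"] == (err <= 0.015)).all()

    def test_hit_boundary(self):
        assert abs(0.0151) > 0.03 / 2
        assert abs(0.0150) <= 0.03 / 2

    def test_rote_transfer_slope_change_is_zero(self, exp1_design, rng):
        """A rote observer re-uses the trained weight for the novel
        likelihood, so its slope does not change between phases."""
        obs = ObserverSpec.ideal(exp1_design, strategy="rote", motor_sd=0.0)
        lik = build_likelihood_only_schedule("exp1", rng)
        coin = build_schedule("exp1", "serial", 0, rng)
        df = simulate_participant(obs, lik, coin, rng)
        est = estimate_cohort(df)[0]
        old_combo = [c for c in est.learning_slopes
                     if c[:2] == est.new_combo[:2]][0]
        assert est.transfer_slopes[est.new_combo].slope == pytest.approx(
            est.learning_slopes[old_combo].slope, abs=1e-9)


class TestSimulateCohort:
    def test_ideal_config_gives_ideal_observers(self, rng):
        cfg = CohortConfig(n_participants=3, strategy="bayes", bias_p=1.0,
                           bias_l=1.0, tau_p=0.0, tau_l=0.0, motor_sd=0.0,
                           seed=9)
        trials, truth = simulate_cohort(cfg)
        assert set(truth["sigma_L_Ln"]) == {0.06}
        assert set(truth["sigma_P_Pw"]) == {0.085}
        # noiseless ideal observers never miss badly: responses are exact
        # posterior means, so slopes equal the optimal weights
        est = estimate_cohort(trials)[0]
        for combo, fit in est.learning_slopes.items():
            w = optimal_slope({"Pn": 0.025, "Pw": 0.085}[combo[:2]],
                              {"Ln": 0.06, "Lw": 0.15}[combo[2:]], 5)
            assert fit.slope == pytest.approx(w, abs=1e-9)

    def test_master_seed_reproducibility(self, tmp_path):
        cfg = CohortConfig(n_participants=3, strategy="exemplar", seed=17)
        a, _ = simulate_cohort(cfg)
        b, _ = simulate_cohort(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_shrunken_internal_likelihood_inflates_slopes(self):
        """Internally underestimated likelihood dispersion produces
        over-reliance on the evidence (slopes above optimal)."""
        cfg = CohortConfig(n_participants=4, strategy="bayes", bias_l=0.7,
                           motor_sd=0.0, seed=13)
        trials, _ = simulate_cohort(cfg)
        for est in estimate_cohort(trials):
            for combo, fit in est.learning_slopes.items():
                w = optimal_slope({"Pn": 0.025, "Pw": 0.085}[combo[:2]],
                                  {"Ln": 0.06, "Lw": 0.15}[combo[2:]], 5)
                assert fit.slope > w

    def test_strategy_mix_assignment(self):
        cfg = CohortConfig(n_participants=10,
                           strategy={"bayes": 0.5, "rote": 0.5}, seed=1)
        _, truth = simulate_cohort(cfg)
        assert set(truth["strategy"]) == {"bayes", "rote"}
        assert (truth["strategy"] == "bayes").sum() == 5
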