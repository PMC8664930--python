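"""Strategy GLMs, stepwise decomposition, exponential fits, differential response."""

import numpy as np
import pytest

from conjlearn import behavior, rl, strategies, task
from conjlearn.behavior import (
    differential_response,
    fit_exponential_timecourse,
    fit_strategy_glms,
    stepwise_strategy_glm,
    strategy_regressors,
)


class TestStrategyGLMs:
    def test_perfect_fc_estimates_give_unit_r2(self, schedule):
        est = strategies.predict_all(schedule, "mixed_fc").predicted
        r2 = fit_strategy_glms(est, schedule)
        assert r2["mixed_fc"] == pytest.approx(1.0, abs=1e-9)

    def test_noise_estimates_give_null_r2(self, schedule):
        """Pure-noise estimates stay inside a permutation null band."""
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(50):
            r2s.append(fit_strategy_glms(rng.random(27), schedule)["mixed_fc"])
        # with 27 points and 1 regressor, E[R2] = 1/26 under the null
        assert np.mean(r2s) < 0.12
        assert np.median(r2s) < 0.08

    def test_agent_latents_ranked_correctly(self, fc1_session, schedule):
        """Late-session latent values of an F+C1 agent: the F+C GLM explains
        more variance than the feature GLM, which beats chance."""
        est = fc1_session.bouts[-1].estimates
        r2 = fit_strategy_glms(est, schedule)
        assert r2["mixed_fc"] > r2["feature"]
        assert r2["feature"] > 0.1

    def test_constant_estimates_flagged(self, schedule):
        out = fit_strategy_glms(np.full(27, 0.4), schedule)
        assert out["degenerate"]


class TestStepwise:
    def test_single_perfect_predictor_selected_alone(self, schedule):
        regs = strategy_regressors(schedule)
        sw = stepwise_strategy_glm(regs["feature"], schedule)
        assert sw.included["feature"]
        assert sw.weights["feature"] == pytest.approx(1.0)
        assert not sw.included["object"]

    def test_fc_mixture_excludes_object(self, schedule):
        regs = strategy_regressors(schedule)
        est = 0.5 * regs["feature"] + 0.5 * regs["conjunction"]
        sw = stepwise_strategy_glm(est, schedule)
        assert sw.included["feature"] and sw.included["conjunction"]
        assert not sw.included["object"]
        assert sw.delta_r2_object == pytest.approx(0.0, abs=1e-9)

    def test_fc1_agent_weight_ordering(self, fc1_session, schedule):
        """Late-session F+C1 agent estimates: feature weight dominates,
        conjunction contributes, object adds little."""
        sw = stepwise_strategy_glm(fc1_session.bouts[-1].estimates, schedule)
        assert sw.weights["feature"] > sw.weights["conjunction"]
        assert sw.weights["feature"] > sw.weights["object"]

    def test_weights_normalized(self, fc1_session, schedule):
        sw = stepwise_strategy_glm(fc1_session.bouts[-1].estimates, schedule)
        total = sum(sw.weights.values())
        assert total == pytest.approx(1.0) or total == 0.0


class TestExponentialTimecourse:
    def test_noiseless_recovery(self):
        t = np.arange(1, 433, 8)
        y = 0.8 - (0.8 - 0.1) * np.exp(-t / 70.0)
        fit = fit_exponential_timecourse(t, y)
        assert fit.tau == pytest.approx(70.0, abs=1.0)
        assert fit.y_ss == pytest.approx(0.8, abs=0.01)

    def test_constant_curve_flagged(self):
        fit = fit_exponential_timecourse(np.arange(10), np.full(10, 0.3))
        assert fit.degenerate
        assert np.isnan(fit.tau)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_exponential_timecourse(np.arange(3), np.arange(3.0))

    def test_fast_slow_ordering_preserved_under_noise(self):
        """tau = 70 vs tau = 985 trajectories keep their order in every
        noisy replicate (sigma = 0.05)."""
        rng = np.random.default_rng(1)
        t = np.arange(1, 433, 4)
        y_fast = 0.7 - (0.7 - 0.0) * np.exp(-t / 70.0)
        y_slow = 0.7 - (0.7 - 0.0) * np.exp(-t / 985.0)
        wins = 0
        n = 50
        for _ in range(n):
            f = fit_exponential_timecourse(t, y_fast + rng.normal(0, 0.05, len(t)))
            s = fit_exponential_timecourse(t, y_slow + rng.normal(0, 0.05, len(t)))
            wins += f.tau < s.tau
        assert wins == n

    def test_residual_shrinks_with_longer_noiseless_data(self):
        t_short = np.arange(1, 200, 8)
        t_long = np.arange(1, 433, 8)
        y = lambda t: 0.8 - 0.7 * np.exp(-t / 150.0)
        r_short = fit_exponential_timecourse(t_short, y(t_short)).residual
        r_long = fit_exponential_timecourse(t_long, y(t_long)).residual
        assert r_long < r_short + 1e-9


def test_group_statistics_utilities():
    """Sign-rank p and effect size behave on a shifted sample (oracle:
    scipy's one-sample test on the same values)."""
    rng = np.random.default_rng(0)
    shifted = rng.normal(0.3, 1.0, 40)
    _, p = behavior.signrank(shifted)
    assert p < 0.2
    assert behavior.cohens_d(shifted) == pytest.approx(
        shifted.mean() / shifted.std(ddof=1)
    )
    centered = rng.normal(0.0, 1.0, 40)
    _, p0 = behavior.signrank(centered)
    assert p0 > 0.01


class TestDifferentialResponse:
    def test_random_agent_near_zero(self, schedule):
        """Reward-insensitive agents show no differential response."""
        vals = []
        for seed in range(50):
            sess = task.generate_session(schedule, seed=seed)
            rng = np.random.default_rng(seed)
            sess.chosen_side = rng.integers(0, 2, sess.n_trials)
            dr = differential_response(sess, schedule)
            if np.isfinite(dr.informative_feature):
                vals.append(dr.informative_feature)
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean) < 2 * se + 0.02

    def test_fc1_agents_show_informative_pattern(self, schedule):
        """F+C1 agents: positive informative feature and conjunction
        differential response; non-informative features near zero."""
        spec = rl.RLModelSpec("fc1", "chosen", True)
        params = rl.RLParams(alpha_rew=0.35, alpha_unr=0.2, d=0.02,
                             w_f=6.0, w_c=6.0)
        feats, confs, nif = [], [], []
        for seed in range(25):
            sess = rl.simulate_agent(schedule, spec, params, seed=100 + seed)
            dr = differential_response(sess, schedule)
            feats.append(dr.informative_feature)
            confs.append(dr.informative_conjunction)
            nif.append(dr.noninformative_features)
        assert np.nanmean(feats) > 0.05
        assert np.nanmean(confs) > 0.05
        assert abs(np.nanmean(nif)) < 0.5 * np.nanmean(feats)

    def test_conjunction_response_discriminates_strategies(self, schedule):
        """The informative-conjunction differential response separates F+C1
        from feature-only learners: only learners who track the conjunction
        re-select its carriers (which share no feature with the previous
        choice) more after reward."""
        fc_spec = rl.RLModelSpec("fc1", "chosen", True)
        fc_params = rl.RLParams(alpha_rew=0.35, alpha_unr=0.2, d=0.02,
                                w_f=6.0, w_c=6.0)
        f_spec = rl.RLModelSpec("feature", "chosen", True)
        f_params = rl.RLParams(alpha_rew=0.35, alpha_unr=0.2, d=0.02,
                               w_f=np.array([7.0, 1.5, 1.5]))
        fc_conj, f_conj = [], []
        for seed in range(25):
            s1 = rl.simulate_agent(schedule, fc_spec, fc_params, seed=300 + seed)
            s2 = rl.simulate_agent(schedule, f_spec, f_params, seed=300 + seed)
            fc_conj.append(differential_response(s1, schedule).informative_conjunction)
            f_conj.append(differential_response(s2, schedule).informative_conjunction)
        assert np.nanmean(fc_conj) > np.nanmean(f_conj) + 0.05

    def test_feature_agents_show_feature_only_pattern(self, schedule):
        """Feature-only learners: positive informative-feature differential
        response, no informative-conjunction response."""
        spec = rl.RLModelSpec("feature", "chosen", True)
        params = rl.RLParams(alpha_rew=0.35, alpha_unr=0.2, d=0.02,
                             w_f=np.array([7.0, 1.5, 1.5]))
        feats, confs = [], []
        for seed in range(25):
            sess = rl.simulate_agent(schedule, spec, params, seed=200 + seed)
            dr = differential_response(sess, schedule)
            feats.append(dr.informative_feature)
            confs.append(dr.informative_conjunction)
        assert np.nanmean(feats) > 0.05
        assert abs(np.nanmean(confs)) < 0.5 * np.nanmean(feats)

    def test_invariant_to_instance_relabeling(self, schedule):
        """Relabeling feature instances globally leaves the statistic
        unchanged (it only depends on share/not-share relations)."""
        sess = task.generate_session(schedule, seed=3)
        rng = np.random.default_rng(3)
        sess.chosen_side = rng.integers(0, 2, sess.n_trials)
        dr1 = differential_response(sess, schedule)

        # relabel instance 0 <-> 1 on dimension 2 (color)
        space = schedule.space
        def relabel(oid):
            i, j, k = space.instances(oid)
            k = {0: 1, 1: 0, 2: 2}[k]
            return space.object_id((i, j, k))

        sess2 = task.generate_session(schedule, seed=3)
        sess2.chosen_side = sess.chosen_side.copy()
        sess2.left = np.array([relabel(o) for o in sess.left])
        sess2.right = np.array([relabel(o) for o in sess.right])
        dr2 = differential_response(sess2, schedule)
        assert dr1.informative_feature == pytest.approx(
            dr2.informative_feature, nan_ok=True
        )
        assert dr1.informative_conjunction == pytest.approx(
            dr2.informative_conjunction, nan_ok=True
        )

    def test_two_trials_minimum(self, schedule):
        sess = task.generate_session(schedule, seed=0, n_trials=1)
        sess.chosen_side[:] = 0
        with pytest.raises(ValueError):
            differential_response(sess, schedule)
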