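"""E/I network dynamics, plasticity, and structural invariants."""

import numpy as np
import pytest

from conjlearn import rnn
from conjlearn.rnn import (
    EIRNN,
    RNNConfig,
    TrainingConfig,
    build_variant,
    choice_layer,
    encode_stimulus,
    lesion,
)


@pytest.fixture(scope="module")
def small_net():
    return EIRNN(RNNConfig(n_rec=40), seed=0)


class TestEncoding:
    def test_seven_active_populations(self):
        for oid in range(27):
            s = encode_stimulus(oid)
            assert s.sum() == 7
            assert set(np.unique(s)) == {0.0, 1.0}

    def test_shared_feature_overlap(self, space):
        """Stimuli sharing one feature overlap in that feature's entry plus
        any shared conjunction (enumerated)."""
        a = space.object_id((0, 0, 0))
        b = space.object_id((0, 1, 1))  # shares shape only
        overlap = np.nonzero(encode_stimulus(a) * encode_stimulus(b))[0]
        assert list(overlap) == [0]  # shape instance 0, no shared conjunction
        c = space.object_id((0, 0, 1))  # shares shape+pattern -> 1 conjunction
        overlap = np.nonzero(encode_stimulus(a) * encode_stimulus(c))[0]
        assert 0 in overlap and 3 in overlap  # shape0, pattern0
        assert len(overlap) == 3  # plus the shape-pattern conjunction


class TestArchitecture:
    def test_ei_ratio_and_balanced_typing(self, small_net):
        assert small_net.is_exc.sum() == 32
        for block in ("Exc", "Inh"):
            sizes = {
                gt: len(small_net.group_indices(f"{block}_{gt}"))
                for gt in ("rr", "fr", "rf", "ff")
            }
            assert len(set(sizes.values())) == 1

    def test_half_of_sensory_connections_plastic(self, small_net):
        assert small_net.plastic_in.sum() == small_net.plastic_in.size / 2

    def test_dale_sign_structure(self, small_net):
        W = small_net._effective_rec()
        for j in range(small_net.config.n_rec):
            col = W[:, j]
            if small_net.is_exc[j]:
                assert np.all(col >= 0)
            else:
                assert np.all(col <= 0)


class TestDynamics:
    def test_zero_drive_geometric_decay(self):
        """With zero weights/bias/noise, x decays by (1 - alpha) per step."""
        net = EIRNN(RNNConfig(n_rec=40), seed=1)
        net.W_in0[:] = 0; net.W_rec0[:] = 0; net.b_rec[:] = 0
        net.x0[:] = 1.0
        net.reset_session()
        trial = net.run_trial(0, np.random.default_rng(0), noise=False,
                              cache=True)
        a = net.config.alpha
        expected = (1 - a) ** np.arange(net.config.n_steps + 1)
        np.testing.assert_allclose(trial["xs"][:, 0], expected, atol=1e-12)

    def test_alpha_one_instantaneous_drive(self):
        cfg = RNNConfig(n_rec=40, dt=0.1, tau=0.1)  # alpha = 1
        net = EIRNN(cfg, seed=1)
        net.W_rec0[:] = 0
        net.reset_session()
        trial = net.run_trial(0, np.random.default_rng(0), noise=False,
                              cache=True)
        t_stim = cfg.window_steps(cfg.stim_window)[0]
        u = net._stim_vectors[0]
        expected = net.W_in_cur @ u + net.b_rec
        np.testing.assert_allclose(trial["xs"][t_stim], expected, atol=1e-12)

    def test_noise_trajectory_reproducible(self, small_net):
        a = small_net.run_trial(3, np.random.default_rng(42))
        b = small_net.run_trial(3, np.random.default_rng(42))
        np.testing.assert_array_equal(a["z"], b["z"])

    def test_deterministic_bounded_long_run(self):
        """With noise off and fixed weights, dynamics stay bounded over
        10^4 steps of repeated trials."""
        net = EIRNN(RNNConfig(n_rec=40), seed=2)
        rng = np.random.default_rng(0)
        for _ in range(100):  # 100 trials x 100 steps = 10^4 Euler steps
            trial = net.run_trial(int(rng.integers(27)), rng, noise=False)
            assert np.all(np.isfinite(trial["z"]))
            assert np.abs(trial["z"]).max() < 1e3


class TestPlasticity:
    def test_no_rates_no_change(self, schedule):
        net = EIRNN(RNNConfig(n_rec=40), seed=3)
        trial = {
            "Su": np.zeros(63), "Sr": np.zeros(40),
            "Sur": np.zeros((40, 63)), "Srr": np.zeros((40, 40)),
        }
        before_in = net.W_in_cur.copy()
        before_rec = net.W_rec_cur.copy()
        net.hebbian_update(trial, reward=0)
        np.testing.assert_array_equal(net.W_in_cur, before_in)
        np.testing.assert_array_equal(net.W_rec_cur, before_rec)

    def test_reward_sign_symmetry(self):
        """With only a correlation term, reward increases and omission
        decreases the same plastic weight symmetrically."""
        net = EIRNN(RNNConfig(n_rec=40), seed=3)
        net.c_in[:] = 0; net.c_in[:, 2] = 0.2
        net.c_rec[:] = 0
        trial = net.run_trial(5, np.random.default_rng(1))
        base = net.W_in_cur.copy()
        net.hebbian_update(trial, reward=1)
        up = net.W_in_cur - base
        net.W_in_cur = base.copy()
        net.hebbian_update(trial, reward=0)
        down = net.W_in_cur - base
        plastic = net.plastic_in & (base + down > 0)  # away from the clip
        np.testing.assert_allclose(up[plastic], -down[plastic], atol=1e-12)
        assert up[plastic].max() > 0

    def test_masked_weights_frozen(self):
        net = EIRNN(RNNConfig(n_rec=40), seed=4)
        rng = np.random.default_rng(0)
        frozen_in = ~net.plastic_in
        before = net.W_in_cur[frozen_in].copy()
        for _ in range(20):
            trial = net.run_trial(int(rng.integers(27)), rng)
            net.hebbian_update(trial, int(rng.integers(2)))
        np.testing.assert_array_equal(net.W_in_cur[frozen_in], before)

    def test_repeated_reward_bounded(self, schedule):
        """Repeated rewarded trials on one stimulus: plastic input weights
        change but stay finite and non-negative over a session."""
        net = EIRNN(RNNConfig(n_rec=40), seed=5)
        rng = np.random.default_rng(0)
        for _ in range(200):
            trial = net.run_trial(7, rng)
            net.hebbian_update(trial, reward=1)
        assert np.all(np.isfinite(net.W_in_cur))
        assert np.all(net.W_in_cur >= 0)
        assert np.all(net.W_rec_cur >= 0)

    def test_dale_holds_after_plasticity_fuzz(self):
        """Sign constraints hold after arbitrary reward sequences."""
        net = EIRNN(RNNConfig(n_rec=40), seed=6)
        net.c_in[:] = np.array([[0.3, 0.1, 0.4], [-0.3, -0.1, -0.4]])
        net.c_rec[:] = 0.05
        rng = np.random.default_rng(1)
        for _ in range(50):
            trial = net.run_trial(int(rng.integers(27)), rng)
            net.hebbian_update(trial, int(rng.integers(2)))
            assert np.all(net.W_in_cur >= 0)
            assert np.all(net.W_rec_cur >= 0)
            assert np.all(net.w_out >= 0)

    def test_zero_coefficients_abolish_learning(self, schedule):
        """Plasticity frozen at zero: estimates are flat across a session."""
        net = EIRNN(RNNConfig(n_rec=40), seed=7)
        net.c_in[:] = 0
        net.c_rec[:] = 0
        rng = np.random.default_rng(0)
        before = rnn.frozen_estimates(net, np.random.default_rng(9))
        for _ in range(100):
            trial = net.run_trial(int(rng.integers(27)), rng)
            net.hebbian_update(trial, int(rng.integers(2)))
        after = rnn.frozen_estimates(net, np.random.default_rng(9))
        np.testing.assert_allclose(before, after, atol=1e-9)


class TestLesionAndVariants:
    def test_lesioned_block_stays_zero(self, schedule):
        net = EIRNN(RNNConfig(n_rec=40), seed=8)
        cut = lesion(net, "Inh_f*", "Exc_f*")
        src = cut.group_indices("Inh_f*")
        tgt = cut.group_indices("Exc_f*")
        rng = np.random.default_rng(0)
        for _ in range(50):
            trial = cut.run_trial(int(rng.integers(27)), rng)
            cut.hebbian_update(trial, int(rng.integers(2)))
        assert np.all(cut.W_rec_cur[np.ix_(tgt, src)] == 0)
        # original untouched
        assert not np.all(net.W_rec0[np.ix_(tgt, src)] == 0)

    def test_unknown_group_raises(self, small_net):
        with pytest.raises(ValueError):
            lesion(small_net, "Mid_xx", "Exc_fr")

    def test_variant_configs(self):
        assert not build_variant("no_plastic_input", n_rec=40).plastic_input
        assert not build_variant("no_plastic_recurrent", n_rec=40).plastic_recurrent
        ff = build_variant("ffnn", n_rec=40)
        assert ff.feedforward and ff.exc_frac == 1.0
        net = EIRNN(ff, seed=0)
        assert np.all(net.W_rec0 == 0)
        assert net.is_exc.all()
        with pytest.raises(ValueError):
            build_variant("spiking")

    def test_no_plastic_input_variant_cannot_learn(self, schedule):
        net = EIRNN(build_variant("no_plastic_input", n_rec=40), seed=1)
        rng = np.random.default_rng(0)
        before_in = net.W_in_cur.copy()
        for _ in range(50):
            trial = net.run_trial(int(rng.integers(27)), rng)
            net.hebbian_update(trial, int(rng.integers(2)))
        np.testing.assert_array_equal(net.W_in_cur, before_in)


def test_choice_session_generation(schedule):
    """Decision-layer choice sessions have the standard structure and are
    reproducible; choices follow the logistic rule stochastically."""
    net = EIRNN(RNNConfig(n_rec=40), seed=17)
    a = rnn.generate_choice_session(net, schedule, seed=2, n_trials=40)
    b = rnn.generate_choice_session(net, schedule, seed=2, n_trials=40)
    assert a.n_trials == 40
    assert np.all(a.chosen_side >= 0)
    np.testing.assert_array_equal(a.chosen_side, b.chosen_side)
    assert np.isfinite(a.bouts[-1].estimates).all()


def test_checkpoint_roundtrip(tmp_path, schedule):
    net = EIRNN(RNNConfig(n_rec=40), seed=21)
    cut = lesion(net, "Inh_f*", "Exc_f*")
    path = tmp_path / "net.npz"
    rnn.save_checkpoint(cut, path)
    back = rnn.load_checkpoint(path)
    np.testing.assert_array_equal(back.W_in0, cut.W_in0)
    np.testing.assert_array_equal(back.c_in, cut.c_in)
    np.testing.assert_array_equal(back.lesion_mask, cut.lesion_mask)
    rng_a, rng_b = np.random.default_rng(5), np.random.default_rng(5)
    np.testing.assert_allclose(
        cut.run_trial(3, rng_a)["z"], back.run_trial(3, rng_b)["z"]
    )


class TestChoiceLayer:
    def test_equal_estimates_half(self):
        assert choice_layer(0.4, 0.4) == pytest.approx(0.5)

    def test_saturation(self):
        assert choice_layer(0.9, 0.1, gain=50.0) > 0.999

    def test_antisymmetry(self):
        p = choice_layer(0.7, 0.3, gain=8.0)
        q = choice_layer(0.3, 0.7, gain=8.0)
        assert p + q == pytest.approx(1.0)


class TestTrainingMachinery:
    def test_short_training_reduces_loss(self, schedule):
        cfg = RNNConfig(n_rec=40)
        tcfg = TrainingConfig(trials_per_session=20, probe_interval=4,
                              max_iterations=8, probe_trials=30)
        net, log = rnn.train(cfg, tcfg, schedule, seed=0)
        assert np.mean(log.losses[-3:]) < log.losses[0]
        assert len(log.probe_mses) >= 2

    def test_best_probe_checkpoint_monotone(self, schedule):
        cfg = RNNConfig(n_rec=40)
        tcfg = TrainingConfig(trials_per_session=15, probe_interval=3,
                              max_iterations=9, probe_trials=30)
        _, log = rnn.train(cfg, tcfg, schedule, seed=1)
        best_so_far = np.minimum.accumulate(log.probe_mses)
        assert log.best_probe == best_so_far[-1]

    def test_simulate_experiment_shapes_and_determinism(self, schedule):
        net = EIRNN(RNNConfig(n_rec=40), seed=9)
        a = rnn.simulate_experiment(net, schedule, seed=3, n_trials=54)
        b = rnn.simulate_experiment(net, schedule, seed=3, n_trials=54)
        assert len(a.estimates) == 54
        np.testing.assert_array_equal(a.estimates, b.estimates)
        np.testing.assert_array_equal(a.probe_estimates, b.probe_estimates)
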