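import numpy as np
import pytest

from semhub.control import (RetrievalConfig, SelectionConfig, Trial,
                            option_weights, run_trial, run_trials_batch,
                            set_context_from_cue, record_trajectory)
from semhub.network import Architecture, init_network, random_context


@pytest.fixture()
def small_net(tiny_arch):
    return init_network(tiny_arch, seed=0)


class TestOptionWeights:
    def test_equal_predictions_give_equal_weights(self):
        w = option_weights(np.array([0.1, 0.1, 0.1, 0.1]), s=200.0)
        assert np.allclose(w, 0.25)

    def test_printed_formula_value(self):
        """I_1 for P = (.02, .01, .01, .01), s = 200 is e^4/(e^4 + 3 e^2)."""
        w = option_weights(np.array([0.02, 0.01, 0.01, 0.01]), s=200.0)
        expected = np.exp(4) / (np.exp(4) + 3 * np.exp(2))
        assert w[0] == pytest.approx(expected, rel=1e-12)

    def test_sums_to_one_and_monotone(self):
        rng = np.random.default_rng(0)
        P = rng.random((50, 4))
        W = option_weights(P, s=200.0)
        assert np.allclose(W.sum(axis=1), 1.0)
        order_p = np.argsort(P, axis=1)
        order_w = np.argsort(W, axis=1)
        assert np.array_equal(order_p, order_w)

    def test_large_activations_stable(self):
        w = option_weights(np.array([1.0, 0.0, 0.0]), s=200.0)
        assert np.isfinite(w).all() and w[0] > 0.999


class TestConfigs:
    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            RetrievalConfig(mode="sometimes")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(noise_sd=-0.1)

    def test_duplicate_options_rejected(self):
        with pytest.raises(ValueError):
            Trial(0, (1, 1, 2), 0)


class TestCueContext:
    def test_no_cue_is_random_pattern(self, small_net):
        ctx = set_context_from_cue(small_net, None,
                                   np.random.default_rng(3))
        assert ctx.shape == (1, small_net.arch.n_context)
        assert (ctx > 0).all() and (ctx < 1).all()

    def test_cue_context_is_cue_hub_state(self, small_net):
        from semhub.network import StimulusFrame, settle, copy_context
        rng1 = np.random.default_rng(9)
        ctx = set_context_from_cue(small_net, 2, rng1)
        rng2 = np.random.default_rng(9)
        frame = StimulusFrame.word(small_net.arch, [2],
                                   random_context(rng2, small_net.arch))
        assert np.allclose(ctx, copy_context(settle(small_net, frame)))

    def test_same_cue_same_seed_identical(self, small_net):
        a = set_context_from_cue(small_net, 1, np.random.default_rng(4))
        b = set_context_from_cue(small_net, 1, np.random.default_rng(4))
        assert np.array_equal(a, b)


class TestRunTrial:
    def test_zero_noise_deterministic_argmax(self, small_net):
        trial = Trial(0, (1, 2, 3), 0)
        res = run_trial(small_net, trial, RetrievalConfig("none"),
                        SelectionConfig(0.0),
                        rng=np.random.default_rng(0), reps=5)
        assert np.array_equal(res.choices,
                              res.activations.argmax(axis=1))

    def test_tied_options_split_evenly_under_noise(self, tiny_arch):
        """Two structurally identical options are chosen ~50/50."""
        w = init_network(tiny_arch, seed=1)
        # make options 1 and 2 exactly interchangeable
        for key in ("vh",):
            w.w[key][2] = w.w[key][1]
        w.w["hp"][:, 2] = w.w["hp"][:, 1]
        trial = Trial(0, (1, 2), 0)
        ctx = np.full((4000, tiny_arch.n_context), 0.2)
        res = run_trial(w, trial, RetrievalConfig("none"),
                        SelectionConfig(0.02), context=ctx,
                        rng=np.random.default_rng(7))
        share = res.choices.mean()
        assert abs(share - 0.5) < 0.03

    def test_static_equals_controlled_with_reweighting_disabled(
            self, small_net):
        trial = Trial(0, (1, 2, 3, 4), 1)
        ctx = np.full((3, small_net.arch.n_context), 0.15)
        res_static = run_trial(small_net, trial, RetrievalConfig("static"),
                               SelectionConfig(0.0), context=ctx,
                               rng=np.random.default_rng(0))
        res_frozen = run_trial(
            small_net, trial,
            RetrievalConfig("controlled", reweight_onset=10_000),
            SelectionConfig(0.0), context=ctx,
            rng=np.random.default_rng(0))
        assert np.allclose(res_static.activations, res_frozen.activations)

    def test_batch_matches_single_trials(self, small_net):
        trials = [Trial(0, (1, 2, 3), 0), Trial(1, (0, 2, 4), 2)]
        ctx = np.full((2 * 3, small_net.arch.n_context), 0.1)
        acc = run_trials_batch(small_net, trials, RetrievalConfig("none"),
                               SelectionConfig(0.0),
                               np.random.default_rng(0), reps=3,
                               contexts=ctx)
        for t, a in zip(trials, acc):
            single = run_trial(small_net, t, RetrievalConfig("none"),
                               SelectionConfig(0.0),
                               context=ctx[:3],
                               rng=np.random.default_rng(0))
            assert a == pytest.approx(single.accuracy)


class TestTrajectory:
    def test_records_all_ticks(self, small_net):
        trial = Trial(0, (1, 2, 3), 0)
        ctx = np.full((1, small_net.arch.n_context), 0.1)
        hub = record_trajectory(small_net, trial,
                                RetrievalConfig("controlled"), ctx)
        assert hub.shape == (29, small_net.arch.n_hub)

    def test_identical_configs_identical_paths(self, small_net):
        trial = Trial(2, (0, 1, 3), 1)
        ctx = np.full((1, small_net.arch.n_context), 0.1)
        a = record_trajectory(small_net, trial, RetrievalConfig(), ctx)
        b = record_trajectory(small_net, trial, RetrievalConfig(), ctx)
        assert np.array_equal(a, b)


class TestOptionWeightProperties:
    def test_invariants_over_random_activations(self):
        from hypothesis import given, settings, strategies as st
        import hypothesis.extra.numpy as hnp

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(hnp.arrays(np.float64, (4,),
                          elements=st.floats(0.0, 1.0)))
        def check(p):
            w = option_weights(p, s=200.0)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert (w >= 0).all()
            # monotone in the activations (ties/underflow allowed)
            for i in range(4):
                for j in range(4):
                    if p[i] < p[j]:
                        assert w[i] <= w[j]

        check()
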