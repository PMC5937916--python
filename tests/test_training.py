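import numpy as np
import pytest

from semhub.corpus import CorpusConfig, generate_corpus
from semhub.network import (Architecture, StimulusFrame, init_network,
                            random_context, settle)
from semhub.training import (OptimizerState, TargetFrame, TrainingConfig,
                             apply_update, backprop_through_settling, loss,
                             make_targets, sm_patterns, train_model)


@pytest.fixture()
def tiny_setup(tiny_arch):
    rng = np.random.default_rng(0)
    w = init_network(tiny_arch, rng)
    v = np.zeros((2, 5)); v[0, 2] = 1.0
    smv = np.zeros((2, 6)); smv[1, [0, 3]] = 1.0
    frame = StimulusFrame(v, rng.random((2, 4)), sm_values=smv,
                          sm_clamp=np.array([False, True]))
    smt = np.zeros((2, 6)); smt[0, [1, 2, 4]] = 1.0
    targets = TargetFrame(np.array([3, -1]), smt, np.array([True, False]))
    return w, frame, targets


class TestTargets:
    def test_concrete_word_has_sm_and_prediction(self, vocab, fmap,
                                                 small_corpus):
        patterns = sm_patterns(vocab, fmap)
        concrete = {c.id for c in vocab if c.cls == "concrete"}
        for i in range(200):
            ep = small_corpus.episode(i)
            if int(ep.concepts[0]) in concrete and ep.verbal[0]:
                tf = make_targets(ep, 0, vocab, patterns)
                assert tf.has_sm[0]
                assert tf.sm.sum() == 9
                assert tf.prediction[0] == ep.concepts[1]
                return
        pytest.fail("no concrete word-initial episode found")

    def test_abstract_word_no_sm(self, vocab, fmap, small_corpus):
        patterns = sm_patterns(vocab, fmap)
        abstract = {c.id for c in vocab if c.cls == "abstract"}
        ep = next(e for e in small_corpus
                  if int(e.concepts[1]) in abstract)
        tf = make_targets(ep, 1, vocab, patterns)
        assert not tf.has_sm[0]

    def test_episode_final_no_prediction_target(self, vocab, fmap,
                                                small_corpus):
        patterns = sm_patterns(vocab, fmap)
        tf = make_targets(small_corpus.episode(0), 4, vocab, patterns)
        assert tf.prediction[0] == -1

    def test_homonym_sense_selects_pattern(self, vocab, fmap, small_corpus):
        patterns = sm_patterns(vocab, fmap)
        hom = {c.id for c in vocab if c.cls == "homonym"}
        for ep in small_corpus:
            for pos in range(4):
                cid = int(ep.concepts[pos])
                if cid in hom and ep.verbal[pos]:
                    tf = make_targets(ep, pos, vocab, patterns)
                    sense = int(ep.senses[pos])
                    assert np.array_equal(tf.sm[0], patterns[cid, sense])
                    return
        pytest.fail("no verbal homonym found")


class TestLoss:
    def test_uniform_prediction_vs_onehot_is_log_n(self, tiny_arch):
        """KL from a one-hot target to the uniform softmax is ln(n) per
        tick in the target window."""
        w = init_network(tiny_arch, 0)
        for k in w.w:
            w.w[k][:] = 0.0
        frame = StimulusFrame.word(tiny_arch, [0], np.zeros((1, 4)))
        traj = settle(w, frame)
        targets = TargetFrame(np.array([2]), np.zeros((1, 6)),
                              np.array([False]))
        expected = tiny_arch.target_ticks * np.log(tiny_arch.n_prediction)
        assert loss(traj, targets, tiny_arch) == pytest.approx(expected,
                                                               rel=1e-9)

    def test_no_targets_zero_loss(self, tiny_arch):
        w = init_network(tiny_arch, 1)
        frame = StimulusFrame.word(tiny_arch, [0], np.zeros((1, 4)))
        traj = settle(w, frame)
        targets = TargetFrame(np.array([-1]), np.zeros((1, 6)),
                              np.array([False]))
        assert loss(traj, targets, tiny_arch) == 0.0


class TestGradients:
    def test_matches_central_differences(self, tiny_setup, tiny_arch):
        w, frame, targets = tiny_setup
        _, grads = backprop_through_settling(w, frame, targets)
        h = 1e-5
        worst = 0.0
        rng = np.random.default_rng(1)
        for key in w.w:
            W = w.w[key]
            for _ in range(6):
                i = rng.integers(W.shape[0]); j = rng.integers(W.shape[1])
                orig = W[i, j]
                W[i, j] = orig + h
                lp = loss(settle(w, frame), targets, tiny_arch)
                W[i, j] = orig - h
                lm = loss(settle(w, frame), targets, tiny_arch)
                W[i, j] = orig
                fd = (lp - lm) / (2 * h)
                rel = abs(fd - grads[key][i, j]) / max(1e-8,
                                                       abs(fd)
                                                       + abs(grads[key][i, j]))
                worst = max(worst, rel)
        assert worst < 1e-4

    def test_zero_loss_zero_gradients(self, tiny_arch):
        w = init_network(tiny_arch, 2)
        frame = StimulusFrame.word(tiny_arch, [0], np.zeros((1, 4)))
        targets = TargetFrame(np.array([-1]), np.zeros((1, 6)),
                              np.array([False]))
        l, grads = backprop_through_settling(w, frame, targets)
        assert l == 0.0
        assert all(np.all(g == 0) for g in grads.values())

    def test_masked_weight_gets_zero_gradient(self, tiny_setup):
        w, frame, targets = tiny_setup
        w.masks["hh"] = np.ones_like(w.w["hh"])
        w.masks["hh"][1, 2] = 0.0
        _, grads = backprop_through_settling(w, frame, targets)
        assert grads["hh"][1, 2] == 0.0


class TestOptimizer:
    def test_decay_only_when_no_gradient(self):
        w = init_network(seed=0)
        before = {k: v.copy() for k, v in w.w.items()}
        state = OptimizerState.for_weights(w)
        apply_update(state, w, TrainingConfig())
        for k in w.w:
            assert np.allclose(w.w[k], before[k] * (1 - 1e-6), atol=1e-12)

    def test_huge_gradient_clipped_to_unit_norm(self, tiny_arch):
        w = init_network(tiny_arch, 1)
        state = OptimizerState.for_weights(w)
        for k in state.grads:
            state.grads[k][:] = 1e4
        before = {k: v.copy() for k, v in w.w.items()}
        apply_update(state, w, TrainingConfig())
        step = {k: w.w[k] - before[k] * (1 - 1e-6) for k in w.w}
        norm = np.sqrt(sum(float((s ** 2).sum()) for s in step.values()))
        assert norm == pytest.approx(1.0, rel=1e-9)

    def test_momentum_recursion(self, tiny_arch):
        """Two updates with a constant small gradient g: the second step is
        (1 + m) times the first (no clipping)."""
        w = init_network(tiny_arch, 2)
        cfg = TrainingConfig()
        g = {k: np.full_like(v, 1e-4) for k, v in w.w.items()}
        state = OptimizerState.for_weights(w)
        for k in g:
            state.grads[k] = g[k].copy()
        w0 = {k: v.copy() for k, v in w.w.items()}
        apply_update(state, w, cfg)
        step1 = {k: w.w[k] - w0[k] * (1 - 1e-6) for k in w.w}
        for k in g:
            state.grads[k] = g[k].copy()
        w1 = {k: v.copy() for k, v in w.w.items()}
        apply_update(state, w, cfg)
        step2 = {k: w.w[k] - w1[k] * (1 - 1e-6) for k in w.w}
        for k in w.w:
            assert np.allclose(step2[k], (1 + cfg.momentum) * step1[k],
                               rtol=1e-6)


class TestTrainingLoop:
    def test_update_count_and_learning(self, vocab, fmap, topics):
        corpus = generate_corpus(CorpusConfig(n_episodes=2_000), rng=11,
                                 topics=topics, vocab=vocab)
        cfg = TrainingConfig(n_passes=1, n_streams=50, dtype="float32")
        w, log = train_model(corpus, vocab, fmap, cfg, seed=0)
        assert log.updates[-1] == 2_000 // 100
        assert log.mean_loss[-1] < log.mean_loss[0]

    def test_reproducible(self, vocab, fmap, topics):
        corpus = generate_corpus(CorpusConfig(n_episodes=400), rng=12,
                                 topics=topics, vocab=vocab)
        cfg = TrainingConfig(n_passes=1, n_streams=20, dtype="float32")
        w1, _ = train_model(corpus, vocab, fmap, cfg, seed=5)
        w2, _ = train_model(corpus, vocab, fmap, cfg, seed=5)
        assert all(np.array_equal(w1.w[k], w2.w[k]) for k in w1.w)
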