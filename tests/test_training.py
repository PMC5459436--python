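import math

import numpy as np
import pytest

from porecall import (NetworkParams, SimConfig, TrainingRead, backward,
                      forward, make_targets, sequence_loss,
                      sgd_nesterov_step, train_1d)
from porecall.dp_align import EventAlignment
from porecall.io_model import ValidationError
from porecall.network import SYMBOL_INDEX
from porecall.simulate import random_genome, simulate_strand
from porecall.training import (TrainConfig, clip_gradient, loss_and_grad,
                               prepare_1d_read, realign_posterior)
from conftest import random_dists
from test_network import onehot_dists

DASH = SYMBOL_INDEX["-"]


def alignment_from_labels(labels):
    intervals, pos = [], 0
    for lab in labels:
        intervals.append((pos, pos + len(lab)))
        pos += len(lab)
    return EventAlignment(intervals=intervals, score=0.0)


class TestMakeTargets:
    def test_bigram_conventions(self):
        aln = alignment_from_labels(["A", "", "CA"])
        t = make_targets(aln, "ACA")
        assert t[0].tolist() == [DASH, SYMBOL_INDEX["A"]]
        assert t[1].tolist() == [DASH, DASH]
        assert t[2].tolist() == [SYMBOL_INDEX["C"], SYMBOL_INDEX["A"]]


class TestSequenceLoss:
    def test_one_hot_correct_predictions_zero_loss(self):
        dists = onehot_dists([("-", "A"), ("C", "G"), ("-", "-")])
        targets = make_targets(alignment_from_labels(["A", "CG", ""]), "ACG")
        assert sequence_loss(dists, targets) == 0.0

    def test_uniform_closed_form(self):
        n = 7
        from porecall import OutputDistributions

        dists = OutputDistributions(p1=np.full((n, 5), 0.2),
                                    p2=np.full((n, 5), 0.2))
        targets = np.zeros((n, 2), dtype=int)
        assert sequence_loss(dists, targets) == pytest.approx(
            2 * n * math.log(5))

    def test_zero_probability_clamped_with_warning(self):
        dists = onehot_dists([("A", "A")])
        targets = np.array([[1, 1]])  # C,C has probability 0
        with pytest.warns(RuntimeWarning):
            loss = sequence_loss(dists, targets)
        assert np.isfinite(loss) and loss > 100


class TestBackward:
    def test_finite_differences_small_net(self, rng):
        p = NetworkParams.init_random(3, [3, 2], rng)
        flat = p.pack() + rng.normal(0, 0.3, p.n_parameters)
        p.unpack_(flat)
        X = rng.normal(size=(5, 3))
        targets = rng.integers(0, 5, size=(5, 2))
        _, g = loss_and_grad(p, X, targets)
        ga = g.pack()
        work = p.like_zeros()
        eps = 1e-5
        idx = rng.choice(flat.size, size=60, replace=False)
        for i in idx:
            fp = flat.copy()
            fp[i] += eps
            lp = sequence_loss(forward(work.unpack_(fp), X), targets)
            fp[i] -= 2 * eps
            lm = sequence_loss(forward(work.unpack_(fp), X), targets)
            num = (lp - lm) / (2 * eps)
            assert ga[i] == pytest.approx(num, abs=1e-7, rel=1e-4)

    def test_zero_loss_point_has_zero_gradient(self, rng):
        """Drive the target probability to 1; loss and gradient vanish.

        Saturated update gates pin every hidden state at h0 = 1, so the
        positive theta row for symbol A dominates both softmaxes."""
        p = NetworkParams.zeros(3, [3])
        for d in (p.layers[0].fwd, p.layers[0].bwd):
            d.b_u[...] = 50.0
            d.h0[...] = 1.0
        p.theta[:, 0, :] = 10.0  # symbol A gets all mass in both slots
        X = rng.normal(size=(4, 3))
        targets = np.zeros((4, 2), dtype=int)
        loss, g = loss_and_grad(p, X, targets)
        assert loss == pytest.approx(0.0, abs=1e-10)
        assert np.abs(g.pack()).max() < 1e-10

    def test_theta_gradient_is_probability_weighted_hidden_state(self, rng):
        """1-event toy: dL/dtheta_q = (p_q - [q == target]) h."""
        p = NetworkParams.init_random(3, [2], rng)
        X = rng.normal(size=(1, 3))
        dists, cache = forward(p, X, return_cache=True)
        h = cache["h_last"][0]
        targets = np.array([[0, 2]])
        g = backward(p, cache, targets)
        for k, tgt in ((0, 0), (1, 2)):
            pk = (dists.p1, dists.p2)[k][0]
            for q in range(5):
                want = (pk[q] - (q == tgt)) * h
                np.testing.assert_allclose(g.theta[k, q], want, atol=1e-12)

    def test_mismatched_cache_rejected(self, rng):
        p = NetworkParams.init_random(3, [3], rng)
        _, cache = forward(p, rng.normal(size=(4, 3)), return_cache=True)
        with pytest.raises(ValidationError):
            backward(p, cache, np.zeros((6, 2), dtype=int))


class TestSgdNesterov:
    def test_zero_momentum_is_plain_gradient_descent(self):
        params = np.array([1.0, -2.0])
        g = np.array([0.5, 0.5])
        p2, v2 = sgd_nesterov_step(params, np.zeros(2), g, 0.1, 0.0)
        np.testing.assert_allclose(p2, params - 0.05)

    def test_quadratic_convergence_with_momentum(self):
        # minimise 0.5 x^2; Nesterov gradient evaluated at lookahead
        x = np.array([1.0])
        v = np.zeros(1)
        for _ in range(200):
            g = x + 0.9 * v  # gradient of 0.5 z^2 at z = x + mu v
            x, v = sgd_nesterov_step(x, v, g, 0.1, 0.9)
        assert abs(x[0]) < 1e-3

    def test_zero_gradient_velocity_decays_geometrically(self):
        v = np.array([1.0])
        x = np.array([0.0])
        for i in range(5):
            x, v = sgd_nesterov_step(x, v, np.zeros(1), 0.1, 0.9)
            assert v[0] == pytest.approx(0.9 ** (i + 1))

    def test_non_finite_gradient_skips_step(self):
        x = np.array([1.0])
        v = np.array([0.5])
        x2, v2 = sgd_nesterov_step(x, v, np.array([np.nan]), 0.1, 0.9)
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(v2, v)

    def test_clip_gradient_norm(self):
        g = np.array([3.0, 4.0])
        np.testing.assert_allclose(np.linalg.norm(clip_gradient(g, 1.0)), 1.0)
        np.testing.assert_array_equal(clip_gradient(g, 10.0), g)


def tiny_training_reads(model, n_reads=8, length=40, noisy=True, seed=0):
    cfg = SimConfig(k=3, p_split=0.05, p_skip=0.05,
                    noise_mean=0.5 if noisy else 0.0,
                    noise_stdev=0.1 if noisy else 0.0, seed=seed)
    if not noisy:
        cfg = cfg.noiseless()
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        frag = random_genome(length, rng)
        ev, _ = simulate_strand(frag, model, cfg, rng=rng,
                                read_id=f"r{i}")
        reads.append(TrainingRead(events=ev, reference=frag))
    return reads


class TestTrain1d:
    def test_loss_decreases_on_tiny_fixture(self, pore_model_k3):
        reads = tiny_training_reads(pore_model_k3)
        cfg = TrainConfig(epochs=15, realign_every=100, seed=3)
        result = train_1d(reads, pore_model_k3, [6, 6], cfg)
        assert result.loss_history[-1] < result.loss_history[0]
        assert min(result.loss_history) < 0.8 * result.loss_history[0]

    def test_fixed_seed_bitwise_reproducible(self, pore_model_k3):
        reads = tiny_training_reads(pore_model_k3, n_reads=4)
        cfg = TrainConfig(epochs=4, realign_every=2, seed=7)
        a = train_1d(reads, pore_model_k3, [4], cfg)
        b = train_1d(reads, pore_model_k3, [4], cfg)
        np.testing.assert_array_equal(a.params.pack(), b.params.pack())
        assert a.loss_history == b.loss_history

    def test_unalignable_read_dropped_with_others_trained(self,
                                                          pore_model_k3):
        reads = tiny_training_reads(pore_model_k3, n_reads=3)
        # 4 events cannot consume the 38 contexts of a 40-base reference
        bad = TrainingRead(events=reads[0].events.replace(
            mean=reads[0].events.mean[:4],
            stdev=reads[0].events.stdev[:4],
            duration=reads[0].events.duration[:4],
            truth=None), reference=reads[0].reference)
        result = train_1d(reads + [bad], pore_model_k3, [4],
                          TrainConfig(epochs=1, seed=0))
        assert result.n_dropped == 1


class TestRealignment:
    def test_realigned_targets_do_not_increase_loss(self, pore_model_k3):
        """The realignment maximises exactly the log probabilities the loss
        sums, so new targets score at most the old loss."""
        reads = tiny_training_reads(pore_model_k3, n_reads=4)
        cfg = TrainConfig(epochs=5, realign_every=100, seed=1)
        result = train_1d(reads, pore_model_k3, [6], cfg)
        prepared = [prepare_1d_read(r, pore_model_k3) for r in reads]
        for pr in prepared:
            dists = forward(result.params, pr.inputs)
            old_loss = sequence_loss(dists, pr.targets)
            aln = realign_posterior(dists, pr.target_seq)
            new_loss = sequence_loss(dists, make_targets(aln, pr.target_seq))
            assert new_loss <= old_loss + 1e-9
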