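import math

import numpy as np
import pytest

from porecall import (EventSequence, OutputDistributions, align_event_pairs,
                      align_expected_signal, align_sequences,
                      orient_complement, realign_posterior, simulate_strand)
from porecall.dp_align import AlignmentError, EventAlignment
from porecall.io_model import ValidationError
from porecall.simulate import SimConfig, random_genome
from conftest import random_dists
from oracles import (enumerate_global_alignment, enumerate_pair_alignment,
                     enumerate_posterior_alignment,
                     enumerate_signal_alignment)


def make_events(means):
    means = np.asarray(means, dtype=float)
    return EventSequence(read_id="r", strand="template", mean=means,
                         stdev=np.ones(len(means)),
                         duration=np.full(len(means), 0.02))


class TestEventAlignmentInvariants:
    def test_three_bases_rejected(self):
        with pytest.raises(ValidationError):
            EventAlignment(intervals=[(0, 3)], score=0.0)

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValidationError):
            EventAlignment(intervals=[(0, 1), (2, 3)], score=0.0)


class TestAlignExpectedSignal:
    def test_single_event_single_context(self, pore_model_k3):
        ref = "ACG"
        ev = make_events([pore_model_k3.level("ACG")[0] + 0.7])
        aln = align_expected_signal(ev, ref, pore_model_k3)
        assert aln.intervals == [(2, 3)]
        assert aln.score == pytest.approx(0.7)

    def test_recovers_noiseless_truth(self, pore_model_k3, noiseless_cfg):
        frag = random_genome(50, np.random.default_rng(7))
        ev, truth = simulate_strand(frag, pore_model_k3, noiseless_cfg)
        aln = align_expected_signal(ev, frag, pore_model_k3,
                                    penalties=(2.0, 2.0))
        assert aln.intervals == truth.intervals
        assert aln.score == pytest.approx(0.0, abs=1e-9)
        assert aln.labels(frag) == truth.labels

    def test_recovers_truth_with_splits(self, pore_model_k3):
        # noiseless with split events only; the true generative path costs
        # exactly one penalty per split, the cheapest on almost every draw
        cfg = SimConfig(k=3, p_split=0.3, p_skip=0.0, noise_mean=0.0,
                        noise_stdev=0.0, scale=(1, 1), shift=(0, 0), seed=0)
        hits = 0
        for seed in range(10):
            frag = random_genome(40, np.random.default_rng(seed + 100))
            ev, truth = simulate_strand(frag, pore_model_k3, cfg,
                                        rng=np.random.default_rng(seed))
            aln = align_expected_signal(ev, frag, pore_model_k3)
            hits += aln.intervals == truth.intervals
        assert hits >= 8

    def test_never_costs_more_than_generative_path(self, pore_model_k3):
        """With skips the DP's landing-context cost differs from the
        simulator's merged-mean law, so exact recovery is not guaranteed —
        but the optimum can never cost more than the generative path."""
        cfg = SimConfig(k=3, p_split=0.15, p_skip=0.15, noise_mean=0.0,
                        noise_stdev=0.0, scale=(1, 1), shift=(0, 0), seed=0)
        for seed in range(5):
            frag = random_genome(40, np.random.default_rng(seed))
            ev, truth = simulate_strand(frag, pore_model_k3, cfg,
                                        rng=np.random.default_rng(seed))
            levels = pore_model_k3.expected_means(frag)
            truth_cost = 0.0
            ctx = 0
            for mean, (s, e) in zip(ev.mean, truth.intervals):
                if e - s == 1:
                    truth_cost += abs(levels[ctx] - mean)
                    ctx += 1
                elif e - s == 0:
                    truth_cost += abs(levels[ctx - 1] - mean) + 2.0
                else:
                    ctx += 2
                    truth_cost += abs(levels[ctx - 1] - mean) + 2.0
            aln = align_expected_signal(ev, frag, pore_model_k3)
            assert aln.score <= truth_cost + 1e-9

    @pytest.mark.parametrize("seed", range(12))
    def test_cost_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        M = int(rng.integers(1, min(2 * n, 8)))
        from porecall.io_model import PoreModel

        k = 2
        model = PoreModel(k=k, level_mean=rng.uniform(50, 150, 16),
                          level_stdev=np.full(16, 1.0))
        ref = random_genome(M + k - 1, rng)
        levels = model.expected_means(ref)
        means = rng.uniform(50, 150, n)
        want = enumerate_signal_alignment(means.tolist(), levels.tolist(),
                                          2.0, 2.0)
        if math.isinf(want):
            with pytest.raises(AlignmentError):
                align_expected_signal(make_events(means), ref, model)
        else:
            aln = align_expected_signal(make_events(means), ref, model)
            assert aln.score == pytest.approx(want, abs=1e-9)

    def test_infeasible_reference_rejected(self, pore_model_k3):
        ref = random_genome(20, np.random.default_rng(0))  # 18 contexts
        with pytest.raises(AlignmentError):
            align_expected_signal(make_events([80.0] * 4), ref, pore_model_k3)


class TestRealignPosterior:
    def test_one_hot_labelling_recovered_with_zero_score(self):
        labels = ["G", "", "TA", "C"]
        rows = []
        for lab in labels:
            if len(lab) == 0:
                rows.append(("-", "-"))
            elif len(lab) == 1:
                rows.append(("-", lab))
            else:
                rows.append((lab[0], lab[1]))
        from test_network import onehot_dists

        dists = onehot_dists(rows)
        aln = realign_posterior(dists, "GTAC")
        assert aln.labels("GTAC") == labels
        assert aln.score == pytest.approx(0.0)  # log 1 everywhere

    def test_uniform_distributions_closed_form(self):
        n, m = 6, 5
        dists = OutputDistributions(p1=np.full((n, 5), 0.2),
                                    p2=np.full((n, 5), 0.2))
        aln = realign_posterior(dists, "ACGTA")
        assert aln.score == pytest.approx(n * 2 * math.log(1 / 5))
        assert sum(e - s for s, e in aln.intervals) == m

    @pytest.mark.parametrize("seed", range(12))
    def test_score_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 7))
        m = int(rng.integers(1, min(2 * n, 10) + 1))
        dists = random_dists(n, rng)
        ref = random_genome(m, rng)
        want = enumerate_posterior_alignment(dists.p1.tolist(),
                                             dists.p2.tolist(), ref)
        aln = realign_posterior(dists, ref)
        assert aln.score == pytest.approx(want, abs=1e-9)

    def test_reference_longer_than_twice_events_rejected(self, rng):
        with pytest.raises(AlignmentError):
            realign_posterior(random_dists(2, rng), "ACGTA")

    def test_onehot_replacement_at_emitted_symbols_never_lowers_score(
            self, rng):
        """Sharpening every distribution into a one-hot at the symbol the
        returned alignment emitted can only raise the optimal score."""
        from porecall import make_targets

        for seed in range(5):
            r = np.random.default_rng(seed)
            dists = random_dists(6, r, peaked=True)
            ref = random_genome(6, r)
            aln = realign_posterior(dists, ref)
            targets = make_targets(aln, ref)
            p1 = np.zeros_like(dists.p1)
            p2 = np.zeros_like(dists.p2)
            p1[np.arange(6), targets[:, 0]] = 1
            p2[np.arange(6), targets[:, 1]] = 1
            resharp = realign_posterior(OutputDistributions(p1=p1, p2=p2),
                                        ref)
            assert resharp.score >= aln.score - 1e-9
            assert resharp.score == pytest.approx(0.0)


class TestAlignEventPairs:
    def test_identical_onehots_fully_paired(self, rng):
        dists = random_dists(5, rng, peaked=True)
        p1 = (dists.p1 == dists.p1.max(1, keepdims=True)).astype(float)
        p2 = (dists.p2 == dists.p2.max(1, keepdims=True)).astype(float)
        oh = OutputDistributions(p1=p1, p2=p2)
        pair = align_event_pairs(oh, oh)
        assert pair.columns == [(i, i) for i in range(5)]
        assert pair.score == pytest.approx(0.0)
        # brute force confirms optimality
        score = (np.log(np.clip(oh.p1 @ oh.p1.T, 1e-300, None))
                 + np.log(np.clip(oh.p2 @ oh.p2.T, 1e-300, None)))
        want = enumerate_pair_alignment(score.tolist(), 5, 5, math.log(0.1))
        assert pair.score == pytest.approx(want)

    def test_empty_complement_gives_all_gap_columns(self, rng):
        dists = random_dists(4, rng)
        empty = OutputDistributions(p1=np.zeros((0, 5)), p2=np.zeros((0, 5)))
        pair = align_event_pairs(dists, empty)
        assert pair.columns == [(i, None) for i in range(4)]

    @pytest.mark.parametrize("seed", range(12))
    def test_score_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        t = random_dists(n, rng)
        c = random_dists(m, rng)
        pair = align_event_pairs(t, c)
        score = (np.log(np.clip(t.p1 @ c.p1.T, 1e-300, None))
                 + np.log(np.clip(t.p2 @ c.p2.T, 1e-300, None)))
        want = enumerate_pair_alignment(score.tolist(), n, m, math.log(0.1))
        assert pair.score == pytest.approx(want, abs=1e-9)

    def test_column_indices_strictly_increase(self, rng):
        t = random_dists(8, rng)
        c = random_dists(6, rng)
        pair = align_event_pairs(t, c)
        ts = [x for x, _ in pair.columns if x is not None]
        cs = [y for _, y in pair.columns if y is not None]
        assert ts == sorted(ts) == list(range(8))
        assert cs == sorted(cs) == list(range(6))


class TestOrientComplement:
    def test_round_trip_is_identity(self, rng):
        dists = random_dists(6, rng)
        back = orient_complement(orient_complement(dists))
        np.testing.assert_allclose(back.p1, dists.p1)
        np.testing.assert_allclose(back.p2, dists.p2)

    def test_base_probabilities_complemented_and_reversed(self, rng):
        dists = random_dists(3, rng)
        out = orient_complement(dists)
        # last event's slot-2 A-probability becomes first event's slot-1 T
        assert out.p1[0, 3] == dists.p2[-1, 0]
        assert out.p1[0, 4] == dists.p2[-1, 4]  # dash fixed


class TestAlignSequences:
    def test_identical_strings_full_accuracy(self):
        _, acc = align_sequences("ACGTACGTAC", "ACGTACGTAC")
        assert acc == 1.0

    def test_single_substitution(self):
        _, acc = align_sequences("ACGTACGTAC", "ACGTTCGTAC")
        assert acc == pytest.approx(0.9)

    def test_deletion_example(self):
        aln, acc = align_sequences("ACGT", "AGT")
        assert aln.length == 4 and aln.matches == 3
        assert acc == pytest.approx(0.75)
        assert aln.score == enumerate_global_alignment("ACGT", "AGT")

    @pytest.mark.parametrize("seed", range(12))
    def test_score_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_genome(int(rng.integers(1, 8)), rng)
        b = random_genome(int(rng.integers(1, 8)), rng)
        aln, _ = align_sequences(a, b)
        assert aln.score == enumerate_global_alignment(a, b)
        # score consistency: matches*1 - mismatches - gaps
        mism = sum(1 for x, y in zip(aln.a_aligned, aln.b_aligned)
                   if "-" not in (x, y) and x != y)
        gaps = aln.a_aligned.count("-") + aln.b_aligned.count("-")
        assert aln.score == aln.matches - mism - gaps

    def test_self_alignment_and_symmetry(self, rng):
        for seed in range(5):
            x = random_genome(int(rng.integers(1, 20)), rng)
            y = random_genome(int(rng.integers(1, 20)), rng)
            assert align_sequences(x, x)[1] == 1.0
            assert align_sequences(x, y)[1] == pytest.approx(
                align_sequences(y, x)[1])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            align_sequences("", "ACGT")
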