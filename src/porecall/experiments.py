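"""Self-contained end-to-end recovery experiments on synthetic data.

These drive the whole pipeline — simulate a pore model, a genome and paired
reads; train template/complement 1D networks and a 2D network; base call
held-out reads; score them against the simulator's truth — and return the
summary numbers.  They exist so the same experiment is runnable from the
test suite, the acceptance script and an interactive session with one call,
fully reproducible from a single seed.

Scale defaults are a desk-scale compromise (one CPU, minutes not weeks):
a 20 kb genome, 60 paired reads, 3-layer hidden-32 networks per strand
and a larger (hidden-48) 2D network.  See docs/methods.md.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .basecall import ModelBundle, call_1d, call_2d, feature_norm
from .dp_align import align_sequences
from .io_model import PoreModel
from .simulate import SimConfig, SimulatedDataset, build_pore_model, \
    simulate_dataset, simulate_strand
from .training import (TrainConfig, Training2DRead, TrainingRead, train_1d,
                       train_2d)

logger = logging.getLogger(__name__)


@dataclass
class RecoveryResult:
    """Summary of one end-to-end recovery experiment."""

    template_noisy: list[float] = field(default_factory=list)
    template_noiseless: list[float] = field(default_factory=list)
    complement_noisy: list[float] = field(default_factory=list)
    twod_noisy: list[float] = field(default_factory=list)
    template_loss: list[float] = field(default_factory=list)
    complement_loss: list[float] = field(default_factory=list)
    twod_loss: list[float] = field(default_factory=list)
    n_train: int = 0
    n_test: int = 0
    runtime_s: float = 0.0
    bundles: tuple = ()
    dataset: SimulatedDataset | None = None

    def medians(self) -> dict[str, float]:
        med = lambda v: float(np.median(v)) if v else float("nan")
        return {
            "median_template_1d_accuracy_noisy": med(self.template_noisy),
            "median_template_1d_accuracy_noiseless":
                med(self.template_noiseless),
            "median_complement_1d_accuracy_noisy": med(self.complement_noisy),
            "median_2d_accuracy_noisy": med(self.twod_noisy),
        }


def _accuracy(call_seq: str, truth: str) -> float:
    if not call_seq:
        return 0.0
    return align_sequences(call_seq, truth)[1]


def recovery_experiment(seed: int,
                        genome_length: int = 20_000,
                        n_reads: int = 60,
                        n_train: int = 45,
                        read_length: tuple[int, int] = (150, 300),
                        hidden_template: tuple[int, ...] = (32, 32, 32),
                        epochs_template: int = 90,
                        hidden_complement: tuple[int, ...] = (32, 32, 32),
                        epochs_complement: int = 90,
                        hidden_2d: tuple[int, ...] = (48, 48, 48),
                        epochs_2d: int = 90,
                        learning_rate: float = 0.03,
                        realign_every: int = 15,
                        sim: SimConfig | None = None,
                        pore_model: PoreModel | None = None,
                        train_complement: bool = True,
                        train_twod: bool = True) -> RecoveryResult:
    """Train on ``n_train`` paired reads, evaluate on the held-out rest.

    Held-out template strands are additionally re-simulated without noise
    or segmentation errors, so the same network is scored on clean and
    noisy versions of the same fragments.  All randomness descends from
    ``seed``.
    """
    t0 = time.perf_counter()
    if sim is None:
        sim = SimConfig(seed=seed)
    if pore_model is None:
        pore_model = build_pore_model(sim.k, seed=seed + 1)
    ds = simulate_dataset(genome_length, n_reads, read_length, pore_model,
                          sim, seed=seed + 2)
    train_set, test_set = ds.reads[:n_train], ds.reads[n_train:]
    result = RecoveryResult(n_train=len(train_set), n_test=len(test_set),
                            dataset=ds)
    norm = feature_norm(pore_model)

    cfg_t = TrainConfig(learning_rate=learning_rate, epochs=epochs_template,
                        realign_every=realign_every, seed=seed + 3)
    res_t = train_1d([TrainingRead(r.template, r.fragment)
                      for r in train_set],
                     pore_model, list(hidden_template), cfg_t)
    result.template_loss = res_t.loss_history
    t_bundle = ModelBundle(res_t.params, norm, "template_1d")
    logger.info("template 1D trained: loss %.3f -> %.3f",
                res_t.loss_history[0], res_t.loss_history[-1])

    c_bundle = bundle_2d = None
    if train_complement:
        from .simulate import reverse_complement

        cfg_c = TrainConfig(learning_rate=learning_rate,
                            epochs=epochs_complement,
                            realign_every=realign_every, seed=seed + 4)
        res_c = train_1d([TrainingRead(r.complement,
                                       reverse_complement(r.fragment))
                          for r in train_set],
                         pore_model, list(hidden_complement), cfg_c)
        result.complement_loss = res_c.loss_history
        c_bundle = ModelBundle(res_c.params, norm, "complement_1d")
    if train_twod:
        if c_bundle is None:
            raise ValueError("2D training requires the complement network")
        cfg_2 = TrainConfig(learning_rate=learning_rate, epochs=epochs_2d,
                            realign_every=realign_every, seed=seed + 5)
        res_2 = train_2d([Training2DRead(r.template, r.complement,
                                         r.fragment) for r in train_set],
                         t_bundle.params, c_bundle.params, pore_model,
                         list(hidden_2d), cfg_2)
        result.twod_loss = res_2.loss_history
        bundle_2d = ModelBundle(res_2.params, norm, "2d")
    result.bundles = (t_bundle, c_bundle, bundle_2d)

    clean_rng = np.random.default_rng(seed + 6)
    k = sim.k
    for read in test_set:
        truth_t = read.fragment[k - 1:]
        bc = call_1d(read.template, t_bundle, pore_model)
        result.template_noisy.append(_accuracy(bc.sequence, truth_t))
        ev0, truth0 = simulate_strand(read.fragment, pore_model,
                                      sim.noiseless(), rng=clean_rng,
                                      read_id=read.read_id)
        bc0 = call_1d(ev0, t_bundle, pore_model)
        result.template_noiseless.append(
            _accuracy(bc0.sequence, truth0.sequence()))
        if c_bundle is not None:
            truth_c = read.truths[1].sequence()
            bcc = call_1d(read.complement, c_bundle, pore_model)
            result.complement_noisy.append(_accuracy(bcc.sequence, truth_c))
        if bundle_2d is not None:
            bc2 = call_2d(read.template, read.complement,
                          (t_bundle, c_bundle, bundle_2d), pore_model)
            result.twod_noisy.append(_accuracy(bc2.sequence, truth_t))
    result.runtime_s = time.perf_counter() - t0
    logger.info("recovery experiment done in %.0fs: %s", result.runtime_s,
                result.medians())
    return result
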