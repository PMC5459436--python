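"""Training of the base-calling networks.

The supervised objective is the negative log likelihood of per-event target
bigrams ``(o1, o2)`` under the network's dual softmax.  Correct targets are
unknown — only the reference region a read maps to — so training is
EM-like: targets start from an expected-signal alignment (events matched
against the signal a pore model predicts for the reference), the network is
fitted by stochastic gradient descent with Nesterov momentum (one read =
one full-sequence backpropagation-through-time update, gradients clipped in
L2 norm), and periodically the events are *realigned* to the reference by
dynamic programming over the network's own output probabilities, producing
new targets.

Gradients are exact analytic backpropagation through the bidirectional GRU
stack, the concatenations, and both softmax heads, including the initial
hidden states and the output weight vectors.  The flat parameter-vector
interface (``NetworkParams.pack``/``unpack_``) also gives any off-the-shelf
batch optimiser (e.g. L-BFGS) a loss/gradient oracle for later fine-tuning;
only the SGD path is built in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np

from .dp_align import (AlignmentError, EventAlignment, align_event_pairs,
                       align_expected_signal, orient_complement,
                       realign_posterior)
from .io_model import EventSequence, PoreModel, ValidationError
from .network import (SYMBOL_INDEX, GRULayerParams, NetworkParams,
                      OutputDistributions, forward)
from .preprocess import scale_to_model

logger = logging.getLogger(__name__)

LOSS_PROB_FLOOR = 1e-30  # target probabilities are clamped here in the loss

_DASH = SYMBOL_INDEX["-"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation knobs.

    ``realign_every`` is the number of full passes between posterior
    realignments (the realignment cadence ignores stalled epochs).  When the
    epoch-mean loss fails to improve for ``stall_epochs`` epochs the
    learning rate decays by ``lr_decay``.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 100
    realign_every: int = 100
    grad_clip: float = 5.0
    lr_decay: float = 0.5
    stall_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValidationError("momentum must be in [0, 1)")
        if self.realign_every < 1:
            raise ValidationError("realign_every must be >= 1")


# ---------------------------------------------------------------------------
# targets and loss
# ---------------------------------------------------------------------------

def make_targets(alignment: EventAlignment, reference: str) -> np.ndarray:
    """Per-event target symbol pairs, shape (n_events, 2) of alphabet indices.

    Zero assigned bases give ``(-, -)``; one base ``b`` gives ``(-, b)``
    (slot 1 is always the dash when a single base is emitted); two bases
    fill both slots in order.
    """
    labels = alignment.labels(reference)
    out = np.empty((len(labels), 2), dtype=np.int64)
    for i, lab in enumerate(labels):
        if len(lab) > 2:
            raise ValidationError(f"event {i} assigned {len(lab)} bases")
        if len(lab) == 0:
            out[i] = (_DASH, _DASH)
        elif len(lab) == 1:
            out[i] = (_DASH, SYMBOL_INDEX[lab])
        else:
            out[i] = (SYMBOL_INDEX[lab[0]], SYMBOL_INDEX[lab[1]])
    return out


def sequence_loss(dists: OutputDistributions, targets: np.ndarray) -> float:
    """Negative log likelihood of the targets under both output slots.

    Zero target probabilities are clamped at ``LOSS_PROB_FLOOR`` (with a
    warning) so a saturated network yields a large finite loss rather than
    an exception.
    """
    n = len(dists)
    if targets.shape != (n, 2):
        raise ValidationError("targets must be (n_events, 2)")
    idx = np.arange(n)
    p1 = dists.p1[idx, targets[:, 0]]
    p2 = dists.p2[idx, targets[:, 1]]
    if (p1 <= 0).any() or (p2 <= 0).any():
        warnings.warn("zero target probability clamped in sequence_loss",
                      RuntimeWarning, stacklevel=2)
    return float(-(np.log(np.clip(p1, LOSS_PROB_FLOOR, None)).sum()
                   + np.log(np.clip(p2, LOSS_PROB_FLOOR, None)).sum()))


# ---------------------------------------------------------------------------
# backpropagation through time
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _backward_kernel(H, U_, R_, N_, Uh, dH, U, U_u, U_r):  # pragma: no cover
    T, m = dH.shape
    da_u = np.empty((T, m))
    da_r = np.empty((T, m))
    da_n = np.empty((T, m))
    dh_next = np.zeros(m)
    for t in range(T - 1, -1, -1):
        dh_prev = np.zeros(m)
        for i in range(m):
            dh = dH[t, i] + dh_next[i]
            u = U_[t, i]
            r = R_[t, i]
            n = N_[t, i]
            dn = dh * (1.0 - u)
            du = dh * (H[t, i] - n)
            an = dn * (1.0 - n * n)
            dr = an * Uh[t, i]
            au = du * u * (1.0 - u)
            ar = dr * r * (1.0 - r)
            da_n[t, i] = an
            da_u[t, i] = au
            da_r[t, i] = ar
            dh_prev[i] += dh * u
            for j in range(m):
                contrib = an * r * U[i, j] + au * U_u[i, j] + ar * U_r[i, j]
                dh_prev[j] += contrib
        dh_next = dh_prev
    return da_u, da_r, da_n, dh_next


def _backward_direction(p: GRULayerParams, X: np.ndarray, cache: dict,
                        dH: np.ndarray, g: GRULayerParams) -> np.ndarray:
    """Backprop one GRU direction (inputs already in scan order).

    ``dH`` holds dLoss/d(hidden state) per scanned position.  Parameter
    gradients accumulate into ``g``; returns dLoss/dX.  The sequential
    time loop runs in a compiled kernel; the per-tensor accumulations are
    single matmuls.
    """
    H, U_, R_, N_, Uh = (cache["H"], cache["u"], cache["r"], cache["n"],
                         cache["Uh"])
    da_u, da_r, da_n, dh0 = _backward_kernel(
        H, U_, R_, N_, Uh, np.ascontiguousarray(dH), p.U, p.U_u, p.U_r)
    H_prev = H[:-1]
    g.W_u += da_u.T @ X
    g.U_u += da_u.T @ H_prev
    g.b_u += da_u.sum(axis=0)
    g.W_r += da_r.T @ X
    g.U_r += da_r.T @ H_prev
    g.b_r += da_r.sum(axis=0)
    g.W += da_n.T @ X
    g.U += (da_n * R_).T @ H_prev
    g.h0 += dh0
    return da_n @ p.W + da_u @ p.W_u + da_r @ p.W_r


def backward(params: NetworkParams, cache: dict,
             targets: np.ndarray) -> NetworkParams:
    """Exact gradient of :func:`sequence_loss` w.r.t. every parameter.

    ``cache`` must come from ``forward(params, X, return_cache=True)`` on
    the same parameters and inputs.
    """
    h_last = cache["h_last"]
    dists = cache["dists"]
    T = h_last.shape[0]
    if targets.shape != (T, 2):
        raise ValidationError("targets length does not match forward cache")
    if len(cache["layers"]) != len(params.layers):
        raise ValidationError("cache does not match parameter layer count")
    grads = params.like_zeros()
    idx = np.arange(T)
    dOut = np.zeros_like(h_last)
    for k, p_k in enumerate((dists.p1, dists.p2)):
        G = p_k.copy()
        G[idx, targets[:, k]] -= 1.0  # softmax cross-entropy logit gradient
        grads.theta[k] = G.T @ h_last
        dOut += G @ params.theta[k]
    for li in range(len(params.layers) - 1, -1, -1):
        layer = params.layers[li]
        c = cache["layers"][li]
        m = len(layer.fwd.h0)
        dX_f = _backward_direction(layer.fwd, c["X"], c["fwd"],
                                   dOut[:, :m], grads.layers[li].fwd)
        dX_b = _backward_direction(layer.bwd, c["X"][::-1], c["bwd"],
                                   dOut[:, m:][::-1], grads.layers[li].bwd)
        dOut = dX_f + dX_b[::-1]
    return grads


def loss_and_grad(params: NetworkParams, X: np.ndarray,
                  targets: np.ndarray) -> tuple[float, NetworkParams]:
    dists, cache = forward(params, X, return_cache=True)
    return sequence_loss(dists, targets), backward(params, cache, targets)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

def sgd_nesterov_step(params: np.ndarray, velocity: np.ndarray,
                      gradient: np.ndarray, learning_rate: float,
                      momentum: float) -> tuple[np.ndarray, np.ndarray]:
    """One Nesterov-momentum update on flat parameter vectors.

    The caller evaluates ``gradient`` at the lookahead point
    ``params + momentum * velocity``; this routine then applies
    ``velocity' = momentum * velocity - lr * gradient`` and
    ``params' = params + velocity'``.  A non-finite gradient skips the step.
    With zero momentum this is plain gradient descent.
    """
    if not np.isfinite(gradient).all():
        logger.warning("non-finite gradient; step skipped")
        return params, velocity
    velocity = momentum * velocity - learning_rate * gradient
    return params + velocity, velocity


def clip_gradient(flat: np.ndarray, max_norm: float) -> np.ndarray:
    norm = float(np.linalg.norm(flat))
    if max_norm > 0 and norm > max_norm:
        return flat * (max_norm / norm)
    return flat


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

@dataclass
class TrainingRead:
    """One 1D training example: raw events plus the oriented reference they
    map to (the genomic fragment for template reads, its reverse complement
    for complement reads)."""

    events: EventSequence
    reference: str


@dataclass
class Training2DRead:
    """One 2D training example: both strands' raw events plus the
    template-oriented fragment."""

    template: EventSequence
    complement: EventSequence
    reference: str


@dataclass
class PreparedRead:
    inputs: np.ndarray      # (n_events_or_columns, input_width)
    target_seq: str         # bases the events must account for
    targets: np.ndarray     # (n, 2) alphabet indices


@dataclass
class TrainResult:
    params: NetworkParams
    loss_history: list[float] = field(default_factory=list)  # mean per event
    n_dropped: int = 0


def fit_network(prepared: list[PreparedRead], input_size: int,
                hidden_sizes: list[int], cfg: TrainConfig) -> TrainResult:
    """Core SGD + realignment loop over prepared reads.

    Deterministic from ``cfg.seed``: initialisation, the per-epoch shuffle
    and every update are driven by one seeded generator.  Returns the
    parameters with the best epoch-mean loss seen.
    """
    if not prepared:
        raise ValidationError("no training reads survived preparation")
    rng = np.random.default_rng(cfg.seed)
    params = NetworkParams.init_random(input_size, hidden_sizes, rng)
    work = params.like_zeros()  # scratch container for lookahead evaluation
    flat = params.pack()
    velocity = np.zeros_like(flat)
    lr = cfg.learning_rate
    n_events_total = sum(len(r.targets) for r in prepared)
    best_loss = np.inf
    best_flat = flat.copy()
    stall = 0
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        total = 0.0
        for ri in order:
            r = prepared[ri]
            work.unpack_(flat + cfg.momentum * velocity)
            loss, grads = loss_and_grad(work, r.inputs, r.targets)
            total += loss
            g = clip_gradient(grads.pack(), cfg.grad_clip)
            flat, velocity = sgd_nesterov_step(flat, velocity, g, lr,
                                               cfg.momentum)
        mean_loss = total / n_events_total
        history.append(mean_loss)
        if mean_loss < best_loss - 1e-12:
            best_loss = mean_loss
            best_flat = flat.copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.stall_epochs:
                lr *= cfg.lr_decay
                stall = 0
                logger.info("epoch %d: loss stalled, lr -> %g", epoch, lr)
        if (epoch + 1) % cfg.realign_every == 0 and (epoch + 1) < cfg.epochs:
            params.unpack_(flat)
            _realign_targets(prepared, params)
    params.unpack_(best_flat)
    return TrainResult(params=params, loss_history=history)


def _realign_targets(prepared: list[PreparedRead],
                     params: NetworkParams) -> None:
    """Rebuild every read's targets from the current network's posteriors."""
    for r in prepared:
        dists = forward(params, r.inputs)
        try:
            aln = realign_posterior(dists, r.target_seq)
        except AlignmentError:
            logger.warning("posterior realignment infeasible; targets kept")
            continue
        r.targets = make_targets(aln, r.target_seq)


def prepare_1d_read(read: TrainingRead, pore_model: PoreModel,
                    penalties=(2.0, 2.0)) -> PreparedRead:
    from .basecall import feature_norm, featurize  # pipeline conventions

    scaled = scale_to_model(read.events, pore_model)
    aln = align_expected_signal(scaled, read.reference, pore_model, penalties)
    start, end = aln.span
    target_seq = read.reference[start:end]
    shifted = EventAlignment(
        intervals=[(s - start, e - start) for s, e in aln.intervals],
        score=aln.score)
    return PreparedRead(inputs=featurize(scaled, feature_norm(pore_model)),
                        target_seq=target_seq,
                        targets=make_targets(shifted, target_seq))


def train_1d(reads: list[TrainingRead], pore_model: PoreModel,
             hidden_sizes: list[int], cfg: TrainConfig,
             penalties=(2.0, 2.0)) -> TrainResult:
    """Train a 1D (single-strand) network.

    All reads must be of the same strand ("we need a separate model for
    each strand"); ``reference`` must already be oriented accordingly.
    Reads whose expected-signal alignment is infeasible are dropped with a
    warning.
    """
    prepared = []
    dropped = 0
    for read in reads:
        try:
            prepared.append(prepare_1d_read(read, pore_model, penalties))
        except (AlignmentError, ValidationError) as exc:
            dropped += 1
            logger.warning("read %s dropped: %s", read.events.read_id, exc)
    result = fit_network(prepared, input_size=3, hidden_sizes=hidden_sizes,
                         cfg=cfg)
    result.n_dropped = dropped
    return result


def prepare_2d_read(read: Training2DRead, template_net: NetworkParams,
                    complement_net: NetworkParams, pore_model: PoreModel,
                    penalties=(2.0, 2.0)) -> PreparedRead:
    """Joint 2D inputs plus initial targets for one paired read.

    The pairing comes from the trained 1D networks' outputs; initial
    targets project the template strand's expected-signal alignment onto
    the pair columns (complement-only columns start as no-base targets).
    """
    from .basecall import build_2d_inputs, feature_norm, featurize

    norm = feature_norm(pore_model)
    t_scaled = scale_to_model(read.template, pore_model)
    c_scaled = scale_to_model(read.complement, pore_model)
    t_feats = featurize(t_scaled, norm)
    c_feats = featurize(c_scaled, norm)
    t_dists = forward(template_net, t_feats)
    c_dists = forward(complement_net, c_feats)
    pair = align_event_pairs(t_dists, orient_complement(c_dists))
    inputs = build_2d_inputs(pair, t_feats, c_feats[::-1])
    t_aln = align_expected_signal(t_scaled, read.reference, pore_model,
                                  penalties)
    start, end = t_aln.span
    target_seq = read.reference[start:end]
    t_labels = [read.reference[s:e] for s, e in t_aln.intervals]
    labels = []
    pos = 0
    for t_idx, _ in pair.columns:
        lab = t_labels[t_idx] if t_idx is not None else ""
        labels.append(lab)
        pos += len(lab)
    col_aln = _labels_to_alignment(labels)
    return PreparedRead(inputs=inputs, target_seq=target_seq,
                        targets=make_targets(col_aln, target_seq))


def _labels_to_alignment(labels: list[str]) -> EventAlignment:
    intervals = []
    pos = 0
    for lab in labels:
        intervals.append((pos, pos + len(lab)))
        pos += len(lab)
    return EventAlignment(intervals=intervals, score=0.0)


def train_2d(reads: list[Training2DRead], template_net: NetworkParams,
             complement_net: NetworkParams, pore_model: PoreModel,
             hidden_sizes: list[int], cfg: TrainConfig,
             penalties=(2.0, 2.0)) -> TrainResult:
    """Train the 2D network on joint template/complement inputs."""
    prepared = []
    dropped = 0
    for read in reads:
        try:
            prepared.append(prepare_2d_read(read, template_net,
                                            complement_net, pore_model,
                                            penalties))
        except (AlignmentError, ValidationError) as exc:
            dropped += 1
            logger.warning("2D read %s dropped: %s",
                           read.template.read_id, exc)
    result = fit_network(prepared, input_size=8, hidden_sizes=hidden_sizes,
                         cfg=cfg)
    result.n_dropped = dropped
    return result
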