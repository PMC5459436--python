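"""Bidirectional gated-recurrent-unit network with a dual-softmax output.

The model maps a sequence of per-event feature vectors to, for every event,
two independent probability distributions over ``{A, C, G, T, -}``.  The two
distributions encode a "bigram" call per event: zero bases (both dashes),
one base (slot 1 is a dash), or two bases.  Greedy decoding takes the argmax
of each slot, so an event contributes at most two bases to the call.

Each layer runs one GRU scan left-to-right and an independent one
right-to-left; their per-position hidden states are concatenated before
feeding the next layer.  The GRU follows the standard gate equations

    u_i = sigmoid(W_u x_i + U_u h_{i-1} + b_u)        (update gate)
    r_i = sigmoid(W_r x_i + U_r h_{i-1} + b_r)        (reset gate)
    n_i = tanh(W x_i + r_i * (U h_{i-1}))             (candidate state)
    h_i = u_i * h_{i-1} + (1 - u_i) * n_i

with the initial state h_0 a trained parameter of each direction.  Note the
candidate has no bias term and the update gate weighs the *previous* state,
conventions this implementation keeps throughout (training differentiates
exactly these equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .io_model import ALPHABET, ValidationError

N_SYMBOLS = len(ALPHABET)  # 5
SYMBOL_INDEX = {c: i for i, c in enumerate(ALPHABET)}

_INIT_SCALE = 0.08  # uniform(-0.08, 0.08) init for weight matrices


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class GRULayerParams:
    """Parameters of one GRU direction: gates, candidate and initial state."""

    W_u: np.ndarray
    U_u: np.ndarray
    b_u: np.ndarray
    W_r: np.ndarray
    U_r: np.ndarray
    b_r: np.ndarray
    W: np.ndarray
    U: np.ndarray
    h0: np.ndarray

    FIELDS = ("W_u", "U_u", "b_u", "W_r", "U_r", "b_r", "W", "U", "h0")

    @classmethod
    def zeros(cls, n_in: int, n_hidden: int) -> "GRULayerParams":
        m, n2, n1 = n_hidden, n_in, n_hidden
        return cls(W_u=np.zeros((m, n2)), U_u=np.zeros((m, n1)), b_u=np.zeros(m),
                   W_r=np.zeros((m, n2)), U_r=np.zeros((m, n1)), b_r=np.zeros(m),
                   W=np.zeros((m, n2)), U=np.zeros((m, n1)), h0=np.zeros(m))

    def check_shapes(self) -> None:
        m = len(self.h0)
        n2 = self.W_u.shape[1]
        for name in ("W_u", "W_r", "W"):
            if getattr(self, name).shape != (m, n2):
                raise ValidationError(f"{name} shape mismatch")
        for name in ("U_u", "U_r", "U"):
            if getattr(self, name).shape != (m, m):
                raise ValidationError(f"{name} shape mismatch")
        for name in ("b_u", "b_r"):
            if getattr(self, name).shape != (m,):
                raise ValidationError(f"{name} shape mismatch")


@dataclass
class BiGRULayer:
    fwd: GRULayerParams
    bwd: GRULayerParams


@dataclass
class NetworkParams:
    """All trainable tensors of a stacked bidirectional GRU base caller.

    ``theta`` has shape ``(2, 5, D)`` where ``D = 2 * hidden_sizes[-1]`` is
    the width of the concatenated final hidden state: one weight vector per
    output slot and symbol.
    """

    input_size: int
    hidden_sizes: list[int]
    layers: list[BiGRULayer] = field(default_factory=list)
    theta: np.ndarray | None = None

    @classmethod
    def zeros(cls, input_size: int, hidden_sizes: list[int]) -> "NetworkParams":
        layers = []
        n_in = input_size
        for m in hidden_sizes:
            layers.append(BiGRULayer(GRULayerParams.zeros(n_in, m),
                                     GRULayerParams.zeros(n_in, m)))
            n_in = 2 * m
        theta = np.zeros((2, N_SYMBOLS, 2 * hidden_sizes[-1]))
        return cls(input_size=input_size, hidden_sizes=list(hidden_sizes),
                   layers=layers, theta=theta)

    @classmethod
    def init_random(cls, input_size: int, hidden_sizes: list[int],
                    rng: np.random.Generator) -> "NetworkParams":
        """Small symmetric init: uniform(-0.08, 0.08) matrices and output
        weights, zero biases and initial states."""
        p = cls.zeros(input_size, hidden_sizes)
        for layer in p.layers:
            for d in (layer.fwd, layer.bwd):
                for name in ("W_u", "U_u", "W_r", "U_r", "W", "U"):
                    arr = getattr(d, name)
                    arr[...] = rng.uniform(-_INIT_SCALE, _INIT_SCALE, arr.shape)
        p.theta[...] = rng.uniform(-_INIT_SCALE, _INIT_SCALE, p.theta.shape)
        return p

    # -- flat-vector view (optimisers, finite differences, serialisation) --

    def named_arrays(self):
        """Deterministically ordered (name, array) pairs; arrays are views."""
        for li, layer in enumerate(self.layers):
            for dname, d in (("fwd", layer.fwd), ("bwd", layer.bwd)):
                for f in GRULayerParams.FIELDS:
                    yield f"layer{li}.{dname}.{f}", getattr(d, f)
        yield "theta", self.theta

    def pack(self) -> np.ndarray:
        return np.concatenate([a.ravel() for _, a in self.named_arrays()])

    def unpack_(self, flat: np.ndarray) -> "NetworkParams":
        """Overwrite parameters in place from a flat vector; returns self."""
        pos = 0
        for _, a in self.named_arrays():
            a[...] = flat[pos:pos + a.size].reshape(a.shape)
            pos += a.size
        if pos != flat.size:
            raise ValidationError(
                f"flat vector has {flat.size} entries, model needs {pos}")
        return self

    def like_zeros(self) -> "NetworkParams":
        return NetworkParams.zeros(self.input_size, self.hidden_sizes)

    def copy(self) -> "NetworkParams":
        return self.like_zeros().unpack_(self.pack())

    @property
    def n_parameters(self) -> int:
        return sum(a.size for _, a in self.named_arrays())


@dataclass
class OutputDistributions:
    """Per-event dual output distributions: arrays of shape (n_events, 5)."""

    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=np.float64)
        self.p2 = np.asarray(self.p2, dtype=np.float64)
        if self.p1.shape != self.p2.shape or self.p1.ndim != 2 \
                or self.p1.shape[1] != N_SYMBOLS:
            raise ValidationError("output distributions must be (n, 5) pairs")

    def __len__(self) -> int:
        return self.p1.shape[0]

    def validate_normalised(self, tol: float = 1e-9) -> None:
        for p in (self.p1, self.p2):
            if (p < 0).any() or np.abs(p.sum(axis=1) - 1.0).max() > tol:
                raise ValidationError("distributions must be normalised")


# ---------------------------------------------------------------------------
# forward computation
# ---------------------------------------------------------------------------

def gru_step(layer: GRULayerParams, h_prev: np.ndarray,
             x: np.ndarray) -> np.ndarray:
    """One GRU update; returns the new hidden state."""
    h_prev = np.asarray(h_prev, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    layer.check_shapes()
    if h_prev.shape != layer.h0.shape or x.shape != (layer.W_u.shape[1],):
        raise ValidationError("gru_step input shapes do not match parameters")
    u = sigmoid(layer.W_u @ x + layer.U_u @ h_prev + layer.b_u)
    r = sigmoid(layer.W_r @ x + layer.U_r @ h_prev + layer.b_r)
    n = np.tanh(layer.W @ x + r * (layer.U @ h_prev))
    return u * h_prev + (1.0 - u) * n


@numba.njit(cache=False)
def _scan_kernel(WuX, WrX, WnX, U_u, U_r, U, h0):  # pragma: no cover - jit
    T, m = WuX.shape
    H = np.empty((T + 1, m))
    U_ = np.empty((T, m))
    R_ = np.empty((T, m))
    N_ = np.empty((T, m))
    Uh = np.empty((T, m))
    H[0] = h0
    for t in range(T):
        hp = H[t]
        for i in range(m):
            au = WuX[t, i]
            ar = WrX[t, i]
            an = 0.0
            for j in range(m):
                au += U_u[i, j] * hp[j]
                ar += U_r[i, j] * hp[j]
                an += U[i, j] * hp[j]
            u = 1.0 / (1.0 + np.exp(-au)) if au >= 0 else \
                np.exp(au) / (1.0 + np.exp(au))
            r = 1.0 / (1.0 + np.exp(-ar)) if ar >= 0 else \
                np.exp(ar) / (1.0 + np.exp(ar))
            n = np.tanh(WnX[t, i] + r * an)
            U_[t, i] = u
            R_[t, i] = r
            N_[t, i] = n
            Uh[t, i] = an
            H[t + 1, i] = u * hp[i] + (1.0 - u) * n
    return H, U_, R_, N_, Uh


def _scan_direction(p: GRULayerParams, X: np.ndarray) -> dict:
    """Run one GRU direction over X (time-major, already in scan order).

    Returns a cache with hidden states H (T+1, m; H[0] = h0) and the gate /
    candidate activations needed by backpropagation.  The input projections
    are one matmul; the sequential recurrence runs in a compiled kernel.
    """
    WuX = X @ p.W_u.T + p.b_u
    WrX = X @ p.W_r.T + p.b_r
    WnX = X @ p.W.T
    H, U_, R_, N_, Uh = _scan_kernel(
        np.ascontiguousarray(WuX), np.ascontiguousarray(WrX),
        np.ascontiguousarray(WnX), p.U_u, p.U_r, p.U, p.h0)
    return {"H": H, "u": U_, "r": R_, "n": N_, "Uh": Uh}


def output_probabilities(h_last: np.ndarray, theta: np.ndarray):
    """Dual softmax over the final concatenated hidden states.

    ``h_last`` is (n_events, D) (a single vector is also accepted); returns
    :class:`OutputDistributions`.  Logits are max-shifted before
    exponentiation for overflow safety.
    """
    h = np.atleast_2d(np.asarray(h_last, dtype=np.float64))
    if theta.shape != (2, N_SYMBOLS, h.shape[1]):
        raise ValidationError("theta shape does not match hidden state width")
    probs = []
    for k in range(2):
        logits = h @ theta[k].T  # (n, 5)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs.append(e / e.sum(axis=1, keepdims=True))
    return OutputDistributions(p1=probs[0], p2=probs[1])


def forward(params: NetworkParams, inputs: np.ndarray,
            return_cache: bool = False):
    """Full network forward pass.

    ``inputs`` is (n_events, input_size).  Returns OutputDistributions, or
    ``(dists, cache)`` when ``return_cache`` — the cache carries every
    intermediate needed for exact backpropagation.
    """
    X = np.asarray(inputs, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.input_size:
        raise ValidationError(
            f"inputs must be (n, {params.input_size}), got {X.shape}")
    if X.shape[0] == 0:
        raise ValidationError("forward requires a non-empty input sequence")
    layer_caches = []
    cur = X
    for layer in params.layers:
        fwd_cache = _scan_direction(layer.fwd, cur)
        bwd_cache = _scan_direction(layer.bwd, cur[::-1])
        out = np.concatenate([fwd_cache["H"][1:], bwd_cache["H"][1:][::-1]],
                             axis=1)
        layer_caches.append({"X": cur, "fwd": fwd_cache, "bwd": bwd_cache})
        cur = out
    dists = output_probabilities(cur, params.theta)
    if return_cache:
        return dists, {"layers": layer_caches, "h_last": cur, "dists": dists}
    return dists


def decode(dists: OutputDistributions) -> str:
    """Greedy call: per event append argmax of slot 1 then slot 2, skipping
    dashes.  ``np.argmax`` returns the first maximum, so ties resolve in
    fixed alphabet order A < C < G < T < -.
    """
    out = []
    a1 = np.argmax(dists.p1, axis=1)
    a2 = np.argmax(dists.p2, axis=1)
    dash = SYMBOL_INDEX["-"]
    for i1, i2 in zip(a1, a2):
        if i1 != dash:
            out.append(ALPHABET[i1])
        if i2 != dash:
            out.append(ALPHABET[i2])
    return "".join(out)
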