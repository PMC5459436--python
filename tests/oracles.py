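"""Independent reference implementations used only by the tests.

Everything here is deliberately naive — scalar loops and exhaustive
enumeration — and shares no code with the package's vectorised / dynamic
programming implementations it cross-checks.
"""

import math

ALPHABET = "ACGT-"


# ---------------------------------------------------------------------------
# scalar-loop GRU
# ---------------------------------------------------------------------------

def _sig(z):
    return 1.0 / (1.0 + math.exp(-z))


def _matvec(M, v):
    return [sum(M[i][j] * v[j] for j in range(len(v))) for i in range(len(M))]


def oracle_gru_step(W_u, U_u, b_u, W_r, U_r, b_r, W, U, h_prev, x):
    """Elementwise GRU update from the four gate formulas."""
    m = len(h_prev)
    wu, uu = _matvec(W_u, x), _matvec(U_u, h_prev)
    wr, ur = _matvec(W_r, x), _matvec(U_r, h_prev)
    wn, un = _matvec(W, x), _matvec(U, h_prev)
    h = []
    for i in range(m):
        u = _sig(wu[i] + uu[i] + b_u[i])
        r = _sig(wr[i] + ur[i] + b_r[i])
        n = math.tanh(wn[i] + r * un[i])
        h.append(u * h_prev[i] + (1.0 - u) * n)
    return h


def _layer_as_lists(p):
    return (p.W_u.tolist(), p.U_u.tolist(), p.b_u.tolist(),
            p.W_r.tolist(), p.U_r.tolist(), p.b_r.tolist(),
            p.W.tolist(), p.U.tolist())


def oracle_forward(params, inputs):
    """Scalar re-implementation of the stacked bidirectional forward pass.

    Returns (p1, p2) as nested lists, one 5-vector per event and slot.
    """
    cur = [list(map(float, row)) for row in inputs]
    T = len(cur)
    for layer in params.layers:
        states = {}
        for direction, order in (("fwd", range(T)),
                                 ("bwd", range(T - 1, -1, -1))):
            p = getattr(layer, direction)
            mats = _layer_as_lists(p)
            h = list(map(float, p.h0))
            for t in order:
                h = oracle_gru_step(*mats, h, cur[t])
                states[(direction, t)] = h
        cur = [states[("fwd", t)] + states[("bwd", t)] for t in range(T)]
    out = ([], [])
    for t in range(T):
        for k in range(2):
            logits = [sum(params.theta[k][q][d] * cur[t][d]
                          for d in range(len(cur[t]))) for q in range(5)]
            mx = max(logits)
            exps = [math.exp(z - mx) for z in logits]
            s = sum(exps)
            out[k].append([e / s for e in exps])
    return out


# ---------------------------------------------------------------------------
# exhaustive alignment enumerations
# ---------------------------------------------------------------------------

def enumerate_signal_alignment(means, levels, split_pen, skip_pen):
    """Minimum cost over all monotone event-to-context alignments.

    Moves mirror the expected-signal DP: diagonal, split (+split_pen, no
    context advance), skip (+skip_pen, two contexts).  All contexts must be
    consumed.  Returns math.inf when infeasible.
    """
    n, M = len(means), len(levels)

    def best(i, j):
        if i == n:
            return 0.0 if j == M else math.inf
        opts = []
        if j < M:
            c = abs(levels[j] - means[i])
            opts.append(c + best(i + 1, j + 1))
            if j + 1 < M:
                opts.append(abs(levels[j + 1] - means[i]) + skip_pen
                            + best(i + 1, j + 2))
        if j >= 1:
            opts.append(abs(levels[j - 1] - means[i]) + split_pen
                        + best(i + 1, j))
        return min(opts) if opts else math.inf

    return best(0, 0)


def enumerate_posterior_alignment(p1, p2, reference):
    """Maximum summed log probability over all 0/1/2-base emissions."""
    n, m = len(p1), len(reference)
    sym = {c: i for i, c in enumerate(ALPHABET)}
    ref = [sym[c] for c in reference]
    dash = sym["-"]

    def lg(p):
        return math.log(max(p, 1e-300))

    def best(i, j):
        if i == n:
            return 0.0 if j == m else -math.inf
        opts = [lg(p1[i][dash]) + lg(p2[i][dash]) + best(i + 1, j)]
        if j < m:
            opts.append(lg(p1[i][dash]) + lg(p2[i][ref[j]]) + best(i + 1, j + 1))
        if j + 1 < m:
            opts.append(lg(p1[i][ref[j]]) + lg(p2[i][ref[j + 1]])
                        + best(i + 1, j + 2))
        return max(opts)

    return best(0, 0)


def enumerate_pair_alignment(score_matrix, n, m, gap):
    """Maximum score over all monotone pairings with per-event gaps."""

    def best(i, j):
        if i == n and j == m:
            return 0.0
        opts = []
        if i < n and j < m:
            opts.append(score_matrix[i][j] + best(i + 1, j + 1))
        if i < n:
            opts.append(gap + best(i + 1, j))
        if j < m:
            opts.append(gap + best(i, j + 1))
        return max(opts)

    return best(0, 0)


def enumerate_global_alignment(a, b):
    """Maximum global-alignment score, match +1 / mismatch -1 / gap -1."""

    def best(i, j):
        if i == len(a) and j == len(b):
            return 0
        opts = []
        if i < len(a) and j < len(b):
            opts.append((1 if a[i] == b[j] else -1) + best(i + 1, j + 1))
        if i < len(a):
            opts.append(-1 + best(i + 1, j))
        if j < len(b):
            opts.append(-1 + best(i, j + 1))
        return max(opts)

    return best(0, 0)
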