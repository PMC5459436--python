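"""Dynamic programs for event-level and sequence-level alignment.

Four alignments drive training, 2D calling and evaluation:

* :func:`align_expected_signal` — initial training alignment: match observed
  (scaled) event means against the expected signal simulated from a
  reference with a pore model, minimising absolute mean differences with
  fixed penalties for split (event consumes no new context) and skip (event
  consumes two contexts) moves.
* :func:`realign_posterior` — EM-style realignment: given the network's
  per-event dual output distributions, find the monotone assignment of 0–2
  reference bases per event maximising the summed log probabilities.
* :func:`align_event_pairs` — template/complement event pairing for 2D
  calling, maximising the log expected agreement of paired output
  distributions with a per-gap penalty.
* :func:`align_sequences` — global Needleman–Wunsch alignment of a called
  sequence against the truth; accuracy = matches / alignment length.

All scores use natural logarithms.  Reference coordinates are 0-based,
half-open throughout.  Each DP has a brute-force-verifiable optimal
substructure; tie-breaks are fixed and documented per function so results
are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_model import EventSequence, PoreModel, ValidationError
from .network import SYMBOL_INDEX, OutputDistributions

_LOG_FLOOR = 1e-300  # probabilities are clipped here before log

DEFAULT_SPLIT_PENALTY = 2.0  # signal units, expected-signal DP
DEFAULT_SKIP_PENALTY = 2.0
DEFAULT_GAP_LOG = math.log(0.1)  # per unpaired event, 2D pairing DP

_DASH = SYMBOL_INDEX["-"]


class AlignmentError(ValidationError):
    """No feasible alignment exists for the given inputs."""


@dataclass
class EventAlignment:
    """Monotone assignment of 0–2 reference bases to each event.

    ``intervals[i]`` is the half-open reference range event *i* accounts
    for; empty intervals mark split events.  Intervals are non-decreasing
    and contiguous over the aligned reference region.
    """

    intervals: list[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        prev = None
        for s, e in self.intervals:
            if not 0 <= e - s <= 2:
                raise ValidationError("each event aligns 0-2 bases")
            if prev is not None and s != prev:
                raise ValidationError("intervals must be contiguous")
            prev = e

    def labels(self, reference: str) -> list[str]:
        return [reference[s:e] for s, e in self.intervals]

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]


@dataclass
class PairAlignment:
    """Columns pairing template with complement event indices; ``None``
    marks a gap.  Indices are strictly increasing along each strand and no
    column is all-gap."""

    columns: list[tuple[int | None, int | None]]
    score: float

    def __post_init__(self) -> None:
        last_t = last_c = -1
        for t, c in self.columns:
            if t is None and c is None:
                raise ValidationError("column with two gaps")
            if t is not None:
                if t <= last_t:
                    raise ValidationError("template indices must increase")
                last_t = t
            if c is not None:
                if c <= last_c:
                    raise ValidationError("complement indices must increase")
                last_c = c


# ---------------------------------------------------------------------------
# expected-signal alignment
# ---------------------------------------------------------------------------

def align_expected_signal(scaled_events: EventSequence, reference: str,
                          model: PoreModel,
                          penalties: tuple[float, float] = (
                              DEFAULT_SPLIT_PENALTY, DEFAULT_SKIP_PENALTY),
                          ) -> EventAlignment:
    """Minimum-cost monotone alignment of events to reference contexts.

    Moves from event *i*, context *j* (both 1-based counts consumed):
    diagonal (event i matches context j) costs ``|level_j - mean_i|``;
    split (event i re-reads context j) adds ``split_penalty``; skip (event i
    lands on context j having jumped context j-1) adds ``skip_penalty``,
    with the signal cost taken against the farther (landing) context.  The
    whole reference (every context) must be consumed.  Ties prefer
    diagonal, then split, then skip.

    Each diagonal event is assigned the base entering its context (the last
    base of the k-mer window); a skip event gets that base plus the jumped
    context's, a split event zero bases — so the first ``k - 1`` reference
    bases are never assigned (context priming).
    """
    split_pen, skip_pen = penalties
    if len(reference) < model.k:
        raise AlignmentError("reference shorter than pore-model k")
    levels = model.expected_means(reference)
    means = scaled_events.mean
    n, M = len(means), len(levels)
    if n == 0 or M == 0:
        raise AlignmentError("empty events or reference")
    if M > 2 * n:
        raise AlignmentError(
            f"{n} events cannot consume {M} contexts (max 2 per event)")
    cost = np.abs(levels[None, :] - means[:, None])  # (n, M)
    INF = np.inf
    D_prev = np.full(M + 1, INF)
    D_prev[0] = 0.0
    choice = np.empty((n, M), dtype=np.uint8)  # 0 diag, 1 split, 2 skip
    for i in range(n):
        diag = D_prev[:-1]
        split = D_prev[1:] + split_pen
        skip = np.full(M, INF)
        skip[1:] = D_prev[:-2] + skip_pen
        cands = np.stack([diag, split, skip])
        arg = cands.argmin(axis=0)  # ties -> lowest index = preferred move
        D_cur = np.full(M + 1, INF)
        D_cur[1:] = cost[i] + cands[arg, np.arange(M)]
        choice[i] = arg
        D_prev = D_cur
    if not np.isfinite(D_prev[M]):
        raise AlignmentError("no feasible expected-signal alignment")
    # traceback
    k = model.k
    intervals: list[tuple[int, int]] = []
    i, j = n, M
    while i > 0:
        mv = choice[i - 1][j - 1]
        base_end = j + k - 1  # ref index one past the entering base of ctx j
        if mv == 0:
            intervals.append((base_end - 1, base_end))
            j -= 1
        elif mv == 1:
            intervals.append((base_end, base_end))
        else:
            intervals.append((base_end - 2, base_end))
            j -= 2
        i -= 1
    intervals.reverse()
    return EventAlignment(intervals=intervals, score=float(D_prev[M]))


# ---------------------------------------------------------------------------
# posterior realignment
# ---------------------------------------------------------------------------

def realign_posterior(dists: OutputDistributions,
                      reference: str) -> EventAlignment:
    """Maximum log-probability assignment of 0–2 reference bases per event.

    An event emitting zero bases scores ``ln P1(-) + ln P2(-)``; one base b
    scores ``ln P1(-) + ln P2(b)`` (the one-base-per-event convention puts
    the base in slot 2); two bases b1 b2 score ``ln P1(b1) + ln P2(b2)``.
    The full reference must be consumed.  Ties prefer one base, then zero,
    then two.
    """
    n = len(dists)
    m = len(reference)
    if m == 0:
        raise AlignmentError("empty reference")
    if m > 2 * n:
        raise AlignmentError(
            f"reference of {m} bases infeasible for {n} events")
    L1 = np.log(np.clip(dists.p1, _LOG_FLOOR, None))
    L2 = np.log(np.clip(dists.p2, _LOG_FLOOR, None))
    ref_idx = np.array([SYMBOL_INDEX[c] for c in reference])
    NEG = -np.inf
    S_prev = np.full(m + 1, NEG)
    S_prev[0] = 0.0
    choice = np.empty((n, m + 1), dtype=np.uint8)  # 0 one-base, 1 zero, 2 two
    for i in range(n):
        e0 = L1[i, _DASH] + L2[i, _DASH]
        e1 = np.full(m + 1, NEG)
        e1[1:] = L1[i, _DASH] + L2[i, ref_idx]
        e2 = np.full(m + 1, NEG)
        if m >= 2:
            e2[2:] = L1[i, ref_idx[:-1]] + L2[i, ref_idx[1:]]
        one = np.full(m + 1, NEG)
        one[1:] = S_prev[:-1] + e1[1:]
        zero = S_prev + e0
        two = np.full(m + 1, NEG)
        if m >= 2:
            two[2:] = S_prev[:-2] + e2[2:]
        cands = np.stack([one, zero, two])
        arg = cands.argmax(axis=0)
        S_prev = cands[arg, np.arange(m + 1)]
        choice[i] = arg
    if not np.isfinite(S_prev[m]):
        raise AlignmentError("no feasible posterior realignment")
    intervals: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0:
        mv = choice[i - 1][j]
        if mv == 0:
            intervals.append((j - 1, j))
            j -= 1
        elif mv == 1:
            intervals.append((j, j))
        else:
            intervals.append((j - 2, j))
            j -= 2
        i -= 1
    intervals.reverse()
    return EventAlignment(intervals=intervals, score=float(S_prev[m]))


# ---------------------------------------------------------------------------
# template/complement event pairing
# ---------------------------------------------------------------------------

def orient_complement(dists: OutputDistributions) -> OutputDistributions:
    """Map complement-strand output distributions into template orientation.

    Event order is reversed; base probabilities are complement-swapped
    (A<->T, C<->G, dash fixed); and the two output slots swap, since
    reversing the read also reverses the base order within an event.
    """
    perm = [SYMBOL_INDEX[c] for c in "TGCA-"]  # complement of A C G T -
    return OutputDistributions(p1=dists.p2[::-1][:, perm],
                               p2=dists.p1[::-1][:, perm])


def align_event_pairs(template_dists: OutputDistributions,
                      complement_dists: OutputDistributions,
                      gap_log: float = DEFAULT_GAP_LOG) -> PairAlignment:
    """Pair template with (template-oriented) complement events.

    A paired column scores ``ln sum_q Pt1(q) Pc1(q) + ln sum_q Pt2(q) Pc2(q)``
    (log expected agreement over both output slots); an unpaired event
    scores ``gap_log`` (the strand's own probability mass is 1, so only the
    penalty remains).  Ties prefer pairing, then a template gap-column, then
    a complement one.
    """
    n, m = len(template_dists), len(complement_dists)
    if n == 0 and m == 0:
        return PairAlignment(columns=[], score=0.0)
    if n == 0:
        return PairAlignment(columns=[(None, j) for j in range(m)],
                             score=m * gap_log)
    if m == 0:
        return PairAlignment(columns=[(i, None) for i in range(n)],
                             score=n * gap_log)
    pair_score = (np.log(np.clip(template_dists.p1 @ complement_dists.p1.T,
                                 _LOG_FLOOR, None))
                  + np.log(np.clip(template_dists.p2 @ complement_dists.p2.T,
                                   _LOG_FLOOR, None)))
    M = np.empty((n + 1, m + 1))
    back = np.empty((n + 1, m + 1), dtype=np.uint8)  # 0 pair, 1 up, 2 left
    M[0, :] = np.arange(m + 1) * gap_log
    M[:, 0] = np.arange(n + 1) * gap_log
    back[0, :] = 2
    back[:, 0] = 1
    for i in range(1, n + 1):
        Mi = M[i]
        Mp = M[i - 1]
        row = pair_score[i - 1]
        for j in range(1, m + 1):
            pair = Mp[j - 1] + row[j - 1]
            up = Mp[j] + gap_log
            left = Mi[j - 1] + gap_log
            if pair >= up and pair >= left:
                Mi[j] = pair
                back[i, j] = 0
            elif up >= left:
                Mi[j] = up
                back[i, j] = 1
            else:
                Mi[j] = left
                back[i, j] = 2
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        b = back[i, j]
        if b == 0:
            cols.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif b == 1:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return PairAlignment(columns=cols, score=float(M[n, m]))


# ---------------------------------------------------------------------------
# sequence alignment for evaluation
# ---------------------------------------------------------------------------

@dataclass
class SequenceAlignment:
    a_aligned: str  # gaps as '-'
    b_aligned: str
    score: int
    matches: int

    @property
    def length(self) -> int:
        return len(self.a_aligned)

    @property
    def accuracy(self) -> float:
        return self.matches / self.length


def align_sequences(called: str, truth: str
                    ) -> tuple[SequenceAlignment, float]:
    """Global alignment, match +1 / mismatch -1 / gap -1.

    Ties prefer the diagonal move (match before mismatch is implied by the
    scores), then the gap consuming ``called`` (up), then ``truth`` (left).
    Returns the alignment and ``matches / alignment length``.
    """
    if not called or not truth:
        raise ValidationError("align_sequences requires non-empty strings")
    n, m = len(called), len(truth)
    a = np.frombuffer(called.encode(), dtype=np.uint8)
    b = np.frombuffer(truth.encode(), dtype=np.uint8)
    M = np.empty((n + 1, m + 1), dtype=np.int64)
    back = np.empty((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    M[0, :] = -np.arange(m + 1)
    M[:, 0] = -np.arange(n + 1)
    back[0, :] = 2
    back[:, 0] = 1
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], 1, -1)
        Mp = M[i - 1]
        Mi = M[i]
        for j in range(1, m + 1):
            diag = Mp[j - 1] + sub[j - 1]
            up = Mp[j] - 1
            left = Mi[j - 1] - 1
            if diag >= up and diag >= left:
                Mi[j] = diag
                back[i, j] = 0
            elif up >= left:
                Mi[j] = up
                back[i, j] = 1
            else:
                Mi[j] = left
                back[i, j] = 2
    out_a: list[str] = []
    out_b: list[str] = []
    matches = 0
    i, j = n, m
    while i > 0 or j > 0:
        mv = back[i, j]
        if mv == 0:
            out_a.append(called[i - 1])
            out_b.append(truth[j - 1])
            matches += called[i - 1] == truth[j - 1]
            i -= 1
            j -= 1
        elif mv == 1:
            out_a.append(called[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(truth[j - 1])
            j -= 1
    aln = SequenceAlignment(a_aligned="".join(reversed(out_a)),
                            b_aligned="".join(reversed(out_b)),
                            score=int(M[n, m]), matches=matches)
    return aln, aln.accuracy
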